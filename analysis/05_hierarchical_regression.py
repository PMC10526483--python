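"""Down-scaling regression cascade over the student cohort.

Fits AI ~ age + pedagogy + sex + SES + age x pedagogy at the whole-brain
level; if the omnibus F-test is significant, descends to the four
classical lobes (BH-FDR within each term's family of four); each
significant lobe then gates its own subregions (family = sibling count).
Writes results/hierarchy_models.tsv, hierarchy_records.tsv, report.txt.
"""

from pathlib import Path

from cthasym import hierarchical_downscale
from cthasym.asymmetry import read_ai_table
from cthasym.io import read_demographics
from cthasym.pipeline import models_frame, render_model_report

OUT = Path(__file__).resolve().parents[1] / "results"


def main(outdir: Path = OUT) -> None:
    ai = read_ai_table(outdir / "ai_table.tsv")
    demo = read_demographics(outdir / "demographics.tsv")
    result = hierarchical_downscale(ai, demo)
    models_frame(result).to_csv(outdir / "hierarchy_models.tsv", sep="\t", index=False)
    result.records().to_csv(outdir / "hierarchy_records.tsv", sep="\t", index=False)
    (outdir / "report.txt").write_text(render_model_report(result))
    for stage in result.stages:
        opened = sorted(r for r, ok in stage.gate_open.items() if ok)
        print(f"{stage.level}: gates open -> {opened or 'none'}")
    sub = next((s for s in result.stages if s.level == "subregion"), None)
    if sub is not None:
        for m in sub.models:
            if sub.gate_open.get(m.region):
                t = m.term("age_x_pedagogy")
                print(f"  {m.region}: age x pedagogy beta = {t.beta:.3g}, "
                      f"p = {t.p:.3f}")


if __name__ == "__main__":
    main()
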