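"""Whole-brain asymmetry: students vs adults.

Tests whether whole-brain cortical-thickness asymmetry differs between the
student and adult groups (pooled t-test) and whether age modulates it
(ANCOVA on group + age + group x age). The developmental expectation is a
null result: hemispheres stay globally symmetric across age. Writes
results/adults_vs_students.json.
"""

import dataclasses
import json
from pathlib import Path

from cthasym import students_vs_adults
from cthasym.asymmetry import read_ai_table
from cthasym.io import read_demographics

OUT = Path(__file__).resolve().parents[1] / "results"


def main(outdir: Path = OUT) -> None:
    ai = read_ai_table(outdir / "ai_table.tsv")
    demo = read_demographics(outdir / "demographics.tsv")
    comp = students_vs_adults(ai, demo)
    payload = dataclasses.asdict(comp)
    payload["ancova"] = comp.ancova.to_dict(orient="records")
    (outdir / "adults_vs_students.json").write_text(json.dumps(payload, indent=2))
    for group in ("student", "adult"):
        w, p = comp.shapiro[group]
        print(f"{group}: mean AI {comp.group_means[group]:.3g} "
              f"(sd {comp.group_sds[group]:.3g}); Shapiro-Wilk p = {p:.2f}")
    print(f"t({comp.df}) = {comp.t:.2f}, p = {comp.p:.3f}, d = {comp.cohens_d:.2f}")
    for row in comp.ancova.itertuples():
        print(f"ANCOVA {row.term}: F(1, {row.df_den}) = {row.F:.2f}, p = {row.p:.3f}")


if __name__ == "__main__":
    main()
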