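"""Check that the two pedagogy groups are demographically comparable.

Pooled t-tests on age, SES, fluid intelligence and home environment;
Pearson chi-squared on sex and handedness. A flagged row would mean the
pedagogy contrast is confounded. Writes results/homogeneity.tsv.
"""

from pathlib import Path

from cthasym import homogeneity_tests
from cthasym.io import read_demographics

OUT = Path(__file__).resolve().parents[1] / "results"


def main(outdir: Path = OUT) -> None:
    demo = read_demographics(outdir / "demographics.tsv")
    table = homogeneity_tests(demo)
    table.to_csv(outdir / "homogeneity.tsv", sep="\t", index=False)
    print(table.to_string(index=False,
                          float_format=lambda v: f"{v:.3g}"))
    flagged = table.loc[table["flagged"], "variable"].tolist()
    print("flagged imbalances:", flagged or "none — groups are comparable")


if __name__ == "__main__":
    main()
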