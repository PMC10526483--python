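import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import cthasym as c

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def lobe_map():
    return c.default_lobe_map()


def make_uniform_cohort(subject_id="s1", cth=2.5, csa=100.0, left_scale=1.0):
    """One subject, all 34 ROIs, right cth fixed and left scaled by a factor."""
    rows = []
    for roi in c.DK_LABELS:
        rows.append((subject_id, "left", roi, cth * left_scale, csa))
        rows.append((subject_id, "right", roi, cth, csa))
    return pd.DataFrame(rows, columns=["subject_id", "hemisphere", "roi", "cth", "csa"])


@pytest.fixture()
def mirrored_cohort():
    return make_uniform_cohort()


@pytest.fixture(scope="session")
def default_cohort():
    """Study-shaped synthetic cohort (111 students + 51 adults), fixed seed."""
    demo, morph = c.generate_cohort(c.GeneratorConfig.default(), seed=1270)
    return demo, morph


@pytest.fixture(scope="session")
def default_ai(default_cohort):
    _, morph = default_cohort
    return c.compute_ai_table(morph)


def aparc_stats_text(rows, colheaders="StructName NumVert SurfArea GrayVol ThickAvg ThickStd"):
    """Minimal aparc-stats dialect fixture; rows are (name, area, thick)."""
    lines = [
        "# Table of FreeSurfer cortical parcellation anatomical statistics",
        "# anything else is a comment",
        f"# ColHeaders {colheaders}",
    ]
    for name, area, thick in rows:
        lines.append(f"{name} 1234 {area} 2345 {thick} 0.5")
    return "\n".join(lines) + "\n"
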