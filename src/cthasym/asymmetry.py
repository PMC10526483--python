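"""Surface-area-weighted thickness and the asymmetry index.

For a set of ROIs R with mean thickness CTh_R (mm) and pial surface area
CSA_R (mm^2), the weighted cortical thickness is

    WCTh = sum_R CTh_R * CSA_R / sum_R CSA_R

computed per hemisphere over a lobe's ROIs, or over all ROIs for the whole
brain. The asymmetry index of a region is

    AI = (WCTh_lh - WCTh_rh) / (WCTh_lh + WCTh_rh)

a dimensionless value in (-1, 1); positive means a thicker left cortex
(leftward asymmetry). The AI is computed top-down at three anatomical
levels: whole brain, the six lobes, and each of the 34 subregions (where
the weighting degenerates to the single ROI's thickness).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .atlas import LobeMap, default_lobe_map
from .errors import DomainError, ValidationError

log = logging.getLogger(__name__)

AI_COLUMNS = ["subject_id", "level", "region", "ai", "wcth_left", "wcth_right"]


def weighted_cth(regions: Iterable[tuple[float, float]]) -> float:
    """Surface-area-weighted mean thickness of a set of (cth, csa) pairs.

    Bounded by the min and max input thickness; reduces to the plain mean
    for equal areas and to the identity for a single region.
    """
    arr = np.asarray(list(regions), dtype=float)
    if arr.size == 0:
        raise DomainError("weighted_cth of an empty region set")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("expected (cth, csa) pairs")
    cth, csa = arr[:, 0], arr[:, 1]
    if (cth <= 0).any():
        raise ValidationError("non-positive thickness")
    if (csa <= 0).any():
        raise ValidationError("non-positive surface area")
    return float(np.dot(cth, csa) / csa.sum())


def asymmetry_index(wcth_left, wcth_right):
    """(L - R) / (L + R); positive = leftward. Accepts scalars or arrays."""
    l = np.asarray(wcth_left, dtype=float)
    r = np.asarray(wcth_right, dtype=float)
    if (l <= 0).any() or (r <= 0).any():
        raise DomainError("weighted thickness must be positive")
    out = (l - r) / (l + r)
    return float(out) if out.ndim == 0 else out


def _paired(cohort: pd.DataFrame, lobe_map: LobeMap) -> pd.DataFrame:
    """Wide per-(subject, roi) frame with both hemispheres; unpaired dropped."""
    known = cohort["roi"].isin(set(lobe_map.rois))
    unknown = cohort.loc[~known, "roi"].unique()
    if len(unknown):
        log.warning("ignoring %d ROI label(s) absent from the lobe map: %s",
                    len(unknown), sorted(unknown)[:5])
    df = cohort[known]
    wide = df.pivot_table(
        index=["subject_id", "roi"],
        columns="hemisphere",
        values=["cth", "csa"],
        aggfunc="first",
    )
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    for col in ("cth_left", "cth_right", "csa_left", "csa_right"):
        if col not in wide.columns:
            wide[col] = np.nan
    unpaired = wide[wide[["cth_left", "cth_right"]].isna().any(axis=1)]
    if len(unpaired):
        log.warning(
            "omitting %d subject/ROI pair(s) lacking a hemisphere counterpart "
            "(e.g. %s)", len(unpaired), unpaired.index[0],
        )
        wide = wide.drop(unpaired.index)
    wide = wide.reset_index()
    wide["lobe"] = wide["roi"].map(lobe_map.lobe_of)
    return wide


def _aggregate(wide: pd.DataFrame, by: Sequence[str], level: str,
               region_from: str | None) -> pd.DataFrame:
    g = wide.assign(
        num_l=wide["cth_left"] * wide["csa_left"],
        num_r=wide["cth_right"] * wide["csa_right"],
    ).groupby(list(by), as_index=False)[["num_l", "num_r", "csa_left", "csa_right"]].sum()
    g["wcth_left"] = g["num_l"] / g["csa_left"]
    g["wcth_right"] = g["num_r"] / g["csa_right"]
    g["ai"] = asymmetry_index(g["wcth_left"].to_numpy(), g["wcth_right"].to_numpy())
    g["level"] = level
    g["region"] = g[region_from] if region_from else "whole_brain"
    return g[AI_COLUMNS]


def compute_ai_table(cohort: pd.DataFrame, lobe_map: LobeMap | None = None) -> pd.DataFrame:
    """Per-subject AI at whole-brain, lobe and subregion level.

    ``cohort`` is a morphometry long table (subject_id, hemisphere, roi,
    cth, csa). Subject/ROI pairs missing one hemisphere are omitted from
    every level with a logged warning. Returns an AI long table with one
    whole-brain row, up to six lobe rows and up to 34 subregion rows per
    subject.
    """
    if lobe_map is None:
        lobe_map = default_lobe_map()
    if cohort.empty:
        raise DomainError("empty cohort")
    wide = _paired(cohort, lobe_map)
    if wide.empty:
        raise DomainError("no subject has bilateral measurements")
    subregion = pd.DataFrame(
        {
            "subject_id": wide["subject_id"],
            "level": "subregion",
            "region": wide["roi"],
            "ai": asymmetry_index(wide["cth_left"].to_numpy(), wide["cth_right"].to_numpy()),
            "wcth_left": wide["cth_left"],
            "wcth_right": wide["cth_right"],
        }
    )
    lobe = _aggregate(wide, ["subject_id", "lobe"], "lobe", "lobe")
    whole = _aggregate(wide, ["subject_id"], "whole_brain", None)
    out = pd.concat([whole, lobe, subregion], ignore_index=True)
    return out[AI_COLUMNS].reset_index(drop=True)


def write_ai_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df[AI_COLUMNS].to_csv(path, sep=sep, index=False)


def read_ai_table(path) -> pd.DataFrame:
    from .io import _sniff_sep

    df = pd.read_csv(path, sep=_sniff_sep(Path(path)), float_precision="round_trip")
    missing = [c for c in AI_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"AI table missing column(s) {missing}")
    df["subject_id"] = df["subject_id"].astype(str)
    return df[AI_COLUMNS]
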