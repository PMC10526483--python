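"""Readers and writers for regional morphometry and demographics tables.

Two on-disk dialects are supported for per-hemisphere regional statistics:

* the FreeSurfer ``?h.aparc.stats`` text dialect (``#`` comment lines, a
  ``# ColHeaders ...`` line naming the body columns, whitespace-delimited
  rows), one file per subject/hemisphere;
* a long-format delimited table (TSV or CSV, auto-detected) with columns
  ``subject_id, hemisphere, roi, cth, csa`` covering a whole cohort.

Both load into the same cohort DataFrame, which is what the asymmetry and
inference layers consume. Demographics travel as a delimited table with
empty fields for missing values.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import FormatError, ValidationError

MORPH_COLUMNS = ["subject_id", "hemisphere", "roi", "cth", "csa"]
HEMISPHERES = ("left", "right")
_HEMI_ALIASES = {
    "left": "left",
    "lh": "left",
    "l": "left",
    "right": "right",
    "rh": "right",
    "r": "right",
}

DEMOGRAPHIC_COLUMNS = [
    "subject_id",
    "group",
    "pedagogy",
    "age",
    "sex",
    "handedness",
    "ses",
    "fiv",
    "hev",
]

# Sanity bounds for human cortex, mm.
_CTH_MAX = 10.0


def _validate_morphometry(df: pd.DataFrame, source: str) -> pd.DataFrame:
    bad = df[(df["cth"] <= 0) | (df["cth"] >= _CTH_MAX)]
    if len(bad):
        row = bad.iloc[0]
        raise ValidationError(
            f"{source}: thickness out of (0, {_CTH_MAX}) mm for "
            f"{row['subject_id']}/{row['hemisphere']}/{row['roi']}: {row['cth']}"
        )
    bad = df[df["csa"] <= 0]
    if len(bad):
        row = bad.iloc[0]
        raise ValidationError(
            f"{source}: non-positive surface area for "
            f"{row['subject_id']}/{row['hemisphere']}/{row['roi']}: {row['csa']}"
        )
    dupes = df.duplicated(subset=["subject_id", "hemisphere", "roi"])
    if dupes.any():
        row = df[dupes].iloc[0]
        raise ValidationError(
            f"{source}: duplicate (subject, hemisphere, roi) triple "
            f"({row['subject_id']}, {row['hemisphere']}, {row['roi']})"
        )
    return df.reset_index(drop=True)


def normalize_hemisphere(token: str) -> str:
    try:
        return _HEMI_ALIASES[str(token).strip().lower()]
    except KeyError:
        raise FormatError(f"unknown hemisphere token {token!r}") from None


def read_aparc_stats(path: str | Path, subject_id: str, hemisphere: str) -> pd.DataFrame:
    """Parse one FreeSurfer ``?h.aparc.stats`` file into morphometry records.

    Column positions are taken from the ``# ColHeaders`` comment line, which
    must name ``StructName``, ``SurfArea`` and ``ThickAvg``. ROI names are
    normalized to lower case. Returns a DataFrame with MORPH_COLUMNS.
    """
    path = Path(path)
    hemisphere = normalize_hemisphere(hemisphere)
    colheaders: list[str] | None = None
    rows: list[tuple[str, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                stripped = line.lstrip("# ").rstrip()
                if stripped.startswith("ColHeaders"):
                    colheaders = stripped.split()[1:]
                continue
            if colheaders is None:
                raise FormatError(f"{path}: body row before any ColHeaders line")
            fields = line.split()
            if len(fields) != len(colheaders):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(colheaders)} fields, got {len(fields)}"
                )
            rec = dict(zip(colheaders, fields))
            try:
                name = rec["StructName"]
                area = float(rec["SurfArea"])
                thick = float(rec["ThickAvg"])
            except KeyError as exc:
                raise FormatError(f"{path}: ColHeaders lacks required column {exc}") from None
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric SurfArea/ThickAvg") from None
            rows.append((name.lower(), thick, area))
    if colheaders is None:
        raise FormatError(f"{path}: no ColHeaders line found")
    for req in ("StructName", "SurfArea", "ThickAvg"):
        if req not in colheaders:
            raise FormatError(f"{path}: ColHeaders lacks required column '{req}'")
    df = pd.DataFrame(
        {
            "subject_id": subject_id,
            "hemisphere": hemisphere,
            "roi": [r[0] for r in rows],
            "cth": [r[1] for r in rows],
            "csa": [r[2] for r in rows],
        }
    )
    return _validate_morphometry(df, str(path))


def write_aparc_stats(df: pd.DataFrame, path: str | Path) -> None:
    """Write one subject/hemisphere's records in the aparc-stats dialect.

    Only the three columns the reader consumes are populated meaningfully;
    the remaining standard columns are filled with zeros so that generic
    FreeSurfer tooling can still split the rows.
    """
    subjects = df["subject_id"].unique()
    hemis = df["hemisphere"].unique()
    if len(subjects) != 1 or len(hemis) != 1:
        raise ValidationError("aparc-stats files hold one subject/hemisphere each")
    buf = _io.StringIO()
    buf.write("# Table of FreeSurfer cortical parcellation anatomical statistics\n")
    buf.write(f"# subjectname {subjects[0]}\n")
    buf.write(f"# hemi {'lh' if hemis[0] == 'left' else 'rh'}\n")
    buf.write("# ColHeaders StructName NumVert SurfArea GrayVol ThickAvg ThickStd\n")
    for _, row in df.iterrows():
        buf.write(
            f"{row['roi']}  0  {row['csa']:.10g}  0  {row['cth']:.10g}  0.000\n"
        )
    Path(path).write_text(buf.getvalue())


def _sniff_sep(path: Path) -> str:
    header = path.open().readline()
    return "\t" if "\t" in header else ","


def read_cohort_long_table(path: str | Path) -> pd.DataFrame:
    """Read a cohort long table (subject_id, hemisphere, roi, cth, csa)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    missing = [c for c in MORPH_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    df = df[MORPH_COLUMNS].copy()
    df["subject_id"] = df["subject_id"].astype(str)
    df["hemisphere"] = df["hemisphere"].map(lambda t: normalize_hemisphere(t))
    df["roi"] = df["roi"].astype(str).str.lower()
    df["cth"] = df["cth"].astype(float)
    df["csa"] = df["csa"].astype(float)
    return _validate_morphometry(df, str(path))


def write_cohort_long_table(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    df[MORPH_COLUMNS].to_csv(path, sep=sep, index=False)


def read_demographics(path: str | Path) -> pd.DataFrame:
    """Read a demographics table; empty fields become missing values."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    missing = [c for c in DEMOGRAPHIC_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    df = df[DEMOGRAPHIC_COLUMNS].copy()
    df["subject_id"] = df["subject_id"].astype(str)
    for col in ("age", "ses", "fiv", "hev"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    validate_demographics(df)
    return df


def validate_demographics(df: pd.DataFrame) -> None:
    bad_group = set(df["group"].dropna()) - {"student", "adult"}
    if bad_group:
        raise ValidationError(f"unknown group label(s): {sorted(bad_group)}")
    bad_ped = set(df["pedagogy"].dropna()) - {"montessori", "traditional", "not_applicable"}
    if bad_ped:
        raise ValidationError(f"unknown pedagogy label(s): {sorted(bad_ped)}")
    students = df[df["group"] == "student"]
    if (students["pedagogy"] == "not_applicable").any():
        raise ValidationError("students must have a pedagogy")
    adults = df[df["group"] == "adult"]
    if not (adults["pedagogy"].isin(["not_applicable"]) | adults["pedagogy"].isna()).all():
        raise ValidationError("adults must have pedagogy = not_applicable")
    ses = df["ses"].dropna()
    if ((ses < 0) | (ses > 4)).any():
        raise ValidationError("SES out of [0, 4]")
    hev = df["hev"].dropna()
    if ((hev < 0) | (hev > 100)).any():
        raise ValidationError("HEV out of [0, 100]")


def write_demographics(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    df[DEMOGRAPHIC_COLUMNS].to_csv(path, sep=sep, index=False, na_rep="")


def concat_morphometry(frames: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-file morphometry frames, re-checking uniqueness."""
    df = pd.concat(list(frames), ignore_index=True)
    return _validate_morphometry(df, "concatenated cohort")
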