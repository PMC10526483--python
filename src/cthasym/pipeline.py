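"""End-to-end orchestration: simulate/ingest -> AI -> statistics -> reports.

A run is configured by a small mapping (usually loaded from YAML) that
names either real input files::

    inputs:
      morphometry: cohort.tsv      # long table, or a list of aparc.stats files
      demographics: subjects.tsv

or a simulation block::

    simulate:
      preset: default              # default | null | <omitted with fields>
      n_montessori: 56             # any GeneratorConfig field may be overridden

All randomness flows from the single top-level seed; per-stage sub-seeds
are derived deterministically from it. Every emitted file is listed in the
run manifest, and a rerun with the same config and seed reproduces
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .asymmetry import compute_ai_table, write_ai_table
from .atlas import default_lobe_map
from .demographics import homogeneity_tests
from .errors import CthAsymError
from .inference import HierarchicalResult, hierarchical_downscale, students_vs_adults
from .io import (
    read_aparc_stats,
    read_cohort_long_table,
    read_demographics,
    write_cohort_long_table,
    write_demographics,
    concat_morphometry,
)
from .simulate import AIModel, GeneratorConfig, generate_cohort

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunManifest:
    config_hash: str
    seed: int
    version: str
    inputs: tuple[str, ...]
    outputs: tuple[str, ...]
    stages: Mapping[str, str]

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _config_hash(config: Mapping[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def build_generator_config(block: Mapping[str, Any]) -> GeneratorConfig:
    block = dict(block)
    preset = block.pop("preset", "default")
    if preset == "default":
        base = GeneratorConfig.default()
    elif preset == "null":
        base = GeneratorConfig.null()
    else:
        raise CthAsymError(f"simulate: unknown preset {preset!r}")
    for models_key in ("student_ai_models", "adult_ai_models"):
        if models_key in block:
            block[models_key] = {
                region: AIModel(**params)
                for region, params in block[models_key].items()
            }
    if "default_ai_model" in block:
        block["default_ai_model"] = AIModel(**block["default_ai_model"])
    if block:
        base = dataclasses.replace(base, **block)
    return base


# ---------------------------------------------------------------------------
# Report formatting


def _fmt(v: float) -> str:
    """3 significant figures; scientific notation for AI-scale values."""
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return "-"
    if v != 0 and abs(v) < 1e-2:
        return f"{v:.3g}"
    return f"{v:.3g}"


def render_model_report(result: HierarchicalResult) -> str:
    """Human-readable per-region model tables (statistics + coefficients)."""
    lines = []
    for stage in result.stages:
        lines.append(f"== {stage.level} stage ==")
        adj = stage.adjusted_p.set_index(["region", "term"])["p_fdr"]
        for m in stage.models:
            gate = "open" if stage.gate_open.get(m.region) else "closed"
            lines.append(
                f"\n[{m.level}] {m.region}  "
                f"F({m.df_num}, {m.df_den}) = {_fmt(m.f)}, R2 = {_fmt(m.r2)}, "
                f"p = {_fmt(m.p_model)}  (gate {gate}; n = {m.n_used})"
            )
            lines.append(f"{'term':<16}{'beta':>12}{'SE':>12}{'t':>8}{'p':>10}{'p_fdr':>10}")
            for t in m.terms:
                p_fdr = adj.get((m.region, t.name), np.nan)
                lines.append(
                    f"{t.name:<16}{_fmt(t.beta):>12}{_fmt(t.se):>12}"
                    f"{_fmt(t.t):>8}{_fmt(t.p):>10}{_fmt(p_fdr):>10}"
                )
        lines.append("")
    return "\n".join(lines)


def models_frame(result: HierarchicalResult) -> pd.DataFrame:
    """Full-precision flat table of every fitted model's terms and omnibus."""
    frames = []
    for stage in result.stages:
        for m in stage.models:
            df = m.to_frame()
            df["f"] = m.f
            df["df_num"] = m.df_num
            df["df_den"] = m.df_den
            df["r2"] = m.r2
            df["p_model"] = m.p_model
            df["n_used"] = m.n_used
            df["gate_open"] = bool(stage.gate_open.get(m.region))
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Pipeline


def run_pipeline(
    config: Mapping[str, Any],
    seed: int,
    outdir: str | Path,
    alpha: float = 0.05,
    fdr: str = "bh",
) -> RunManifest:
    """Execute simulate/ingest -> AI table -> homogeneity -> group
    comparison -> hierarchical down-scaling -> reports.

    Any stage failure is re-raised with the stage name attached. Returns
    the run manifest (also written to ``<outdir>/manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs: list[str] = []
    outputs: list[str] = []
    stages: dict[str, str] = {}

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        outputs.append(name)
        return path

    def run_stage(name: str, fn):
        try:
            out = fn()
        except Exception as exc:
            raise CthAsymError(f"stage '{name}' failed: {exc}") from exc
        log.info("stage %s done", name)
        return out

    # -- acquire data
    if "simulate" in config:
        gen_config = build_generator_config(config["simulate"])
        demo, morph = run_stage(
            "simulate", lambda: generate_cohort(gen_config, stage_seed(seed, "simulate"))
        )
        stages["simulate"] = (
            f"generated {len(demo)} subjects, {len(morph)} morphometry rows"
        )
        emit("demographics.tsv", lambda p: write_demographics(demo, p))
        emit("morphometry.tsv", lambda p: write_cohort_long_table(morph, p))
    elif "inputs" in config:
        spec = config["inputs"]
        morph_src = spec["morphometry"]
        if isinstance(morph_src, (list, tuple)):
            frames = [
                read_aparc_stats(item["path"], item["subject_id"], item["hemisphere"])
                for item in morph_src
            ]
            morph = run_stage("ingest", lambda: concat_morphometry(frames))
            inputs.extend(str(item["path"]) for item in morph_src)
        else:
            morph = run_stage("ingest", lambda: read_cohort_long_table(morph_src))
            inputs.append(str(morph_src))
        demo = run_stage("ingest", lambda: read_demographics(spec["demographics"]))
        inputs.append(str(spec["demographics"]))
        stages["ingest"] = f"read {len(demo)} subjects, {len(morph)} morphometry rows"
    else:
        raise CthAsymError("config must contain a 'simulate' or 'inputs' block")

    # -- asymmetry
    lobe_map = default_lobe_map()
    ai = run_stage("compute_ai", lambda: compute_ai_table(morph, lobe_map))
    emit("ai_table.tsv", lambda p: write_ai_table(ai, p))
    stages["compute_ai"] = f"{len(ai)} AI records"

    # -- demographics homogeneity (students)
    homog = run_stage("homogeneity", lambda: homogeneity_tests(demo, alpha=alpha))
    emit("homogeneity.tsv", lambda p: homog.to_csv(p, sep="\t", index=False))
    flagged = homog.loc[homog["flagged"], "variable"].tolist()
    stages["homogeneity"] = (
        f"flagged: {flagged}" if flagged else "no group imbalance flagged"
    )

    # -- students vs adults (only when both groups exist)
    if (demo["group"] == "adult").any() and (demo["group"] == "student").any():
        comparison = run_stage("compare_groups", lambda: students_vs_adults(ai, demo))
        payload = dataclasses.asdict(comparison)
        payload["ancova"] = comparison.ancova.to_dict(orient="records")
        emit(
            "adults_vs_students.json",
            lambda p: Path(p).write_text(json.dumps(payload, indent=2)),
        )
        stages["compare_groups"] = (
            f"t({comparison.df}) = {comparison.t:.3g}, p = {comparison.p:.3g}"
        )
    else:
        stages["compare_groups"] = "skipped (single group)"

    # -- hierarchical down-scaling over students
    result = run_stage(
        "downscale",
        lambda: hierarchical_downscale(ai, demo, lobe_map, alpha=alpha, fdr=fdr),
    )
    emit(
        "hierarchy_models.tsv",
        lambda p: models_frame(result).to_csv(p, sep="\t", index=False),
    )
    emit(
        "hierarchy_records.tsv",
        lambda p: result.records().to_csv(p, sep="\t", index=False),
    )
    emit("report.txt", lambda p: Path(p).write_text(render_model_report(result)))
    gates = {
        s.level: sorted(r for r, ok in s.gate_open.items() if ok) for s in result.stages
    }
    stages["downscale"] = f"gates open: {gates}"
    for level, open_regions in gates.items():
        log.info("gate decisions at %s level: open=%s", level, open_regions)

    manifest = RunManifest(
        config_hash=_config_hash(config),
        seed=seed,
        version=__version__,
        inputs=tuple(inputs),
        outputs=tuple(outputs),
        stages=stages,
    )
    manifest.write(outdir / "manifest.json")
    return manifest
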