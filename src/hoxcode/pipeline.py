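"""End-to-end pipeline: subset -> build codes -> validate -> score -> classify.

`run_pipeline` reads an expression matrix and sample metadata, restricts
to the 39 HOX genes, builds per-tissue codes, validates them by the
self-correlation procedure, scores and classifies every sample against
the codes, and writes all artifacts (TSV tables, heatmaps, run log) into
one output directory.  Outputs are deterministic for identical inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .codes import build_codes, validate_codes
from .genes import hox_gene_set
from .io import (
    read_expression,
    read_metadata,
    subset_to_gene_set,
    write_table,
)
from .scoring import DEFAULT_THRESHOLD, calls_to_frame, classify, score_samples, summarize_calls
from .viz import render_heatmap

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """All knobs of an end-to-end run; mirrors the CLI flags."""

    expression: str
    metadata: str
    out_dir: str
    transform: str = "log2p1"
    threshold: float = DEFAULT_THRESHOLD
    min_group_size: int = 1
    gene_policy: str = "intersect"
    heatmap_order: str = "fixed"
    image_format: str = "png"
    log_level: str = "INFO"
    seed: int | None = None  # recorded in the log; the pipeline itself is deterministic

    def __post_init__(self) -> None:
        if not -1.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must lie in (-1, 1), got {self.threshold}")
        if self.gene_policy not in {"strict", "intersect"}:
            raise ValueError(f"unknown gene policy {self.gene_policy!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full HOX-code workflow; returns the artifact directory.

    Artifacts: codes.tsv, validation.tsv, scores.tsv, calls.tsv,
    summary.tsv, validation.<ext>, scores.<ext>, run.log.  Any stage
    error aborts with a stage-named message and removes partial outputs.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    m = _stage("read_expression")(read_expression, cfg.expression)
    meta = _stage("read_metadata")(read_metadata, cfg.metadata)
    sub = _stage("subset")(subset_to_gene_set, m, hox_gene_set(), cfg.gene_policy)
    codes = _stage("build_codes")(
        build_codes, sub, meta, cfg.transform, cfg.min_group_size
    )
    validation = _stage("validate_codes")(validate_codes, sub, meta, codes)
    scores = _stage("score_samples")(score_samples, sub, codes)
    calls = _stage("classify")(classify, scores, meta, cfg.threshold)
    summary = _stage("summarize")(summarize_calls, calls, meta)

    written: list[Path] = []
    try:
        written.append(write_table(codes.codes, out / "codes.tsv"))
        written.append(write_table(validation, out / "validation.tsv"))
        written.append(write_table(scores, out / "scores.tsv"))
        written.append(write_table(calls_to_frame(calls), out / "calls.tsv"))
        written.append(write_table(summary, out / "summary.tsv"))
        ext = cfg.image_format.lstrip(".")
        written.append(
            render_heatmap(validation, out / f"validation.{ext}", cfg.heatmap_order,
                           title="tissue groups vs HOX codes (median r)")
        )
        written.append(
            render_heatmap(scores, out / f"scores.{ext}", cfg.heatmap_order,
                           title="samples vs HOX codes (Pearson r)")
        )
        log_lines = [
            f"hoxcode {__version__}",
            *(f"{k} = {v}" for k, v in asdict(cfg).items()),
            f"n_genes = {sub.shape[0]}",
            f"n_samples = {sub.shape[1]}",
            f"n_tissues = {len(codes.tissue_ids)}",
        ]
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(f"stage 'write_artifacts' failed: {exc}") from exc
    return out
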