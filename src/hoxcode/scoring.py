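"""Correlation scoring of samples against HOX codes and lineage calls.

A sample keeps its lineage identity when its HOX profile correlates with
the code of its labeled (home) tissue above the cutoff r > 0.3; a sample
whose home correlation falls at or below the cutoff has "switched", either
toward some other tissue's code or — the neuroendocrine trans-
differentiation phenotype — toward no tissue at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codes import HoxCodeTable, apply_transform
from .io import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "pearson",
    "score_samples",
    "classify",
    "summarize_calls",
    "LineageCall",
    "calls_to_frame",
    "DEFAULT_THRESHOLD",
]

#: Correlation cutoff for keeping lineage identity (strict inequality).
DEFAULT_THRESHOLD = 0.3

CALL_CATEGORIES = (
    "kept",
    "switched_to_other",
    "switched_no_identity",
    "ambiguous",
    "undefined",
)


def pearson(x, y) -> float:
    """Sample Pearson correlation of two equal-length vectors.

    Returns NaN (not an exception) when either vector has zero variance;
    raises on length mismatch, length < 3, or non-finite input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return float("nan")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def score_samples(m: pd.DataFrame, codes: HoxCodeTable) -> pd.DataFrame:
    """Pearson correlation of every sample against every tissue code.

    `m` holds raw (untransformed) abundances on the code table's gene set;
    the table's own transform is applied before correlating, so scores and
    codes always live on the same scale.  Samples with zero variance
    across the gene set get a fully missing row and a warning.
    """
    if list(m.index) != codes.gene_ids:
        raise ValidationError(
            "gene set/order mismatch between expression matrix and code table"
        )
    if len(codes.gene_ids) < 3:
        raise ValidationError("need at least 3 genes to correlate")
    X = apply_transform(m.to_numpy(), codes.transform)  # genes x samples
    C = codes.codes.to_numpy()  # tissues x genes

    Xc = X - X.mean(axis=0, keepdims=True)
    Cc = C - C.mean(axis=1, keepdims=True)
    xn = np.sqrt((Xc**2).sum(axis=0))  # per sample
    cn = np.sqrt((Cc**2).sum(axis=1))  # per tissue
    flat_samples = xn == 0
    flat_codes = cn == 0
    if flat_samples.any():
        logger.warning(
            "%d sample(s) have zero variance across the gene set: %s",
            flat_samples.sum(),
            list(m.columns[flat_samples]),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ Cc.T) / np.outer(xn, cn)
    r[flat_samples, :] = np.nan
    r[:, flat_codes] = np.nan
    r = np.clip(r, -1.0, 1.0)
    out = pd.DataFrame(r, index=m.columns.copy(), columns=codes.tissue_ids)
    out.index.name = "sample_id"
    out.columns.name = "tissue"
    return out


@dataclass(frozen=True)
class LineageCall:
    """Per-sample lineage-identity classification."""

    sample_id: str
    home_tissue: str | None
    home_score: float  # NaN when no home label or score undefined
    best_tissue: str
    best_score: float
    call: str
    threshold: float

    def __post_init__(self) -> None:
        if self.call not in CALL_CATEGORIES:
            raise ValueError(f"unknown call category {self.call!r}")


def _best(scores: pd.Series) -> tuple[str, float]:
    """Top-scoring tissue; ties broken lexicographically by label."""
    ordered = scores.sort_index()
    idx = ordered.to_numpy().argmax()
    return str(ordered.index[idx]), float(ordered.iloc[idx])


def classify(
    scores: pd.DataFrame,
    home_labels: pd.Series | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[LineageCall]:
    """Call lineage identity per sample from a sample x tissue score matrix.

    With a home label: `kept` when home score > threshold (strict, per the
    r > 0.3 convention); otherwise `switched_to_other` if some other
    tissue exceeds the threshold (best such reported), else
    `switched_no_identity`.  Without a home label the best tissue is
    reported, with `ambiguous` when two or more tissues exceed the
    threshold, `kept` when exactly one does, `switched_no_identity` when
    none does.  A fully missing score row gives `undefined`.
    """
    if not -1.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (-1, 1), got {threshold}")
    if home_labels is not None:
        labeled = home_labels.loc[home_labels.index.intersection(scores.index)]
        unknown = set(labeled.unique()) - set(scores.columns)
        if unknown:
            raise ValidationError(f"home tissues absent from score matrix: {sorted(unknown)}")

    calls: list[LineageCall] = []
    for sample_id, row in scores.iterrows():
        home = None
        if home_labels is not None and sample_id in home_labels.index:
            home = str(home_labels.loc[sample_id])
        if row.isna().all():
            calls.append(
                LineageCall(str(sample_id), home, float("nan"), "", float("nan"),
                            "undefined", threshold)
            )
            continue
        best_tissue, best_score = _best(row.dropna())
        above = row.index[row > threshold]
        if home is not None:
            home_score = float(row.get(home, np.nan))
            if home_score > threshold:
                call = "kept"
            else:
                others = [t for t in above if t != home]
                if others:
                    call = "switched_to_other"
                    best_tissue, best_score = _best(row.loc[others])
                else:
                    call = "switched_no_identity"
        else:
            home_score = float("nan")
            if len(above) >= 2:
                call = "ambiguous"
            elif len(above) == 1:
                call = "kept"
            else:
                call = "switched_no_identity"
        calls.append(
            LineageCall(str(sample_id), home, home_score, best_tissue,
                        best_score, call, threshold)
        )
    return calls


def calls_to_frame(calls: list[LineageCall]) -> pd.DataFrame:
    """Tabular view of lineage calls (columns as written by the CLI)."""
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "home_tissue": [c.home_tissue if c.home_tissue is not None else "" for c in calls],
            "home_score": [c.home_score for c in calls],
            "best_tissue": [c.best_tissue for c in calls],
            "best_score": [c.best_score for c in calls],
            "call": [c.call for c in calls],
        }
    ).set_index("sample_id")


def summarize_calls(calls: list[LineageCall], groups: pd.Series) -> pd.DataFrame:
    """Per-group contingency of call categories plus the fraction kept."""
    if not calls:
        raise ValueError("no calls to summarize")
    missing = [c.sample_id for c in calls if c.sample_id not in groups.index]
    if missing:
        raise ValidationError(f"calls for samples absent from groups: {missing}")
    frame = calls_to_frame(calls)
    frame["group"] = groups.loc[frame.index].to_numpy()
    counts = (
        frame.groupby("group")["call"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(CALL_CATEGORIES), fill_value=0)
    )
    counts["n"] = counts.sum(axis=1)
    counts["fraction_kept"] = counts["kept"] / counts["n"]
    counts.index.name = "group"
    return counts.sort_index()
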