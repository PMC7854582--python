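"""Semiquantitative IHC H-scores and their correlation with tumor grade.

The H-score summarizes immunohistochemical staining over four intensity
levels (0 = negative .. 3 = strong): H = 1*pct1 + 2*pct2 + 3*pct3, where
pct_i is the percentage of cells at level i, so H ranges 0-300.  Grade
labels are ordinal, with benign hyperplasia (BPH) below all Gleason
scores: BPH < GS6 < GS7 < GS8 < GS9 < GS10.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GRADE_LEVELS",
    "compute_hscore",
    "score_table",
    "spearman_grade_correlation",
    "read_hscore_table",
]

GRADE_LEVELS = ("BPH", "GS6", "GS7", "GS8", "GS9", "GS10")
_GRADE_RANK = {g: i for i, g in enumerate(GRADE_LEVELS)}

PCT_SUM_TOL = 0.5  # pathologist percentages are rounded; allow sum 100 +/- 0.5


def compute_hscore(pct_by_intensity) -> float:
    """H-score from the four intensity-level percentages (0,1,2,3)."""
    p = np.asarray(pct_by_intensity, dtype=float)
    if p.shape != (4,):
        raise ValueError(f"need exactly 4 intensity percentages, got shape {p.shape}")
    if not np.isfinite(p).all() or (p < 0).any():
        raise ValueError(f"percentages must be finite and >= 0: {p.tolist()}")
    total = p.sum()
    if abs(total - 100.0) > PCT_SUM_TOL:
        raise ValueError(f"percentages sum to {total}, expected 100 +/- {PCT_SUM_TOL}")
    h = 1.0 * p[1] + 2.0 * p[2] + 3.0 * p[3]
    return float(np.clip(h, 0.0, 300.0))


def score_table(records: pd.DataFrame) -> pd.DataFrame:
    """Add an ``h_score`` column to a specimen table.

    Expects columns pct0..pct3 and optionally ``grade``; index = specimen id.
    """
    required = ["pct0", "pct1", "pct2", "pct3"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    out = records.copy()
    out["h_score"] = [
        compute_hscore(row) for row in out[required].to_numpy()
    ]
    return out


def spearman_grade_correlation(records: pd.DataFrame) -> tuple[float, float]:
    """Spearman rho (average-rank ties) of H-score vs ordinal grade.

    Returns (rho, two-sided p by the large-sample t approximation).
    Requires >= 3 graded records; all-identical grades give (nan, nan).
    """
    if "grade" not in records.columns or "h_score" not in records.columns:
        raise ValueError("records need 'grade' and 'h_score' columns")
    graded = records.dropna(subset=["grade", "h_score"])
    unknown = set(graded["grade"]) - set(GRADE_LEVELS)
    if unknown:
        raise ValueError(f"unknown grade labels: {sorted(unknown)}")
    if len(graded) < 3:
        raise ValueError(f"need >= 3 graded records, got {len(graded)}")
    ordinal = graded["grade"].map(_GRADE_RANK).to_numpy(dtype=float)
    h = graded["h_score"].to_numpy(dtype=float)
    if np.ptp(ordinal) == 0 or np.ptp(h) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(h, ordinal)
    return float(rho), float(p)


def read_hscore_table(path) -> pd.DataFrame:
    """Read a specimen TSV: specimen_id, pct0..pct3, and optional grade."""
    t = pd.read_csv(path, sep="\t", header=0, index_col=0)
    t.index = t.index.astype(str)
    return t
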