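"""Construction and validation of tissue HOX codes.

A tissue's HOX code is the per-gene median expression over the samples
labeled with that tissue, taken on a chosen scale (log2(x+1) by default).
Validation recomputes, for every (tissue, code) pair, the median Pearson
correlation of that tissue's samples against that code — the diagonal of
the resulting matrix is the self-consistency of each code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ValidationError, validate_expression

logger = logging.getLogger(__name__)

__all__ = ["HoxCodeTable", "TRANSFORMS", "apply_transform", "build_codes", "validate_codes"]

TRANSFORMS = ("log2p1", "none")


def apply_transform(values, transform: str):
    """Apply the named expression transform elementwise."""
    if transform == "log2p1":
        return np.log2(np.asarray(values, dtype=float) + 1.0)
    if transform == "none":
        return np.asarray(values, dtype=float)
    raise ValueError(f"unknown transform {transform!r}; expected one of {TRANSFORMS}")


@dataclass
class HoxCodeTable:
    """Tissue x gene table of median (transformed) expression.

    Attributes
    ----------
    codes : DataFrame, tissues in rows (lexicographic), genes in columns.
    transform : scale under which the medians were taken ("log2p1"/"none").
    group_sizes : Series, number of samples behind each tissue's code.
    """

    codes: pd.DataFrame
    transform: str = "log2p1"
    group_sizes: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.group_sizes is None:
            self.group_sizes = pd.Series(1, index=self.codes.index)
        if not np.isfinite(self.codes.to_numpy()).all():
            raise ValidationError("non-finite value in code table")
        if self.codes.index.duplicated().any():
            raise ValidationError("duplicate tissue labels in code table")
        if (self.group_sizes < 1).any():
            raise ValidationError("group sizes must be >= 1")

    @property
    def tissue_ids(self) -> list[str]:
        return list(self.codes.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.codes.columns)


def _align_meta(m: pd.DataFrame, meta: pd.Series) -> pd.Series:
    """Metadata restricted to samples present in `m`, with warnings."""
    in_matrix = meta.index.intersection(m.columns)
    orphan_meta = meta.index.difference(m.columns)
    orphan_samples = m.columns.difference(meta.index)
    if len(orphan_meta):
        logger.warning("%d metadata entries have no matching sample column", len(orphan_meta))
    if len(orphan_samples):
        logger.warning("%d samples lack metadata and are dropped", len(orphan_samples))
    return meta.loc[in_matrix]


def build_codes(
    m: pd.DataFrame,
    meta: pd.Series,
    transform: str = "log2p1",
    min_group_size: int = 1,
) -> HoxCodeTable:
    """Median per-tissue expression profiles from a labeled matrix.

    For each retained tissue group and each gene, the code entry is the
    median over that group's samples of the transformed value (even-sized
    groups: mean of the two middle values).  Groups smaller than
    `min_group_size` are excluded with a log message; tissues are ordered
    lexicographically.
    """
    validate_expression(m)
    meta = _align_meta(m, meta)
    if meta.empty:
        raise ValidationError("no labeled samples shared between matrix and metadata")
    sizes = meta.value_counts()
    keep = sorted(sizes.index[sizes >= min_group_size])
    dropped = sorted(set(sizes.index) - set(keep))
    if dropped:
        logger.info("build_codes: dropping groups below size %d: %s", min_group_size, dropped)
    if not keep:
        raise ValidationError(f"no group reaches min_group_size={min_group_size}")

    X = pd.DataFrame(
        apply_transform(m.to_numpy(), transform), index=m.index, columns=m.columns
    )
    rows = {t: X.loc[:, meta.index[meta == t]].median(axis=1) for t in keep}
    codes = pd.DataFrame(rows).T.loc[keep, m.index]
    codes.index.name = "tissue"
    codes.columns.name = "gene"
    used = sizes.loc[keep].sort_index()
    return HoxCodeTable(codes=codes, transform=transform, group_sizes=used)


def validate_codes(
    m: pd.DataFrame, meta: pd.Series, codes: HoxCodeTable
) -> pd.DataFrame:
    """Median within-group correlation of each tissue's samples vs each code.

    Entry (t, u) is the median over samples labeled t of the Pearson
    correlation between the sample's transformed profile and code u.  The
    diagonal is the self-consistency score read off the usual
    tissue-vs-code heatmap.  Tissues present in `codes` but absent from
    the metadata give a missing-valued row.
    """
    from .scoring import score_samples  # local import to avoid a cycle

    if list(m.index) != codes.gene_ids:
        raise ValidationError(
            "expression matrix gene set/order differs from the code table"
        )
    meta = _align_meta(m, meta)
    scores = score_samples(m, codes)  # samples x tissues, on codes.transform scale
    tissues = codes.tissue_ids
    out = pd.DataFrame(np.nan, index=pd.Index(tissues, name="tissue"), columns=tissues)
    out.columns.name = "code"
    for t in tissues:
        members = meta.index[meta == t]
        if len(members) == 0:
            logger.warning("validate_codes: tissue %r has no labeled samples", t)
            continue
        out.loc[t] = scores.loc[members].median(axis=0).to_numpy()
    return out
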