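"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a multi-tissue cell-line compendium: each tissue
gets an archetypal log2 HOX profile (entries i.i.d. uniform on [0, 12]
log2 units, roughly the observed FPKM dynamic range), and each sample is
that archetype plus i.i.d. Gaussian noise on the log2 scale (log-normal
dispersion on the raw scale, sd 0.25 by default).  Lineage-switch samples
instead draw a fresh archetype of their own, decorrelating them from
their labeled tissue.  A planted-shift contrast generator emulates the
adenocarcinoma-vs-neuroendocrine comparison (34 vs 15 samples), and a
simplex sampler produces IHC H-score tables with a controllable
grade trend.  All randomness flows from an explicit integer seed through
numpy's PCG64 generator — identical config and seed give bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genes import HoxGeneSet, hox_gene_set
from .hscore import GRADE_LEVELS

__all__ = [
    "SyntheticConfig",
    "generate_cohort",
    "generate_nepca_contrast",
    "generate_hscore_table",
    "null_matrix",
]

LOG2_RANGE = (0.0, 12.0)  # archetype entries, log2(FPKM+1) units


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic multi-tissue cohort.

    switch_fraction may be a single fraction applied to every tissue or a
    mapping tissue -> fraction; planted_shifts maps gene -> additive log2
    shift applied to the contrast generator's second group.
    """

    seed: int
    n_tissues: int = 24
    samples_per_tissue: int | list[int] = 8
    noise_sd: float = 0.25
    switch_fraction: float | dict[str, float] = 0.0
    planted_shifts: dict[str, float] = field(default_factory=dict)
    genes: HoxGeneSet = field(default_factory=hox_gene_set)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required; the generator has no hidden state")
        if self.n_tissues < 2:
            raise ValueError(f"n_tissues must be >= 2, got {self.n_tissues}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        fracs = (
            self.switch_fraction.values()
            if isinstance(self.switch_fraction, dict)
            else [self.switch_fraction]
        )
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("switch_fraction values must lie in [0, 1]")
        sizes = self.sizes()
        if any(s < 1 for s in sizes):
            raise ValueError("every tissue needs at least one sample")

    def tissue_names(self) -> list[str]:
        return [f"tissue{i + 1:02d}" for i in range(self.n_tissues)]

    def sizes(self) -> list[int]:
        if isinstance(self.samples_per_tissue, int):
            return [self.samples_per_tissue] * self.n_tissues
        sizes = list(self.samples_per_tissue)
        if len(sizes) != self.n_tissues:
            raise ValueError(
                f"samples_per_tissue lists {len(sizes)} sizes for "
                f"{self.n_tissues} tissues"
            )
        return sizes

    def switch_fraction_for(self, tissue: str) -> float:
        if isinstance(self.switch_fraction, dict):
            return float(self.switch_fraction.get(tissue, 0.0))
        return float(self.switch_fraction)


def _from_log2(z: np.ndarray) -> np.ndarray:
    """Inverse of the log2(x+1) transform, truncated at zero abundance."""
    return np.maximum(np.exp2(z) - 1.0, 0.0)


def generate_cohort(
    cfg: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Expression matrix, metadata and truth table for a multi-tissue cohort.

    Returns (matrix genes x samples, sample -> tissue labels, truth table
    with each sample's generating tissue and switch status).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = list(cfg.genes)
    tissues = cfg.tissue_names()
    archetypes = rng.uniform(*LOG2_RANGE, size=(cfg.n_tissues, len(genes)))

    columns: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}
    truth_rows = []
    for t_idx, (tissue, n) in enumerate(zip(tissues, cfg.sizes())):
        n_switch = int(round(cfg.switch_fraction_for(tissue) * n))
        for j in range(n):
            sample_id = f"{tissue}_s{j + 1:02d}"
            is_switch = j >= n - n_switch
            base = (
                rng.uniform(*LOG2_RANGE, size=len(genes))
                if is_switch
                else archetypes[t_idx]
            )
            z = base + rng.normal(0.0, cfg.noise_sd, size=len(genes))
            columns[sample_id] = _from_log2(z)
            labels[sample_id] = tissue
            truth_rows.append((sample_id, tissue, is_switch))

    m = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    meta = pd.Series(labels, name="label").rename_axis("sample_id")
    truth = pd.DataFrame(
        truth_rows, columns=["sample_id", "tissue", "is_switch"]
    ).set_index("sample_id")
    return m, meta, truth


def generate_nepca_contrast(
    cfg: SyntheticConfig, n_adpca: int = 34, n_nepca: int = 15
) -> tuple[pd.DataFrame, pd.Series]:
    """Two-group contrast with planted per-gene log2 shifts.

    AdPCa samples come from a single (prostate-like) archetype; NEPCa
    samples from the same archetype plus ``cfg.planted_shifts``.  Default
    group sizes 34 vs 15 mirror a typical castration-resistant vs
    neuroendocrine cohort.
    """
    if not cfg.planted_shifts:
        raise ValueError("planted_shifts must be non-empty for a contrast")
    genes = list(cfg.genes)
    unknown = set(cfg.planted_shifts) - set(genes)
    if unknown:
        raise ValueError(f"planted_shifts name unknown genes: {sorted(unknown)}")
    rng = np.random.default_rng(cfg.seed)
    archetype = rng.uniform(*LOG2_RANGE, size=len(genes))
    shift = np.array([cfg.planted_shifts.get(g, 0.0) for g in genes])

    columns: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}
    for j in range(n_adpca):
        sid = f"AdPCa_s{j + 1:02d}"
        columns[sid] = _from_log2(archetype + rng.normal(0, cfg.noise_sd, len(genes)))
        labels[sid] = "AdPCa"
    for j in range(n_nepca):
        sid = f"NEPCa_s{j + 1:02d}"
        columns[sid] = _from_log2(
            archetype + shift + rng.normal(0, cfg.noise_sd, len(genes))
        )
        labels[sid] = "NEPCa"
    m = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    meta = pd.Series(labels, name="label").rename_axis("sample_id")
    return m, meta


def generate_hscore_table(n: int, trend: float, seed: int) -> pd.DataFrame:
    """Synthetic specimen table of intensity percentages with a grade trend.

    Grades are drawn uniformly over BPH, GS6..GS10 (ordinal 0..5).  The
    expected staining intensity rises by ``trend`` intensity units per
    grade step from a baseline of 1.0; percentages are Dirichlet draws
    whose mean follows a Binomial(3, mu/3) intensity profile, so trend=0
    gives no grade association and trend around 0.4 drives the mean
    H-score from ~100 (BPH) to ~300 (GS10).
    """
    if n < 3:
        raise ValueError(f"need n >= 3 specimens, got {n}")
    rng = np.random.default_rng(seed)
    levels = np.arange(4)
    grades = rng.integers(0, len(GRADE_LEVELS), size=n)
    rows = []
    for i, g in enumerate(grades):
        mu = float(np.clip(1.0 + trend * g, 0.05, 2.95))
        # Binomial(3, mu/3) pmf as the mean intensity profile
        q = mu / 3.0
        w = np.array([
            (1 - q) ** 3,
            3 * q * (1 - q) ** 2,
            3 * q**2 * (1 - q),
            q**3,
        ])
        alpha = 25.0 * w + 0.2
        pct = rng.dirichlet(alpha) * 100.0
        # renormalize exactly to 100 to satisfy the record invariant
        pct = pct / pct.sum() * 100.0
        rows.append(
            {
                "specimen_id": f"spec{i + 1:03d}",
                "pct0": pct[0],
                "pct1": pct[1],
                "pct2": pct[2],
                "pct3": pct[3],
                "grade": GRADE_LEVELS[g],
                "h_score": float((levels[1:] * pct[1:]).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("specimen_id")


def null_matrix(
    n_genes: int, n_samples: int, seed: int, noise_sd: float = 1.0
) -> tuple[pd.DataFrame, pd.Series]:
    """Label-free null: i.i.d. log-normal expression, two balanced groups.

    Every gene shares one archetypal mean across both groups, so any
    per-gene significance is a false positive; used to check the t-test's
    type-I error calibration.
    """
    rng = np.random.default_rng(seed)
    base = rng.uniform(*LOG2_RANGE, size=(n_genes, 1))
    z = base + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    genes = [f"g{i:04d}" for i in range(n_genes)]
    samples = [f"s{j:03d}" for j in range(n_samples)]
    m = pd.DataFrame(_from_log2(z), index=pd.Index(genes, name="gene"), columns=samples)
    half = n_samples // 2
    labels = ["groupA"] * half + ["groupB"] * (n_samples - half)
    meta = pd.Series(labels, index=pd.Index(samples, name="sample_id"), name="label")
    return m, meta
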