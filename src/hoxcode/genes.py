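"""The canonical human HOX gene set.

Humans carry 39 HOX transcription-factor genes in four paralogous clusters
(A-D) on separate chromosomes; each cluster holds a subset of paralog
positions 1-13.  The combined expression pattern of these genes in a tissue
is its "HOX code", and every operation in this package is defined over this
fixed gene family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["HoxGeneSet", "HOX_GENES", "HGNC_ALIASES", "hox_gene_set"]

# HGNC symbols in cluster order; the gaps (no HOXA8, HOXB10-12, ...) are real.
_CLUSTER_PARALOGS = {
    "A": (1, 2, 3, 4, 5, 6, 7, 9, 10, 11, 13),
    "B": (1, 2, 3, 4, 5, 6, 7, 8, 9, 13),
    "C": (4, 5, 6, 8, 9, 10, 11, 12, 13),
    "D": (1, 3, 4, 8, 9, 10, 11, 12, 13),
}

HOX_GENES: tuple[str, ...] = tuple(
    f"HOX{cluster}{paralog}"
    for cluster, paralogs in _CLUSTER_PARALOGS.items()
    for paralog in paralogs
)

# Legacy HGNC symbols (pre-1992 nomenclature) still found in old array
# annotation; mapped before case-insensitive matching.
HGNC_ALIASES: dict[str, str] = {
    "HOX1F": "HOXA1", "HOX1K": "HOXA2", "HOX1E": "HOXA3", "HOX1D": "HOXA4",
    "HOX1C": "HOXA5", "HOX1B": "HOXA6", "HOX1A": "HOXA7", "HOX1G": "HOXA9",
    "HOX1H": "HOXA10", "HOX1I": "HOXA11", "HOX1J": "HOXA13",
    "HOX2I": "HOXB1", "HOX2H": "HOXB2", "HOX2G": "HOXB3", "HOX2F": "HOXB4",
    "HOX2A": "HOXB5", "HOX2B": "HOXB6", "HOX2C": "HOXB7", "HOX2D": "HOXB8",
    "HOX2E": "HOXB9",
    "HOX3E": "HOXC4", "HOX3D": "HOXC5", "HOX3C": "HOXC6", "HOX3A": "HOXC8",
    "HOX3B": "HOXC9", "HOX3I": "HOXC10", "HOX3H": "HOXC11", "HOX3F": "HOXC12",
    "HOX3G": "HOXC13",
    "HOX4G": "HOXD1", "HOX4A": "HOXD3", "HOX4B": "HOXD4", "HOX4E": "HOXD8",
    "HOX4C": "HOXD9", "HOX4D": "HOXD10", "HOX4F": "HOXD11", "HOX4H": "HOXD12",
    "HOX4I": "HOXD13",
}


@dataclass(frozen=True)
class HoxGeneSet:
    """Ordered set of the 39 HOX gene symbols with cluster/paralog annotation."""

    genes: tuple[str, ...] = HOX_GENES
    clusters: tuple[str, ...] = field(default=None)  # type: ignore[assignment]
    paralogs: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.clusters is None:
            object.__setattr__(self, "clusters", tuple(g[3] for g in self.genes))
        if self.paralogs is None:
            object.__setattr__(self, "paralogs", tuple(int(g[4:]) for g in self.genes))
        if len(self.genes) != 39:
            raise ValueError(f"expected 39 HOX genes, got {len(self.genes)}")
        if len(set(self.genes)) != 39:
            raise ValueError("duplicate gene symbols in HOX gene set")
        bad = set(self.clusters) - set("ABCD")
        if bad:
            raise ValueError(f"invalid cluster labels: {sorted(bad)}")
        if any(not 1 <= p <= 13 for p in self.paralogs):
            raise ValueError("paralog numbers must lie in 1..13")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def canonicalize(self, symbol: str) -> str:
        """Map a raw symbol (any case, possibly a legacy alias) to its HGNC form."""
        up = symbol.strip().upper()
        return HGNC_ALIASES.get(up, up)


def hox_gene_set() -> HoxGeneSet:
    """Return the default 39-gene HOX set."""
    return HoxGeneSet()
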