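"""Gene assignment to scan outliers and permutation tests for shared gene sets.

Sweep positions gather genes within a 5-kb flank on either side; Fst
outlier windows gather genes by half-open overlap.  The significance of an
observed overlap between two flagged gene sets is assessed by permuting
flagged/unflagged labels over the shared gene universe with both set sizes
fixed — distributionally identical to hypergeometric sampling of the
overlap, which serves as the exact cross-check.  The p-value uses the
add-one estimator (b+1)/(N+1), which can never report zero.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .types import GeneModel, GeneSet, Window


def _point_interval_distance(x: float, start: int, end: int) -> float:
    """Distance in bp from position x to half-open interval [start, end)."""
    if x < start:
        return start - x
    if x > end - 1:
        return x - (end - 1)
    return 0.0


def genes_near_sweeps(
    sweep_positions,
    genes,
    flank: int = 5000,
    label: str = "sweep",
) -> GeneSet:
    """Genes within ``flank`` bp of any sweep test position (inclusive).

    ``sweep_positions`` is an iterable of ``(chrom, position)``; a gene
    overlapping a position is at distance 0.
    """
    by_chrom: dict[str, list[float]] = {}
    for chrom, pos in sweep_positions:
        by_chrom.setdefault(chrom, []).append(float(pos))
    members = []
    for g in genes:
        for x in by_chrom.get(g.chrom, ()):
            if _point_interval_distance(x, g.start, g.end) <= flank:
                members.append(g.gene_id)
                break
    return GeneSet([g.gene_id for g in genes], members, label=label)


def genes_in_windows(windows, genes, label: str = "fst") -> GeneSet:
    """Genes whose span overlaps any selected window (half-open overlap)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for w in windows:
        if isinstance(w, Window):
            by_chrom.setdefault(w.chrom, []).append((w.start, w.end))
        else:
            chrom, s, e = w
            by_chrom.setdefault(chrom, []).append((int(s), int(e)))
    members = []
    for g in genes:
        for s, e in by_chrom.get(g.chrom, ()):
            if g.start < e and s < g.end:
                members.append(g.gene_id)
                break
    return GeneSet([g.gene_id for g in genes], members, label=label)


@dataclass
class PermutationResult:
    """Outcome of a shared-gene permutation test."""

    observed: int
    n_perm: int
    n_exceed: int  # permutations with overlap >= observed
    seed: int | None

    def __post_init__(self) -> None:
        if not 0 <= self.n_exceed <= self.n_perm:
            raise ValueError("exceedance count outside [0, N]")

    @property
    def p_value(self) -> float:
        return (self.n_exceed + 1) / (self.n_perm + 1)


def shared_gene_permutation_test(
    set_a: GeneSet,
    set_b: GeneSet,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PermutationResult:
    """Permutation test for the overlap of two flagged gene sets.

    Each permutation independently redraws both sets as uniform random
    subsets of the common universe with the observed sizes fixed, and counts
    how often the permuted overlap reaches the observed one.
    """
    if set_a.universe != set_b.universe:
        raise ValueError("gene sets must share the same universe")
    rng = np.random.default_rng(seed)
    universe = set_a.universe
    u, ka, kb = len(universe), len(set_a.members), len(set_b.members)
    observed = len(set_a.members & set_b.members)
    flags_a = np.zeros(u, dtype=bool)
    flags_a[:ka] = True
    flags_b = np.zeros(u, dtype=bool)
    flags_b[:kb] = True
    n_exceed = 0
    for _ in range(n_perm):
        pa = rng.permutation(flags_a)
        pb = rng.permutation(flags_b)
        if int(np.count_nonzero(pa & pb)) >= observed:
            n_exceed += 1
    return PermutationResult(observed, n_perm, n_exceed, seed)


# the CLR-vs-Fst comparison uses the identical machinery; the two flagged
# sets differ only in provenance
clr_fst_shared_test = shared_gene_permutation_test


def hypergeom_overlap_tail(universe_size: int, size_a: int, size_b: int, observed: int) -> float:
    """Exact P(overlap >= observed) under independent uniform subsets."""
    return float(hypergeom.sf(observed - 1, universe_size, size_a, size_b))


__all__ = [
    "genes_near_sweeps",
    "genes_in_windows",
    "PermutationResult",
    "shared_gene_permutation_test",
    "clr_fst_shared_test",
    "hypergeom_overlap_tail",
]
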