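"""Windowed nucleotide diversity and Weir & Cockerham (1984) Fst.

Nucleotide diversity uses the unbiased per-site estimator
pi = k(n-k)/C(n,2) for a site with derived count k among n non-missing
haplotypes; window values divide the summed per-site pi by the full window
width (a callable-site mask is not assumed).

Per-site Fst is the Weir & Cockerham moment estimator for two populations
of diploids, theta_hat = a/(a+b+c) from the among-population (a),
among-individual (b) and within-individual (c) variance components.
Window means average the defined per-site estimates arithmetically,
retaining negative values, which matches the convention of PLINK-style
windowed Fst.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .types import MISSING, GenotypeMatrix, WindowTrack

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

def site_pi(k: int, n: int) -> float:
    """Per-site pi for derived count ``k`` among ``n`` haplotypes.

    Equals the fraction of the C(n,2) haplotype pairs that differ.
    """
    if n < 2:
        raise ValueError("site_pi needs at least 2 haplotypes")
    return k * (n - k) / (n * (n - 1) / 2)


def _site_pi_array(alleles: np.ndarray) -> np.ndarray:
    """Vector of per-site pi over columns of a haplotype block (MISSING-aware).

    Sites with fewer than 2 non-missing haplotypes contribute 0 and are
    logged at debug level.
    """
    ok = alleles != MISSING
    n = ok.sum(axis=0)
    k = np.where(ok, alleles == 1, False).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(n >= 2, k * (n - k) / (n * (n - 1) / 2.0), 0.0)
    return pi


def window_pi(matrix: GenotypeMatrix, windows: WindowTrack, population: str | None = None) -> WindowTrack:
    """Per-window nucleotide diversity for one population.

    Window pi = sum of per-site pi over SNPs in the window, divided by the
    full window width.  Windows without SNPs report 0.
    """
    alleles = matrix.population_alleles(population)
    for chrom in windows.chroms():
        cols = matrix.chrom_columns(chrom)
        pos = matrix.site_positions(chrom)
        pis = _site_pi_array(alleles[:, cols]) if cols.size else np.empty(0)
        for w in windows.on_chrom(chrom):
            sel = (pos >= w.start) & (pos < w.end)
            w.site_count = int(sel.sum())
            w.values["pi"] = float(pis[sel].sum() / w.width) if cols.size else 0.0
    return windows


# ---------------------------------------------------------------------------
# Weir & Cockerham Fst
# ---------------------------------------------------------------------------

@dataclass
class FstSiteComponents:
    """Variance components of the 1984 estimator at one site."""

    a: float  # among populations
    b: float  # among individuals within populations
    c: float  # within individuals

    @property
    def theta_hat(self) -> float | None:
        denom = self.a + self.b + self.c
        if denom == 0:
            return None
        return self.a / denom


def _diploid_counts(alleles: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n_individuals, alt_freq, het_freq) from a haplotype block.

    Individuals with either haplotype missing at a site are excluded there.
    """
    h1 = alleles[0::2]
    h2 = alleles[1::2]
    ok = (h1 != MISSING) & (h2 != MISSING)
    n = ok.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(ok, h1 + h2, 0).sum(axis=0) / np.where(n > 0, 2 * n, np.nan)
        h = np.where(ok, h1 != h2, False).sum(axis=0) / np.where(n > 0, n, np.nan)
    return n, p, h


def _wc_components(n1, p1, h1, n2, p2, h2):
    """Vectorised Weir & Cockerham (1984) a, b, c for two populations."""
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar)
        - (r - 1.0) / r * s2
        - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def wc_fst_site(alleles_pop1: np.ndarray, alleles_pop2: np.ndarray) -> FstSiteComponents:
    """Weir & Cockerham components at one site from two haplotype blocks.

    Each block is a 1-D array of allele codes for one population, ordered so
    rows 2i, 2i+1 are one diploid individual.  Requires at least two
    non-missing diploids per population.
    """
    out = []
    for block in (alleles_pop1, alleles_pop2):
        n, p, h = _diploid_counts(np.asarray(block, dtype=np.int8).reshape(-1, 1))
        if n[0] < 2:
            raise ValueError("need >= 2 non-missing diploids per population")
        out.append((n[0], p[0], h[0]))
    (n1, p1, h1), (n2, p2, h2) = out
    a, b, c = _wc_components(n1, p1, h1, n2, p2, h2)
    return FstSiteComponents(float(a), float(b), float(c))


def site_fst_track(matrix: GenotypeMatrix, pop_a: str, pop_b: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-site theta_hat over all matrix columns for two populations.

    Returns ``(theta, defined)`` where undefined sites (monomorphic overall
    or with < 2 genotyped diploids in either population) carry NaN.
    """
    b1 = matrix.population_alleles(pop_a)
    b2 = matrix.population_alleles(pop_b)
    n1, p1, h1 = _diploid_counts(b1)
    n2, p2, h2 = _diploid_counts(b2)
    usable = (n1 >= 2) & (n2 >= 2)
    n_skip = int((~usable).sum())
    if n_skip:
        log.info("Fst: skipping %d sites with < 2 genotyped diploids in a group", n_skip)
    a, b, c = _wc_components(n1, p1, h1, n2, p2, h2)
    denom = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(usable & (denom != 0), a / denom, np.nan)
    return theta, ~np.isnan(theta)


def window_mean_fst(matrix: GenotypeMatrix, windows: WindowTrack, pop_a: str, pop_b: str) -> WindowTrack:
    """Arithmetic mean of defined per-site theta_hat per window.

    Windows containing no defined site carry no ``fst`` value and are
    excluded from downstream quantiles.
    """
    theta, defined = site_fst_track(matrix, pop_a, pop_b)
    for chrom in windows.chroms():
        cols = matrix.chrom_columns(chrom)
        pos = matrix.site_positions(chrom)
        th = theta[cols] if cols.size else np.empty(0)
        ok = defined[cols] if cols.size else np.empty(0, dtype=bool)
        for w in windows.on_chrom(chrom):
            sel = (pos >= w.start) & (pos < w.end) & ok if cols.size else np.empty(0, dtype=bool)
            w.site_count = int(sel.sum()) if cols.size else 0
            if w.site_count:
                w.values["fst"] = float(th[sel].mean())
    return windows


def mean_fst(matrix: GenotypeMatrix, pop_a: str, pop_b: str) -> float:
    """Genome-wide mean of defined per-site theta_hat."""
    theta, defined = site_fst_track(matrix, pop_a, pop_b)
    if not defined.any():
        raise ValueError("no site with a defined Fst estimate")
    return float(theta[defined].mean())


# ---------------------------------------------------------------------------
# Empirical outlier cutoffs
# ---------------------------------------------------------------------------

def empirical_top_cutoff(track: WindowTrack, stat: str, q: float = 0.01):
    """Select the top-``q`` fraction of valued windows of a track.

    Takes the ceil(q*W) highest of the W valued windows; ties at the
    threshold value are all included (the selection may then exceed
    ceil(q*W), which is logged).  Returns ``(threshold, selected_windows)``.
    """
    if not 0 < q < 1:
        raise ValueError("quantile q must be in (0,1)")
    valued = track.valued(stat)
    if not valued:
        raise ValueError(f"no window carries statistic {stat!r}")
    vals = np.array([w.values[stat] for w in valued])
    m = math.ceil(q * len(valued))
    threshold = float(np.sort(vals)[::-1][m - 1])
    selected = [w for w in valued if w.values[stat] >= threshold]
    if len(selected) > m:
        log.info(
            "top-%g%% cutoff %g: %d windows selected (ties beyond %d)",
            100 * q, threshold, len(selected), m,
        )
    return threshold, selected


__all__ = [
    "site_pi",
    "window_pi",
    "FstSiteComponents",
    "wc_fst_site",
    "site_fst_track",
    "window_mean_fst",
    "mean_fst",
    "empirical_top_cutoff",
]
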