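"""Composite-likelihood-ratio scan for selective sweeps (SweepFinder/SweeD model).

The scan contrasts, at each test position, the probability of the observed
derived-allele counts under a sweep at that position against the genome-wide
background site frequency spectrum.  The sweep spectrum uses the classic
star-genealogy approximation: a lineage at recombination distance ``d`` from
a sweep of strength ``alpha`` escapes the sweep with probability
``p_e = 1 - exp(-alpha * d)``; non-escaping lineages coalesce into a single
ancestor at the sweep, so a present-day sample of n behaves like a pre-sweep
sample of ``b + 1`` lineages (b escapees plus the swept ancestor), whose
allele counts are obtained by hypergeometric down-projection of the
background spectrum.  Maximising over a grid of ``alpha`` (including the
null sentinel alpha = infinity, which recovers the background exactly)
yields the composite likelihood ratio

    CLR(x) = 2 * [ max_alpha sum_s ln P(j_s | d_s, alpha) - sum_s ln p_bg(j_s) ]

which is clamped at >= 0 because the null is inside the grid.

For genome scans the per-site log-likelihood ratio is precomputed on a dense
grid of the composite distance ``t = alpha * d`` and linearly interpolated;
``sweep_site_prob`` itself always evaluates the exact mixture.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom, hypergeom

from .types import MISSING, GenotypeMatrix, WindowTrack

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Site frequency spectra
# ---------------------------------------------------------------------------

@dataclass
class SFS:
    """Background spectrum: P(derived count = j | polymorphic), j = 1..n-1."""

    n: int
    probs: np.ndarray  # length n-1, index j-1
    folded: bool = False

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.size != self.n - 1:
            raise ValueError(f"need {self.n - 1} class probabilities, got {self.probs.size}")
        if np.any(self.probs < 0) or abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("SFS probabilities must be >= 0 and sum to 1")

    def full(self) -> np.ndarray:
        """Distribution over 0..n with zero monomorphic mass."""
        out = np.zeros(self.n + 1)
        out[1:-1] = self.probs
        return out


def fold_sfs(sfs: SFS) -> SFS:
    """Minor-allele-class spectrum: class j pools derived counts j and n-j."""
    if sfs.folded:
        return sfs
    n = sfs.n
    half = n // 2
    probs = np.zeros(n - 1)
    for j in range(1, n):
        m = min(j, n - j)
        probs[m - 1] += sfs.probs[j - 1]
    # represent folded spectrum in the same (n-1)-vector with zero upper half
    return SFS(n, probs, folded=True)


def background_sfs(
    matrix: GenotypeMatrix,
    population: str | None = None,
    folded: bool = False,
    n_project: int | None = None,
) -> SFS:
    """Genome-wide background spectrum of one population.

    With missing data, observations are hypergeometrically down-projected to
    a common haplotype number (the largest n that at least half the
    polymorphic sites attain); sites below the common n are dropped with a
    log entry.  Allele 0 is treated as ancestral (guaranteed by the
    simulator; for real data this means REF-as-ancestral, which is logged).
    """
    alleles = matrix.population_alleles(population)
    ok = alleles != MISSING
    ns = ok.sum(axis=0)
    ks = np.where(ok, alleles == 1, False).sum(axis=0)
    poly = (ks > 0) & (ks < ns) & (ns >= 2)
    if not poly.any():
        raise ValueError("no polymorphic site in this population")
    ns, ks = ns[poly], ks[poly]
    if n_project is None:
        n_project = int(np.median(ns))
    drop = ns < n_project
    if drop.any():
        log.info("background_sfs: dropping %d/%d sites with n < %d", drop.sum(), ns.size, n_project)
    ns, ks = ns[~drop], ks[~drop]
    n = int(n_project)
    counts = np.zeros(n + 1)
    exact = ns == n
    if exact.any():
        counts += np.bincount(ks[exact], minlength=n + 1)[: n + 1]
    i = np.arange(n + 1)
    for n_s in np.unique(ns[~exact]):
        for k_s, mult in zip(*np.unique(ks[ns == n_s], return_counts=True)):
            counts += mult * hypergeom.pmf(i, n_s, k_s, n)
    probs = counts[1:n]
    total = probs.sum()
    if total <= 0:
        raise ValueError("no polymorphic mass after projection")
    sfs = SFS(n, probs / total, folded=False)
    log.debug("background spectrum from %d sites at n=%d", ns.size, n)
    return fold_sfs(sfs) if folded else sfs


def project_distribution(q: np.ndarray, m: int) -> np.ndarray:
    """Hypergeometric down-projection of a count distribution over 0..n to 0..m."""
    q = np.asarray(q, dtype=float)
    n = q.size - 1
    if not 0 <= m <= n:
        raise ValueError(f"cannot project n={n} to m={m}")
    i = np.arange(m + 1)
    out = np.zeros(m + 1)
    for j in range(n + 1):
        if q[j]:
            out += q[j] * hypergeom.pmf(i, n, j, m)
    return out


def project_sfs(sfs: SFS, m: int) -> np.ndarray:
    """Project a background spectrum to sample size ``m``.

    Returns the full distribution over classes 0..m; monomorphic classes
    (mass lost to down-sampling) are retained for internal use by the sweep
    spectrum.
    """
    if m < 2:
        raise ValueError("projection target must be >= 2")
    return project_distribution(sfs.full(), m)


# ---------------------------------------------------------------------------
# Sweep model
# ---------------------------------------------------------------------------

def default_alpha_grid(n_points: int = 40, d_half_min: float = 100.0, d_half_max: float = 1e7) -> np.ndarray:
    """Log-spaced sweep strengths covering escape half-distances 100 bp - 10 Mb.

    ``alpha = ln 2 / d_half`` makes ``p_e(d_half) = 0.5``.  The null sentinel
    (alpha = infinity, every lineage escapes) is appended last.
    """
    alphas = math.log(2.0) / np.geomspace(d_half_max, d_half_min, n_points)
    return np.append(alphas, np.inf)


class SweepModel:
    """Background spectrum + escape model p_e = 1 - exp(-alpha d), with the
    per-site machinery for exact sweep spectra and fast scan lookups."""

    #: composite distance beyond which the sweep spectrum is background
    T_BACKGROUND = 30.0
    T_MIN = 1e-6

    def __init__(self, sfs: SFS, alpha_grid: np.ndarray | None = None, table_size: int = 1024):
        self.sfs = sfs
        self.n = sfs.n
        self.folded = sfs.folded
        self.alpha_grid = (
            np.asarray(alpha_grid, dtype=float) if alpha_grid is not None else default_alpha_grid()
        )
        if not np.isinf(self.alpha_grid).any():
            self.alpha_grid = np.append(self.alpha_grid, np.inf)
        # a folded background is propagated through the sweep mixture via the
        # symmetric unfolded spectrum consistent with it; outputs are re-folded
        if self.folded:
            full = np.zeros(self.n + 1)
            for j in range(1, self.n):
                m = min(j, self.n - j)
                full[j] = sfs.probs[m - 1] * (0.5 if 2 * m != self.n else 1.0)
            self._base_full = full
        else:
            self._base_full = sfs.full()
        self._valid = sfs.probs > 0
        with np.errstate(divide="ignore"):
            self._log_bg = np.log(sfs.probs)
        self._T = self._transition_matrix()
        self._build_tables(table_size)

    def _fold_vector(self, poly: np.ndarray) -> np.ndarray:
        """Fold a polymorphic-class vector (1..n-1) onto minor-allele classes."""
        n = self.n
        out = np.zeros(n - 1)
        for j in range(1, n):
            out[min(j, n - j) - 1] += poly[j - 1]
        return out

    # -- exact spectrum -------------------------------------------------
    def _transition_matrix(self) -> np.ndarray:
        """T[b, j]: P(present-day derived count j | b escapees), j = 0..n."""
        n = self.n
        T = np.zeros((n + 1, n + 1))
        full = self._base_full
        for b in range(n):
            q = project_distribution(full, b + 1)  # pre-sweep sample of b+1
            for i in range(b + 2):
                if not q[i]:
                    continue
                w_swept = i / (b + 1)
                # swept ancestor carries the derived allele: its n-b
                # descendants are derived plus the i-1 other escapees
                T[b, n - b + i - 1] += q[i] * w_swept
                T[b, i] += q[i] * (1.0 - w_swept)
        T[n] = full  # every lineage escaped: plain background sample
        return T

    def mixture(self, p_e: float) -> np.ndarray:
        """Exact polymorphic spectrum (classes 1..n-1) at escape probability p_e.

        For a folded model the classes are minor-allele counts (upper half
        zero), matching the background representation.
        """
        w = binom.pmf(np.arange(self.n + 1), self.n, p_e)
        raw = w @ self._T
        poly = raw[1:-1]
        mass = poly.sum()
        if mass < 1e-12:
            raise ValueError(
                f"degenerate sweep spectrum at p_e={p_e}: polymorphic mass {mass}"
            )
        poly = poly / mass
        return self._fold_vector(poly) if self.folded else poly

    def sweep_site_prob(self, j: int, d: float, alpha: float) -> float:
        """Exact P(derived count j | distance d, strength alpha)."""
        if not 1 <= j <= self.n - 1:
            raise ValueError(f"derived count must be in 1..{self.n - 1}")
        if d < 0:
            raise ValueError("distance must be >= 0")
        if alpha is None or np.isinf(alpha) or alpha * d >= self.T_BACKGROUND:
            return float(self.sfs.probs[j - 1])
        if alpha <= 0:
            raise ValueError("alpha must be positive (or inf for the null)")
        p_e = -math.expm1(-alpha * d)
        return float(self.mixture(p_e)[j - 1])

    # -- scan tables ----------------------------------------------------
    def _build_tables(self, K: int) -> None:
        """Per-class log-likelihood ratio g_j(t) on a log grid of t = alpha*d."""
        self._log_t_lo = math.log(self.T_MIN)
        self._log_t_hi = math.log(self.T_BACKGROUND)
        self._K = K
        ts = np.exp(np.linspace(self._log_t_lo, self._log_t_hi, K + 1))
        G = np.zeros((self.n - 1, K + 1), dtype=np.float64)
        v = self._valid
        with np.errstate(divide="ignore"):
            for k, t in enumerate(ts):
                mix = self.mixture(-math.expm1(-t))
                G[v, k] = np.log(mix[v]) - self._log_bg[v]
        self._G = np.ascontiguousarray(G, dtype=np.float32)
        self._h = (self._log_t_hi - self._log_t_lo) / K

    def clr_positions(self, xs: np.ndarray, positions: np.ndarray, counts: np.ndarray):
        """CLR and argmax alpha at each test position ``xs``.

        Per-site log-likelihood ratios come from the precomputed t-grid with
        linear interpolation; sites beyond the background distance contribute
        exactly zero, so the alpha = infinity sentinel gives CLR >= 0 always.
        """
        xs = np.asarray(xs, dtype=float)
        positions = np.asarray(positions, dtype=float)
        counts = np.asarray(counts, dtype=int)
        if positions.size == 0:
            raise ValueError("no SNPs supplied")
        if counts.min() < 1 or counts.max() > self.n - 1:
            raise ValueError("derived counts outside 1..n-1; filter monomorphic sites")
        logd = np.log(np.maximum(np.abs(positions[None, :] - xs[:, None]), 0.5)).astype(np.float32)
        jrow = (counts - 1).astype(np.int64) * (self._K + 1)
        Gf = self._G.ravel()
        best = np.zeros(xs.size)
        best_alpha = np.full(xs.size, np.inf)
        lo, h, K = self._log_t_lo, self._h, self._K
        for alpha in self.alpha_grid:
            if np.isinf(alpha):
                continue
            u = (logd + np.float32(math.log(alpha) - lo)) / np.float32(h)
            np.clip(u, 0.0, K - 1e-4, out=u)
            ui = u.astype(np.int64)
            frac = u - ui
            idx = jrow[None, :] + ui
            g = Gf[idx] * (1.0 - frac) + Gf[idx + 1] * frac
            ll = g.sum(axis=1, dtype=np.float64)
            better = ll > best
            best[better] = ll[better]
            best_alpha[better] = alpha
        return 2.0 * best, best_alpha

    def clr_at_position(self, x: float, positions: np.ndarray, counts: np.ndarray):
        lam, a = self.clr_positions(np.array([x]), positions, counts)
        return float(lam[0]), float(a[0])


# ---------------------------------------------------------------------------
# Genome scan
# ---------------------------------------------------------------------------

def derived_counts(matrix: GenotypeMatrix, population: str | None, chrom: str):
    """Positions (0-based) and derived counts of complete polymorphic sites.

    Sites with missing calls in the population are dropped with a log entry
    (the scan model is built at a single sample size).
    """
    alleles = matrix.population_alleles(population)
    cols = matrix.chrom_columns(chrom)
    pos = matrix.site_positions(chrom)
    block = alleles[:, cols]
    n = block.shape[0]
    complete = (block != MISSING).all(axis=0)
    k = (block == 1).sum(axis=0)
    keep = complete & (k > 0) & (k < n)
    n_inc = int((~complete).sum())
    if n_inc:
        log.info("scan: dropping %d sites on %s with missing calls", n_inc, chrom)
    return pos[keep], k[keep]


def scan_genome(
    matrix: GenotypeMatrix,
    population: str | None,
    windows: WindowTrack,
    model: SweepModel | None = None,
    folded: bool = False,
) -> WindowTrack:
    """One CLR evaluation per window, at the window midpoint.

    The background spectrum defaults to the genome-wide spectrum of the same
    population.  Chromosomes without SNPs leave their windows unvalued.
    """
    if model is None:
        model = SweepModel(background_sfs(matrix, population, folded=folded))
    for chrom in windows.chroms():
        pos, counts = derived_counts(matrix, population, chrom)
        wins = windows.on_chrom(chrom)
        if pos.size == 0:
            log.warning("no SNPs on %s; windows left unvalued", chrom)
            continue
        if model.folded:
            counts = np.minimum(counts, model.n - counts)
        xs = np.array([w.midpoint for w in wins])
        lam, alpha_hat = model.clr_positions(xs, pos, counts)
        for w, l, a in zip(wins, lam, alpha_hat):
            w.values["CLR"] = float(l)
            w.values["alpha_hat"] = float(a)
    return windows


# ---------------------------------------------------------------------------
# Loess smoothing
# ---------------------------------------------------------------------------

def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.5,
    degree: int = 2,
    eval_x: np.ndarray | None = None,
) -> np.ndarray:
    """Tricube-weighted local polynomial regression (Cleveland's loess).

    The neighbourhood of each evaluation point is the ceil(span * n) nearest
    data points; weights are tricube in scaled distance.  ``degree`` 1 gives
    classic lowess, 2 the loess default used for genome-wide visualisation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if eval_x is None:
        eval_x = x
    n = x.size
    k = min(n, max(degree + 2, int(math.ceil(span * n))))
    out = np.empty(eval_x.size)
    for m, xi in enumerate(np.asarray(eval_x, dtype=float)):
        dist = np.abs(x - xi)
        if k < n:
            idx = np.argpartition(dist, k - 1)[:k]
        else:
            idx = np.arange(n)
        dmax = dist[idx].max()
        if dmax == 0:
            w = np.ones(idx.size)
        else:
            w = (1.0 - np.minimum(dist[idx] / dmax, 1.0) ** 3) ** 3
        pos = w > 0
        if pos.sum() <= degree:  # not enough support for the fit
            w = np.maximum(w, 1e-12)
            pos = np.ones_like(w, dtype=bool)
        xc = x[idx] - xi  # centre for conditioning
        coeffs = np.polyfit(xc[pos], y[idx][pos], degree, w=np.sqrt(w[pos]))
        out[m] = coeffs[-1]
    return out


def loess_smooth(
    track: WindowTrack,
    stat: str = "CLR",
    span: float = 0.5,
    degree: int = 2,
    fill_gaps_zero: bool = True,
    out_stat: str | None = None,
) -> WindowTrack:
    """Loess-smooth a window statistic per chromosome for visualisation.

    Unvalued windows (gaps) are assigned 0 before fitting when
    ``fill_gaps_zero`` is set.  Chromosomes with fewer than 5 windows are
    returned unsmoothed with a warning.
    """
    out_stat = out_stat or f"{stat}_smooth"
    for chrom in track.chroms():
        wins = track.on_chrom(chrom)
        xs = np.array([w.midpoint for w in wins])
        if fill_gaps_zero:
            ys = np.array([w.values.get(stat, 0.0) for w in wins])
        else:
            wins = [w for w in wins if stat in w.values]
            xs = np.array([w.midpoint for w in wins])
            ys = np.array([w.values[stat] for w in wins])
        if len(wins) < 5:
            log.warning("%s: fewer than 5 windows; returned unsmoothed", chrom)
            for w, v in zip(wins, ys):
                w.values[out_stat] = float(v)
            continue
        sm = loess_fit(xs, ys, span=span, degree=degree)
        for w, v in zip(wins, sm):
            w.values[out_stat] = float(v)
    return track


__all__ = [
    "SFS",
    "fold_sfs",
    "background_sfs",
    "project_distribution",
    "project_sfs",
    "default_alpha_grid",
    "SweepModel",
    "derived_counts",
    "scan_genome",
    "loess_fit",
    "loess_smooth",
]
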