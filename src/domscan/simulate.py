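"""Synthetic three-population cohorts with machine-readable ground truth.

The generator emulates the statistical structure the scans assume: three
populations related by two nested splits (topology ((Lowland, Guatemalan),
Mexican)), neutral diversity near 0.0035 per site, optional hard-sweep
footprints, admixed accessions, structural-variant sets over synthetic gene
models, and clean/noisy coalescence-rate curves with a known split time.

The coalescent runs on independent 1-kb segments: no recombination within a
segment, free recombination between segments.  This approximates linkage at
the window scale the statistics operate on while keeping every segment's
genealogy exact and cheap.

Default demographic anchors: per-population diploid Ne of 23,148 gives
theta = 4*Ne*mu = 0.0035 at mu = 3.78e-8 per site per generation
(5.4e-9 per year x 7-year generations); the Lowland/Guatemalan split sits
at 44,000 years (6,286 generations) and the Mexican split at 1.3 million
years (185,714 generations).

Sweeps are emulated with the star-approximation hard-sweep coalescent: at
a recent time ``duration`` (default 0.05 * 2Ne generations, the timescale
of a strong completed sweep) each lineage of the swept population escapes
the sweep independently with probability f(d) = s + (1-s)*min(1, d/r) for
a segment at distance d from the sweep center, and all non-escaping
lineages coalesce instantly into the single swept ancestor.  Full capture
at the center (escape factor s) carves the diversity trough; partial
capture in the flanks leaves the classic U-shaped spectrum — excess
singletons on the short terminal branches plus high-frequency derived
alleles on the branch subtending the captured clade — which is exactly the
signature a composite-likelihood sweep scan detects.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .types import GROUPS, GeneModel, GenotypeMatrix, SVRecord, VariantSite

# mutation rate per site per generation: 5.4e-9 / site / year * 7 years
MU_PER_GEN = 5.4e-9 * 7.0
#: diploid Ne giving theta = 4*Ne*mu = 0.0035
NE_DEFAULT = int(round(0.0035 / (4 * MU_PER_GEN)))
#: generations for the 44,000-year Lowland/Guatemalan split
T_RECENT_DEFAULT = int(round(44_000 / 7))
#: generations for the 1.3-My Mexican split
T_DEEP_DEFAULT = int(round(1_300_000 / 7))

_BASES = np.array(list("ACGT"))


@dataclass
class SweepSpec:
    """A planted hard-sweep footprint."""

    population: str
    chrom: str
    center: int
    radius: int = 50_000
    s: float = 0.05  # escape factor at the center: 1-s of lineages captured
    duration: int | None = None  # sweep age in generations; default 0.05 * 2Ne

    def __post_init__(self) -> None:
        if not 0 < self.s <= 1:
            raise ValueError("sweep intensity s must be in (0, 1]")

    def escape_factor(self, position: float) -> float:
        """f(d): per-lineage escape probability at ``position``.

        Equals ``s`` at the sweep center and recovers linearly to 1
        (neutral) at distance ``radius``.
        """
        d = abs(position - self.center)
        return self.s + (1.0 - self.s) * min(1.0, d / self.radius)


@dataclass
class HybridSpec:
    """An admixed accession built by segment-wise copying from source pools."""

    name: str
    proportions: dict[str, float]

    def __post_init__(self) -> None:
        if abs(sum(self.proportions.values()) - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: hybrid proportions must sum to 1")


@dataclass
class SVSpec:
    """Plan for a synthetic structural-variant set over gene models."""

    n_sv: int = 60
    frac_low: tuple[float, float] = (0.05, 0.18)
    frac_high: tuple[float, float] = (0.22, 0.60)
    p_high: float = 0.3
    supports: tuple[int, ...] = (2, 3, 4, 6, 10)
    p_insertion: float = 0.2


@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic cohort."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 1_000_000 for i in range(1, 13)}
    )
    segment_length: int = 1000
    samples: dict[str, int] = field(
        default_factory=lambda: {"Mexican": 3, "Lowland": 5, "Guatemalan": 10}
    )
    ne: dict[str, int] = field(
        default_factory=lambda: {g: NE_DEFAULT for g in GROUPS}
    )
    ne_ancestral_recent: int = NE_DEFAULT  # Lowland+Guatemalan ancestor
    ne_ancestral_deep: int = NE_DEFAULT  # root population
    t_recent: int = T_RECENT_DEFAULT  # generations
    t_deep: int = T_DEEP_DEFAULT
    mu: float = MU_PER_GEN
    sweeps: list[SweepSpec] = field(default_factory=list)
    hybrids: list[HybridSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.t_recent >= self.t_deep:
            raise ValueError("t_recent must be younger than t_deep")
        n_hap = 2 * sum(self.samples.values())
        if n_hap > 64:
            raise ValueError("at most 32 diploid samples supported")


@dataclass
class TruthSet:
    """Ground truth emitted alongside the cohort."""

    seed: int | None
    config: SimulationConfig
    sweeps: list[SweepSpec]
    #: hybrid name -> chrom -> (n_segments, 2) array of source-population indices
    hybrid_sources: dict[str, dict[str, np.ndarray]]
    #: chrom -> per-segment TMRCA in generations
    segment_tmrca: dict[str, np.ndarray]
    source_pops: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Structured coalescent
# ---------------------------------------------------------------------------

def simulate_genealogy(
    samples: dict[str, int],
    ne: dict[str, int],
    t_recent: float,
    t_deep: float,
    rng: np.random.Generator,
    ne_anc_recent: float | None = None,
    ne_anc_deep: float | None = None,
    sweep_pop: str | None = None,
    sweep_escape: float = 1.0,
    sweep_time: float = 0.0,
):
    """One structured-coalescent genealogy for a single non-recombining segment.

    Lineages within a population of diploid size N coalesce pairwise at rate
    1/(2N) per generation; at ``t_recent`` the Lowland and Guatemalan pools
    merge, at ``t_deep`` the merged pool joins Mexican.  No migration.

    If a sweep is active (``sweep_escape < 1``), at ``sweep_time`` each
    lineage of ``sweep_pop`` escapes independently with probability
    ``sweep_escape``; the non-escaping lineages merge instantly into the
    swept ancestor (star approximation of a completed hard sweep).

    Returns ``(parent, time, n_leaves)``: arrays over the tree nodes
    (leaves first, in the order the populations appear in ``samples``),
    ``parent[root] == -1``, times in generations.
    """
    ne_anc_recent = ne_anc_recent if ne_anc_recent is not None else max(ne.values())
    ne_anc_deep = ne_anc_deep if ne_anc_deep is not None else max(ne.values())
    n = sum(2 * k for k in samples.values())
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    pools: dict[str, list[int]] = {}
    i = 0
    for pop, k in samples.items():
        pools[pop] = list(range(i, i + 2 * k))
        i += 2 * k
    pool_ne = {p: float(ne[p]) for p in pools}

    boundaries: list[tuple[float, str]] = []
    if sweep_pop in pools and sweep_escape < 1.0:
        boundaries.append((sweep_time, "sweep_capture"))
    boundaries.append((t_recent, "merge_recent"))
    boundaries.append((t_deep, "merge_deep"))
    boundaries.sort()

    next_id = n
    t = 0.0
    bi = 0
    exp = rng.exponential
    randint = rng.integers
    while sum(len(v) for v in pools.values()) > 1:
        rates = []
        total = 0.0
        for pop, lin in pools.items():
            k = len(lin)
            if k < 2:
                rates.append((pop, 0.0))
                continue
            r = k * (k - 1) / 2.0 / (2.0 * pool_ne[pop])
            rates.append((pop, r))
            total += r
        if total > 0:
            dt = exp(1.0 / total)
        else:
            dt = math.inf
        if bi < len(boundaries) and t + dt >= boundaries[bi][0]:
            t, what = boundaries[bi]
            bi += 1
            if what == "sweep_capture":
                lin = pools.get(sweep_pop, [])
                captured = [x for x in lin if rng.random() >= sweep_escape]
                if len(captured) >= 2:
                    keep = captured[0]
                    for other in captured[1:]:
                        parent[keep] = parent[other] = next_id
                        time[next_id] = t
                        keep = next_id
                        next_id += 1
                    pools[sweep_pop] = [x for x in lin if x not in captured] + [keep]
            elif what == "merge_recent":
                merged = pools.pop("Lowland", []) + pools.pop("Guatemalan", [])
                if merged:
                    pools["LG"] = merged
                    pool_ne["LG"] = float(ne_anc_recent)
            elif what == "merge_deep":
                merged = []
                for p in list(pools):  # root population absorbs every pool
                    merged += pools.pop(p)
                pools["ANC"] = merged
                pool_ne["ANC"] = float(ne_anc_deep)
            continue
        t += dt
        # choose pool proportional to rate
        u = rng.random() * total
        acc = 0.0
        for pop, r in rates:
            acc += r
            if u <= acc:
                break
        lin = pools[pop]
        k = len(lin)
        a = int(randint(k))
        b = int(randint(k - 1))
        if b >= a:
            b += 1
        ca, cb = lin[a], lin[b]
        parent[ca] = parent[cb] = next_id
        time[next_id] = t
        # replace a with the new node, remove b
        lin[a] = next_id
        lin[b] = lin[-1]
        lin.pop()
        next_id += 1
    return parent, time, n


def leaf_masks(parent: np.ndarray, n_leaves: int) -> np.ndarray:
    """Per-node descendant-leaf bitmasks (uint64); leaves are bits 0..n-1."""
    masks = np.zeros(parent.size, dtype=np.uint64)
    masks[:n_leaves] = np.uint64(1) << np.arange(n_leaves, dtype=np.uint64)
    for i in range(parent.size - 1):  # root is last, parent -1
        p = parent[i]
        if p >= 0:
            masks[p] |= masks[i]
    return masks


def drop_mutations(
    parent: np.ndarray,
    time: np.ndarray,
    n_leaves: int,
    segment_length: int,
    mu: float,
    rng: np.random.Generator,
):
    """Poisson mutations on the tree under infinite sites.

    Returns ``(positions, masks)``: unique 0-based positions within the
    segment and the descendant-leaf bitmask of each mutation's branch.
    """
    blen = np.zeros(parent.size)
    has_parent = parent >= 0
    blen[has_parent] = time[parent[has_parent]] - time[has_parent]
    total = blen.sum()
    n_mut = rng.poisson(total * mu * segment_length)
    if n_mut == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint64)
    cum = np.cumsum(blen)
    nodes = np.searchsorted(cum, rng.random(n_mut) * total)
    pos = rng.integers(0, segment_length, size=n_mut)
    pos, first = np.unique(pos, return_index=True)  # infinite sites: drop collisions
    masks = leaf_masks(parent, n_leaves)[nodes[first]]
    return pos.astype(np.int64), masks


def _mask_columns(masks: np.ndarray, n_leaves: int) -> np.ndarray:
    """(n_leaves, n_mut) 0/1 allele block from descendant bitmasks."""
    bits = (masks[None, :] >> np.arange(n_leaves, dtype=np.uint64)[:, None]) & np.uint64(1)
    return bits.astype(np.int8)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def apply_sweep_distortion(config: SimulationConfig, chrom: str, seg_mid: float):
    """Per-segment sweep parameters: (pop, escape factor, sweep age) or None.

    The escape factor is f(d) = s + (1-s)*min(1, d/r): full distortion
    (factor s) at the center, linear recovery to neutral at distance r.
    When several sweeps overlap a segment the strongest (smallest factor)
    wins.
    """
    best = None
    for sw in config.sweeps:
        if sw.chrom != chrom:
            continue
        f = sw.escape_factor(seg_mid)
        if f < 1.0 and (best is None or f < best[1]):
            dur = sw.duration
            if dur is None:
                dur = 0.05 * 2.0 * config.ne[sw.population]
            best = (sw.population, f, dur)
    return best


def simulate_cohort(config: SimulationConfig, seed: int | None = None):
    """Simulate the full cohort; returns ``(GenotypeMatrix, TruthSet)``."""
    rng = np.random.default_rng(seed)
    pops = [p for p in config.samples if config.samples[p] > 0]
    sample_names: list[str] = []
    sample_pops: list[str] = []
    for p in pops:
        for i in range(config.samples[p]):
            sample_names.append(f"{p[:3]}{i + 1:02d}")
            sample_pops.append(p)
    n_pure_hap = 2 * sum(config.samples[p] for p in pops)
    hap_pop = np.repeat(
        [pops.index(p) for p in sample_pops], 2
    )  # per pure haplotype, source-pop index
    for h in config.hybrids:
        sample_names.append(h.name)
        sample_pops.append("admixed")
        for p in h.proportions:
            if p not in pops:
                raise ValueError(f"hybrid {h.name}: unknown source population {p}")

    L = config.segment_length
    blocks: list[np.ndarray] = []
    sites: list[VariantSite] = []
    hybrid_sources: dict[str, dict[str, list]] = {
        h.name: {} for h in config.hybrids
    }
    tmrca: dict[str, np.ndarray] = {}
    samples_active = {p: config.samples[p] for p in pops}
    for chrom, length in config.chrom_lengths.items():
        n_seg = (length + L - 1) // L
        seg_tm = np.empty(n_seg)
        for h in config.hybrids:
            hybrid_sources[h.name][chrom] = []
        for si in range(n_seg):
            seg_start = si * L
            seg_len = min(L, length - seg_start)
            sweep = apply_sweep_distortion(config, chrom, seg_start + seg_len / 2)
            kwargs = {}
            if sweep is not None:
                kwargs = dict(
                    sweep_pop=sweep[0], sweep_escape=sweep[1], sweep_time=sweep[2]
                )
            parent, time, n = simulate_genealogy(
                samples_active,
                config.ne,
                config.t_recent,
                config.t_deep,
                rng,
                ne_anc_recent=config.ne_ancestral_recent,
                ne_anc_deep=config.ne_ancestral_deep,
                **kwargs,
            )
            seg_tm[si] = time.max()
            pos, masks = drop_mutations(parent, time, n, seg_len, config.mu, rng)
            block = _mask_columns(masks, n)
            # hybrids copy one pure haplotype per segment, per haplotype
            hyb_rows = []
            for h in config.hybrids:
                probs = np.array([h.proportions.get(p, 0.0) for p in pops])
                src = rng.choice(len(pops), size=2, p=probs)
                hybrid_sources[h.name][chrom].append(src)
                for s_idx in src:
                    pool = np.flatnonzero(hap_pop == s_idx)
                    hyb_rows.append(block[rng.choice(pool)])
            if hyb_rows:
                block = np.vstack([block] + [r[None, :] for r in hyb_rows])
            blocks.append(block)
            ref_idx = rng.integers(0, 4, size=pos.size)
            refs = _BASES[ref_idx]
            alts = _BASES[(ref_idx + rng.integers(1, 4, size=pos.size)) % 4]
            for p, r, a in zip(pos, refs, alts):
                sites.append(
                    VariantSite(chrom, int(seg_start + p) + 1, str(r), (str(a),), qual=60.0, depth=25)
                )
        tmrca[chrom] = seg_tm
    hap = (
        np.hstack(blocks)
        if blocks
        else np.empty((n_pure_hap + 2 * len(config.hybrids), 0), dtype=np.int8)
    )
    matrix = GenotypeMatrix(hap, sample_names, sample_pops, sites)
    truth = TruthSet(
        seed=seed,
        config=config,
        sweeps=list(config.sweeps),
        hybrid_sources={
            name: {c: np.array(v) for c, v in per.items()}
            for name, per in hybrid_sources.items()
        },
        segment_tmrca=tmrca,
        source_pops=pops,
    )
    return matrix, truth


def make_hybrids(matrix: GenotypeMatrix, hybrid_specs, segment_length: int, seed=None):
    """Standalone hybridiser for an existing pure cohort.

    Each hybrid haplotype copies, independently per segment, one haplotype
    from a source population chosen with the spec's proportions.  Returns the
    augmented matrix and the per-segment source records.
    """
    rng = np.random.default_rng(seed)
    pops = [p for p in dict.fromkeys(matrix.populations) if p not in ("admixed",)]
    new_rows = []
    names = list(matrix.samples)
    labels = list(matrix.populations)
    sources: dict[str, list] = {}
    chrom_of = np.array([s.chrom for s in matrix.sites])
    seg_of = np.array([(s.pos - 1) // segment_length for s in matrix.sites])
    seg_key = np.unique(np.stack([chrom_of, seg_of.astype(str)], axis=1), axis=0)
    for h in hybrid_specs:
        probs = np.array([h.proportions.get(p, 0.0) for p in pops])
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"{h.name}: proportions must sum to 1 over {pops}")
        rows = [np.empty(matrix.n_sites, dtype=np.int8) for _ in range(2)]
        rec = []
        for chrom, seg in seg_key:
            sel = (chrom_of == chrom) & (seg_of == int(seg))
            src = rng.choice(len(pops), size=2, p=probs)
            rec.append(src)
            for hap_i, s_idx in enumerate(src):
                pool = matrix.haplotype_rows(pops[s_idx])
                rows[hap_i][sel] = matrix.haplotypes[rng.choice(pool)][sel]
        sources[h.name] = rec
        new_rows += rows
        names.append(h.name)
        labels.append("admixed")
    hap = np.vstack([matrix.haplotypes] + [r[None, :] for r in new_rows])
    return GenotypeMatrix(hap, names, labels, matrix.sites), sources


# ---------------------------------------------------------------------------
# Gene models and structural variants
# ---------------------------------------------------------------------------

def make_genes(
    chrom_lengths: dict[str, int],
    spacing: int = 10_000,
    gene_length: int = 3_000,
    n_exons: int = 3,
    seed: int | None = None,
) -> list[GeneModel]:
    """Regularly spaced synthetic gene models with ``n_exons`` CDS exons."""
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    for chrom, length in chrom_lengths.items():
        gi = 0
        for start in range(spacing // 2, length - gene_length, spacing):
            jitter = int(rng.integers(0, spacing // 4))
            s = start + jitter
            e = s + gene_length
            if e > length:
                break
            exon_len = gene_length // (2 * n_exons)
            cds = []
            for x in range(n_exons):
                cs = s + x * 2 * exon_len
                cds.append((cs, cs + exon_len))
            gi += 1
            genes.append(GeneModel(f"{chrom}.g{gi:04d}", chrom, s, e, cds))
    return genes


def _deletion_covering(gene: GeneModel, cds_bases: int) -> tuple[int, int]:
    """Genomic (start, length) of a deletion covering ``cds_bases`` of CDS."""
    start = gene.cds[0][0]
    remaining = cds_bases
    for s, e in gene.cds:
        take = min(e - s, remaining)
        remaining -= take
        if remaining == 0:
            return start, (s + take) - start
    raise ValueError("requested more CDS bases than the gene has")


def simulate_sv_set(genes, spec: SVSpec, seed: int | None = None):
    """Plant deletions/insertions over genes with known hemizygosity truth.

    Returns ``(svs, truth_flags)`` where ``truth_flags`` maps gene_id -> bool
    under the calling rules (CDS fraction >= 0.20 and read support >= 4).
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    idx = rng.permutation(len(genes))[: spec.n_sv]
    svs: list[SVRecord] = []
    truth: dict[str, bool] = {g.gene_id: False for g in genes}
    for i in idx:
        g = genes[i]
        if g.cds_length == 0:
            continue
        high = rng.random() < spec.p_high
        lo, hi = spec.frac_high if high else spec.frac_low
        frac = rng.uniform(lo, hi)
        support = int(rng.choice(spec.supports))
        cds_bases = max(1, int(round(frac * g.cds_length)))
        achieved = cds_bases / g.cds_length
        if rng.random() < spec.p_insertion:
            # insertion breakpoint inside the first CDS exon
            bp = g.cds[0][0] + int(rng.integers(0, g.cds[0][1] - g.cds[0][0]))
            svs.append(SVRecord(g.chrom, bp, "INS", cds_bases, support))
        else:
            start, length = _deletion_covering(g, cds_bases)
            svs.append(SVRecord(g.chrom, start, "DEL", length, support))
        if achieved >= 0.20 and support >= 4:
            truth[g.gene_id] = True
    return svs, truth


def write_sv_vcf(path, svs) -> None:
    """Write SVs in a SNIFFLES-like VCF dialect (SVTYPE/SVLEN/END/RE)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=domscan-simulate\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n')
        fh.write('##INFO=<ID=RE,Number=1,Type=Integer,Description="Supporting reads">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for i, sv in enumerate(svs, 1):
            svlen = -sv.length if sv.svtype == "DEL" else sv.length
            end = sv.start + sv.length if sv.svtype == "DEL" else sv.start + 1
            fh.write(
                f"{sv.chrom}\t{sv.start + 1}\t{sv.svtype}.{i}\tN\t<{sv.svtype}>\t.\tPASS\t"
                f"SVTYPE={sv.svtype};SVLEN={svlen};END={end};RE={sv.read_support}\t"
                "GT\t0/1\n"
            )


# ---------------------------------------------------------------------------
# Coalescence-rate curves
# ---------------------------------------------------------------------------

def simulate_rate_curves(
    t_split_years: float = 44_000,
    ne: float = NE_DEFAULT,
    mu_per_year: float = 5.4e-9,
    generation_years: float = 7.0,
    n_epochs: int = 32,
    t_min_years: float = 1e3,
    t_max_years: float = 1e7,
    noise_sigma: float = 0.0,
    seed: int | None = None,
):
    """Piecewise-constant rate curves with a sharp cross-coalescence step.

    Clean mode sets lambda00 = lambda11 = 1/(2*Ne*mu_gen) (in the scaled
    units where Ne = 1/(2*lambda*mu_gen)) and lambda01 = 0 for epochs whose
    midpoint is younger than the split, equal to lambda00 for older epochs.
    Noisy mode multiplies every rate by lognormal(0, sigma) noise.

    Returns ``(RateCurve, truth)`` where ``truth['implied_split_years']`` is
    the crossing time the constructed step implies under midpoint
    interpolation — the quantity a correct rCCR analysis should recover.
    """
    from .crosscoal import RateCurve

    rng = np.random.default_rng(seed)
    mu_gen = mu_per_year * generation_years
    edges_years = np.concatenate(
        [[0.0], np.geomspace(t_min_years, t_max_years, n_epochs)]
    )
    left_y, right_y = edges_years[:-1], edges_years[1:]
    mid_y = 0.5 * (left_y + right_y)
    lam = 1.0 / (2.0 * ne * mu_gen)
    lam00 = np.full(n_epochs, lam)
    lam11 = np.full(n_epochs, lam)
    lam01 = np.where(mid_y >= t_split_years, lam, 0.0)
    if noise_sigma > 0:
        lam00 = lam00 * rng.lognormal(0.0, noise_sigma, n_epochs)
        lam11 = lam11 * rng.lognormal(0.0, noise_sigma, n_epochs)
        lam01 = lam01 * rng.lognormal(0.0, noise_sigma, n_epochs)
    step = np.flatnonzero(mid_y >= t_split_years)
    if step.size == 0 or step[0] == 0:
        implied = float(mid_y[0])
    else:
        k = step[0]
        implied = float(0.5 * (mid_y[k - 1] + mid_y[k]))
    curve = RateCurve(
        left=left_y * mu_per_year,
        right=right_y * mu_per_year,
        lambda00=lam00,
        lambda01=lam01,
        lambda11=lam11,
        labels=("pop0", "pop1"),
    )
    truth = {
        "requested_split_years": float(t_split_years),
        "implied_split_years": implied,
        "ne": float(ne),
    }
    return curve, truth


__all__ = [
    "MU_PER_GEN",
    "NE_DEFAULT",
    "T_RECENT_DEFAULT",
    "T_DEEP_DEFAULT",
    "SweepSpec",
    "HybridSpec",
    "SVSpec",
    "SimulationConfig",
    "TruthSet",
    "simulate_genealogy",
    "leaf_masks",
    "drop_mutations",
    "apply_sweep_distortion",
    "simulate_cohort",
    "make_hybrids",
    "make_genes",
    "simulate_sv_set",
    "write_sv_vcf",
    "simulate_rate_curves",
]
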