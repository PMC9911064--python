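"""VCF/GFF3/Q-matrix I/O, site- and sample-level QC, window tiling and
ancestry-based cohort classification.

Site QC mirrors the bcftools expression ``-s LowQual -e "%QUAL < 20 || DP > 32"``
used to flag low-confidence calls in resequencing cohorts: a site is LowQual
when its quality is strictly below the minimum *or* its depth strictly above
the maximum (excess depth marks collapsed repeats).  Sample QC removes
individuals with too much missing data, with a laxer bound for outgroup taxa.
"""
from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import (
    GROUPS,
    MISSING,
    AncestryProfile,
    GeneModel,
    GenotypeMatrix,
    VariantSite,
    Window,
    WindowTrack,
    merge_intervals,
    replace,
)

log = logging.getLogger(__name__)

OUTGROUP_LABELS = frozenset({"outgroup"})


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, sample_subset: Sequence[str] | None = None):
    """Read a VCF into ``(list[VariantSite], GenotypeMatrix)``.

    Every record becomes one matrix column; missing genotypes map to
    :data:`~domscan.types.MISSING` on both haplotypes.  Multiallelic records
    are retained (allele codes > 1) but are flagged non-biallelic on the
    site and removed later by :func:`select_biallelic_snps`.

    Population labels default to ``unknown``; callers attach labels via
    :func:`attach_populations` or take them from a classification table.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    if sample_subset is not None:
        unknown = set(sample_subset) - set(vcf.samples)
        if unknown:
            raise ValueError(f"samples not in VCF header: {sorted(unknown)}")
        vcf.set_samples(list(sample_subset))
    samples = list(vcf.samples)

    sites: list[VariantSite] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if rec.REF is None or rec.POS is None:
            raise ValueError(f"malformed VCF record near {rec.CHROM}:{rec.POS}")
        depth = rec.INFO.get("DP")
        site = VariantSite(
            chrom=rec.CHROM,
            pos=rec.POS,
            ref=rec.REF,
            alt=tuple(rec.ALT),
            qual=rec.QUAL,
            depth=int(depth) if depth is not None else None,
            filter_flag=rec.FILTER or "PASS",
        )
        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            a, b = gt[0], gt[1]
            col[2 * i] = a if a is not None and a >= 0 else MISSING
            col[2 * i + 1] = b if b is not None and b >= 0 else MISSING
        sites.append(site)
        columns.append(col)
    hap = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((2 * len(samples), 0), dtype=np.int8)
    )
    matrix = GenotypeMatrix(hap, samples, ["unknown"] * len(samples), sites)
    return sites, matrix


def write_vcf(path, matrix: GenotypeMatrix, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a minimal phased VCF 4.2 for ``matrix``."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=domscan\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Site depth">\n')
        fh.write('##FILTER=<ID=LowQual,Description="QUAL < 20 || DP > 32">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        hap = matrix.haplotypes
        for j, site in enumerate(matrix.sites):
            qual = "." if site.qual is None else f"{site.qual:g}"
            info = "." if site.depth is None else f"DP={site.depth}"
            gts = []
            for i in range(matrix.n_samples):
                a, b = hap[2 * i, j], hap[2 * i + 1, j]
                gts.append(
                    ("." if a == MISSING else str(a))
                    + "|"
                    + ("." if b == MISSING else str(b))
                )
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{','.join(site.alt)}\t"
                f"{qual}\t{site.filter_flag}\t{info}\tGT\t" + "\t".join(gts) + "\n"
            )


def attach_populations(matrix: GenotypeMatrix, labels: dict[str, str]) -> GenotypeMatrix:
    """Return a copy of ``matrix`` with per-sample population labels set."""
    pops = [labels.get(s, "unknown") for s in matrix.samples]
    return GenotypeMatrix(matrix.haplotypes, matrix.samples, pops, matrix.sites)


# ---------------------------------------------------------------------------
# Site and sample QC
# ---------------------------------------------------------------------------

def site_qc_flag(site: VariantSite, qual_min: float = 20.0, dp_max: int = 32) -> VariantSite:
    """Flag ``site`` LowQual iff ``qual < qual_min`` or ``depth > dp_max``.

    Both inequalities are strict, mirroring the bcftools expression.  A site
    with no depth annotation passes the depth clause (the expression cannot
    evaluate it); this is logged once per call site.
    """
    if site.depth is not None and site.depth < 0:
        raise ValueError(f"negative depth at {site.chrom}:{site.pos}")
    low = False
    if site.qual is not None and site.qual < qual_min:
        low = True
    if site.depth is None:
        log.debug("site %s:%d has no DP; depth clause passes", site.chrom, site.pos)
    elif site.depth > dp_max:
        low = True
    return replace(site, filter_flag="LowQual" if low else "PASS")


def apply_site_qc(matrix: GenotypeMatrix, qual_min: float = 20.0, dp_max: int = 32) -> GenotypeMatrix:
    sites = [site_qc_flag(s, qual_min, dp_max) for s in matrix.sites]
    return GenotypeMatrix(matrix.haplotypes, matrix.samples, matrix.populations, sites)


def select_biallelic_snps(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Keep only PASS, biallelic, single-nucleotide sites, in original order."""
    keep = [
        i
        for i, s in enumerate(matrix.sites)
        if s.filter_flag == "PASS" and s.is_snp
    ]
    return matrix.subset_sites(keep)


def missingness_filter(
    matrix: GenotypeMatrix,
    max_missing_ingroup: float = 0.50,
    max_missing_outgroup: float = 0.75,
) -> GenotypeMatrix:
    """Drop samples with too much missing data (strict: keep iff frac < cutoff).

    Samples labelled ``outgroup`` use the laxer outgroup cutoff; every other
    label counts as ingroup.
    """
    if matrix.n_samples == 0 or matrix.n_sites == 0:
        raise ValueError("cannot compute missingness on an empty matrix")
    frac = matrix.sample_missingness()
    keep = []
    for i, (f, pop) in enumerate(zip(frac, matrix.populations)):
        cutoff = max_missing_outgroup if pop in OUTGROUP_LABELS else max_missing_ingroup
        if f < cutoff:
            keep.append(i)
        else:
            log.info(
                "dropping %s (%s): %.1f%% missing", matrix.samples[i], pop, 100 * f
            )
    return matrix.subset_samples(keep)


# ---------------------------------------------------------------------------
# Window tiling
# ---------------------------------------------------------------------------

def tile_windows(
    chrom_lengths: dict[str, int],
    width: int,
    gap_intervals: dict[str, Iterable[tuple[int, int]]] | None = None,
) -> WindowTrack:
    """Tile each chromosome into non-overlapping ``width``-bp windows.

    The final partial window is kept.  Windows lying entirely inside an
    assembly gap (run of Ns) are removed; the rest carry the fraction of
    their span covered by gaps, so downstream densities can renormalise.
    Overlapping gap intervals are merged, never an error.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    gap_intervals = gap_intervals or {}
    windows: list[Window] = []
    for chrom, length in chrom_lengths.items():
        gaps = merge_intervals(gap_intervals.get(chrom, []))
        for start in range(0, length, width):
            end = min(start + width, length)
            overlap = sum(
                max(0, min(end, ge) - max(start, gs)) for gs, ge in gaps
            )
            if overlap >= end - start:
                continue  # fully inside a gap
            windows.append(
                Window(chrom, start, end, gap_fraction=overlap / (end - start))
            )
    return WindowTrack(windows)


def count_sites_in_windows(track: WindowTrack, matrix: GenotypeMatrix) -> WindowTrack:
    """Fill ``site_count`` for each window from the matrix's site positions."""
    for chrom in track.chroms():
        pos = matrix.site_positions(chrom)
        for w in track.on_chrom(chrom):
            w.site_count = int(np.count_nonzero((pos >= w.start) & (pos < w.end)))
    return track


# ---------------------------------------------------------------------------
# Ancestry classification
# ---------------------------------------------------------------------------

def _normalise_row(accession: str, props: dict[str, float]) -> dict[str, float]:
    total = sum(props.values())
    if 0.99 <= total <= 1.01:
        scale = 1.0
    elif 99.0 <= total <= 101.0:
        scale = 100.0
    else:
        raise ValueError(
            f"{accession}: ancestry proportions sum to {total}; "
            "expected ~1 (fractions) or ~100 (percent)"
        )
    return {g: p / scale for g, p in props.items()}


def classify_accessions(
    profiles: Iterable[AncestryProfile | tuple[str, dict[str, float]]],
    threshold: float = 0.80,
    exclusions: Iterable[str] = (),
) -> list[AncestryProfile]:
    """Assign each accession to its majority group iff Qi > ``threshold``.

    The comparison is strict, so a maximum proportion of exactly 0.80 yields
    ``admixed``.  Accessions in ``exclusions`` (e.g. near-relatives of an
    over-sampled cultivar) are labelled ``excluded`` regardless of Q.
    Rows given in percent (sum ~100) are rescaled to fractions; a row whose
    sum is near neither 1 nor 100 is an error.
    """
    exclusions = set(exclusions)
    out: list[AncestryProfile] = []
    for item in profiles:
        if isinstance(item, AncestryProfile):
            acc, props = item.accession, item.proportions
        else:
            acc, props = item
        props = _normalise_row(acc, dict(props))
        if acc in exclusions:
            group = "excluded"
        else:
            best = max(props, key=props.get)  # type: ignore[arg-type]
            group = best if props[best] > threshold else "admixed"
        out.append(AncestryProfile(acc, props, assigned_group=group))
    return out


def read_qmatrix(
    path,
    accessions: Sequence[str] | None = None,
    groups: Sequence[str] = ("Guatemalan", "Mexican", "Lowland"),
) -> list[tuple[str, dict[str, float]]]:
    """Read a whitespace-delimited Q-matrix (one row per accession, K columns).

    If the file has no accession column, names must be supplied via
    ``accessions``.  A header row naming the groups is honoured; headerless
    files assume the column order given by ``groups``.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    first = df.iloc[0]
    if all(isinstance(v, str) for v in first):  # header row
        df.columns = list(first)
        df = df.iloc[1:].reset_index(drop=True)
    if df.iloc[:, 0].dtype == object:
        names = df.iloc[:, 0].tolist()
        qs = df.iloc[:, 1:].astype(float)
    else:
        if accessions is None:
            raise ValueError("Q-matrix lacks an accession column; pass accessions=")
        names = list(accessions)
        qs = df.astype(float)
    if qs.shape[1] != len(groups):
        raise ValueError(f"expected {len(groups)} Q columns, found {qs.shape[1]}")
    cols = list(qs.columns) if all(isinstance(c, str) for c in qs.columns) else groups
    return [
        (name, {g: float(v) for g, v in zip(cols, row)})
        for name, row in zip(names, qs.to_numpy())
    ]


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def read_gff_genes(path) -> list[GeneModel]:
    """Parse gene models with merged CDS intervals from a GFF3 file.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    CDS features that cannot be traced to a gene are skipped with a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    claimed_cds: set[str] = set()
    for gene in db.features_of_type("gene"):
        cds = []
        for c in db.children(gene, featuretype="CDS"):
            cds.append((c.start - 1, c.end))
            claimed_cds.add(id_of(c))
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                start=gene.start - 1,
                end=gene.end,
                cds=cds,
            )
        )
    for c in db.features_of_type("CDS"):
        if id_of(c) not in claimed_cds:
            log.warning("CDS %s at %s:%d has no parent gene; skipped", c.id, c.seqid, c.start)
    return genes


def id_of(feature) -> str:
    return f"{feature.seqid}:{feature.start}-{feature.end}:{feature.id}"


def write_gff_genes(path, genes: Sequence[GeneModel]) -> None:
    """Write gene models (gene + mRNA + CDS rows) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tdomscan\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\tID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tdomscan\tmRNA\t{g.start + 1}\t{g.end}\t.\t+\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.cds, 1):
                fh.write(
                    f"{g.chrom}\tdomscan\tCDS\t{s + 1}\t{e}\t.\t+\t0\t"
                    f"ID={mrna}.cds{i};Parent={mrna}\n"
                )


# ---------------------------------------------------------------------------
# Assembly summaries
# ---------------------------------------------------------------------------

def n50(lengths: Iterable[int]) -> int:
    """N50 of a set of contig/scaffold lengths.

    The length L such that contigs of length >= L cover at least half the
    assembly.
    """
    arr = np.sort(np.asarray(list(lengths), dtype=np.int64))[::-1]
    if arr.size == 0 or arr[-1] <= 0:
        raise ValueError("n50 requires positive lengths")
    csum = np.cumsum(arr)
    return int(arr[np.searchsorted(csum, csum[-1] / 2)])


__all__ = [
    "read_vcf",
    "write_vcf",
    "attach_populations",
    "site_qc_flag",
    "apply_site_qc",
    "select_biallelic_snps",
    "missingness_filter",
    "tile_windows",
    "count_sites_in_windows",
    "classify_accessions",
    "read_qmatrix",
    "read_gff_genes",
    "write_gff_genes",
    "n50",
]
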