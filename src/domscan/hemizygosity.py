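"""Genic hemizygosity from structural-variant calls.

A gene is called hemizygous when a single well-supported insertion or
deletion affects at least 20% of its coding region: for a deletion, the
overlap between the deleted span and the gene's merged CDS intervals must
reach 20% of the total CDS length; for an insertion (a point event on the
reference), the breakpoint must fall inside the CDS and the inserted
sequence must be at least 20% of the CDS length.  SVs need at least 4
supporting reads to count.  Both thresholds are inclusive; the fraction is
per-event, not cumulative over SVs.
"""
from __future__ import annotations

import logging

import numpy as np

from .types import GeneModel, GeneSet, SVRecord

log = logging.getLogger(__name__)

_SUPPORTED = {"DEL", "INS"}


def read_sv_vcf(path) -> list[SVRecord]:
    """Read SNIFFLES-style SV calls (INFO SVTYPE/SVLEN, RE or SUPPORT)."""
    from cyvcf2 import VCF

    out: list[SVRecord] = []
    for rec in VCF(str(path)):
        svtype = rec.INFO.get("SVTYPE")
        if svtype is None:
            log.warning("record at %s:%d lacks SVTYPE; skipped", rec.CHROM, rec.POS)
            continue
        svlen = rec.INFO.get("SVLEN")
        if svlen is None:
            end = rec.INFO.get("END")
            svlen = (int(end) - rec.POS) if end is not None else None
        if svlen is None:
            log.warning("record at %s:%d lacks SVLEN/END; skipped", rec.CHROM, rec.POS)
            continue
        support = rec.INFO.get("RE")
        if support is None:
            support = rec.INFO.get("SUPPORT", 0)
        out.append(
            SVRecord(
                chrom=rec.CHROM,
                start=rec.POS - 1,
                svtype=str(svtype),
                length=abs(int(svlen)),
                read_support=int(support),
            )
        )
    return out


def read_sv_bed(path) -> list[SVRecord]:
    """Read SVs from BED3+ columns: chrom, start, end, svtype, support."""
    out: list[SVRecord] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, svtype, support = line.split()[:5]
            out.append(
                SVRecord(
                    chrom=chrom,
                    start=int(start),
                    svtype=svtype,
                    length=int(end) - int(start),
                    read_support=int(support),
                )
            )
    return out


def filter_sv(svs, min_support: int = 4) -> list[SVRecord]:
    """Keep indel SVs with read support >= ``min_support`` (inclusive).

    Non-indel types (inversions, duplications, translocations) are skipped
    with a warning: the hemizygosity rule is defined for indels only.
    """
    out: list[SVRecord] = []
    for sv in svs:
        if sv.svtype not in _SUPPORTED:
            log.warning("skipping %s at %s:%d (not an indel)", sv.svtype, sv.chrom, sv.start)
            continue
        if sv.read_support >= min_support:
            out.append(sv)
    return out


def _cds_overlap(gene: GeneModel, start: int, end: int) -> int:
    """Bases of [start, end) overlapping the gene's merged CDS."""
    return sum(max(0, min(end, e) - max(start, s)) for s, e in gene.cds)


def sv_cds_fraction(gene: GeneModel, sv: SVRecord) -> float:
    """Fraction of the gene's coding region affected by one SV.

    Deletions: overlapped CDS bases / total CDS length.  Insertions: the
    inserted length / total CDS length if the breakpoint is inside the CDS,
    else 0.
    """
    if gene.cds_length == 0:
        return 0.0
    if sv.svtype == "DEL":
        return _cds_overlap(gene, sv.start, sv.start + sv.length) / gene.cds_length
    if sv.svtype == "INS":
        inside = any(s <= sv.start < e for s, e in gene.cds)
        return (sv.length / gene.cds_length) if inside else 0.0
    return 0.0


def call_hemizygous(
    genes,
    svs,
    min_cds_fraction: float = 0.20,
    min_support: int | None = None,
    label: str = "hemizygous",
) -> GeneSet:
    """Flag genes where a single SV affects >= ``min_cds_fraction`` of CDS.

    ``svs`` should already be support-filtered via :func:`filter_sv`; pass
    ``min_support`` to apply the filter here instead.  Genes without CDS are
    never flagged (logged).  The decision uses the maximum single-SV
    fraction.
    """
    genes = list(genes)
    if min_support is not None:
        svs = filter_sv(svs, min_support)
    by_chrom: dict[str, list[SVRecord]] = {}
    for sv in svs:
        if sv.svtype in _SUPPORTED:
            by_chrom.setdefault(sv.chrom, []).append(sv)
    members = []
    for g in genes:
        if g.cds_length == 0:
            log.info("gene %s has no CDS; never flagged", g.gene_id)
            continue
        best = 0.0
        for sv in by_chrom.get(g.chrom, ()):
            span_s, span_e = sv.span
            if span_e <= g.start or span_s >= g.end:
                continue
            best = max(best, sv_cds_fraction(g, sv))
        if best >= min_cds_fraction:
            members.append(g.gene_id)
    return GeneSet([g.gene_id for g in genes], members, label=label)


def hemizygosity_rate(geneset: GeneSet) -> tuple[float, str]:
    """Hemizygous fraction of the universe and its percent string (1 dp)."""
    frac = geneset.rate
    return frac, f"{100 * frac:.1f}%"


__all__ = [
    "read_sv_vcf",
    "read_sv_bed",
    "filter_sv",
    "sv_cds_fraction",
    "call_hemizygous",
    "hemizygosity_rate",
]
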