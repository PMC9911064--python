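"""Core containers shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the package; the
1-based conventions of VCF and GFF3 are converted at the I/O boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

MISSING = -1  # haplotype allele code for a missing call

#: population labels the cohort machinery understands
GROUPS = ("Mexican", "Lowland", "Guatemalan")


@dataclass
class VariantSite:
    """One VCF record: position, alleles and the site-level QC fields."""

    chrom: str
    pos: int  # 1-based, as printed in VCF
    ref: str
    alt: tuple[str, ...]
    qual: float | None = None
    depth: int | None = None
    filter_flag: str = "PASS"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"VCF position must be >= 1, got {self.pos}")
        if isinstance(self.alt, str):
            self.alt = (self.alt,)
        else:
            self.alt = tuple(self.alt)

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt) == 1

    @property
    def is_snp(self) -> bool:
        return (
            self.is_biallelic
            and len(self.ref) == 1
            and len(self.alt[0]) == 1
            and self.ref != self.alt[0]
        )


class GenotypeMatrix:
    """Haplotype-by-site allele matrix with diploid sample metadata.

    Row ``2*i`` and ``2*i + 1`` are the two haplotypes of sample ``i``.
    Allele codes are 0 (REF), 1.. (ALT index) and :data:`MISSING`.
    """

    def __init__(
        self,
        haplotypes: np.ndarray,
        samples: Sequence[str],
        populations: Sequence[str],
        sites: Sequence[VariantSite],
    ) -> None:
        haplotypes = np.asarray(haplotypes, dtype=np.int8)
        if haplotypes.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        if haplotypes.shape[0] != 2 * len(samples):
            raise ValueError(
                f"haplotype count {haplotypes.shape[0]} != 2 x {len(samples)} samples"
            )
        if haplotypes.shape[1] != len(sites):
            raise ValueError(
                f"site columns {haplotypes.shape[1]} != {len(sites)} VariantSites"
            )
        if len(populations) != len(samples):
            raise ValueError("one population label per sample required")
        self.haplotypes = haplotypes
        self.samples = list(samples)
        self.populations = list(populations)
        self.sites = list(sites)

    # -- bookkeeping ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def sample_indices(self, population: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.populations) == np.asarray(population))

    def haplotype_rows(self, population: str | None = None) -> np.ndarray:
        """Row indices of the haplotypes belonging to ``population`` (all if None)."""
        if population is None:
            return np.arange(self.n_haplotypes)
        idx = self.sample_indices(population)
        if idx.size == 0:
            raise ValueError(f"no samples labelled {population!r}")
        return np.stack([2 * idx, 2 * idx + 1], axis=1).ravel()

    def population_alleles(self, population: str | None = None) -> np.ndarray:
        return self.haplotypes[self.haplotype_rows(population)]

    def sample_missingness(self) -> np.ndarray:
        """Fraction of missing haplotype calls per sample."""
        miss = (self.haplotypes == MISSING).reshape(self.n_samples, 2, self.n_sites)
        return miss.mean(axis=(1, 2))

    def subset_samples(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = np.asarray(keep, dtype=int)
        rows = np.stack([2 * keep, 2 * keep + 1], axis=1).ravel()
        return GenotypeMatrix(
            self.haplotypes[rows],
            [self.samples[i] for i in keep],
            [self.populations[i] for i in keep],
            self.sites,
        )

    def subset_sites(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = np.asarray(keep, dtype=int)
        return GenotypeMatrix(
            self.haplotypes[:, keep],
            self.samples,
            self.populations,
            [self.sites[i] for i in keep],
        )

    def site_positions(self, chrom: str) -> np.ndarray:
        """0-based positions of the sites on ``chrom``, in matrix order."""
        return np.array(
            [s.pos - 1 for s in self.sites if s.chrom == chrom], dtype=np.int64
        )

    def chrom_columns(self, chrom: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.sites) if s.chrom == chrom], dtype=np.int64
        )


@dataclass
class Window:
    """A genomic window (0-based half-open) carrying named statistic values."""

    chrom: str
    start: int
    end: int
    site_count: int = 0
    gap_fraction: float = 0.0
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"window start {self.start} >= end {self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


class WindowTrack:
    """An ordered collection of windows, sorted within each chromosome."""

    def __init__(self, windows: Iterable[Window]) -> None:
        self.windows = sorted(windows, key=lambda w: (w.chrom, w.start))
        for a, b in zip(self.windows, self.windows[1:]):
            if a.chrom == b.chrom and a.end > b.start:
                raise ValueError(f"overlapping windows {a} / {b}")

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self) -> Iterator[Window]:
        return iter(self.windows)

    def __getitem__(self, i: int) -> Window:
        return self.windows[i]

    def chroms(self) -> list[str]:
        out: list[str] = []
        for w in self.windows:
            if not out or out[-1] != w.chrom:
                out.append(w.chrom)
        return out

    def on_chrom(self, chrom: str) -> list[Window]:
        return [w for w in self.windows if w.chrom == chrom]

    def values(self, stat: str) -> np.ndarray:
        """Values of ``stat`` per window; NaN where the window carries none."""
        return np.array([w.values.get(stat, np.nan) for w in self.windows])

    def valued(self, stat: str) -> list[Window]:
        return [w for w in self.windows if stat in w.values]

    def to_dataframe(self, stats: Sequence[str] | None = None):
        import pandas as pd

        if stats is None:
            seen: dict[str, None] = {}
            for w in self.windows:
                for k in w.values:
                    seen.setdefault(k)
            stats = list(seen)
        rows = [
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "site_count": w.site_count,
                **{k: w.values.get(k, np.nan) for k in stats},
            }
            for w in self.windows
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path, stats: Sequence[str] | None = None) -> None:
        self.to_dataframe(stats).to_csv(path, sep="\t", index=False)


@dataclass
class AncestryProfile:
    """Per-accession admixture proportions over the three named groups."""

    accession: str
    proportions: dict[str, float]
    assigned_group: str | None = None

    def __post_init__(self) -> None:
        for g, p in self.proportions.items():
            if not -1e-9 <= p <= 1 + 1e-9:
                raise ValueError(f"{self.accession}: proportion {g}={p} outside [0,1]")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"{self.accession}: proportions sum to {total}, expected 1"
            )


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty interval [{s},{e})")
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class GeneModel:
    """A gene span with merged CDS intervals, all 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: empty span")
        self.cds = merge_intervals(self.cds) if self.cds else []
        for s, e in self.cds:
            if s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: CDS [{s},{e}) outside gene span")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


class GeneSet:
    """A flagged subset of a gene universe (e.g. sweep genes of one group)."""

    def __init__(self, universe: Iterable[str], members: Iterable[str], label: str = "") -> None:
        self.universe = tuple(dict.fromkeys(universe))
        self.members = frozenset(members)
        self.label = label
        extra = self.members - set(self.universe)
        if extra:
            raise ValueError(f"members outside universe: {sorted(extra)[:5]}")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def rate(self) -> float:
        if not self.universe:
            raise ValueError("empty gene universe")
        return len(self.members) / len(self.universe)


@dataclass
class SVRecord:
    """A structural-variant call (deletion or insertion) with read support."""

    chrom: str
    start: int  # 0-based
    svtype: str
    length: int
    read_support: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"SV length must be > 0, got {self.length}")

    @property
    def span(self) -> tuple[int, int]:
        """Affected reference interval: [start, start+length) for DEL, a point for INS."""
        if self.svtype == "DEL":
            return (self.start, self.start + self.length)
        return (self.start, self.start + 1)


__all__ = [
    "MISSING",
    "GROUPS",
    "VariantSite",
    "GenotypeMatrix",
    "Window",
    "WindowTrack",
    "AncestryProfile",
    "GeneModel",
    "GeneSet",
    "SVRecord",
    "merge_intervals",
    "replace",
]
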