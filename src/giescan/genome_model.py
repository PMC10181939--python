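"""Genome coordinate registry: chromosomes, arms, fixed-width bins and the GIE gene set.

All coordinates are 0-based half-open (BED convention). Autosomes are the only
chromosomes eligible for randomization; sex chromosomes are loaded but flagged
excluded. The default build is hg19, shipped as small text tables under
``giescan/data``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

BIN_SIZE = 100_000
HIGHLY_FOCAL_MAX_BP = 3_000_000
NONFOCAL_ARM_FRACTION = 0.75

_SEX_CHROMS = {"chrX", "chrY", "X", "Y", "chrM", "MT"}


@dataclass(frozen=True)
class GenomeBuild:
    """Chromosome lengths and arm boundaries (p-arm end == centromere)."""

    chroms: tuple[str, ...]
    lengths: Mapping[str, int]
    centromeres: Mapping[str, int]
    excluded: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for chrom in self.chroms:
            length = self.lengths[chrom]
            cen = self.centromeres[chrom]
            if length <= 0:
                raise ValueError(f"chromosome {chrom}: non-positive length {length}")
            if not 0 < cen < length:
                raise ValueError(
                    f"chromosome {chrom}: centromere {cen} outside (0, {length})"
                )

    @property
    def autosomes(self) -> tuple[str, ...]:
        """Shuffle-eligible chromosomes, in input order."""
        return tuple(c for c in self.chroms if c not in self.excluded)

    def arms(self, chrom: str) -> tuple[tuple[int, int], tuple[int, int]]:
        """(p-arm, q-arm) as half-open intervals partitioning the chromosome."""
        cen = self.centromeres[chrom]
        return (0, cen), (cen, self.lengths[chrom])

    def autosome_length(self) -> int:
        return sum(self.lengths[c] for c in self.autosomes)


def _data_path(name: str) -> Path:
    return Path(resources.files("giescan.data") / name)


def load_genome(chrom_sizes_path: str | Path, arm_table_path: str | Path) -> GenomeBuild:
    """Load a genome build from a UCSC two-column chrom.sizes file and an arm table.

    The arm table is either a simple two-column ``chrom<TAB>centromere`` file or a
    cytoBand-style table whose ``acen`` rows define the centromere. Sex
    chromosomes are flagged excluded from shuffling.
    """
    sizes: dict[str, int] = {}
    order: list[str] = []
    with open(chrom_sizes_path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{chrom_sizes_path}:{i}: expected two columns")
            try:
                length = int(parts[1])
            except ValueError as exc:
                raise ValueError(
                    f"{chrom_sizes_path}:{i}: non-integer length {parts[1]!r}"
                ) from exc
            sizes[parts[0]] = length
            order.append(parts[0])

    centromeres = _parse_arm_table(arm_table_path)
    for chrom in order:
        if chrom not in centromeres:
            raise KeyError(f"arm table {arm_table_path} is missing chromosome {chrom!r}")
    excluded = frozenset(c for c in order if c in _SEX_CHROMS)
    return GenomeBuild(
        chroms=tuple(order),
        lengths=sizes,
        centromeres={c: centromeres[c] for c in order},
        excluded=excluded,
    )


def _parse_arm_table(path: str | Path) -> dict[str, int]:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                rows.append(line.rstrip("\n").split("\t"))
    if rows and len(rows[0]) >= 5:
        # cytoBand table: chrom, start, end, band, stain; centromere = acen span
        acen: dict[str, list[int]] = {}
        for r in rows:
            if r[4] == "acen":
                acen.setdefault(r[0], []).extend((int(r[1]), int(r[2])))
        return {c: (min(v) + max(v)) // 2 for c, v in acen.items()}
    out = {}
    for r in rows:
        try:
            out[r[0]] = int(r[1])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"arm table {path}: malformed row {r!r}") from exc
    return out


def hg19_genome() -> GenomeBuild:
    """The shipped hg19 build (22 autosomes shuffle-eligible, X/Y excluded)."""
    return load_genome(_data_path("hg19.chrom.sizes"), _data_path("hg19.arms.tsv"))


def toy_genome(
    n_chroms: int = 4,
    length: int = 50_000_000,
    centromere_fraction: float = 0.4,
) -> GenomeBuild:
    """Small synthetic genome for fast experiments; all chromosomes autosomal."""
    chroms = tuple(f"chr{i + 1}" for i in range(n_chroms))
    return GenomeBuild(
        chroms=chroms,
        lengths={c: length for c in chroms},
        centromeres={c: int(length * centromere_fraction) for c in chroms},
    )


@dataclass(frozen=True)
class BinIndex:
    """Fixed-width tiling of the autosomes; the last bin of a chromosome may be short."""

    chrom: np.ndarray  # str array, one entry per bin
    start: np.ndarray
    end: np.ndarray
    bin_size: int
    offsets: Mapping[str, int]  # chrom -> global id of its first bin

    @property
    def n_bins(self) -> int:
        return len(self.start)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "start": self.start, "end": self.end})

    def span(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Global bin-id range [lo, hi) overlapped by a half-open interval."""
        if chrom not in self.offsets:
            raise KeyError(f"chromosome {chrom!r} is not binned")
        if end <= start:
            raise ValueError(f"empty interval {chrom}:{start}-{end}")
        off = self.offsets[chrom]
        lo = off + start // self.bin_size
        hi = off + (end - 1) // self.bin_size + 1
        return lo, hi


def make_bins(genome: GenomeBuild, bin_size: int = BIN_SIZE) -> BinIndex:
    """Tile each autosome into ceil(length / bin_size) bins, ordered by chromosome."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    chroms, starts, ends = [], [], []
    offsets: dict[str, int] = {}
    n_total = 0
    for chrom in genome.autosomes:
        offsets[chrom] = n_total
        length = genome.lengths[chrom]
        n = math.ceil(length / bin_size)
        s = np.arange(n, dtype=np.int64) * bin_size
        e = np.minimum(s + bin_size, length)
        chroms.append(np.repeat(chrom, n))
        starts.append(s)
        ends.append(e)
        n_total += n
    return BinIndex(
        chrom=np.concatenate(chroms),
        start=np.concatenate(starts),
        end=np.concatenate(ends),
        bin_size=bin_size,
        offsets=offsets,
    )


@dataclass(frozen=True)
class GeneDef:
    """One registry gene: coding-region span, escape pathway and mechanism class."""

    symbol: str
    chrom: str
    start: int
    end: int
    pathway: int  # 1..6
    mechanism: str  # "loss" or "gain"
    coding_len: int = 0

    @property
    def is_hla(self) -> bool:
        return self.pathway == 1


def load_gene_registry(
    bed_path: str | Path | None = None,
    pathway_path: str | Path | None = None,
) -> list[GeneDef]:
    """The 21-gene / six-pathway registry (shipped hg19 coordinates by default)."""
    bed_path = bed_path or _data_path("gie_genes.hg19.bed")
    pathway_path = pathway_path or _data_path("gie_pathways.tsv")
    bed = pd.read_csv(
        bed_path, sep="\t", header=None,
        names=["chrom", "start", "end", "symbol", "score", "strand"],
    )
    meta = pd.read_csv(pathway_path, sep="\t").set_index("gene")
    genes = []
    for row in bed.itertuples():
        if row.symbol not in meta.index:
            raise KeyError(f"gene {row.symbol!r} missing from pathway table")
        m = meta.loc[row.symbol]
        genes.append(
            GeneDef(
                symbol=row.symbol,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                pathway=int(m["pathway"]),
                mechanism=str(m["mechanism"]),
                coding_len=int(m["coding_len"]),
            )
        )
    return genes


def registry_for_genome(registry: list[GeneDef], genome: GenomeBuild) -> list[GeneDef]:
    """Registry genes that fit on this genome's autosomes (toy-genome mode drops the rest)."""
    return [
        g for g in registry
        if g.chrom in genome.autosomes and g.end <= genome.lengths[g.chrom]
    ]


def segment_scale(
    chrom: str, start: int, end: int, genome: GenomeBuild
) -> str:
    """Classify a copy-number segment as nonfocal / focal / highly_focal.

    A segment is nonfocal when it covers more than 75% of at least one arm it
    overlaps; otherwise it is focal, and additionally highly focal when shorter
    than 3 Mb (highly_focal implies focal).
    """
    if chrom not in genome.lengths:
        raise KeyError(f"unknown chromosome {chrom!r}")
    if end <= start:
        raise ValueError(f"zero-length segment {chrom}:{start}-{end}")
    for arm_start, arm_end in genome.arms(chrom):
        overlap = min(end, arm_end) - max(start, arm_start)
        if overlap > NONFOCAL_ARM_FRACTION * (arm_end - arm_start):
            return "nonfocal"
    if end - start < HIGHLY_FOCAL_MAX_BP:
        return "highly_focal"
    return "focal"


def scale_matches(scale_class: str, requested: str) -> bool:
    """Whether a segment's scale class satisfies a requested scale.

    ``focal`` includes highly focal segments (every <3 Mb segment is also <75%
    of an arm); ``highly_focal`` and ``nonfocal`` are exact.
    """
    if requested == "focal":
        return scale_class in ("focal", "highly_focal")
    return scale_class == requested


def gene_min_cn(segments: pd.DataFrame, gene: GeneDef) -> float:
    """Minimum total copy number (major + minor) over segments overlapping the gene."""
    seg = segments[
        (segments["chrom"] == gene.chrom)
        & (segments["start"] < gene.end)
        & (segments["end"] > gene.start)
    ]
    if seg.empty:
        raise ValueError(
            f"no copy-number segment covers {gene.symbol} "
            f"({gene.chrom}:{gene.start}-{gene.end})"
        )
    total = seg["major_cn"].to_numpy() + seg["minor_cn"].to_numpy()
    return float(total.min())


def bins_for_gene(bins: BinIndex, gene: GeneDef) -> np.ndarray:
    """Global ids of every bin overlapping the gene's coding span (never empty)."""
    lo, hi = bins.span(gene.chrom, gene.start, gene.end)
    return np.arange(lo, hi)
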