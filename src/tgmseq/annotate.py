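"""Region catalog construction: genes, strand-specific intergenic windows, Pol III sites.

The genome is partitioned, per strand, into annotated gene footprints
(protein-coding and, by default, non-coding genes) and the remaining
intergenic space.  Intergenic gaps longer than the window size (default
500 bp) are tiled into fixed-size windows anchored at the left edge of
each gap; these windows are the unit of the intergenic differential
expression analysis.  tRNA genes and user-supplied extra-TFIIIC (ETC)
sites form a registry of Pol III complex binding sites against which
proximity of differential regions is measured.

Coordinates are 0-based half-open throughout.  GFF3 input (1-based
inclusive) is converted on load; BED is consumed natively.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd

logger = logging.getLogger(__name__)

PLUS = "+"
MINUS = "-"
UNSTRANDED = "."

ROLE_CODING = "coding_gene"
ROLE_NONCODING = "noncoding_gene"
ROLE_WINDOW = "intergenic_window"

SITE_TDNA = "tDNA"
SITE_ETC = "ETC"
SITE_OTHER = "other_polIII"

#: GFF3 feature types mapped to gene roles.  tRNA genes additionally
#: enter the Pol III site registry.
_CODING_TYPES = {"gene", "protein_coding_gene"}
_TRNA_TYPES = {"tRNA_gene", "tRNA"}
_NONCODING_TYPES = {"ncRNA_gene", "noncoding_gene", "snoRNA_gene", "snRNA_gene", "rRNA_gene"}


@dataclass(frozen=True)
class GenomicInterval:
    """A located, stranded genome segment (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end}) on {self.chrom}")
        if self.strand not in (PLUS, MINUS, UNSTRANDED):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def gap_to(self, other: "GenomicInterval") -> int:
        """Distance in bases between closest edges; 0 if overlapping or abutting."""
        if self.chrom != other.chrom:
            raise ValueError("gap between intervals on different chromosomes")
        return max(self.start - other.end, other.start - self.end, 0)


@dataclass(frozen=True)
class Region:
    """A catalog entry: a gene footprint or one intergenic window."""

    id: str
    interval: GenomicInterval
    role: str
    block_id: str = ""
    flank_left_gene: str = ""
    flank_right_gene: str = ""


@dataclass(frozen=True)
class PolIIISite:
    """A tDNA, ETC site, or other Pol III-associated locus."""

    id: str
    interval: GenomicInterval
    site_class: str
    name: str = ""


@dataclass(frozen=True)
class PartitionConfig:
    window_size: int = 500
    min_window: int = 100
    include_noncoding_in_genespace: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.min_window <= self.window_size):
            raise ValueError("require 0 < min_window <= window_size")


#: Sentinel returned by nearest_polIII_site when the registry is empty.
NO_SITE = PolIIISite("__none__", GenomicInterval("__none__", 0, 1), SITE_OTHER, "none")


@dataclass
class RegionCatalog:
    """Ordered collection of regions plus the chromosome-size table."""

    regions: list[Region]
    chrom_sizes: dict[str, int]
    partition_config: PartitionConfig = field(default_factory=PartitionConfig)

    _df: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.regions)

    def to_frame(self) -> pd.DataFrame:
        """Catalog as a DataFrame indexed by region id (cached)."""
        if self._df is None:
            self._df = pd.DataFrame(
                {
                    "id": [r.id for r in self.regions],
                    "chrom": [r.interval.chrom for r in self.regions],
                    "start": [r.interval.start for r in self.regions],
                    "end": [r.interval.end for r in self.regions],
                    "strand": [r.interval.strand for r in self.regions],
                    "role": [r.role for r in self.regions],
                    "block_id": [r.block_id for r in self.regions],
                    "flank_left_gene": [r.flank_left_gene for r in self.regions],
                    "flank_right_gene": [r.flank_right_gene for r in self.regions],
                }
            ).set_index("id", drop=False)
        return self._df

    def genes(self) -> list[Region]:
        return [r for r in self.regions if r.role != ROLE_WINDOW]

    def windows(self) -> list[Region]:
        return [r for r in self.regions if r.role == ROLE_WINDOW]

    def region(self, region_id: str) -> Region:
        for r in self.regions:
            if r.id == region_id:
                return r
        raise KeyError(region_id)

    def write_bed(self, path: str | Path) -> None:
        """BED6 export (name = region id, score = 0)."""
        with open(path, "w") as fh:
            for r in self.regions:
                iv = r.interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.id}\t0\t{iv.strand}\n")

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_chrom_sizes(source: str | Path) -> dict[str, int]:
    """Two-column TSV chromosome-size table."""
    sizes: dict[str, int] = {}
    with open(source) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{source}: malformed chrom-sizes line {lineno}: {line!r}")
            sizes[parts[0]] = int(parts[1])
    return sizes


def _gene_role(feature_type: str) -> str | None:
    if feature_type in _CODING_TYPES:
        return ROLE_CODING
    if feature_type in _TRNA_TYPES or feature_type in _NONCODING_TYPES:
        return ROLE_NONCODING
    return None


def load_annotation(
    gff_source: str | Path,
    etc_bed_source: str | Path | None,
    chrom_sizes_source: str | Path | dict[str, int],
) -> tuple[list[Region], list[PolIIISite], dict[str, int]]:
    """Parse a GFF3 annotation plus an optional BED of extra Pol III sites.

    Gene-level features become catalog gene regions (tRNA genes with role
    ``noncoding_gene``); tRNA genes additionally enter the site registry
    with class ``tDNA``.  BED4 rows become sites classified from the
    column-4 label (labels containing ``ETC`` -> class ETC, ``tDNA``/``t(``
    -> tDNA, anything else ``other_polIII``).
    """
    if isinstance(chrom_sizes_source, dict):
        chrom_sizes = dict(chrom_sizes_source)
    else:
        chrom_sizes = read_chrom_sizes(chrom_sizes_source)

    try:
        db = gffutils.create_db(
            str(gff_source),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises heterogeneous errors
        raise ValueError(f"malformed GFF3 {gff_source}: {exc}") from exc

    genes: list[Region] = []
    sites: list[PolIIISite] = []
    for feat in db.all_features(order_by=("seqid", "start")):
        role = _gene_role(feat.featuretype)
        if role is None:
            continue
        if feat.seqid not in chrom_sizes:
            raise ValueError(
                f"chromosome {feat.seqid!r} (feature {feat.id}) absent from chrom-sizes table"
            )
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand or UNSTRANDED)
        if iv.end > chrom_sizes[feat.seqid]:
            raise ValueError(f"feature {feat.id} extends past end of {feat.seqid}")
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(Region(gid, iv, role))
        if feat.featuretype in _TRNA_TYPES:
            name = feat.attributes.get("Name", [gid])[0]
            sites.append(PolIIISite(gid, iv, SITE_TDNA, name))

    if etc_bed_source is not None:
        sites.extend(_read_site_bed(etc_bed_source, chrom_sizes))
    return genes, sites, chrom_sizes


def _classify_site_label(label: str) -> str:
    lab = label.upper()
    if "ETC" in lab:
        return SITE_ETC
    if lab.startswith("TDNA") or lab.startswith("T("):
        return SITE_TDNA
    return SITE_OTHER


def _read_site_bed(source: str | Path, chrom_sizes: dict[str, int]) -> list[PolIIISite]:
    sites: list[PolIIISite] = []
    with open(source) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{source}: malformed BED line {lineno}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if chrom not in chrom_sizes:
                raise ValueError(f"{source}: unknown chromosome {chrom!r} at line {lineno}")
            name = parts[3] if len(parts) > 3 else f"site{lineno}"
            strand = parts[5] if len(parts) > 5 else UNSTRANDED
            sites.append(
                PolIIISite(
                    f"{name}:{chrom}:{start}",
                    GenomicInterval(chrom, start, end, strand),
                    _classify_site_label(name),
                    name,
                )
            )
    return sites


def _merge_footprints(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of possibly-overlapping [start, end) pairs, with a warning on overlap."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        ps, pe = merged[-1]
        if s < pe:
            logger.warning("overlapping same-strand gene footprints [%d,%d) and [%d,%d); merged", ps, pe, s, e)
            merged[-1] = (ps, max(pe, e))
        elif s == pe:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    return merged


def _tile_block(start: int, end: int, cfg: PartitionConfig) -> list[tuple[int, int]]:
    """Cut one intergenic block into windows.

    Blocks no longer than ``window_size`` stay whole.  Longer blocks are
    tiled from the left edge; a trailing remainder shorter than
    ``min_window`` is absorbed into the final window.
    """
    length = end - start
    w = cfg.window_size
    if length <= w:
        return [(start, end)]
    n_full, rem = divmod(length, w)
    edges = [start + i * w for i in range(n_full)] + [start + n_full * w]
    windows = list(zip(edges[:-1], edges[1:]))
    if rem >= cfg.min_window:
        windows.append((end - rem, end))
    elif rem > 0:
        windows[-1] = (windows[-1][0], end)
    return windows


def partition_genome(
    genes: Sequence[Region],
    chrom_sizes: dict[str, int],
    partition_config: PartitionConfig | None = None,
) -> RegionCatalog:
    """Build the full strand-specific region catalog.

    Per chromosome and strand, gene footprints are subtracted from
    ``[0, length)``; every maximal remaining gap becomes an intergenic
    block tiled into windows.  The union of gene footprints and windows
    covers each strand exactly, with no same-strand overlap, so every
    uniquely mapped read lands in exactly one region.
    """
    cfg = partition_config or PartitionConfig()
    for g in genes:
        if g.interval.chrom not in chrom_sizes:
            raise ValueError(f"gene {g.id}: unknown chromosome {g.interval.chrom!r}")
        if g.interval.end > chrom_sizes[g.interval.chrom]:
            raise ValueError(f"gene {g.id} extends past end of {g.interval.chrom}")

    def in_genespace(g: Region) -> bool:
        if g.role == ROLE_CODING:
            return True
        return cfg.include_noncoding_in_genespace

    regions: list[Region] = [g for g in sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start, g.id))]
    for chrom in sorted(chrom_sizes):
        length = chrom_sizes[chrom]
        for strand in (PLUS, MINUS):
            strand_genes = sorted(
                (g for g in genes if in_genespace(g) and g.interval.chrom == chrom and g.interval.strand == strand),
                key=lambda g: (g.interval.start, g.interval.end),
            )
            footprints = _merge_footprints([(g.interval.start, g.interval.end) for g in strand_genes])
            # maximal gaps between consecutive footprints
            gaps: list[tuple[int, int]] = []
            cursor = 0
            for s, e in footprints:
                if s > cursor:
                    gaps.append((cursor, s))
                cursor = e
            if cursor < length:
                gaps.append((cursor, length))
            for bi, (bs, be) in enumerate(gaps):
                left = _nearest_gene_id(strand_genes, bs, side="left")
                right = _nearest_gene_id(strand_genes, be, side="right")
                block_id = f"{chrom}:{strand}:block{bi:04d}"
                for wi, (ws, we) in enumerate(_tile_block(bs, be, cfg)):
                    regions.append(
                        Region(
                            id=f"{block_id}:w{wi:02d}",
                            interval=GenomicInterval(chrom, ws, we, strand),
                            role=ROLE_WINDOW,
                            block_id=block_id,
                            flank_left_gene=left,
                            flank_right_gene=right,
                        )
                    )
    return RegionCatalog(regions=regions, chrom_sizes=dict(chrom_sizes), partition_config=cfg)


def _nearest_gene_id(sorted_genes: Sequence[Region], pos: int, side: str) -> str:
    """Id of the same-strand gene whose footprint abuts the block at ``pos``."""
    if side == "left":
        for g in reversed(sorted_genes):
            if g.interval.end <= pos:
                return g.id
    else:
        for g in sorted_genes:
            if g.interval.start >= pos:
                return g.id
    return ""


def nearest_polIII_site(
    region: Region | GenomicInterval,
    sites: Iterable[PolIIISite],
) -> tuple[PolIIISite, float]:
    """Closest Pol III site to a region, strand-blind.

    Distance is 0 for overlapping (or abutting, under half-open
    coordinates) intervals, else the gap in bases between closest edges.
    Ties are broken toward the site with the smaller start.  An empty
    registry yields ``(NO_SITE, inf)``.
    """
    iv = region.interval if isinstance(region, Region) else region
    best: PolIIISite | None = None
    best_d = math.inf
    for site in sorted(sites, key=lambda s: (s.interval.chrom, s.interval.start, s.id)):
        if site.interval.chrom != iv.chrom:
            continue
        d = iv.gap_to(site.interval)
        if d < best_d:
            best, best_d = site, d
    if best is None:
        return NO_SITE, math.inf
    return best, float(best_d)
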