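"""Strand-specific assignment of uniquely mapped reads to catalog regions.

Fragments are reduced to a single reference point — the 5'-most base of
the fragment on its strand — and assigned to the one same-strand region
containing that point.  Because the catalog is a complete disjoint
partition of each strand, every unique fragment is counted exactly once,
which makes per-sample totals conserved by construction.

Input is either SAM/BAM (via pysam; secondary/supplementary/unmapped
records dropped) or a simplified 6-column alignment BED.  Library
strandedness follows the usual dialects: ``reverse`` (first read is
antisense to the transcript, the default for dUTP-based stranded kits),
``forward``, or ``unstranded``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotate import (
    MINUS,
    PLUS,
    ROLE_CODING,
    UNSTRANDED,
    RegionCatalog,
)

logger = logging.getLogger(__name__)

DIALECTS = ("forward", "reverse", "unstranded")


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned fragment (mate-union span for proper pairs)."""

    chrom: str
    start: int
    end: int
    strand: str
    n_hits: int = 1          # reported alignments; -1 when unknown
    mapq: int = 255
    read_role: str = "unpaired"   # first-in-pair / second-in-pair / unpaired

    @property
    def five_prime(self) -> int:
        """5'-most reference base of the fragment on its strand."""
        return self.start if self.strand != MINUS else self.end - 1


@dataclass
class SampleSheet:
    """Sample id -> condition label, replicate index, alignment source."""

    samples: pd.DataFrame  # columns: sample, condition, replicate, path

    def __post_init__(self) -> None:
        required = {"sample", "condition"}
        if not required.issubset(self.samples.columns):
            raise ValueError(f"sample sheet needs columns {sorted(required)}")
        counts = self.samples["condition"].value_counts()
        if (counts < 1).any():
            raise ValueError("every condition needs at least one sample")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample": str, "condition": str}))

    @property
    def conditions(self) -> list[str]:
        """Condition labels in first-appearance order."""
        return list(dict.fromkeys(self.samples["condition"]))

    def samples_of(self, condition: str) -> list[str]:
        return list(self.samples.loc[self.samples["condition"] == condition, "sample"])


@dataclass
class QCStats:
    total_records: dict[str, int]
    unique_fraction: dict[str, float]
    antisense_fraction: dict[str, float]
    replicate_correlation: dict[str, float]


def _fragment_strand(read_is_reverse: bool, is_read2: bool, dialect: str) -> str:
    if dialect == "unstranded":
        return UNSTRANDED
    read_strand = MINUS if read_is_reverse else PLUS
    if is_read2:
        read_strand = MINUS if read_strand == PLUS else PLUS
    if dialect == "reverse":
        return MINUS if read_strand == PLUS else PLUS
    return read_strand


def read_alignments(
    source: str | Path,
    strandedness_dialect: str = "reverse",
) -> Iterator[AlignmentRecord]:
    """Stream fragments from SAM/BAM or simplified alignment BED6.

    For SAM/BAM, proper pairs are collapsed to one fragment spanning the
    mate union (emitted at the leftmost mate); orphan mates count singly.
    """
    if strandedness_dialect not in DIALECTS:
        raise ValueError(f"unknown strandedness dialect {strandedness_dialect!r}; choose from {DIALECTS}")
    path = str(source)
    if path.endswith((".sam", ".bam")):
        yield from _read_sam(path, strandedness_dialect)
    else:
        yield from _read_alignment_bed(path, strandedness_dialect)


def _read_sam(path: str, dialect: str) -> Iterator[AlignmentRecord]:
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            role = "unpaired"
            start, end = aln.reference_start, aln.reference_end
            if aln.is_paired:
                role = "second-in-pair" if aln.is_read2 else "first-in-pair"
                if aln.mate_is_unmapped or aln.next_reference_id != aln.reference_id:
                    pass  # orphan: count singly over its own span
                elif aln.template_length > 0:
                    end = start + aln.template_length  # leftmost mate carries the pair
                elif aln.template_length < 0:
                    continue  # rightmost mate of a pair already counted
                # tlen == 0 with mapped mate: degenerate, count singly
            nh = aln.get_tag("NH") if aln.has_tag("NH") else -1
            strand = _fragment_strand(aln.is_reverse, aln.is_paired and aln.is_read2, dialect)
            yield AlignmentRecord(
                chrom=aln.reference_name,
                start=start,
                end=end,
                strand=strand,
                n_hits=int(nh),
                mapq=aln.mapping_quality,
                read_role=role,
            )


def _read_alignment_bed(path: str, dialect: str) -> Iterator[AlignmentRecord]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise OSError(f"{path}: truncated alignment BED at line {lineno}")
            chrom, start, end, _name, score, strand = parts[:6]
            strand = _fragment_strand(strand == MINUS, False, dialect)
            yield AlignmentRecord(
                chrom=chrom,
                start=int(start),
                end=int(end),
                strand=strand,
                n_hits=1,
                mapq=int(score) if score != "." else 255,
            )


def filter_unique(
    records: Iterable[AlignmentRecord],
    policy: str = "auto",
    mapq_threshold: int = 10,
) -> tuple[list[AlignmentRecord], dict[str, int]]:
    """Keep only uniquely mapped fragments.

    Policies: ``hit-count`` (reported hit count == 1), ``mapq`` (mapping
    quality >= threshold), ``auto`` (hit count when reported, else mapq).
    Returns the surviving records plus a drop log by reason.
    """
    if policy not in ("hit-count", "mapq", "auto"):
        raise ValueError(f"unknown uniqueness policy {policy!r}")
    kept: list[AlignmentRecord] = []
    drops = {"multi_hit": 0, "low_mapq": 0}
    for rec in records:
        if policy == "hit-count" or (policy == "auto" and rec.n_hits >= 0):
            if rec.n_hits == 1:
                kept.append(rec)
            else:
                drops["multi_hit"] += 1
        else:
            if rec.mapq >= mapq_threshold:
                kept.append(rec)
            else:
                drops["low_mapq"] += 1
    if sum(drops.values()):
        logger.info("uniqueness filter dropped %s", drops)
    return kept, drops


def _region_lookup(catalog: RegionCatalog) -> dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]:
    """Per (chrom, strand): sorted window/gene start positions and region row indices."""
    df = catalog.to_frame()
    lookup = {}
    for (chrom, strand), sub in df.groupby(["chrom", "strand"], sort=False):
        sub = sub.sort_values("start")
        lookup[(chrom, strand)] = (sub["start"].to_numpy(), sub.index.to_numpy())
    return lookup


def assign_region(rec: AlignmentRecord, lookup, catalog_df) -> str:
    """Region id of the same-strand region containing the fragment's 5' base."""
    key = (rec.chrom, rec.strand)
    if key not in lookup:
        raise ValueError(f"chromosome/strand {key} absent from catalog")
    starts, ids = lookup[key]
    i = int(np.searchsorted(starts, rec.five_prime, side="right")) - 1
    if i < 0:
        raise RuntimeError(f"no region contains 5' base {rec.five_prime} on {key}")
    rid = ids[i]
    if catalog_df.at[rid, "end"] <= rec.five_prime:
        raise RuntimeError(
            f"internal error: partition gap at {rec.chrom}:{rec.five_prime} ({rec.strand})"
        )
    return rid


def count_reads(
    records: Iterable[AlignmentRecord],
    catalog: RegionCatalog,
) -> pd.Series:
    """One column of the count matrix: unique fragments per region."""
    df = catalog.to_frame()
    lookup = _region_lookup(catalog)
    counts = pd.Series(0, index=df.index, dtype=np.int64)
    for rec in records:
        counts[assign_region(rec, lookup, df)] += 1
    counts.name = "count"
    return counts


def build_count_matrix(
    sample_sheet: SampleSheet,
    catalog: RegionCatalog,
    strandedness_dialect: str = "reverse",
    uniqueness_policy: str = "auto",
    mapq_threshold: int = 10,
) -> pd.DataFrame:
    """Assemble the region x sample count matrix from the sample sheet paths."""
    columns = {}
    for row in sample_sheet.samples.itertuples():
        records = read_alignments(row.path, strandedness_dialect)
        unique, drops = filter_unique(records, uniqueness_policy, mapq_threshold)
        columns[row.sample] = count_reads(unique, catalog)
        logger.info("sample %s: %d unique fragments, drops %s", row.sample, len(unique), drops)
    mat = pd.DataFrame(columns)
    mat.attrs["provenance"] = f"dialect={strandedness_dialect};policy={uniqueness_policy}"
    return mat


def antisense_fraction(
    records: Sequence[AlignmentRecord],
    catalog: RegionCatalog,
) -> float:
    """Fraction of unique fragments whose 5' base lies inside an ORF on the opposite strand.

    Only protein-coding gene footprints enter the numerator; fragments
    antisense to non-coding genes are not counted.  Returns NaN for an
    empty record set.
    """
    if not records:
        logger.warning("antisense_fraction of zero records is undefined")
        return float("nan")
    df = catalog.to_frame()
    orfs = df[df["role"] == ROLE_CODING]
    by_chrom_strand: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for (chrom, strand), sub in orfs.groupby(["chrom", "strand"], sort=False):
        sub = sub.sort_values("start")
        by_chrom_strand[(chrom, strand)] = (sub["start"].to_numpy(), sub["end"].to_numpy())
    n_anti = 0
    for rec in records:
        opp = MINUS if rec.strand == PLUS else PLUS
        key = (rec.chrom, opp)
        if key not in by_chrom_strand:
            continue
        starts, ends = by_chrom_strand[key]
        i = int(np.searchsorted(starts, rec.five_prime, side="right")) - 1
        if i >= 0 and rec.five_prime < ends[i]:
            n_anti += 1
    return n_anti / len(records)


def replicate_correlation(
    count_matrix: pd.DataFrame,
    sample_sheet: SampleSheet,
) -> dict[str, float]:
    """Per-condition Pearson r of log2(count+1) between the two replicates."""
    out: dict[str, float] = {}
    for cond in sample_sheet.conditions:
        cols = sample_sheet.samples_of(cond)
        if len(cols) < 2:
            logger.warning("condition %s has <2 replicates; correlation skipped", cond)
            continue
        x = np.log2(count_matrix[cols[0]].to_numpy(dtype=float) + 1.0)
        y = np.log2(count_matrix[cols[1]].to_numpy(dtype=float) + 1.0)
        if np.std(x) == 0 or np.std(y) == 0:
            logger.warning("condition %s: constant replicate column; r undefined", cond)
            out[cond] = float("nan")
            continue
        out[cond] = float(np.corrcoef(x, y)[0, 1])
    return out


def write_bedgraph(
    records: Sequence[AlignmentRecord],
    strand: str,
    out: str | Path,
    track_name: str = "coverage",
    negate_minus: bool = False,
) -> None:
    """Per-base coverage of one strand as bedGraph (maximal constant runs).

    Coverage at a base is the number of unique fragments overlapping it.
    Zero-coverage stretches are omitted, so the track's mass
    (sum of value x interval length) equals the summed fragment lengths.
    """
    events: dict[str, list[tuple[int, int]]] = {}
    for rec in records:
        if rec.strand != strand:
            continue
        events.setdefault(rec.chrom, []).append((rec.start, rec.end))
    sign = -1 if (negate_minus and strand == MINUS) else 1
    with open(out, "w") as fh:
        fh.write(f'track type=bedGraph name="{track_name}({strand})"\n')
        for chrom in sorted(events):
            edges: list[tuple[int, int]] = []
            for s, e in events[chrom]:
                edges.append((s, 1))
                edges.append((e, -1))
            edges.sort()
            depth = 0
            prev_pos: int | None = None
            for pos, delta in edges:
                if prev_pos is not None and pos != prev_pos and depth > 0:
                    fh.write(f"{chrom}\t{prev_pos}\t{pos}\t{sign * depth}\n")
                if prev_pos is None or pos != prev_pos:
                    prev_pos = pos
                depth += delta
            # depth returns to 0 at the final edge; nothing to flush


def compute_qc(
    per_sample_records: dict[str, list[AlignmentRecord]],
    per_sample_drops: dict[str, dict[str, int]],
    count_matrix: pd.DataFrame,
    catalog: RegionCatalog,
    sample_sheet: SampleSheet,
) -> QCStats:
    """Assemble the per-sample and per-condition QC summary."""
    total = {}
    uniq_frac = {}
    anti = {}
    for sample, recs in per_sample_records.items():
        dropped = sum(per_sample_drops.get(sample, {}).values())
        total[sample] = len(recs) + dropped
        uniq_frac[sample] = len(recs) / total[sample] if total[sample] else float("nan")
        anti[sample] = antisense_fraction(recs, catalog)
    return QCStats(
        total_records=total,
        unique_fraction=uniq_frac,
        antisense_fraction=anti,
        replicate_correlation=replicate_correlation(count_matrix, sample_sheet),
    )
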