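"""Synthetic genomes, Pol III site registries, and NB count matrices with planted events.

The generator inverts the analysis model so every pipeline stage is
testable without external data.  A genome is assembled from locus
cassettes laid left-to-right with random spacers: background genes,
background tDNAs/ETC sites, and one cassette per planted event whose
internal geometry guarantees the event class is realizable:

* five_prime_extension — elevated windows abutting the 5' end of a
  downstream same-strand gene, a tDNA ~200 bp away (FAR3-like);
* three_prime_extension — elevated windows continuing from a gene's
  3' end, stopping short of a convergent tDNA (PCL5-like);
* readthrough — elevated windows continuing from a gene's 3' end
  across a convergent tDNA and beyond it (SUT467/ATG31-like);
* derepressed_intergenic — an isolated elevated window ~300 bp from a
  tDNA, touching no gene (SPO74-like);
* trans_gene_up — a coding gene up-regulated in the mutant with no
  nearby site, mimicking the indirect Gcn4p-mediated response.

Event tDNAs are placed on the strand opposite the event (convergent
geometry): a same-strand tDNA is itself an annotated gene and would
split the intergenic block.  Counts are drawn per region as
NB(mean = s_j * q_i * effect, dispersion alpha): two replicates per
condition, log-normal baseline gene means, near-silent intergenic
windows (mean 0.5), per-sample library-size factors, and 16-fold
planted effects by default (within the 4.8- to 21-fold range of the
effects the analysis is designed to detect).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import (
    MINUS,
    PLUS,
    ROLE_CODING,
    ROLE_NONCODING,
    ROLE_WINDOW,
    SITE_ETC,
    SITE_TDNA,
    GenomicInterval,
    PolIIISite,
    Region,
    RegionCatalog,
)
from .counting import AlignmentRecord, SampleSheet

logger = logging.getLogger(__name__)

EVENT_5EXT = "five_prime_extension"
EVENT_3EXT = "three_prime_extension"
EVENT_READTHROUGH = "readthrough"
EVENT_DEREP = "derepressed_intergenic"
EVENT_TRANS = "trans_gene_up"
INTERGENIC_EVENTS = (EVENT_5EXT, EVENT_3EXT, EVENT_READTHROUGH, EVENT_DEREP)
ALL_EVENTS = INTERGENIC_EVENTS + (EVENT_TRANS,)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 3
    n_genes: int = 200                       # coding genes, event flank genes included
    n_tdna: int = 40                         # tDNAs, event-associated ones included
    n_etc: int = 10
    gene_length_meanlog: float = np.log(1200.0)
    gene_length_sdlog: float = 0.35
    tdna_length: tuple[int, int] = (70, 120)
    etc_length: int = 120
    replicates: int = 2
    conditions: tuple[str, str] = ("wildtype", "mutant")
    library_size_factors: tuple[float, ...] = (0.8, 1.0, 1.1, 1.25)
    gene_mean_meanlog: float = np.log(50.0)  # log-normal distribution of NB gene means
    gene_mean_sdlog: float = 1.0
    intergenic_baseline_mean: float = 0.5
    dispersion: float = 0.1
    events_per_class: dict = field(default_factory=lambda: {c: 10 for c in ALL_EVENTS})
    event_fold: float = 16.0
    read_length: int = 100

    @property
    def n_samples(self) -> int:
        return len(self.conditions) * self.replicates


@dataclass
class SimulatedGenome:
    genes: list[Region]
    sites: list[PolIIISite]
    chrom_sizes: dict[str, int]
    truth: pd.DataFrame       # event_id, event_class, chrom, start, end, strand, fold, gene_id
    config: SimulationConfig


# ---------------------------------------------------------------------------
# cassette templates (plus-strand relative layouts; mirrored for minus events)

@dataclass
class _Cassette:
    length: int
    genes: list[tuple[int, int, str, str]] = field(default_factory=list)   # start, end, strand, role
    sites: list[tuple[int, int, str, str]] = field(default_factory=list)   # start, end, strand, class
    event: tuple[str, int, int, str, float] | None = None                  # class, span, strand, fold
    event_gene_slot: int | None = None   # index into .genes of the gene a trans event elevates

    def mirrored(self) -> "_Cassette":
        """The cassette reflected end-to-start with all strands flipped."""
        flip = {PLUS: MINUS, MINUS: PLUS}
        L = self.length
        genes = sorted((L - e, L - s, flip[st], role) for s, e, st, role in self.genes)
        sites = sorted((L - e, L - s, flip[st], sc) for s, e, st, sc in self.sites)
        ev = None
        if self.event is not None:
            cls, s, e, st, fold = self.event
            ev = (cls, L - e, L - s, flip[st], fold)
        slot = None
        if self.event_gene_slot is not None:
            old = self.genes[self.event_gene_slot]
            slot = genes.index((L - old[1], L - old[0], flip[old[2]], old[3]))
        return _Cassette(L, genes, sites, ev, slot)


def _tdna_len(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    lo, hi = cfg.tdna_length
    return int(rng.integers(lo, hi + 1))


def _event_cassette(event_class: str, cfg: SimulationConfig, rng: np.random.Generator) -> _Cassette:
    fold = cfg.event_fold
    tl = _tdna_len(rng, cfg)
    if event_class == EVENT_5EXT:
        cas = _Cassette(
            length=2700,
            genes=[(0, 600, PLUS, ROLE_CODING), (2100, 2700, PLUS, ROLE_CODING)],
            sites=[(850, 850 + tl, MINUS, SITE_TDNA)],
            event=(EVENT_5EXT, 1100, 2100, PLUS, fold),
        )
    elif event_class == EVENT_3EXT:
        cas = _Cassette(
            length=3200,
            genes=[(0, 600, PLUS, ROLE_CODING), (2600, 3200, PLUS, ROLE_CODING)],
            sites=[(1700, 1700 + tl, MINUS, SITE_TDNA)],
            event=(EVENT_3EXT, 600, 1600, PLUS, fold),
        )
    elif event_class == EVENT_READTHROUGH:
        cas = _Cassette(
            length=3200,
            genes=[(0, 600, PLUS, ROLE_CODING), (2600, 3200, PLUS, ROLE_CODING)],
            sites=[(1300, 1300 + tl, MINUS, SITE_TDNA)],
            event=(EVENT_READTHROUGH, 600, 2100, PLUS, fold),
        )
    elif event_class == EVENT_DEREP:
        cas = _Cassette(
            length=2700,
            genes=[(0, 600, PLUS, ROLE_CODING), (2100, 2700, PLUS, ROLE_CODING)],
            sites=[(750, 750 + tl, MINUS, SITE_TDNA)],
            event=(EVENT_DEREP, 1100, 1600, PLUS, fold),
        )
    elif event_class == EVENT_TRANS:
        cas = _Cassette(
            length=900,
            genes=[(0, 900, PLUS, ROLE_CODING)],
            event=(EVENT_TRANS, 0, 900, PLUS, fold),
            event_gene_slot=0,
        )
    else:
        raise ValueError(f"unknown event class {event_class!r}")
    if rng.random() < 0.5:
        cas = cas.mirrored()
    return cas


def simulate_genome(config: SimulationConfig | None = None) -> SimulatedGenome:
    """Deterministic genome + site registry + truth-table skeleton."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng([int(cfg.seed), 11])

    cassettes: list[_Cassette] = []
    event_tdnas = 0
    for cls in ALL_EVENTS:
        for _ in range(int(cfg.events_per_class.get(cls, 0))):
            cas = _event_cassette(cls, cfg, rng)
            event_tdnas += sum(1 for s in cas.sites if s[3] == SITE_TDNA)
            cassettes.append(cas)
    event_genes = sum(len(c.genes) for c in cassettes)
    n_background_genes = cfg.n_genes - event_genes
    if n_background_genes < 0:
        raise ValueError(
            f"infeasible placement: events require {event_genes} genes but n_genes={cfg.n_genes}"
        )
    n_background_tdna = cfg.n_tdna - event_tdnas
    if n_background_tdna < 0:
        raise ValueError(
            f"infeasible placement: events require {event_tdnas} tDNAs but n_tdna={cfg.n_tdna}"
        )

    for _ in range(n_background_genes):
        glen = int(np.clip(rng.lognormal(cfg.gene_length_meanlog, cfg.gene_length_sdlog), 300, 5000))
        strand = PLUS if rng.random() < 0.5 else MINUS
        cassettes.append(_Cassette(glen, genes=[(0, glen, strand, ROLE_CODING)]))
    for _ in range(n_background_tdna):
        tl = _tdna_len(rng, cfg)
        strand = PLUS if rng.random() < 0.5 else MINUS
        cassettes.append(_Cassette(tl, sites=[(0, tl, strand, SITE_TDNA)]))
    for _ in range(cfg.n_etc):
        strand = PLUS if rng.random() < 0.5 else MINUS
        cassettes.append(_Cassette(cfg.etc_length, sites=[(0, cfg.etc_length, strand, SITE_ETC)]))
    rng.shuffle(cassettes)  # type: ignore[arg-type]

    genes: list[Region] = []
    sites: list[PolIIISite] = []
    truth_rows: list[dict] = []
    cursors = {f"chrsim{i + 1}": 0 for i in range(cfg.n_chromosomes)}
    chrom_names = list(cursors)
    n_gene = n_tdna = n_etc = 0
    for i, cas in enumerate(cassettes):
        chrom = chrom_names[i % cfg.n_chromosomes]
        gap = int(rng.integers(300, 900))
        off = cursors[chrom] + gap
        gene_ids_here: list[str] = []
        for s, e, st, role in cas.genes:
            n_gene += 1
            gid = f"gene{n_gene:04d}"
            gene_ids_here.append(gid)
            genes.append(Region(gid, GenomicInterval(chrom, off + s, off + e, st), role))
        for s, e, st, sc in cas.sites:
            if sc == SITE_TDNA:
                n_tdna += 1
                sid, name = f"tdna{n_tdna:03d}", f"tSim{n_tdna:03d}"
                # a tDNA is itself an annotated non-coding gene
                genes.append(Region(sid, GenomicInterval(chrom, off + s, off + e, st), ROLE_NONCODING))
            else:
                n_etc += 1
                sid, name = f"etc{n_etc:03d}", f"ETCsim{n_etc}"
            sites.append(PolIIISite(sid, GenomicInterval(chrom, off + s, off + e, st), sc, name))
        if cas.event is not None:
            cls, s, e, st, fold = cas.event
            truth_rows.append(
                {
                    "event_id": f"ev{len(truth_rows) + 1:03d}",
                    "event_class": cls,
                    "chrom": chrom,
                    "start": off + s,
                    "end": off + e,
                    "strand": st,
                    "fold": fold,
                    "gene_id": gene_ids_here[cas.event_gene_slot] if cas.event_gene_slot is not None else "",
                }
            )
        cursors[chrom] = off + cas.length
    chrom_sizes = {c: cursors[c] + int(rng.integers(300, 900)) for c in chrom_names}

    truth = pd.DataFrame(
        truth_rows,
        columns=["event_id", "event_class", "chrom", "start", "end", "strand", "fold", "gene_id"],
    )
    return SimulatedGenome(genes=genes, sites=sites, chrom_sizes=chrom_sizes, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# file export (standard formats, consumed back through annotate/counting)

def write_genome_files(sim: SimulatedGenome, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gff = outdir / "genome.gff3"
    tdna_ids = {s.id for s in sim.sites if s.site_class == SITE_TDNA}
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(sim.genes, key=lambda g: (g.interval.chrom, g.interval.start, g.id)):
            ftype = "tRNA_gene" if g.id in tdna_ids else "gene"
            iv = g.interval
            fh.write(
                f"{iv.chrom}\ttgmseq_sim\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\tID={g.id};Name={g.id}\n"
            )
    bed = outdir / "sites.bed"
    with open(bed, "w") as fh:
        for s in sorted(sim.sites, key=lambda s: (s.interval.chrom, s.interval.start)):
            if s.site_class == SITE_ETC:
                iv = s.interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s.name}\t0\t{iv.strand}\n")
    sizes = outdir / "chrom.sizes"
    with open(sizes, "w") as fh:
        for c in sorted(sim.chrom_sizes):
            fh.write(f"{c}\t{sim.chrom_sizes[c]}\n")
    truth = outdir / "truth.tsv"
    sim.truth.to_csv(truth, sep="\t", index=False)
    return {"gff": gff, "sites_bed": bed, "chrom_sizes": sizes, "truth": truth}


# ---------------------------------------------------------------------------
# count-level simulation (primary path)

def make_sample_sheet(cfg: SimulationConfig) -> SampleSheet:
    rows = []
    i = 0
    for cond in cfg.conditions:
        for rep in range(1, cfg.replicates + 1):
            rows.append({"sample": f"{cond}_rep{rep}", "condition": cond, "replicate": rep, "path": ""})
            i += 1
    return SampleSheet(pd.DataFrame(rows))


def baseline_means(catalog: RegionCatalog, cfg: SimulationConfig) -> pd.Series:
    """Per-region NB means under the wild-type condition (seed-deterministic)."""
    rng = np.random.default_rng([int(cfg.seed), 13])
    df = catalog.to_frame()
    mu = pd.Series(cfg.intergenic_baseline_mean, index=df.index, dtype=float)
    gene_mask = df["role"] != ROLE_WINDOW
    n = int(gene_mask.sum())
    mu[gene_mask] = rng.lognormal(cfg.gene_mean_meanlog, cfg.gene_mean_sdlog, size=n)
    return mu


def event_effect_matrix(
    truth: pd.DataFrame,
    catalog: RegionCatalog,
    cfg: SimulationConfig,
) -> pd.DataFrame:
    """Per-region fold multiplier in each condition (wild type is all ones)."""
    df = catalog.to_frame()
    effect = pd.DataFrame(1.0, index=df.index, columns=list(cfg.conditions))
    mutant = cfg.conditions[1]
    for ev in truth.itertuples():
        if ev.event_class == EVENT_TRANS:
            effect.loc[ev.gene_id, mutant] *= ev.fold
            continue
        hit = (
            (df["role"] == ROLE_WINDOW)
            & (df["chrom"] == ev.chrom)
            & (df["strand"] == ev.strand)
            & (df["start"] < ev.end)
            & (df["end"] > ev.start)
        )
        effect.loc[hit, mutant] *= ev.fold
    return effect


def affected_region_ids(truth: pd.DataFrame, catalog: RegionCatalog) -> dict[str, list[str]]:
    """Truth event id -> catalog region ids carrying the planted effect."""
    df = catalog.to_frame()
    out: dict[str, list[str]] = {}
    for ev in truth.itertuples():
        if ev.event_class == EVENT_TRANS:
            out[ev.event_id] = [ev.gene_id]
            continue
        hit = df[
            (df["role"] == ROLE_WINDOW)
            & (df["chrom"] == ev.chrom)
            & (df["strand"] == ev.strand)
            & (df["start"] < ev.end)
            & (df["end"] > ev.start)
        ]
        out[ev.event_id] = list(hit.sort_values("start")["id"])
    return out


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if alpha <= 0:
        return rng.poisson(mean)
    n = 1.0 / alpha
    p = 1.0 / (1.0 + alpha * mean)
    return rng.negative_binomial(n, p)


def simulate_counts(
    truth: pd.DataFrame,
    catalog: RegionCatalog,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, SampleSheet]:
    """Region x sample NB count matrix with planted effects applied in the mutant."""
    cfg = config
    rng = np.random.default_rng([int(cfg.seed), 17])
    sheet = make_sample_sheet(cfg)
    mu0 = baseline_means(catalog, cfg)
    effect = event_effect_matrix(truth, catalog, cfg)
    sf = list(cfg.library_size_factors)
    if len(sf) != cfg.n_samples:
        raise ValueError(f"need {cfg.n_samples} library size factors, got {len(sf)}")
    cols = {}
    for j, row in enumerate(sheet.samples.itertuples()):
        mean_j = sf[j] * mu0.to_numpy() * effect[row.condition].to_numpy()
        cols[row.sample] = _nb_draw(rng, mean_j, cfg.dispersion)
    counts = pd.DataFrame(cols, index=catalog.to_frame().index)
    counts.attrs["provenance"] = f"simulated;seed={cfg.seed};alpha={cfg.dispersion}"
    return counts, sheet


# ---------------------------------------------------------------------------
# read-level simulation (secondary path, exercises counting end to end)

def simulate_reads(
    counts: pd.DataFrame,
    catalog: RegionCatalog,
    config: SimulationConfig,
) -> dict[str, list[AlignmentRecord]]:
    """Stranded fixed-length alignment records realizing a drawn count matrix.

    Each region with count k in a sample receives exactly k records whose
    5' base is uniform within the region and whose strand matches the
    region, so re-counting the records reproduces the matrix exactly.
    """
    cfg = config
    rng = np.random.default_rng([int(cfg.seed), 19])
    df = catalog.to_frame()
    out: dict[str, list[AlignmentRecord]] = {}
    L = cfg.read_length
    for sample in counts.columns:
        recs: list[AlignmentRecord] = []
        col = counts[sample]
        for rid, k in col.items():
            if k == 0:
                continue
            row = df.loc[rid]
            chrom_len = catalog.chrom_sizes[row["chrom"]]
            anchors = rng.integers(int(row["start"]), int(row["end"]), size=int(k))
            for a in anchors:
                if row["strand"] == MINUS:
                    recs.append(AlignmentRecord(row["chrom"], max(0, int(a) + 1 - L), int(a) + 1, MINUS))
                else:
                    recs.append(AlignmentRecord(row["chrom"], int(a), min(chrom_len, int(a) + L), PLUS))
        recs.sort(key=lambda r: (r.chrom, r.start, r.end, r.strand))
        out[sample] = recs
    return out


def write_alignment_bed(records: Sequence[AlignmentRecord], path: str | Path) -> None:
    """Simplified alignment BED6 (name r<i>, score = mapq)."""
    with open(path, "w") as fh:
        for i, r in enumerate(records):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tr{i}\t{r.mapq}\t{r.strand}\n")


# ---------------------------------------------------------------------------
# recovery evaluation against the truth table

@dataclass
class RecoveryReport:
    per_class: pd.DataFrame       # class, n_truth, n_called, tp_called, precision, recall, f1
    confusion: pd.DataFrame       # planted class x called class (incl. "missed")
    n_false_positive_chains: int

    def metric(self, event_class: str, name: str) -> float:
        return float(self.per_class.set_index("class").at[event_class, name])


def evaluate_recovery(
    classified,
    de_results: pd.DataFrame,
    truth: pd.DataFrame,
    catalog: RegionCatalog | None = None,
) -> RecoveryReport:
    """Per-class precision/recall of planted events.

    An intergenic event is recovered when a called chain of the same
    class overlaps its span on its strand; a trans gene event is
    recovered when that gene is a significant up-regulated DE gene.
    Chains overlapping no planted span count as false positives.
    """
    chains = [(cr.category, cr.chain.interval) for cr in classified]

    def overlaps(iv: GenomicInterval, ev) -> bool:
        return iv.chrom == ev.chrom and iv.strand == ev.strand and iv.start < ev.end and ev.start < iv.end

    rows = []
    confusion: dict[tuple[str, str], int] = {}
    for cls in INTERGENIC_EVENTS:
        evs = list(truth[truth["event_class"] == cls].itertuples())
        called = [(c, iv) for c, iv in chains if c == cls]
        tp_truth = 0
        for ev in evs:
            hits = [c for c, iv in chains if overlaps(iv, ev)]
            best = hits[0] if hits else "missed"
            if cls in hits:
                best = cls
                tp_truth += 1
            confusion[(cls, best)] = confusion.get((cls, best), 0) + 1
        tp_called = sum(
            1 for c, iv in called
            if any(overlaps(iv, ev) for ev in truth[truth["event_class"] == cls].itertuples())
        )
        rows.append(_metric_row(cls, len(evs), len(called), tp_called, tp_truth))

    # trans events: recovered through the gene-scope DE calls
    trans = truth[truth["event_class"] == EVENT_TRANS]
    sig_up_genes = de_results[
        (de_results["role"] != ROLE_WINDOW)
        & de_results["significant"]
        & (de_results["direction"] == "up")
    ]
    planted_genes = set(trans["gene_id"])
    tp = sum(1 for g in sig_up_genes.index if g in planted_genes)
    for ev in trans.itertuples():
        hit = ev.gene_id in sig_up_genes.index
        confusion[(EVENT_TRANS, EVENT_TRANS if hit else "missed")] = (
            confusion.get((EVENT_TRANS, EVENT_TRANS if hit else "missed"), 0) + 1
        )
    rows.append(_metric_row(EVENT_TRANS, len(trans), int(len(sig_up_genes)), tp, tp))

    n_fp = sum(
        1 for c, iv in chains
        if not any(overlaps(iv, ev) for ev in truth.itertuples())
    )
    per_class = pd.DataFrame(rows)
    conf = (
        pd.Series(confusion).rename_axis(["planted", "called"]).unstack(fill_value=0)
        if confusion
        else pd.DataFrame()
    )
    return RecoveryReport(per_class=per_class, confusion=conf, n_false_positive_chains=n_fp)


def _metric_row(cls: str, n_truth: int, n_called: int, tp_called: int, tp_truth: int) -> dict:
    precision = tp_called / n_called if n_called else float("nan")
    recall = tp_truth / n_truth if n_truth else float("nan")
    f1 = (
        2 * precision * recall / (precision + recall)
        if n_called and n_truth and (precision + recall) > 0
        else float("nan")
    )
    return {
        "class": cls,
        "n_truth": n_truth,
        "n_called": n_called,
        "tp": tp_called,
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }
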