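"""Categorize differentially expressed intergenic regions.

Up-regulated DE intergenic windows are merged into chains (adjacent
windows of one block with continuous mutant-condition expression) and
each chain is assigned one mis-expression category by explicit rules
with fixed precedence:

1. readthrough        — the chain continues from the 3' end of a
                        same-strand upstream gene, spans a tDNA, and
                        expression continues past the tDNA's far edge;
2. five_prime_extension — the chain is contiguous with the 5' end of a
                        same-strand downstream gene (an upstream
                        transcription start extending the 5'-UTR);
3. three_prime_extension — the chain is contiguous with the 3' end of a
                        same-strand upstream gene (termination
                        readthrough past the annotated end);
4. derepressed_intergenic — everything else: standalone up-regulated
                        intergenic signal.

Readthrough outranks the extensions because a readthrough chain also
touches a gene 3' end; it is the distinct phenomenon of an upstream
transcript failing to stop at an intervening tDNA.  Every chain is also
annotated with its nearest Pol III site (tDNA or ETC site, strand-blind
distance) and a proximity flag (default threshold 500 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import (
    PLUS,
    ROLE_WINDOW,
    SITE_TDNA,
    GenomicInterval,
    PolIIISite,
    RegionCatalog,
    nearest_polIII_site,
)

CAT_5EXT = "five_prime_extension"
CAT_3EXT = "three_prime_extension"
CAT_READTHROUGH = "readthrough"
CAT_DEREP = "derepressed_intergenic"
CATEGORIES = (CAT_5EXT, CAT_3EXT, CAT_READTHROUGH, CAT_DEREP)


@dataclass(frozen=True)
class ClassifyConfig:
    proximity_threshold: int = 500
    contiguity_gap: int = 0
    expression_continuity_ratio: float = 0.1
    bridge_alpha: float = 0.05   # nominal p required of non-seed chained windows

    def __post_init__(self) -> None:
        if self.proximity_threshold < 0 or self.contiguity_gap < 0 or self.expression_continuity_ratio < 0:
            raise ValueError("classification thresholds must be >= 0")
        if not (0 < self.bridge_alpha <= 1):
            raise ValueError("bridge_alpha must lie in (0, 1]")


@dataclass
class Chain:
    """A merged run of significant up-regulated intergenic windows."""

    region_ids: list[str]
    interval: GenomicInterval
    block_id: str
    flank_left_gene: str
    flank_right_gene: str
    window_means: list[float]        # mutant-condition normalized mean per window

    @property
    def max_mean(self) -> float:
        return max(self.window_means)


@dataclass
class ClassifiedRegion:
    chain: Chain
    category: str
    associated_gene: str = ""
    nearest_site: PolIIISite | None = None
    distance: float = float("inf")
    proximal: bool = False
    ambiguous: bool = False


@dataclass
class CategorySummary:
    counts: dict[str, int] = field(default_factory=dict)
    proximal_counts: dict[str, int] = field(default_factory=dict)
    n_up_chains: int = 0
    n_down_windows: int = 0
    n_de_genes: int = 0
    n_de_genes_with_nearby_site: int = 0


def chain_de_windows(
    de_results: pd.DataFrame,
    catalog: RegionCatalog,
    config: ClassifyConfig | None = None,
) -> list[Chain]:
    """Merge significant up-regulated intergenic windows into chains.

    Windows of the same block separated by at most ``contiguity_gap``
    bases form a chain when each carries continuous mutant-condition
    expression (at least ``expression_continuity_ratio`` of the block's
    strongest significant window).  Windows that are not themselves
    BH-significant can be bridged in — leniently in a chain's interior,
    strictly at its ends (see the inline rule below) — so a single weak
    draw does not shatter one transcript into fragments; every chain
    still needs at least one BH-significant seed window.
    """
    cfg = config or ClassifyConfig()
    cat = catalog.to_frame()
    windows = de_results[de_results["role"] == ROLE_WINDOW]
    sig_up = windows["significant"] & (windows["direction"] == "up")
    chains: list[Chain] = []
    if not sig_up.any():
        return chains
    sub = cat.loc[windows.index].join(windows[["meanB", "pval", "direction"]])
    sub["sig_up"] = sig_up
    # typical silent-window level of this data set, the reference point for
    # deciding whether a window looks like chain signal or like background
    base_level = max(float(sub["meanB"].median()), 1e-3)
    sig_blocks = sub.loc[sub["sig_up"], "block_id"].unique()
    for block_id in sorted(sig_blocks):
        block = sub[sub["block_id"] == block_id].sort_values("start")
        # A window belongs to a chain when it is itself significant-up, or
        # bridges/extends one with continuous mutant expression (at least
        # expression_continuity_ratio of the block's strongest significant
        # window, direction up).  Interior windows — lying between two
        # significant windows — bridge on expression continuity alone: a
        # weak draw flanked by strong signal is part of the same transcript.
        # Terminal extensions must additionally look like chain signal
        # rather than background: nominally significant (raw p below
        # bridge_alpha) or closer to the chain maximum than to the silent-
        # window level on a log scale (above their geometric mean).  This
        # keeps baseline noise at a chain's edge from stretching it onto a
        # gene end or across a tDNA, which would change its category.
        ref = float(block.loc[block["sig_up"], "meanB"].max())
        expressed = (
            (block["direction"] == "up")
            & (block["meanB"] >= cfg.expression_continuity_ratio * ref)
        )
        sig_pos = block.index[block["sig_up"]]
        first_sig, last_sig = block.index.get_loc(sig_pos[0]), block.index.get_loc(sig_pos[-1])
        pos = np.arange(len(block))
        interior = (pos > first_sig) & (pos < last_sig)
        chain_like = block["meanB"] >= np.sqrt(base_level * ref)
        member = block["sig_up"].to_numpy() | (
            expressed.to_numpy()
            & (interior | (block["pval"] < cfg.bridge_alpha).to_numpy() | chain_like.to_numpy())
        )
        cur: list[pd.Series] = []
        for (_, row), is_member in zip(block.iterrows(), member):
            if cur and (not is_member or row["start"] - cur[-1]["end"] > cfg.contiguity_gap):
                if any(r["sig_up"] for r in cur):
                    chains.append(_make_chain(cur, block_id))
                cur = []
            if is_member:
                cur.append(row)
        if cur and any(r["sig_up"] for r in cur):
            chains.append(_make_chain(cur, block_id))
    chains.sort(key=lambda c: (c.interval.chrom, c.interval.strand, c.interval.start))
    return chains


def _make_chain(rows: list[pd.Series], block_id: str) -> Chain:
    first, last = rows[0], rows[-1]
    return Chain(
        region_ids=[str(r["id"]) for r in rows],
        interval=GenomicInterval(first["chrom"], int(first["start"]), int(last["end"]), first["strand"]),
        block_id=str(block_id),
        flank_left_gene=str(first["flank_left_gene"]),
        flank_right_gene=str(first["flank_right_gene"]),
        window_means=[float(r["meanB"]) for r in rows],
    )


def _gene_interval(catalog_df: pd.DataFrame, gene_id: str) -> GenomicInterval | None:
    if not gene_id or gene_id not in catalog_df.index:
        return None
    row = catalog_df.loc[gene_id]
    return GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]), row["strand"])


def classify_chain(
    chain: Chain,
    catalog: RegionCatalog,
    sites: Sequence[PolIIISite],
    config: ClassifyConfig | None = None,
) -> ClassifiedRegion:
    """Assign one mis-expression category to a chain (precedence above)."""
    cfg = config or ClassifyConfig()
    cat = catalog.to_frame()
    iv = chain.interval
    gap = cfg.contiguity_gap

    # Orientation bookkeeping: for a plus-strand chain the upstream gene
    # (transcribing into the block) is the left flank and its 3' end is
    # gene.end; mirrored on the minus strand.
    if iv.strand == PLUS:
        up_gene = _gene_interval(cat, chain.flank_left_gene)
        down_gene = _gene_interval(cat, chain.flank_right_gene)
        up_id, down_id = chain.flank_left_gene, chain.flank_right_gene
        touches_up = up_gene is not None and iv.start - up_gene.end <= gap
        touches_down = down_gene is not None and down_gene.start - iv.end <= gap
    else:
        up_gene = _gene_interval(cat, chain.flank_right_gene)
        down_gene = _gene_interval(cat, chain.flank_left_gene)
        up_id, down_id = chain.flank_right_gene, chain.flank_left_gene
        touches_up = up_gene is not None and up_gene.start - iv.end <= gap
        touches_down = down_gene is not None and iv.start - down_gene.end <= gap

    overlapping_tdnas = [
        s for s in sites
        if s.site_class == SITE_TDNA and s.interval.chrom == iv.chrom
        and s.interval.start < iv.end and iv.start < s.interval.end
    ]

    category = CAT_DEREP
    associated = ""
    if touches_up and overlapping_tdnas and _continues_past_tdna(chain, overlapping_tdnas, cfg):
        category = CAT_READTHROUGH
        associated = up_id
    elif touches_down:
        category = CAT_5EXT
        associated = down_id
    elif touches_up:
        category = CAT_3EXT
        associated = up_id

    site, dist = nearest_polIII_site(iv, sites)
    return ClassifiedRegion(
        chain=chain,
        category=category,
        associated_gene=associated,
        nearest_site=site if dist != float("inf") else None,
        distance=dist,
        proximal=dist <= cfg.proximity_threshold,
        ambiguous=touches_up and touches_down,
    )


def _continues_past_tdna(chain: Chain, tdnas: Sequence[PolIIISite], cfg: ClassifyConfig) -> bool:
    """Same-strand expression continues beyond the tDNA's far edge.

    The far edge is the tDNA edge distal to the chain's 5' end.  The
    chain must extend past it and the distal-most window must carry at
    least ``expression_continuity_ratio`` of the chain maximum.
    """
    iv = chain.interval
    distal_mean = chain.window_means[-1] if iv.strand == PLUS else chain.window_means[0]
    for t in tdnas:
        far = t.interval.end if iv.strand == PLUS else t.interval.start
        extends = iv.end > far if iv.strand == PLUS else iv.start < far
        if extends and distal_mean >= cfg.expression_continuity_ratio * chain.max_mean:
            return True
    return False


def classify_all(
    de_results: pd.DataFrame,
    catalog: RegionCatalog,
    sites: Sequence[PolIIISite],
    config: ClassifyConfig | None = None,
) -> list[ClassifiedRegion]:
    cfg = config or ClassifyConfig()
    return [classify_chain(c, catalog, sites, cfg) for c in chain_de_windows(de_results, catalog, cfg)]


def summarize(
    classified: Sequence[ClassifiedRegion],
    de_results: pd.DataFrame,
    catalog: RegionCatalog,
    sites: Sequence[PolIIISite],
    config: ClassifyConfig | None = None,
) -> CategorySummary:
    """Category totals, proximity totals, and DE genes with a nearby site.

    A DE gene counts as having a nearby site when a tDNA or ETC site
    lies between it and the next annotated gene on either side
    (strand-blind, as sites act on local chromatin, not one strand).
    """
    cfg = config or ClassifyConfig()
    counts = {c: 0 for c in CATEGORIES}
    prox = {c: 0 for c in CATEGORIES}
    for cr in classified:
        counts[cr.category] += 1
        if cr.proximal:
            prox[cr.category] += 1

    down = de_results[
        (de_results["role"] == ROLE_WINDOW)
        & de_results["significant"]
        & (de_results["direction"] == "down")
    ]

    cat = catalog.to_frame()
    gene_rows = cat[cat["role"] != ROLE_WINDOW].sort_values(["chrom", "start"])
    de_genes = de_results[(de_results["role"] != ROLE_WINDOW) & de_results["significant"]]
    n_near = 0
    for rid in de_genes.index:
        row = cat.loc[rid]
        same_chrom = gene_rows[gene_rows["chrom"] == row["chrom"]]
        prev_end = same_chrom.loc[same_chrom["end"] <= row["start"], "end"].max()
        next_start = same_chrom.loc[same_chrom["start"] >= row["end"], "start"].min()
        lo = 0 if pd.isna(prev_end) else int(prev_end)
        hi = catalog.chrom_sizes[row["chrom"]] if pd.isna(next_start) else int(next_start)
        if any(
            s.interval.chrom == row["chrom"] and s.interval.start < hi and lo < s.interval.end
            for s in sites
        ):
            n_near += 1

    return CategorySummary(
        counts=counts,
        proximal_counts=prox,
        n_up_chains=len(classified),
        n_down_windows=int(len(down)),
        n_de_genes=int(len(de_genes)),
        n_de_genes_with_nearby_site=n_near,
    )


def classification_table(classified: Sequence[ClassifiedRegion]) -> pd.DataFrame:
    rows = []
    for cr in classified:
        iv = cr.chain.interval
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "strand": iv.strand,
                "n_windows": len(cr.chain.region_ids),
                "windows": ",".join(cr.chain.region_ids),
                "category": cr.category,
                "associated_gene": cr.associated_gene,
                "nearest_site": cr.nearest_site.name if cr.nearest_site else "",
                "site_class": cr.nearest_site.site_class if cr.nearest_site else "",
                "distance": cr.distance,
                "proximal": cr.proximal,
                "ambiguous_flanks": cr.ambiguous,
            }
        )
    cols = [
        "chrom", "start", "end", "strand", "n_windows", "windows", "category",
        "associated_gene", "nearest_site", "site_class", "distance", "proximal",
        "ambiguous_flanks",
    ]
    return pd.DataFrame(rows, columns=cols)


def summary_table(summary: CategorySummary) -> pd.DataFrame:
    rows = [
        {"category": c, "n": summary.counts.get(c, 0), "n_proximal": summary.proximal_counts.get(c, 0)}
        for c in CATEGORIES
    ]
    rows.append({"category": "de_genes_with_nearby_site",
                 "n": summary.n_de_genes_with_nearby_site, "n_proximal": summary.n_de_genes_with_nearby_site})
    return pd.DataFrame(rows)
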