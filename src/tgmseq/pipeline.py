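"""End-to-end orchestration: annotate -> count -> test -> classify -> summarize.

A single YAML config drives a run; every output directory receives the
resolved configuration that produced it, so a run can be reproduced from
its own outputs.  All tabular outputs are TSV.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import annotate, classify, counting, diffexp, simulate

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    gff: str = ""
    sites_bed: str = ""
    chrom_sizes: str = ""
    sample_sheet: str = ""
    counts: str = ""                 # precomputed count matrix TSV (alternative to alignments)
    outdir: str = "tgmseq_out"
    strandedness: str = "reverse"
    uniqueness_policy: str = "auto"
    mapq_threshold: int = 10
    partition: annotate.PartitionConfig = dataclasses.field(default_factory=annotate.PartitionConfig)
    de: diffexp.DEConfig = dataclasses.field(default_factory=diffexp.DEConfig)
    classify: classify.ClassifyConfig = dataclasses.field(default_factory=classify.ClassifyConfig)
    truth: str = ""                  # optional truth table for recovery evaluation

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (("partition", annotate.PartitionConfig), ("de", diffexp.DEConfig), ("classify", classify.ClassifyConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def write_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the output directory.

    Stage failures raise with the stage name; no partial DE/classify
    outputs are left behind (each stage writes only on success).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.write_yaml(out / "resolved_config.yaml")

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("annotate")
        genes, sites, chrom_sizes = annotate.load_annotation(
            config.gff, config.sites_bed or None, config.chrom_sizes
        )
        catalog = annotate.partition_genome(genes, chrom_sizes, config.partition)
        catalog.write_bed(out / "catalog.bed")
        catalog.write_tsv(out / "catalog.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage annotate failed: {exc}") from exc

    try:
        stage("counting")
        sheet = counting.SampleSheet.from_tsv(config.sample_sheet)
        if config.counts:
            counts = pd.read_csv(config.counts, sep="\t", index_col=0)
            counts = counts[list(sheet.samples["sample"])]
            counts = counts.loc[catalog.to_frame().index]
        else:
            counts = counting.build_count_matrix(
                sheet, catalog, config.strandedness, config.uniqueness_policy, config.mapq_threshold
            )
        counts.to_csv(out / "counts.tsv", sep="\t")
        qc_corr = counting.replicate_correlation(counts, sheet)
        pd.Series(qc_corr, name="pearson_r_log2").rename_axis("condition").to_csv(
            out / "replicate_correlation.tsv", sep="\t"
        )
    except Exception as exc:
        raise RuntimeError(f"stage counting failed: {exc}") from exc

    try:
        stage("diffexp")
        de = diffexp.run_de(counts, sheet, catalog, config.de)
        diffexp.write_de_table(de, out / "de_results.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage diffexp failed: {exc}") from exc

    try:
        stage("classify")
        classified = classify.classify_all(de, catalog, sites, config.classify)
        classify.classification_table(classified).to_csv(out / "classification.tsv", sep="\t", index=False)
        summary = classify.summarize(classified, de, catalog, sites, config.classify)
        classify.summary_table(summary).to_csv(out / "category_summary.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage classify failed: {exc}") from exc

    if config.truth:
        try:
            stage("evaluate")
            truth = pd.read_csv(config.truth, sep="\t")
            report = simulate.evaluate_recovery(classified, de, truth, catalog)
            report.per_class.to_csv(out / "recovery.tsv", sep="\t", index=False)
            report.confusion.to_csv(out / "confusion.tsv", sep="\t")
        except Exception as exc:
            raise RuntimeError(f"stage evaluate failed: {exc}") from exc

    return out
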