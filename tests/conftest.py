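import numpy as np
import pandas as pd
import pytest

from tgmseq import annotate, classify, diffexp, simulate
from tgmseq.counting import SampleSheet


@pytest.fixture(scope="session")
def standard_scenario():
    """The standard planted-event simulation run through the full pipeline.

    200 genes, 40 tDNAs, 10 ETC sites, 10 events per class at 16-fold,
    NB dispersion 0.1, two replicates per condition.
    """
    cfg = simulate.SimulationConfig(seed=1)
    sim = simulate.simulate_genome(cfg)
    catalog = annotate.partition_genome(sim.genes, sim.chrom_sizes)
    counts, sheet = simulate.simulate_counts(sim.truth, catalog, cfg)
    de = diffexp.run_de(counts, sheet, catalog)
    classified = classify.classify_all(de, catalog, sim.sites)
    report = simulate.evaluate_recovery(classified, de, sim.truth, catalog)
    return {
        "config": cfg,
        "sim": sim,
        "catalog": catalog,
        "counts": counts,
        "sheet": sheet,
        "de": de,
        "classified": classified,
        "report": report,
    }


@pytest.fixture()
def two_gene_catalog():
    """One 2300-b chromosome, one plus-strand gene at [1000, 1600)."""
    genes = [
        annotate.Region(
            "geneA", annotate.GenomicInterval("chrT", 1000, 1600, "+"), annotate.ROLE_CODING
        )
    ]
    return annotate.partition_genome(genes, {"chrT": 2300})


@pytest.fixture()
def sheet_2v2():
    return SampleSheet(
        pd.DataFrame(
            {
                "sample": ["wt_r1", "wt_r2", "mut_r1", "mut_r2"],
                "condition": ["wt", "wt", "mut", "mut"],
                "replicate": [1, 2, 1, 2],
                "path": "",
            }
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
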