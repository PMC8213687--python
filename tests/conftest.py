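import numpy as np
import pytest

from permdeg import (
    CountMatrix,
    DEGeneSpec,
    SampleMetadata,
    SimulationConfig,
    cpm_normalize,
    simulate_cohort,
    tmm_factors,
)


@pytest.fixture
def tiny_counts_tsv(tmp_path):
    path = tmp_path / "counts.tsv"
    path.write_text(
        "gene_id\tS1\tS2\n"
        "ENSG00000000001.1\t10\t20\n"
        "ENSG00000000002.3\t0\t5\n"
        "ENSG00000000003.1\t7\t1\n"
    )
    return path


@pytest.fixture
def metadata_rows():
    return [
        SampleMetadata("C1", "control", "male", "none", "discovery", fev1_fvc=0.80),
        SampleMetadata("C2", "control", "male", "none", "discovery", fev1_fvc=0.75),
        SampleMetadata("C3", "control", "female", "none", "discovery", fev1_fvc=0.90),
        SampleMetadata("P1", "case", "male", "Eex", "discovery", fev1_fvc=0.40),
        SampleMetadata("P2", "case", "male", "E", "discovery", fev1_fvc=0.55),
        SampleMetadata("P3", "case", "male", "Aex", "discovery", fev1_fvc=0.60),
        SampleMetadata("P4", "case", "female", "A", "discovery", fev1_fvc=0.50),
        SampleMetadata("P5", "case", "male", "none", "confirmation"),
    ]


def small_cohort_config(seed=11, n_genes=120, n_ctl=25, n_case=25, de=()):
    """A compact two-group cohort (controls vs male E cases)."""
    return SimulationConfig(
        seed=seed,
        n_genes=n_genes,
        group_sizes={("male", "control"): n_ctl, ("male", "E"): n_case},
        de_genes=tuple(de),
    )


@pytest.fixture(scope="session")
def spiked_cohort():
    """25 vs 25 cohort, 120 genes, 10 whole-distribution spikes at FC 4."""
    de = tuple(DEGeneSpec(gene_index=i, fold=4.0) for i in range(10))
    config = small_cohort_config(seed=202, de=de)
    counts, metadata, truth = simulate_cohort(config)
    norm = cpm_normalize(counts, tmm_factors(counts))
    return counts, metadata, truth, norm
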