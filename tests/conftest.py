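import numpy as np
import pytest

from pleioqtl.io import AssocRecord
from pleioqtl.simulate import CohortConfig, simulate_cohort


def make_record(
    variant_id="rs1",
    chrom="chr1",
    pos=1000,
    beta=0.1,
    se=0.02,
    pvalue=1e-9,
    eaf=0.3,
    n=50_000,
    study_id="gwas_a",
):
    return AssocRecord(
        variant_id=variant_id,
        chrom=chrom,
        pos=pos,
        ref="A",
        alt="G",
        beta=beta,
        se=se,
        pvalue=pvalue,
        eaf=eaf,
        n=n,
        study_id=study_id,
    )


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """A small synthetic cohort shared across tests (read-only)."""
    path = tmp_path_factory.mktemp("cohort")
    config = CohortConfig(seed=7, plant_mhc_locus=True)
    ledger = simulate_cohort(config, path)
    return path, ledger


@pytest.fixture(scope="session")
def pipeline_run(cohort_dir, tmp_path_factory):
    """Full pipeline outputs on the shared cohort."""
    from pleioqtl.pipeline import PipelineConfig, run_pipeline

    path, ledger = cohort_dir
    out = tmp_path_factory.mktemp("run")
    config = PipelineConfig(cohort_dir=str(path), out_dir=str(out), seed=7)
    manifest = run_pipeline(config)
    return out, manifest, ledger
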