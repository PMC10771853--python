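import numpy as np
import pandas as pd
import pytest

from epiresponse import preprocess, synthetic


@pytest.fixture(scope="session")
def references():
    return synthetic.generate_reference_profiles(60, 10, seed=1)


@pytest.fixture(scope="session")
def default_cohort(references):
    """A 92-sample cohort at the default study conditions (2000 probes,
    20 informative CpGs, 20 SNP-like probes, 49/92 responders)."""
    cfg = synthetic.GeneratorConfig(seed=11)
    beta, sheet, manifest, truth = synthetic.generate_cohort(cfg, references)
    return cfg, beta, sheet, manifest, truth


@pytest.fixture(scope="session")
def tiny_cohort(references):
    """A small cohort for fast structural tests."""
    cfg = synthetic.GeneratorConfig(
        n_samples=40, n_probes=300, n_informative=5, n_snp_probes=5, seed=3
    )
    beta, sheet, manifest, truth = synthetic.generate_cohort(cfg, references)
    return cfg, beta, sheet, manifest, truth


@pytest.fixture(scope="session")
def default_m_values(default_cohort):
    _, beta, *_ = default_cohort
    return preprocess.beta_to_m(beta, offset=1e-6)


def two_group_m_matrix(n_probes, n_per_group, rng, delta=0.0, n_affected=0):
    """Simple iid-normal M-value matrix with an optional planted group shift."""
    n = 2 * n_per_group
    m = rng.normal(0.0, 1.0, size=(n_probes, n))
    labels = np.array(["non_responder"] * n_per_group + ["responder"] * n_per_group)
    m[:n_affected, labels == "responder"] += delta
    samples = [f"S{i:03d}" for i in range(n)]
    m_df = pd.DataFrame(m, index=[f"cg{i:06d}" for i in range(n_probes)], columns=samples)
    sheet = pd.DataFrame({"response": labels}, index=pd.Index(samples, name="sample_id"))
    return m_df, sheet
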