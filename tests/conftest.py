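import pytest

from steplink.engine import run_protocol
from steplink.protocol import canonical_protocol, preprocess
from steplink.synthetic import SyntheticConfig, generate_pair


@pytest.fixture(scope="session")
def protocol_steps():
    return canonical_protocol()


@pytest.fixture(scope="session")
def perfect_pair():
    """Zero-error overlapping cohort: every patient has an exact claims twin."""
    cfg = SyntheticConfig(n_clinical=80, n_claims_extra=120,
                          overlap_fraction=1.0, p_surgery=1.0,
                          p_missing=0.0, p_date_error=0.0,
                          p_facility_error=0.0, seed=11)
    clinical, claims, truth = generate_pair(cfg)
    return preprocess(clinical), preprocess(claims), truth


@pytest.fixture(scope="session")
def noisy_run(protocol_steps):
    """One seeded noisy cohort run end-to-end through the canonical protocol."""
    cfg = SyntheticConfig(n_clinical=150, n_claims_extra=300, seed=5)
    clinical, claims, truth = generate_pair(cfg)
    clinical = preprocess(clinical)
    claims = preprocess(claims)
    result, outcomes = run_protocol(clinical, claims, protocol_steps)
    return clinical, claims, truth, result, outcomes
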