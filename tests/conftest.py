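import pandas as pd
import pytest

import carecycle as cc


@pytest.fixture(scope="session")
def spec():
    return cc.default_msk_spec()


@pytest.fixture(scope="session")
def sim_cohort():
    """One mid-sized simulated cohort shared by read-only tests."""
    cfg = cc.emulation_config(n_patients=1200, seed=42)
    cohort, truth = cc.simulate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def sim_matrix(spec, sim_cohort):
    _, cohort, _ = sim_cohort
    return cc.derive_element_matrix(cohort, spec)


@pytest.fixture(scope="session")
def sim_estimates(spec, sim_matrix):
    return cc.estimate_continuum(sim_matrix, spec)


def two_by_two_matrix(a: int, b: int, c: int, d: int) -> pd.DataFrame:
    """Element matrix encoding a 2x2 table: stratum B exposed (a events /
    b non-events), stratum A unexposed (c events / d non-events)."""
    rows = []
    for stratum, events, total in (("B", a, a + b), ("A", c, c + d)):
        for i in range(total):
            rows.append(
                {"patient_id": f"{stratum}{i:04d}", "stratum": stratum,
                 "age_years": 50.0, "sex": "female", "outcome": i < events}
            )
    return pd.DataFrame(rows)
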