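"""Shared fixtures: a small simulated cohort with derived gates.

Everything is generated at test time from the seeded simulator; no stored
data files. The session cohort is deliberately small (6 subjects, 2000
events per sample) — enough events for stable medians and gate valleys,
small enough that the whole suite stays fast.
"""

import numpy as np
import pytest

import floodcyto as fc


@pytest.fixture(scope="session")
def small_config():
    return fc.default_cohort_config(n_subjects=6, events_per_sample=2000)


@pytest.fixture(scope="session")
def cohort(small_config):
    return fc.simulate_cohort(small_config, seed=11)


@pytest.fixture(scope="session")
def control_pool(cohort):
    controls = [r for r in cohort if r.group == "control"]
    return fc.EventMatrix(
        values=np.vstack([r.events.values for r in controls]),
        panel=controls[0].events.panel,
    )


@pytest.fixture(scope="session")
def gates(control_pool):
    return fc.derive_gates(control_pool)


@pytest.fixture(scope="session")
def flood_fit(cohort, gates):
    """Fitted response model plus per-sample scores on the session cohort."""
    return fc.flood_from_records(cohort, gates)
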