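"""Shared fixtures: small simulated cohorts and their coherence maps.

Simulation sizes here are deliberately modest (shorter records, lower EEG
rates) so the whole suite runs on one CPU in minutes; the generator's
coupling structure is rate- and duration-invariant above ~4 cycles of the
slowest coupled period.
"""

import numpy as np
import pytest

from nvcoh import simulate as sim
from nvcoh.pipeline import PipelineConfig, subject_map

# scaled conditions reused across tests: 12 h records, 64 Hz EEG carrier,
# oximeter at 0.21 Hz, coupling in the 25-60 min band
COUPLED_SPEC = sim.CohortSpec(
    n_group_a=5, n_group_b=5, duration_h=12.0, eeg_rate=64.0,
    coupling_strength_a=1.0, coupling_strength_b=0.0, seed=20260924)

REDUCED_CONFIG = PipelineConfig(
    period_limits_min=(4.0, 120.0), n_permutations=200,
    analysis_hours=12.0, seed=7)


@pytest.fixture(scope="session")
def reduced_config():
    return REDUCED_CONFIG


@pytest.fixture(scope="session")
def coupled_cohort():
    """5 strongly coupled (group A) + 5 uncoupled (group B) recordings."""
    return sim.simulate_cohort(COUPLED_SPEC)


@pytest.fixture(scope="session")
def cohort_maps(coupled_cohort):
    """Native-grid coherence maps for the coupled cohort, keyed by subject."""
    return {rec.subject_id: subject_map(rec, REDUCED_CONFIG)
            for rec in coupled_cohort}


@pytest.fixture(scope="session")
def band_mask():
    def _mask(periods, lo=25.0, hi=60.0):
        return (periods >= lo) & (periods <= hi)
    return _mask


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
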