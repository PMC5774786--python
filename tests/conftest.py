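"""Shared fixtures: small bases, in-model-class cohorts, a trained pipeline.

Cohorts use shortened epochs (a few seconds at 256 Hz) so the suite stays
fast; the generative structure (10 subjects, two states, gain flip on
branches 2 and 4 of input 2, 20 dB SNR) matches the package defaults.
"""

from dataclasses import replace

import numpy as np
import pytest

import eegpdm as eg


@pytest.fixture(scope="session")
def basis_small():
    return eg.laguerre_basis(alpha=0.7, L=4, M=32)


@pytest.fixture(scope="session")
def inspan_gt():
    """Ground truth with PDMs inside the Laguerre span, 20 dB SNR."""
    gt = eg.make_ground_truth_laguerre(M=64, H=5, epoch_seconds=8.0, seed=3)
    return replace(gt, noise_sd=eg.calibrate_noise_sd(gt, 20.0, seed=0))


@pytest.fixture(scope="session")
def shifted_cohort(inspan_gt):
    """10-subject cohort with the ictal gain flip on branches 2 & 4 of input 2."""
    pairs = eg.make_cohort(inspan_gt, n_subjects=10, gain_shift=-1.0, seed=11)
    return [ep for pair in pairs for ep in pair]


@pytest.fixture(scope="session")
def trained(shifted_cohort):
    cfg = eg.PipelineConfig(preprocess=False, screen_cross_terms=False, seed=1)
    return eg.run_train(cfg, shifted_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
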