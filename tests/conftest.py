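"""Shared fixtures: small synthetic stacks, phantom volumes, and the
session-scoped two-state study dataset used by the end-to-end tests.

Everything is generated programmatically; the working pixel size for the
desk-scale harness is 4 A (64-px boxes), which keeps every helical feature
(pitch ~100 A, rise ~12 A) well inside Nyquist while making whole-pipeline
runs affordable.
"""

from __future__ import annotations

import numpy as np
import pytest

import helifil as hf

from helpers import make_config, WORK_BOX, WORK_PIXEL


@pytest.fixture(scope="session")
def extended_volume() -> hf.VolumeGrid:
    """Noise-free extended-state phantom at the working scale."""
    return hf.build_helical_volume(hf.extended_state(n_turns=3.0),
                                   WORK_BOX, WORK_PIXEL)


@pytest.fixture(scope="session")
def small_random_stack() -> hf.ImageStack:
    rng = np.random.default_rng(0)
    return hf.ImageStack(images=rng.normal(size=(5, 32, 32)).astype(np.float32),
                         pixel_size=1.59)


@pytest.fixture(scope="session")
def study_mixture():
    """The scaled-down study dataset: 500 extended + 250 compressed segments
    (snr 0.1, 64-px box at 4 A/px, no CTF) with ground-truth metadata."""
    cfg = make_config(42, n_segments=750, states=[
        {"name": "extended", "fraction": 2 / 3},
        {"name": "compressed", "fraction": 1 / 3},
    ])
    stack, meta = hf.generate_dataset(cfg)
    return stack, meta


@pytest.fixture(scope="session")
def study_analysis(study_mixture):
    """Full two-state analysis of the study mixture (classification +
    two-stage grid search per state).  Shared across the end-to-end tests
    because it is the most expensive computation in the suite."""
    from helifil.pipeline import analyze_states
    stack, meta = study_mixture
    analysis = analyze_states(stack, seed=42)
    return analysis, meta
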