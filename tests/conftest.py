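"""Shared fixtures: small trained runs reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import restsal as rs
from restsal.cv import PreparedSubject, make_folds, run_cv


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def _linear_cohort(seed: int, n: int = 60, t: int = 30, r: int = 6):
    """Subjects whose first region's level encodes the trait exactly.

    The planted signal is a constant offset of region 0 equal to g, on top of
    white noise; the network only has to read out a level, which makes
    training fast and the informative region unambiguous.
    """
    gen = np.random.default_rng(seed)
    subjects = []
    for i in range(n):
        g = float(gen.standard_normal())
        x = 0.3 * gen.standard_normal((t, r))
        x[:, 0] += g
        subjects.append(
            PreparedSubject(
                subject_id=f"s{i:03d}",
                family_id=f"f{i:03d}",
                g=g,
                confounds=gen.standard_normal(2) * 0.1,
                sessions=x[None],
                region_ids=[f"r{j:03d}" for j in range(r)],
            )
        )
    return subjects


@pytest.fixture(scope="session")
def linear_cohort():
    return _linear_cohort(7)


@pytest.fixture(scope="session")
def linear_run(linear_cohort):
    """A trained 5-fold run on the readable-signal cohort (3 members)."""
    folds = make_folds(linear_cohort, k=5, seed=7)
    arch = rs.ArchitectureSpec(input_dim=6, hidden_dim=8)
    config = rs.TrainingConfig.desk_scale(
        seed=7, ensemble_size=3, epochs=30, max_crop=2, batch_size=32
    )
    return run_cv(linear_cohort, folds, arch, config)


@pytest.fixture(scope="session")
def tiny_params():
    """A 2-member toy network for gradient and invariance checks."""
    spec = rs.ArchitectureSpec(input_dim=4, hidden_dim=3)
    return rs.init_ensemble(spec, [11, 22])
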