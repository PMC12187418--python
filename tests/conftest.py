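"""Shared fixtures.

The two expensive session fixtures run the package's standard study
conditions once and are shared between the acceptance tests and the
module-level trend tests:

* ``desk_sweep``  -- the default desk-scale coupling sweep (L=16, J = 0.05
  ... 1.00 step 0.05, both dynamics, 10 replicates of 2e6 events);
* ``finite_size_result`` -- the finite-size analysis near the critical
  coupling (L in {8, 16, 32}, J = 0.40 ... 0.60 step 0.025, 8 replicates).
"""

from __future__ import annotations

import numpy as np
import pytest

from spinloop.lattice import DynamicsSpec, simulate
from spinloop.sweep import SweepConfig, run_sweep

#: Near-critical J window for the finite-size study.
FS_GRID = tuple(np.round(np.arange(0.40, 0.601, 0.025), 10))
#: Sparse high-J Fisher grid covering the work integral up to J* = 10.
FS_EXTENSION = (0.65, 0.7, 0.8, 0.9, 1.0, 1.25, 1.5, 2.0, 3.0, 5.0, 10.0)


@pytest.fixture(scope="session")
def desk_sweep():
    return run_sweep(SweepConfig(base_seed=0))


@pytest.fixture(scope="session")
def finite_size_result():
    config = SweepConfig(
        J_grid=FS_GRID,
        L=(8, 16, 32),
        replicates=8,
        base_seed=0,
        measures=("entropy", "fisher"),
        fisher_extension=FS_EXTENSION,
    )
    return run_sweep(config)


@pytest.fixture(scope="session")
def frozen_records():
    """Deep-ordered chain: every site aligned, no flips ever accepted."""
    spec = DynamicsSpec(rule="metropolis", J=10.0, seed=3, n_steps=5_000, snapshot_interval=16)
    return simulate(spec, 4, init="all-up")


@pytest.fixture(scope="session")
def j0_records():
    """Disordered chain at J=0 (glauber): the binomial sensory regime."""
    spec = DynamicsSpec(rule="glauber", J=0.0, seed=5, n_steps=400_000)
    return simulate(spec, 8)
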