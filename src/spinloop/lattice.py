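"""Single-spin-flip Ising simulator viewed as a perception-action loop.

Each lattice site is treated as an agent: it senses the alignment of its
four nearest neighbours (the sensory category ``m``), acts by flipping its
spin or keeping it (action ``a`` in {-1 flip, +1 no-flip}), and lives in a
world summarised by the lattice magnetization ``w``.  One time step is one
single-site update attempt; dynamics are Glauber or Metropolis at inverse
temperature ``beta`` (default 1) with the coupling ``J`` as the control
parameter.

The simulator is the package's data generator: it produces equilibrium
event records (pre/post action, spin, sensory category, magnetization) and
periodic full-lattice snapshots.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "LatticeState",
    "DynamicsSpec",
    "SampleRecord",
    "SampleSet",
    "neighbour_alignment",
    "site_energy",
    "delta_energy",
    "flip_probability",
    "step",
    "simulate",
]

RULES = ("glauber", "metropolis")

#: Sensory alphabet: sum of the four neighbour-alignment products.
SENSORY_ALPHABET = (-4, -2, 0, 2, 4)


@dataclass
class LatticeState:
    """L x L periodic grid of +/-1 spins (the "world").

    Parameters
    ----------
    spins
        Square integer array with entries in {-1, +1}.  Coordinates are
        row-major ``(row, col)``, 0-based, wrapping via modular arithmetic.
    """

    spins: np.ndarray

    def __post_init__(self) -> None:
        self.spins = np.asarray(self.spins, dtype=np.int8)
        if self.spins.ndim != 2 or self.spins.shape[0] != self.spins.shape[1]:
            raise ValueError("spins must be a square 2-D array")
        if not np.all(np.abs(self.spins) == 1):
            raise ValueError("spins must be exactly -1 or +1")

    @property
    def L(self) -> int:
        return self.spins.shape[0]

    @property
    def n_sites(self) -> int:
        return self.L * self.L

    def magnetization(self) -> float:
        """Average spin w in [-1, 1]."""
        return float(self.spins.sum()) / self.n_sites

    def copy(self) -> "LatticeState":
        return LatticeState(self.spins.copy())

    @classmethod
    def random(cls, L: int, rng: np.random.Generator) -> "LatticeState":
        if L <= 0:
            raise ValueError(f"lattice side must be positive, got {L}")
        spins = rng.integers(0, 2, size=(L, L)).astype(np.int8) * 2 - 1
        return cls(spins)

    @classmethod
    def all_up(cls, L: int) -> "LatticeState":
        if L <= 0:
            raise ValueError(f"lattice side must be positive, got {L}")
        return cls(np.ones((L, L), dtype=np.int8))


@dataclass(frozen=True)
class DynamicsSpec:
    """Parameters of a simulation run.

    ``burn_in`` and ``snapshot_interval`` may be left as ``None``; they then
    default at :func:`simulate` time to ``200 * L**2`` discarded steps
    (200 sweeps) and ``L**2`` steps (one sweep) respectively.
    """

    rule: str
    J: float
    beta: float = 1.0
    seed: int = 0
    burn_in: int | None = None
    n_steps: int = 2_000_000
    snapshot_interval: int | None = None

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown dynamics rule {self.rule!r}; expected one of {RULES}")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.burn_in is not None and self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")
        if self.snapshot_interval is not None and self.snapshot_interval < 1:
            raise ValueError("snapshot_interval must be >= 1")

    def resolved(self, L: int) -> "DynamicsSpec":
        """Spec with L-dependent defaults filled in."""
        burn = self.burn_in if self.burn_in is not None else 200 * L * L
        snap = self.snapshot_interval if self.snapshot_interval is not None else L * L
        return DynamicsSpec(self.rule, self.J, self.beta, self.seed, burn, self.n_steps, snap)


class SampleRecord(NamedTuple):
    """One site-update event of the perception-action loop."""

    a: int            # action: -1 flip, +1 no-flip
    sigma_pre: int    # spin of the selected site before the action
    sigma_post: int   # spin after the action (= a * sigma_pre)
    m_pre: int        # sensory category before (sum of 4 alignment products)
    m_post: int       # sensory category after (= a * m_pre)
    w_pre: float      # lattice magnetization before
    w_post: float     # lattice magnetization after


def neighbour_alignment(state: LatticeState, site: tuple[int, int]) -> int:
    """Sensory category m = sum_{j in nu(i)} sigma(i) sigma(j) in {-4,-2,0,2,4}.

    The site energy is E(i) = -J * m, so m is a J-independent encoding of the
    site's sensory state.
    """
    r, c = site
    L = state.L
    if not (0 <= r < L and 0 <= c < L):
        raise IndexError(f"site {site} out of bounds for L={L}")
    s = state.spins
    return int(
        s[r, c]
        * (s[(r + 1) % L, c] + s[(r - 1) % L, c] + s[r, (c + 1) % L] + s[r, (c - 1) % L])
    )


def site_energy(state: LatticeState, site: tuple[int, int], J: float) -> float:
    """Local energy E(i) = -J * m of a site with its four neighbours."""
    return -J * neighbour_alignment(state, site)


def delta_energy(state: LatticeState, site: tuple[int, int], J: float) -> float:
    """Energy change dE = 2*J*m incurred by flipping the site's spin."""
    return 2.0 * J * neighbour_alignment(state, site)


def flip_probability(dE: float, beta: float, rule: str) -> float:
    """Probability of accepting the spin flip.

    Glauber: 0.5 * (1 - tanh(0.5*beta*dE)); Metropolis: min(1, exp(-beta*dE)).
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    if rule == "glauber":
        return 0.5 * (1.0 - np.tanh(0.5 * beta * dE))
    if rule == "metropolis":
        return float(min(1.0, np.exp(-beta * dE)))
    raise ValueError(f"unknown dynamics rule {rule!r}; expected one of {RULES}")


def step(
    state: LatticeState, spec: DynamicsSpec, rng: np.random.Generator
) -> tuple[LatticeState, SampleRecord]:
    """One single-site update attempt, mutating ``state`` in place.

    Draws one site index and one uniform variate from ``rng``.  Returns the
    (same, updated) state and the event record.
    """
    L = state.L
    N = L * L
    idx = int(rng.integers(0, N))
    r, c = divmod(idx, L)
    m = neighbour_alignment(state, (r, c))
    s = int(state.spins[r, c])
    ssum = int(state.spins.sum())
    p = flip_probability(2.0 * spec.J * m, spec.beta, spec.rule)
    flip = rng.random() < p
    a = -1 if flip else 1
    if flip:
        state.spins[r, c] = -s
    ssum_post = ssum - 2 * s if flip else ssum
    rec = SampleRecord(
        a=a,
        sigma_pre=s,
        sigma_post=a * s,
        m_pre=m,
        m_post=a * m,
        w_pre=ssum / N,
        w_post=ssum_post / N,
    )
    return state, rec


@njit(cache=True)
def _run_chain(spins, J, beta, glauber, sites, u, burn_in, a_out, spre_out, m_out, ssum_out, snap_interval, snaps):  # pragma: no cover - jitted
    L = spins.shape[0]
    ssum = 0
    for r in range(L):
        for c in range(L):
            ssum += spins[r, c]
    n_total = sites.shape[0]
    snap_idx = 0
    for t in range(n_total):
        idx = sites[t]
        r = idx // L
        c = idx - r * L
        s = spins[r, c]
        m = s * (
            spins[(r + 1) % L, c]
            + spins[(r - 1) % L, c]
            + spins[r, (c + 1) % L]
            + spins[r, (c - 1) % L]
        )
        dE = 2.0 * J * m
        if glauber:
            p = 0.5 * (1.0 - np.tanh(0.5 * beta * dE))
        else:
            p = np.exp(-beta * dE)
            if p > 1.0:
                p = 1.0
        flip = u[t] < p
        k = t - burn_in
        if k >= 0:
            a_out[k] = -1 if flip else 1
            spre_out[k] = s
            m_out[k] = m
            ssum_out[k] = ssum
        if flip:
            spins[r, c] = -s
            ssum -= 2 * s
        if k >= 0 and (k + 1) % snap_interval == 0:
            snaps[snap_idx, :, :] = spins
            snap_idx += 1


@dataclass
class SampleSet:
    """Equilibrium event records plus periodic lattice snapshots.

    Records are stored columnar; post-action fields are derived from the
    invariants sigma_post = a*sigma_pre, m_post = a*m_pre and
    w_post = w_pre - (1 - a)*sigma_pre / L^2, which hold by construction.
    """

    spec: DynamicsSpec
    L: int
    a: np.ndarray           # int8, -1/+1
    sigma_pre: np.ndarray   # int8
    m_pre: np.ndarray       # int8
    ssum_pre: np.ndarray    # int32 spin sums (w_pre = ssum_pre / L^2)
    snapshots: np.ndarray   # (n_snap, L, L) int8
    init: str = "random"

    def __len__(self) -> int:
        return self.a.shape[0]

    @property
    def n_sites(self) -> int:
        return self.L * self.L

    @property
    def sigma_post(self) -> np.ndarray:
        return (self.a * self.sigma_pre).astype(np.int8)

    @property
    def m_post(self) -> np.ndarray:
        return (self.a * self.m_pre).astype(np.int8)

    @property
    def ssum_post(self) -> np.ndarray:
        return self.ssum_pre - (1 - self.a.astype(np.int32)) * self.sigma_pre

    @property
    def w_pre(self) -> np.ndarray:
        return self.ssum_pre / self.n_sites

    @property
    def w_post(self) -> np.ndarray:
        return self.ssum_post / self.n_sites

    def record(self, i: int) -> SampleRecord:
        return SampleRecord(
            int(self.a[i]),
            int(self.sigma_pre[i]),
            int(self.sigma_post[i]),
            int(self.m_pre[i]),
            int(self.m_post[i]),
            float(self.w_pre[i]),
            float(self.w_post[i]),
        )

    def __iter__(self) -> Iterator[SampleRecord]:
        return (self.record(i) for i in range(len(self)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": np.arange(len(self)),
                "a": self.a,
                "sigma_pre": self.sigma_pre,
                "sigma_post": self.sigma_post,
                "m_pre": self.m_pre,
                "m_post": self.m_post,
                "w_pre": self.w_pre,
                "w_post": self.w_post,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def manifest(self) -> dict:
        return {
            "spec": asdict(self.spec),
            "L": self.L,
            "init": self.init,
            "n_records": len(self),
            "n_snapshots": int(self.snapshots.shape[0]),
        }

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2)


def simulate(spec: DynamicsSpec, L: int, init: str = "random") -> SampleSet:
    """Run the chain and collect ``n_steps`` equilibrium event records.

    The first ``burn_in`` steps are discarded; full-lattice snapshots are
    stored every ``snapshot_interval`` recorded steps.  All randomness comes
    from one ``numpy`` Generator seeded with ``spec.seed``: the initial
    condition (if random) is drawn first, then the whole site-index stream,
    then the whole uniform stream, so a run is reproducible from the spec
    alone.

    Parameters
    ----------
    init
        "random" for uniform random spins, "all-up" for the fully aligned
        start (useful deep in the ordered phase where a random start would
        take long to equilibrate).
    """
    if L <= 0:
        raise ValueError(f"lattice side must be positive, got {L}")
    spec = spec.resolved(L)
    rng = np.random.default_rng(spec.seed)
    if init == "random":
        state = LatticeState.random(L, rng)
    elif init == "all-up":
        state = LatticeState.all_up(L)
    else:
        raise ValueError(f"unknown init mode {init!r}")

    n_total = spec.burn_in + spec.n_steps
    sites = rng.integers(0, L * L, size=n_total, dtype=np.int64)
    u = rng.random(n_total)

    a = np.empty(spec.n_steps, dtype=np.int8)
    spre = np.empty(spec.n_steps, dtype=np.int8)
    m = np.empty(spec.n_steps, dtype=np.int8)
    ssum = np.empty(spec.n_steps, dtype=np.int32)
    n_snap = spec.n_steps // spec.snapshot_interval
    snaps = np.empty((n_snap, L, L), dtype=np.int8)

    _run_chain(
        state.spins,
        float(spec.J),
        float(spec.beta),
        spec.rule == "glauber",
        sites,
        u,
        spec.burn_in,
        a,
        spre,
        m,
        ssum,
        spec.snapshot_interval,
        snaps,
    )
    return SampleSet(spec=spec, L=L, a=a, sigma_pre=spre, m_pre=m, ssum_pre=ssum, snapshots=snaps, init=init)
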