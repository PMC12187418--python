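"""Plug-in estimators of the three information-theoretic intrinsic utilities.

From a :class:`~spinloop.lattice.SampleSet` of perception-action events:

* predictive information -- mutual information between the pre- and
  post-action sensory categories, with the diversity/unpredictability
  decomposition;
* average empowerment -- the capacity of the one-step action channel
  p(s_{t+1} | a_t), averaged over the equilibrium distribution of sensory
  contexts (the channel is noiseless binary for m != 0, degenerate for
  m = 0);
* negative variational free energy -- the intrinsic active-inference term
  -H(S_{t+1} | W_{t+1}, a_t), a weighted average over actions.

All values are reported in bits.  Entropies are maximum-likelihood plug-in
estimates; the optional Miller-Madow flag adds the (K-1)/(2n) first-order
bias correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import SampleSet, SENSORY_ALPHABET

__all__ = [
    "EmpiricalJoint",
    "PIResult",
    "empirical_joint",
    "entropy_bits",
    "mutual_information",
    "predictive_information",
    "sensor_channel_capacity",
    "action_channel",
    "blahut_arimoto",
    "capacity_achieving_input",
    "average_empowerment",
    "negative_free_energy",
    "bin_magnetization",
]

_RECORD_FIELDS = ("a", "sigma_pre", "sigma_post", "m_pre", "m_post", "w_pre", "w_post")
_W_FIELDS = ("w_pre", "w_post")

#: Number of equal-width magnetization bins used when exact levels are too many.
DEFAULT_W_BINS = 21
#: Largest lattice side for which the exact magnetization levels are used
#: under the "auto" binning rule.
EXACT_W_MAX_L = 8


def bin_magnetization(w: np.ndarray, w_binning, L: int) -> np.ndarray:
    """Discretize magnetization values into integer bin codes.

    ``w_binning`` is "exact" (one bin per achievable value of the spin sum),
    an integer number of equal-width bins on [-1, 1], or "auto" (exact for
    L <= 8, else 21 bins).  The rule must be fixed per run and recorded in
    the run manifest.
    """
    if w_binning == "auto":
        w_binning = "exact" if L <= EXACT_W_MAX_L else DEFAULT_W_BINS
    if w_binning == "exact":
        N = L * L
        return np.round((np.asarray(w) * N + N) / 2).astype(np.int64)
    nbins = int(w_binning)
    if nbins < 2:
        raise ValueError("w_binning bin count must be >= 2")
    codes = np.floor((np.asarray(w) + 1.0) / 2.0 * nbins).astype(np.int64)
    return np.clip(codes, 0, nbins - 1)


@dataclass
class EmpiricalJoint:
    """Counts over the product alphabet of selected discrete record fields."""

    variables: tuple[str, ...]
    levels: tuple[np.ndarray, ...]   # observed category values per variable
    counts: np.ndarray               # len(variables)-dimensional table
    n: int

    def probs(self) -> np.ndarray:
        return self.counts / self.n


def empirical_joint(records: SampleSet, variables, w_binning="auto") -> EmpiricalJoint:
    """Empirical joint counts of record fields, magnetization binned.

    ``variables`` is an ordered selection from a, sigma_pre, sigma_post,
    m_pre, m_post, w_pre, w_post.
    """
    variables = tuple(variables)
    if len(variables) == 0:
        raise ValueError("at least one variable must be selected")
    if len(set(variables)) != len(variables):
        raise ValueError(f"duplicate variable selection: {variables}")
    unknown = set(variables) - set(_RECORD_FIELDS)
    if unknown:
        raise ValueError(f"unknown record fields: {sorted(unknown)}")
    if len(records) == 0:
        raise ValueError("empty record set")

    codes, levels, shape = [], [], []
    for name in variables:
        values = getattr(records, name)
        if name in _W_FIELDS:
            values = bin_magnetization(values, w_binning, records.L)
        lv, inv = np.unique(np.asarray(values), return_inverse=True)
        codes.append(inv)
        levels.append(lv)
        shape.append(len(lv))
    flat = np.ravel_multi_index(codes, shape)
    counts = np.bincount(flat, minlength=int(np.prod(shape))).reshape(shape)
    return EmpiricalJoint(variables=variables, levels=tuple(levels), counts=counts, n=len(records))


def entropy_bits(counts: np.ndarray, miller_madow: bool = False) -> float:
    """Plug-in Shannon entropy (bits) of a count table; 0*log0 = 0."""
    counts = np.asarray(counts, dtype=float).ravel()
    n = counts.sum()
    if n <= 0:
        raise ValueError("empty count table")
    p = counts[counts > 0] / n
    h = float(-(p * np.log2(p)).sum())
    if miller_madow:
        h += (len(p) - 1) / (2.0 * n * np.log(2))
    return h


def mutual_information(joint: EmpiricalJoint, miller_madow: bool = False) -> float:
    """Plug-in mutual information (bits) of a two-variable joint."""
    if len(joint.variables) != 2:
        raise ValueError("mutual information needs exactly two variables")
    c = joint.counts
    if c.size == 1:
        return 0.0
    hx = entropy_bits(c.sum(axis=1), miller_madow)
    hy = entropy_bits(c.sum(axis=0), miller_madow)
    hxy = entropy_bits(c, miller_madow)
    return max(0.0, hx + hy - hxy)


@dataclass(frozen=True)
class PIResult:
    """Predictive information and its decomposition.

    pi = diversity (H of the future sensory state) minus unpredictability
    (H of the future given the past).
    """

    pi_bits: float
    diversity_bits: float
    unpredictability_bits: float


def predictive_information(records: SampleSet, miller_madow: bool = False) -> PIResult:
    """One-step predictive information I(m_post ; m_pre) in bits.

    Pairs are within-event: the sensory category immediately before and
    after one action.
    """
    if len(records) == 0:
        raise ValueError("empty record set")
    ipre = (records.m_pre.astype(np.int64) + 4) // 2
    ipost = (records.m_post.astype(np.int64) + 4) // 2
    counts = np.bincount(5 * ipre + ipost, minlength=25).reshape(5, 5)
    diversity = entropy_bits(counts.sum(axis=0), miller_madow)
    h_joint = entropy_bits(counts, miller_madow)
    h_pre = entropy_bits(counts.sum(axis=1), miller_madow)
    unpredictability = h_joint - h_pre
    return PIResult(
        pi_bits=diversity - unpredictability,
        diversity_bits=diversity,
        unpredictability_bits=unpredictability,
    )


def sensor_channel_capacity(m: int) -> float:
    """Capacity (bits) of the one-step action channel in sensory context m.

    For m != 0, flip and no-flip lead to distinct sensory outcomes (-m vs m):
    a noiseless binary channel with capacity 1 bit.  For m = 0 both actions
    give the same outcome and the capacity is 0.
    """
    if m not in SENSORY_ALPHABET:
        raise ValueError(f"sensory category must be one of {SENSORY_ALPHABET}, got {m}")
    return 1.0 if m != 0 else 0.0


def action_channel(m: int) -> np.ndarray:
    """Conditional p(s_post | a) as a (2, n_outputs) row-stochastic matrix.

    Rows index actions (flip, no-flip); columns index the possible sensory
    outputs (-m, m) for m != 0, or the single output 0 for m = 0.
    """
    if m not in SENSORY_ALPHABET:
        raise ValueError(f"sensory category must be one of {SENSORY_ALPHABET}, got {m}")
    if m == 0:
        return np.ones((2, 1))
    return np.array([[1.0, 0.0], [0.0, 1.0]])


def blahut_arimoto(
    channel: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 10_000,
    init: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Channel capacity (bits) and optimal input law by Blahut-Arimoto.

    ``channel`` is row-stochastic p(y|x).  Returns (capacity, p(x)).
    """
    Q = np.asarray(channel, dtype=float)
    if Q.ndim != 2 or np.any(Q < 0) or not np.allclose(Q.sum(axis=1), 1.0):
        raise ValueError("channel must be a row-stochastic matrix")
    nx = Q.shape[0]
    p = np.full(nx, 1.0 / nx) if init is None else np.asarray(init, dtype=float) / np.sum(init)
    logQ = np.log(np.where(Q > 0, Q, 1.0))
    cap = 0.0
    for _ in range(max_iter):
        q = p @ Q  # output law
        # D(Q_x || q) per input, in nats
        d = (Q * (logQ - np.log(np.where(q > 0, q, 1.0)))).sum(axis=1)
        new_cap_upper = float(d.max())
        new_cap_lower = float(np.log((p * np.exp(d)).sum()))
        p = p * np.exp(d)
        p /= p.sum()
        cap = new_cap_lower
        if new_cap_upper - new_cap_lower < tol:
            break
    return cap / np.log(2), p


def capacity_achieving_input(m: int) -> np.ndarray:
    """Input law over (flip, no-flip) achieving the channel capacity.

    For any m != 0 the channel is a symmetric noiseless binary channel and
    the uniform law (1/2, 1/2) is optimal.  m = 0 is the degenerate channel
    where capacity is 0 for every input; it is rejected here.
    """
    if m not in SENSORY_ALPHABET:
        raise ValueError(f"sensory category must be one of {SENSORY_ALPHABET}, got {m}")
    if m == 0:
        raise ValueError("m = 0 is a degenerate channel: any input achieves capacity 0")
    return np.array([0.5, 0.5])


def average_empowerment(records: SampleSet) -> float:
    """Average one-step empowerment sum_m p(m) C(m) = 1 - p(m_pre = 0), bits."""
    if len(records) == 0:
        raise ValueError("empty record set")
    return 1.0 - float(np.mean(records.m_pre == 0))


def negative_free_energy(
    records: SampleSet, w_binning="auto", miller_madow: bool = False
) -> float:
    """Average negative variational free energy (bits, <= 0).

    -F-bar = -sum_a p(a) H(m_post | w_post, a): minus the expected entropy
    of the post-action sensory category given the post-action world state
    (binned magnetization) and the action.  Zero iff the sensory outcome is
    deterministic given (w, a); large negative when the site's local view is
    uninformative about the lattice.
    """
    if len(records) == 0:
        raise ValueError("empty record set")
    n = len(records)
    ia = (1 - records.a.astype(np.int64)) // 2  # 0 no-flip... (a=+1 -> 0, a=-1 -> 1)
    iw = bin_magnetization(records.w_post, w_binning, records.L)
    im = (records.m_post.astype(np.int64) + 4) // 2
    nw = int(iw.max()) + 1
    flat = (ia * nw + iw) * 5 + im
    counts = np.bincount(flat, minlength=2 * nw * 5).reshape(2 * nw, 5)
    cond = 0.0
    for cell in counts:
        nc = cell.sum()
        if nc > 0:
            cond += (nc / n) * entropy_bits(cell, miller_madow)
    return -cond
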