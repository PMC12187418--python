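"""Brute-force enumeration oracle for tiny lattices (L <= 4).

Enumerates the full Boltzmann distribution p(sigma) ~ exp(beta*J*M(sigma)),
where M(sigma) = sum over links of sigma_i sigma_j with each link counted
once, builds the exact single-spin-flip transition matrix (L <= 3), the
exact distribution of perception-action events, and exact values of all
intrinsic-utility measures.  Everything here is ground truth for the
sampling-based estimators elsewhere in the package.

Configurations are indexed by L^2-bit integers, bit order row-major to
match the simulator's coordinates; bit b of index i is site (b // L, b % L),
with bit value 1 meaning spin +1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .lattice import flip_probability

__all__ = [
    "ExactModel",
    "ExactMeasures",
    "enumerate_boltzmann",
    "transition_matrix",
    "stationary_distribution",
    "exact_event_distribution",
    "ExactEventDistribution",
    "exact_measures",
    "fisher_from_kl",
]

_MAX_ENUM_L = 4
_MAX_MATRIX_L = 3


def _spin_table(L: int) -> np.ndarray:
    """(2^(L^2), L, L) int8 array of all configurations."""
    N = L * L
    idx = np.arange(1 << N, dtype=np.int64)
    bits = (idx[:, None] >> np.arange(N)) & 1
    return (2 * bits - 1).astype(np.int8).reshape(-1, L, L)


def _link_sum(spins: np.ndarray) -> np.ndarray:
    """M(sigma): per-configuration sum over links (each counted once).

    For L = 2 the periodic wrap makes each physical pair adjacent twice; the
    roll-based sum keeps that multiplicity, which is exactly what the
    4-neighbour site dynamics see.
    """
    s = spins.astype(np.int32)
    return (s * np.roll(s, -1, axis=-1)).sum(axis=(-2, -1)) + (
        s * np.roll(s, -1, axis=-2)
    ).sum(axis=(-2, -1))


@dataclass(frozen=True)
class ExactModel:
    """Exact Boltzmann equilibrium on an enumerable lattice."""

    L: int
    J: float
    beta: float
    config_probs: np.ndarray  # (2^(L^2),)
    link_sum: np.ndarray      # (2^(L^2),) int, M(sigma)

    @property
    def n_sites(self) -> int:
        return self.L * self.L

    def spins(self) -> np.ndarray:
        return _spin_table(self.L)


def enumerate_boltzmann(L: int, J: float, beta: float = 1.0) -> ExactModel:
    """Exact Boltzmann distribution over all 2^(L^2) configurations.

    Raises
    ------
    ValueError
        If L > 4 (the enumeration bound: 65,536 states at L = 4).
    """
    if L < 2:
        raise ValueError("enumeration needs L >= 2")
    if L > _MAX_ENUM_L:
        raise ValueError(f"enumeration limited to L <= {_MAX_ENUM_L}, got L={L}")
    spins = _spin_table(L)
    M = _link_sum(spins)
    logw = beta * J * M
    probs = np.exp(logw - logsumexp(logw))
    return ExactModel(L=L, J=J, beta=beta, config_probs=probs, link_sum=M)


def _site_alignments(spins: np.ndarray) -> np.ndarray:
    """(n_cfg, N) sensory category m of every site in every configuration."""
    s = spins.astype(np.int32)
    m = s * (
        np.roll(s, -1, axis=-1)
        + np.roll(s, 1, axis=-1)
        + np.roll(s, -1, axis=-2)
        + np.roll(s, 1, axis=-2)
    )
    return m.reshape(m.shape[0], -1)


def _flip_probs(m: np.ndarray, J: float, beta: float, rule: str) -> np.ndarray:
    dE = 2.0 * J * m
    if rule == "glauber":
        return 0.5 * (1.0 - np.tanh(0.5 * beta * dE))
    if rule == "metropolis":
        return np.minimum(1.0, np.exp(-beta * dE))
    raise ValueError(f"unknown dynamics rule {rule!r}")


def transition_matrix(model: ExactModel, rule: str) -> np.ndarray:
    """Exact single-site-update transition matrix over configurations.

    Row sigma, column sigma': probability of moving in one step (uniform
    site choice, then accept/reject the flip).  Limited to L <= 3 (512x512).
    """
    if model.L > _MAX_MATRIX_L:
        raise ValueError(f"transition matrix limited to L <= {_MAX_MATRIX_L}")
    L, N = model.L, model.n_sites
    n_cfg = 1 << N
    spins = model.spins()
    m = _site_alignments(spins)
    pf = _flip_probs(m, model.J, model.beta, rule)  # (n_cfg, N)
    P = np.zeros((n_cfg, n_cfg))
    idx = np.arange(n_cfg)
    for k in range(N):
        targets = idx ^ (1 << k)
        P[idx, targets] += pf[:, k] / N
    P[idx, idx] += 1.0 - pf.sum(axis=1) / N
    return P


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a stochastic matrix (left eigenvector)."""
    vals, vecs = np.linalg.eig(P.T)
    i = np.argmin(np.abs(vals - 1.0))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


class ExactEventDistribution:
    """Exact joint law of one perception-action event at equilibrium.

    An event: draw a configuration from the Boltzmann distribution, a site
    uniformly, then the action from the flip probability.  The joint over
    (m_pre, a, s_pre, w_pre) is stored as a dense table ``A`` indexed by
    [m_index, a_index, w_index, spin_index]; post-action variables follow
    deterministically (m_post = a*m_pre, w_post from the flipped spin).
    """

    def __init__(self, A: np.ndarray, L: int):
        self.A = A
        self.L = L
        self.N = L * L

    def marginal_m_pre(self) -> np.ndarray:
        """p(m_pre) over the alphabet (-4, -2, 0, 2, 4)."""
        return self.A.sum(axis=(1, 2, 3))

    def p_flip(self) -> float:
        return float(self.A[:, 0].sum())

    def joint_pre_post(self) -> np.ndarray:
        """5x5 joint p(m_pre, m_post)."""
        J2 = np.zeros((5, 5))
        by_m = self.A.sum(axis=(2, 3))  # (m, a)
        for im in range(5):
            J2[im, 4 - im] += by_m[im, 0]  # flip: m -> -m
            J2[im, im] += by_m[im, 1]      # no-flip
        return J2

    def joint_a_wpost_mpost(self) -> np.ndarray:
        """(2, N+1, 5) joint p(a, w_post, m_post) on exact w values."""
        N = self.N
        B = np.zeros((2, N + 1, 5))
        for iw in range(N + 1):
            for ispin in range(2):
                # flip: ssum' = ssum - 2*s  ->  iw' = iw - s
                s = 2 * ispin - 1
                iw_post = iw - s
                if 0 <= iw_post <= N:
                    B[0, iw_post, ::-1] += self.A[:, 0, iw, ispin]
                B[1, iw, :] += self.A[:, 1, iw, ispin]
        return B

    def marginal_w_pre(self) -> np.ndarray:
        """p(w_pre) over the N+1 exact magnetization levels."""
        return self.A.sum(axis=(0, 1, 3))

    def table(self) -> pd.DataFrame:
        """Long-format table (m_pre, a, m_post, w_pre, w_post, p)."""
        rows = []
        N = self.N
        for im, ia, iw, ispin in zip(*np.nonzero(self.A)):
            m = 2 * im - 4
            a = -1 if ia == 0 else 1
            s = 2 * ispin - 1
            ssum = 2 * iw - N
            ssum_post = ssum - 2 * s if a == -1 else ssum
            rows.append(
                {
                    "m_pre": m,
                    "a": a,
                    "m_post": a * m,
                    "w_pre": ssum / N,
                    "w_post": ssum_post / N,
                    "p": self.A[im, ia, iw, ispin],
                }
            )
        df = pd.DataFrame(rows)
        return df.groupby(["m_pre", "a", "m_post", "w_pre", "w_post"], as_index=False)["p"].sum()


def exact_event_distribution(model: ExactModel, rule: str) -> ExactEventDistribution:
    """Exact counterpart of the simulator's event sampling."""
    spins = model.spins()
    n_cfg = spins.shape[0]
    N = model.n_sites
    m = _site_alignments(spins)                       # (n_cfg, N)
    pf = _flip_probs(m, model.J, model.beta, rule)
    s_flat = spins.reshape(n_cfg, N).astype(np.int32)
    ssum = s_flat.sum(axis=1)

    im = (m + 4) // 2
    iw = np.broadcast_to(((ssum + N) // 2)[:, None], (n_cfg, N))
    ispin = (s_flat + 1) // 2
    base_w = model.config_probs[:, None] / N

    A = np.zeros((5, 2, N + 1, 2))
    np.add.at(A, (im, 0, iw, ispin), base_w * pf)
    np.add.at(A, (im, 1, iw, ispin), base_w * (1.0 - pf))
    return ExactEventDistribution(A, model.L)


def _entropy(p: np.ndarray, base: float = 2.0) -> float:
    p = np.asarray(p, dtype=float).ravel()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(base))


@dataclass(frozen=True)
class ExactMeasures:
    """Exact intrinsic-utility values on an enumerable lattice."""

    pi_bits: float
    diversity_bits: float
    unpredictability_bits: float
    empowerment_bits: float
    neg_free_energy_bits: float
    entropy_per_site_nats: float
    kikuchi_per_site_nats: float
    fisher_per_site: float


def _exact_kikuchi(model: ExactModel) -> float:
    """Kikuchi entropy S4 - 2*S2 + S1 per site from exact marginals (nats)."""
    spins = model.spins()
    n_cfg = spins.shape[0]
    N = model.n_sites
    b = ((spins + 1) // 2).astype(np.int64)
    right = np.roll(b, -1, axis=-1)
    down = np.roll(b, -1, axis=-2)
    diag = np.roll(down, -1, axis=-1)
    code4 = (b + 2 * right + 4 * down + 8 * diag).reshape(n_cfg, N)
    w_site = np.repeat(model.config_probs / N, N)
    P4 = np.bincount(code4.ravel(), weights=w_site, minlength=16)
    pair_codes = np.concatenate(
        [(b + 2 * right).reshape(n_cfg, N), (b + 2 * down).reshape(n_cfg, N)], axis=1
    )
    P2 = np.bincount(pair_codes.ravel(), weights=np.repeat(model.config_probs / (2 * N), 2 * N), minlength=4)
    P1 = np.bincount(b.reshape(n_cfg, N).ravel(), weights=w_site, minlength=2)
    S4 = _entropy(P4, base=np.e)
    S2 = _entropy(P2, base=np.e)
    S1 = _entropy(P1, base=np.e)
    return S4 - 2 * S2 + S1


def exact_measures(model: ExactModel, rule: str) -> ExactMeasures:
    """Exact PI, average empowerment, -F-bar, entropies, Fisher information.

    PI, empowerment and -F-bar are in bits (matching the reporting
    convention); configuration entropies are per site in nats; Fisher
    information is beta^2 * Var(M) / L^2.
    """
    ev = exact_event_distribution(model, rule)
    p_m = ev.marginal_m_pre()

    J2 = ev.joint_pre_post()
    diversity = _entropy(J2.sum(axis=0))
    h_joint = _entropy(J2)
    h_pre = _entropy(J2.sum(axis=1))
    unpredictability = h_joint - h_pre
    pi = diversity - unpredictability

    empowerment = 1.0 - float(p_m[2])  # m = 0 has alphabet index 2

    B = ev.joint_a_wpost_mpost()  # (a, w_post, m_post)
    cond = 0.0
    for ia in range(2):
        for iw in range(B.shape[1]):
            cell = B[ia, iw]
            pc = cell.sum()
            if pc > 0:
                cond += pc * _entropy(cell / pc)
    neg_f = -cond

    S = _entropy(model.config_probs, base=np.e) / model.n_sites
    M = model.link_sum.astype(float)
    var_M = float((model.config_probs * M**2).sum() - (model.config_probs * M).sum() ** 2)
    fisher = model.beta**2 * var_M / model.n_sites

    return ExactMeasures(
        pi_bits=pi,
        diversity_bits=diversity,
        unpredictability_bits=unpredictability,
        empowerment_bits=empowerment,
        neg_free_energy_bits=neg_f,
        entropy_per_site_nats=S,
        kikuchi_per_site_nats=_exact_kikuchi(model),
        fisher_per_site=fisher,
    )


def fisher_from_kl(L: int, J: float, beta: float = 1.0, step: float = 1e-3) -> float:
    """Fisher information per site via symmetric KL finite differences.

    Uses [KL(p_J || p_{J+h}) + KL(p_J || p_{J-h})] / h^2 -> I(J) + O(h^2),
    an independent cross-check of the exponential-family variance identity.
    """
    p0 = enumerate_boltzmann(L, J, beta).config_probs
    kl = 0.0
    for h in (step, -step):
        ph = enumerate_boltzmann(L, J + h, beta).config_probs
        kl += float((p0 * (np.log(p0) - np.log(ph))).sum())
    return kl / step**2 / (L * L)
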