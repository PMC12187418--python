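"""Coupling sweeps: replicated simulations, aggregation, finite-size analysis.

A sweep holds the coupling J fixed per run, simulates ``replicates``
independent chains per (rule, L, J), computes the requested intrinsic
utilities from each chain, and aggregates means and standard errors across
replicates.  Fisher information is additionally measured on a sparse
high-J extension grid so the generalized-work integral can run to the
zero-response point J*.

Replicate seeds derive from the base seed by a fixed rule
(``SeedSequence([base_seed, L, rule_code, round(J * 1e6), replicate])``),
so replicates are independent, individually reproducible, and
order-independent to aggregate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import measures as im
from . import thermo
from .analytic import onsager_critical_coupling
from .lattice import DynamicsSpec, SampleSet, simulate

__all__ = [
    "SweepConfig",
    "SweepResult",
    "replicate_seed",
    "compute_measures",
    "run_sweep",
    "finite_size_analysis",
    "DEFAULT_MEASURES",
    "DESK_J_GRID",
]

DEFAULT_MEASURES = ("pi", "empowerment", "neg_free_energy", "entropy", "fisher")

#: Desk-scale default grid: J = 0.05 ... 1.00 in steps of 0.05.
DESK_J_GRID = tuple(np.round(np.arange(1, 21) * 0.05, 10))

#: Sparse high-J grid on which only Fisher information is measured, so the
#: work integral covers [J, J*]; the lattice is essentially frozen there.
DEFAULT_FISHER_EXTENSION = (1.25, 1.5, 2.0, 3.0, 5.0, 7.0, 10.0)

_RULE_CODES = {"glauber": 0, "metropolis": 1}


@dataclass(frozen=True)
class SweepConfig:
    """Full specification of a sweep; with the base seed it determines every output.

    ``L`` may be a single side length or a list (finite-size mode).  ``init``
    is "random", "all-up" or "auto" (all-up above the critical coupling,
    random below: ordered-phase runs then skip the slow coarsening
    transient).
    """

    J_grid: tuple[float, ...] = DESK_J_GRID
    L: int | tuple[int, ...] = 16
    rules: tuple[str, ...] = ("glauber", "metropolis")
    beta: float = 1.0
    n_steps: int = 2_000_000
    burn_in: int | None = None
    snapshot_interval: int | None = None
    replicates: int = 10
    base_seed: int = 0
    Jstar: float = thermo.DEFAULT_JSTAR
    w_binning: str | int = "auto"
    measures: tuple[str, ...] = DEFAULT_MEASURES
    init: str = "auto"
    fisher_extension: tuple[float, ...] = DEFAULT_FISHER_EXTENSION
    extension_n_steps: int | None = None     # default: n_steps // 4
    extension_replicates: int | None = None  # default: min(replicates, 4)
    smooth: int | None = None                # entropy-derivative smoothing window

    def __post_init__(self) -> None:
        g = np.asarray(self.J_grid, dtype=float)
        if len(g) == 0 or np.any(np.diff(g) <= 0):
            raise ValueError("J_grid must be non-empty and strictly ascending")
        if g[0] <= 0 or g[-1] > self.Jstar:
            raise ValueError("J_grid must lie in (0, Jstar]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        unknown = set(self.measures) - set(DEFAULT_MEASURES)
        if unknown:
            raise ValueError(f"unknown measures: {sorted(unknown)}")
        for r in self.rules:
            if r not in _RULE_CODES:
                raise ValueError(f"unknown dynamics rule {r!r}")

    @property
    def L_list(self) -> tuple[int, ...]:
        return (self.L,) if isinstance(self.L, int) else tuple(self.L)

    def to_dict(self) -> dict:
        return asdict(self)


def replicate_seed(base_seed: int, L: int, rule: str, J: float, replicate: int) -> int:
    """Derived seed for one replicate; documented, grid-order independent."""
    ss = np.random.SeedSequence(
        [int(base_seed), int(L), _RULE_CODES[rule], int(round(J * 1e6)), int(replicate)]
    )
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def _init_mode(config: SweepConfig, J: float) -> str:
    if config.init != "auto":
        return config.init
    return "all-up" if J > onsager_critical_coupling(config.beta).Jc else "random"


def compute_measures(ss: SampleSet, names: Iterable[str], w_binning="auto") -> dict[str, float]:
    """Requested intrinsic utilities from one simulated chain."""
    out: dict[str, float] = {}
    for name in names:
        if name == "pi":
            out[name] = im.predictive_information(ss).pi_bits
        elif name == "empowerment":
            out[name] = im.average_empowerment(ss)
        elif name == "neg_free_energy":
            out[name] = im.negative_free_energy(ss, w_binning=w_binning)
        elif name == "entropy":
            out[name] = thermo.kikuchi_entropy(ss.snapshots).S
        elif name == "fisher":
            out[name] = thermo.fisher_information(ss.snapshots, J=ss.spec.J, beta=ss.spec.beta)
        else:
            raise ValueError(f"unknown measure {name!r}")
    return out


def _aggregate(long: pd.DataFrame) -> pd.DataFrame:
    g = long.groupby(["measure", "rule", "L", "J"], as_index=False)["value"]
    agg = g.agg(mean="mean", std=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0, n="count")
    agg["stderr"] = agg["std"] / np.sqrt(agg["n"])
    return agg.drop(columns="std")


@dataclass
class SweepResult:
    """Long-format per-replicate values plus the replicate-aggregated table."""

    config: SweepConfig
    long: pd.DataFrame        # measure, rule, L, J, replicate, value, n_events
    aggregated: pd.DataFrame  # measure, rule, L, J, mean, stderr, n

    def values(self, measure: str, rule: str, L: int) -> pd.DataFrame:
        sel = self.aggregated.query("measure == @measure and rule == @rule and L == @L")
        return sel.sort_values("J").reset_index(drop=True)

    def entropy_curve(self, rule: str, L: int) -> thermo.EntropyCurve:
        t = self.values("entropy", rule, L)
        main = t[t["J"].round(9).isin(np.round(self.config.J_grid, 9))]
        return thermo.EntropyCurve(
            main["J"].to_numpy(), main["mean"].to_numpy(), main["stderr"].to_numpy()
        )

    def fisher_curve(self, rule: str, L: int) -> thermo.FisherCurve:
        t = self.values("fisher", rule, L)
        return thermo.FisherCurve(
            t["J"].to_numpy(), np.maximum(t["mean"].to_numpy(), 0.0), t["stderr"].to_numpy()
        )

    def efficiency_curve(self, rule: str, L: int) -> thermo.EfficiencyCurve:
        return thermo.efficiency(
            self.entropy_curve(rule, L),
            self.fisher_curve(rule, L),
            Jstar=self.config.Jstar,
            smooth=self.config.smooth,
        )

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.long.to_csv(out / "long.csv", index=False)
        self.aggregated.to_csv(out / "aggregated.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.config.to_dict(), fh, indent=2)


def _run_point(
    config: SweepConfig, rule: str, L: int, J: float, replicate: int,
    n_steps: int, names: tuple[str, ...],
) -> list[dict]:
    seed = replicate_seed(config.base_seed, L, rule, J, replicate)
    spec = DynamicsSpec(
        rule=rule,
        J=J,
        beta=config.beta,
        seed=seed,
        burn_in=config.burn_in,
        n_steps=n_steps,
        snapshot_interval=config.snapshot_interval,
    )
    ss = simulate(spec, L, init=_init_mode(config, J))
    vals = compute_measures(ss, names, w_binning=config.w_binning)
    return [
        {
            "measure": name,
            "rule": rule,
            "L": L,
            "J": J,
            "replicate": replicate,
            "value": value,
            "n_events": len(ss),
        }
        for name, value in vals.items()
    ]


def run_sweep(config: SweepConfig, progress: bool = False) -> SweepResult:
    """Run the full sweep and aggregate across replicates.

    Fully reproducible from ``config`` alone; replicates share no state.
    """
    rows: list[dict] = []
    ext_steps = config.extension_n_steps or max(1, config.n_steps // 4)
    ext_reps = config.extension_replicates or min(config.replicates, 4)
    need_ext = "fisher" in config.measures and config.fisher_extension
    for rule in config.rules:
        for L in config.L_list:
            for J in config.J_grid:
                for r in range(config.replicates):
                    if progress:  # pragma: no cover - cosmetic
                        print(f"[sweep] rule={rule} L={L} J={J:g} replicate={r}", flush=True)
                    rows.extend(_run_point(config, rule, L, float(J), r, config.n_steps, config.measures))
            if need_ext:
                for J in config.fisher_extension:
                    if J <= config.J_grid[-1]:
                        continue
                    for r in range(ext_reps):
                        rows.extend(
                            _run_point(config, rule, L, float(J), r, ext_steps, ("fisher",))
                        )
    long = pd.DataFrame(rows)
    return SweepResult(config=config, long=long, aggregated=_aggregate(long))


def _curve_from_long(long: pd.DataFrame, config: SweepConfig, rule: str, L: int,
                     drop_replicate: int | None = None) -> thermo.EfficiencyCurve:
    sub = long[(long["rule"] == rule) & (long["L"] == L)]
    if drop_replicate is not None:
        sub = sub[sub["replicate"] != drop_replicate]
    agg = _aggregate(sub)
    res = SweepResult(config=config, long=sub, aggregated=agg)
    return res.efficiency_curve(rule, L)


def finite_size_analysis(result: SweepResult) -> pd.DataFrame:
    """Efficiency-peak location per lattice size, with jackknife errors.

    Requires a sweep run with >= 2 lattice sizes.  Returns one row per
    (rule, L) with the peak J of the efficiency curve, a leave-one-
    replicate-out jackknife standard error, and the critical coupling for
    reference; rows are sorted by L so the expected finite-size trend (peak
    approaching Jc from above as L grows) is visible directly.
    """
    sizes = result.config.L_list
    if len(sizes) < 2:
        raise ValueError("finite-size analysis needs at least 2 lattice sizes")
    Jc = onsager_critical_coupling(result.config.beta).Jc
    rows = []
    for rule in result.config.rules:
        for L in sizes:
            peak = thermo.peak_location(result.efficiency_curve(rule, L))
            reps = sorted(
                result.long.query("rule == @rule and L == @L")["replicate"].unique()
            )
            jk = []
            if len(reps) > 1:
                for r in reps:
                    jk.append(
                        thermo.peak_location(
                            _curve_from_long(result.long, result.config, rule, L, drop_replicate=r)
                        )
                    )
                jk = np.asarray(jk)
                se = float(np.sqrt((len(jk) - 1) / len(jk) * ((jk - jk.mean()) ** 2).sum()))
            else:
                se = float("nan")
            rows.append(
                {"rule": rule, "L": L, "peak_J": peak, "peak_stderr": se, "Jc": Jc,
                 "excess": peak - Jc}
            )
    return pd.DataFrame(rows).sort_values(["rule", "L"]).reset_index(drop=True)
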