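"""Uniform design, batch execution, and main-effect sensitivity analysis.

The sensitivity pipeline mirrors standard computer-experiment practice:

1. a space-filling *uniform design* over the 8-dimensional NF1 factor box —
   a Latin hypercube optimized for centered-L2 discrepancy (200 runs by
   default);
2. batch simulation of the design (rows are independent; failed rows are
   flagged, never dropped silently);
3. a Gaussian-process surrogate per response and day
   (:mod:`callus.surrogate`);
4. *main effects*: first-order Sobol variance shares of the surrogate's
   posterior-mean function, estimated by a seeded pick-freeze Monte-Carlo
   scheme, with the factors explaining at least 10% of the response variance
   reported; plus marginal model profiles (the prediction as a function of
   one factor, averaged over the others).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .driver import FACTOR_NAMES, Scenario, nf1_ranges, run_simulation
from .surrogate import GPSurrogate


@dataclass
class DesignMatrix:
    """An n_runs x d factor table with its ranges and discrepancy score."""

    values: np.ndarray
    factor_names: tuple
    ranges: np.ndarray         # (d, 2)
    seed: int
    discrepancy: float

    @property
    def n_runs(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.factor_names))


@dataclass
class MainEffects:
    """Per-factor first-order variance shares (percent)."""

    shares: dict               # factor -> share in %
    dominant: list = field(default_factory=list)  # factors with share >= 10%
    total_variance: float = 0.0

    @classmethod
    def from_shares(cls, shares: dict, total_variance: float,
                    threshold: float = 10.0) -> "MainEffects":
        dominant = sorted((f for f, s in shares.items() if s >= threshold),
                          key=lambda f: -shares[f])
        return cls(shares=shares, dominant=dominant, total_variance=total_variance)


def _ranges_array(ranges) -> tuple:
    if isinstance(ranges, dict):
        names = tuple(ranges)
        arr = np.array([ranges[k] for k in names], float)
    else:
        arr = np.asarray(ranges, float)
        names = tuple(f"x{i+1}" for i in range(len(arr)))
    return names, arr


def uniform_design(n_runs: int = 200, ranges=None, seed: int = 0) -> DesignMatrix:
    """Centered-L2-discrepancy-optimized Latin hypercube over the factor box.

    Defaults to 200 runs over the NF1 ranges.  Degenerate ranges (lo == hi)
    are held constant with a warning.  Deterministic per seed.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if ranges is None:
        ranges = nf1_ranges()
    names, arr = _ranges_array(ranges)
    d = len(arr)
    degenerate = arr[:, 0] == arr[:, 1]
    for i in np.where(degenerate)[0]:
        warnings.warn(f"factor {names[i]} has a degenerate range; held constant")
    sampler = qmc.LatinHypercube(d=d, optimization="random-cd", seed=seed)
    unit = sampler.random(n_runs)
    disc = float(qmc.discrepancy(unit, method="CD"))
    values = qmc.scale(unit, arr[:, 0], np.where(degenerate, arr[:, 0] + 1.0,
                                                 arr[:, 1]))
    values[:, degenerate] = arr[degenerate, 0]
    return DesignMatrix(values=values, factor_names=names, ranges=arr,
                        seed=seed, discrepancy=disc)


def run_design(design: DesignMatrix, domain=None, params=None, seed: int = 0,
               horizon: float = 49.0, snapshot_days=(7, 21, 35, 49),
               sim_config=None, n_jobs: int = 1) -> pd.DataFrame:
    """Simulate every design row and tabulate the responses.

    One row of the returned table per (run, snapshot day), with the seven
    responses, the eight factors and a ``failed`` flag carrying the failure
    cause for rows whose simulation did not complete.  Row seeds are spawned
    deterministically from ``seed``.
    """
    from joblib import Parallel, delayed

    from .geometry import build_domain
    from .responses import response_table

    if domain is None:
        domain = build_domain()
    row_seeds = np.random.SeedSequence(seed).generate_state(design.n_runs) % (2 ** 31)

    def one(run_id):
        factors = dict(zip(FACTOR_NAMES, design.values[run_id]))
        scenario = Scenario(factors, label=f"run{run_id}")
        try:
            res = run_simulation(scenario, domain, params, seed=int(row_seeds[run_id]),
                                 horizon=horizon, snapshot_days=snapshot_days,
                                 sim_config=sim_config)
            tab = response_table(res, domain, params)
            tab["run_id"] = run_id
            tab["failed"] = ""
            return tab
        except Exception as exc:  # noqa: BLE001 - cause recorded, batch continues
            rows = [{"run_id": run_id, "day": day, "failed": repr(exc),
                     **dict(zip(FACTOR_NAMES, design.values[run_id]))}
                    for day in snapshot_days]
            return pd.DataFrame(rows)

    parts = Parallel(n_jobs=n_jobs)(delayed(one)(i) for i in range(design.n_runs))
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# sensitivity
# ---------------------------------------------------------------------------


def _predictor(gp_or_fn, ranges: np.ndarray):
    if callable(gp_or_fn) and not isinstance(gp_or_fn, GPSurrogate):
        return gp_or_fn
    return lambda X: gp_or_fn.predict(X)


def _sample_box(rng: np.random.Generator, n: int, ranges: np.ndarray) -> np.ndarray:
    lo, hi = ranges[:, 0], ranges[:, 1]
    return lo + rng.random((n, len(ranges))) * (hi - lo)


def main_effects(gp_or_fn, ranges=None, n_mc: int = 2 ** 13, seed: int = 0,
                 threshold: float = 10.0) -> MainEffects:
    """First-order Sobol variance shares of a prediction function.

    ``gp_or_fn`` is a fitted :class:`GPSurrogate` (its posterior mean is
    analysed) or any callable mapping an (n, d) array to n values.  Shares
    use the pick-freeze scheme with the centered (Janon) estimator over a
    scrambled-Sobol quasi-Monte-Carlo block pair A, B of ``n_mc`` points in
    the factor box; negative estimates are clipped at zero.  Returns percent
    shares and the descending list of factors at or above ``threshold``.
    """
    import warnings as _warnings

    if ranges is None:
        if isinstance(gp_or_fn, GPSurrogate):
            ranges = gp_or_fn.ranges_
        else:
            raise ValueError("ranges required for a bare callable")
    names, arr = _ranges_array(ranges)
    f = _predictor(gp_or_fn, arr)
    d = len(arr)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", UserWarning)  # non power-of-two n_mc
        U = qmc.Sobol(2 * d, scramble=True, seed=seed).random(n_mc)
    lo, span = arr[:, 0], arr[:, 1] - arr[:, 0]
    A = lo + U[:, :d] * span
    B = lo + U[:, d:] * span
    fA = np.asarray(f(A), float)
    fB = np.asarray(f(B), float)
    V = float(np.concatenate([fA, fB]).var())
    if V <= 1e-300:
        return MainEffects.from_shares({n: 0.0 for n in names}, 0.0, threshold)
    shares = {}
    for i in range(d):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        fABi = np.asarray(f(ABi), float)
        mu = float(0.5 * (fB + fABi).mean())
        Vi_den = float(0.5 * (fB ** 2 + fABi ** 2).mean() - mu ** 2)
        Si = (float(np.mean(fB * fABi)) - mu ** 2) / Vi_den if Vi_den > 0 else 0.0
        shares[names[i]] = float(100.0 * min(max(Si, 0.0), 1.0))
    return MainEffects.from_shares(shares, V, threshold)


def marginal_profile(gp_or_fn, factor, ranges=None, grid_size: int = 25,
                     n_mc: int = 512, seed: int = 0,
                     design: np.ndarray | None = None,
                     actuals: np.ndarray | None = None) -> dict:
    """Marginal model profile for one factor.

    For each grid value of the chosen factor, the prediction is averaged over
    ``n_mc`` uniform draws of the other factors (seeded).  Optionally returns
    the raw (factor value, actual response) scatter for overlay.
    """
    if ranges is None:
        if isinstance(gp_or_fn, GPSurrogate):
            ranges = gp_or_fn.ranges_
        else:
            raise ValueError("ranges required for a bare callable")
    names, arr = _ranges_array(ranges)
    idx = factor if isinstance(factor, int) else names.index(factor)
    f = _predictor(gp_or_fn, arr)
    rng = np.random.default_rng(seed)
    base = _sample_box(rng, n_mc, arr)
    grid = np.linspace(arr[idx, 0], arr[idx, 1], grid_size)
    profile = np.empty(grid_size)
    for k, v in enumerate(grid):
        X = base.copy()
        X[:, idx] = v
        profile[k] = float(np.mean(f(X)))
    out = {"factor": names[idx], "grid": grid, "profile": profile}
    if design is not None and actuals is not None:
        out["scatter"] = (np.asarray(design, float)[:, idx],
                          np.asarray(actuals, float))
    return out


def random_design_discrepancy(n_runs: int, d: int, seeds=range(1, 101)) -> float:
    """Mean centered-L2 discrepancy of plain random designs (baseline)."""
    vals = []
    for s in seeds:
        rng = np.random.default_rng(s)
        vals.append(qmc.discrepancy(rng.random((n_runs, d)), method="CD"))
    return float(np.mean(vals))
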