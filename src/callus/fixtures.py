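"""Synthetic fixtures: tiny domains, canned tissue states, analytic surfaces.

Everything the test-suite and the sensitivity validation need without running
the full model at production scale:

* :func:`tiny_config` — a reduced-resolution simulation configuration whose
  full coupled run completes in seconds;
* :func:`tissue_pattern` — tissue states with known ground-truth responses
  (a fully bridged gap, an empty gap, a fibrous hamartoma-like non-union, a
  three-tissue mixture);
* :func:`analytic_surface` — response surfaces over the 8-factor box with
  known sensitivity structure: the Sobol g-function and the Ishigami
  function (analytic first-order indices) and ``ci_mimic``, a synthetic
  severity surface reproducing the qualitative two-class behaviour of the
  Complication Index (threshold terms in the cartilage-formation and
  endochondral-ossification factors, plus a fibroblast-invasion ramp).
"""

from __future__ import annotations

import numpy as np

from .driver import FACTOR_NAMES, nf1_ranges
from .geometry import DomainGrid, build_domain
from .tissue import ModelParams, TissueState

TINY_GEOMETRY = {
    "length": 1.0, "radius": 1.0,
    "marrow_radius": 0.25, "cortex_thickness": 0.2, "half_gap": 0.25,
    "n_z": 16, "n_r": 16,
}

TINY_SIM = {"dt": 0.25, "coupling_interval": 0.25}


def tiny_config() -> dict:
    """Reduced-resolution configuration: 16x16 domain, 21-day horizon.

    Geometry is deterministic (seed-independent); the coupled simulation on
    it completes in well under two minutes on one CPU.
    """
    return {
        "geometry": dict(TINY_GEOMETRY),
        "sim": dict(TINY_SIM),
        "horizon": 21.0,
        "snapshot_days": (7, 21),
    }


def tiny_domain() -> DomainGrid:
    return build_domain(TINY_GEOMETRY)


PATTERNS = ("bridged", "empty", "fibrous_hamartoma", "tri_tissue")


def tissue_pattern(name: str, domain: DomainGrid,
                   params: ModelParams | None = None) -> TissueState:
    """Canned tissue states with known ground-truth responses.

    * ``bridged``  — bone matrix fills every callus cell: union (γ6 = 0),
      bone fraction γ1 = 100;
    * ``empty``    — nothing anywhere: non-union, all fractions zero;
    * ``fibrous_hamartoma`` — fibrous matrix and fibroblasts saturate the
      gap: non-union with γ2 = 100, γ4 = 1;
    * ``tri_tissue`` — all three matrices present in every gap cell:
      γ1 = γ2 = γ3 = 100/3 under equal weighting.
    """
    p = params or ModelParams()
    state = TissueState.zeros(domain)
    callus = domain.callus_mask
    gap = domain.gap_mask
    if name == "bridged":
        state.m_b[callus] = p.m_max
    elif name == "empty":
        pass
    elif name == "fibrous_hamartoma":
        state.m_f[gap] = p.m_max
        state.c_f[gap] = p.cap
    elif name == "tri_tissue":
        third = p.m_max / 3.0
        state.m_f[gap] = third
        state.m_c[gap] = third
        state.m_b[gap] = third
    else:
        raise ValueError(f"unknown pattern {name!r}; valid: {PATTERNS}")
    return state


# ---------------------------------------------------------------------------
# analytic response surfaces
# ---------------------------------------------------------------------------


def g_function_indices(a: np.ndarray) -> np.ndarray:
    """Analytic first-order Sobol indices of the Sobol g-function."""
    a = np.asarray(a, float)
    vi = 1.0 / (3.0 * (1.0 + a) ** 2)
    V = np.prod(1.0 + vi) - 1.0
    return vi / V


def sobol_g_function(a: np.ndarray):
    """The Sobol g-function on the unit box: prod_i (|4x_i-2|+a_i)/(1+a_i)."""
    a = np.asarray(a, float)

    def f(X):
        X = np.atleast_2d(np.asarray(X, float))
        return np.prod((np.abs(4.0 * X - 2.0) + a) / (1.0 + a), axis=1)

    return f


def ishigami_indices(a: float = 7.0, b: float = 0.1) -> np.ndarray:
    """Analytic first-order Sobol indices of the Ishigami function."""
    V1 = 0.5 * (1.0 + b * np.pi ** 4 / 5.0) ** 2
    V2 = a ** 2 / 8.0
    V3 = 0.0
    V = a ** 2 / 8.0 + b * np.pi ** 4 / 5.0 + b ** 2 * np.pi ** 8 / 18.0 + 0.5
    return np.array([V1 / V, V2 / V, V3 / V])


def ishigami(a: float = 7.0, b: float = 0.1):
    """Ishigami function on [-pi, pi]^3."""

    def f(X):
        X = np.atleast_2d(np.asarray(X, float))
        return (np.sin(X[:, 0]) + a * np.sin(X[:, 1]) ** 2
                + b * X[:, 2] ** 4 * np.sin(X[:, 0]))

    return f


CI_MIMIC_WEIGHTS = (0.35, 0.35, 0.3)  # threshold, threshold, invasion ramp


def ci_mimic(ranges: dict | None = None, smooth_amp: float = 0.03):
    """Synthetic Complication-Index surface over the NF1 factor box.

    High severity is triggered by low cartilage formation (P_mc < 0.05) or
    low endochondral ossification (Y_3cb < 200), with a fibroblast-invasion
    ramp saturating at c_f_BC = 10 and a small smooth background; clipped to
    [0, 1].  The two threshold factors dominate the variance, mirroring the
    two-class severity behaviour of the mechanistic model.
    """
    rng_map = ranges or nf1_ranges()
    names = tuple(rng_map)
    i_cfbc = names.index("c_f_BC")
    i_y3 = names.index("Y_3cb")
    i_pmc = names.index("P_mc")
    w1, w2, w3 = CI_MIMIC_WEIGHTS

    def f(X):
        X = np.atleast_2d(np.asarray(X, float))
        out = (w1 * (X[:, i_pmc] < 0.05)
               + w2 * (X[:, i_y3] < 200.0)
               + w3 * np.minimum(X[:, i_cfbc], 10.0) / 10.0)
        if smooth_amp:
            lo = np.array([rng_map[n][0] for n in names])
            hi = np.array([rng_map[n][1] for n in names])
            U = (X - lo) / np.where(hi > lo, hi - lo, 1.0)
            out = out + smooth_amp * np.sin(2 * np.pi * U).sum(axis=1) / len(names)
        return np.clip(out, 0.0, 1.0)

    return f


SURFACES = ("g_function", "ishigami", "ci_mimic")


def analytic_surface(name: str, ranges=None, **kwargs):
    """(callable, ranges, analytic first-order indices or None)."""
    if name == "g_function":
        a = np.asarray(kwargs.get("a", (0.0, 1.0, 4.5, 9.0, 99.0, 99.0, 99.0, 99.0)))
        rng = np.repeat([[0.0, 1.0]], len(a), axis=0)
        return sobol_g_function(a), rng, g_function_indices(a)
    if name == "ishigami":
        rng = np.repeat([[-np.pi, np.pi]], 3, axis=0)
        return ishigami(**kwargs), rng, ishigami_indices(**kwargs)
    if name == "ci_mimic":
        rng_map = ranges or nf1_ranges()
        return ci_mimic(rng_map, **kwargs), rng_map, None
    raise ValueError(f"unknown surface {name!r}; valid: {SURFACES}")


def random_bone_grid(domain: DomainGrid, rng: np.random.Generator,
                     p_fill: float = 0.5) -> np.ndarray:
    """Random bone-presence grid on the callus cells (non-union test oracle
    fixtures)."""
    bone = rng.random((domain.n_z, domain.n_r)) < p_fill
    bone &= domain.callus_mask
    return bone
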