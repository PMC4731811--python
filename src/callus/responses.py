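"""Response extraction: tissue fractions, non-union, Complication Index.

The healing outcome of a run is summarized per snapshot day by seven
responses evaluated over the fracture-gap area:

* γ1/γ2/γ3 — bone / fibrous / cartilage tissue (area) fractions in percent.
  Matrix fields are first binarized with tissue-specific thresholds; a gap
  cell containing k tissues contributes area/k to each (equal weighting), so
  the three fractions sum to at most 100%.
* γ4/γ5 — the bulk amounts of fibrous tissue and of fibroblasts, gap means
  normalized to [0, 1] by the matrix saturation and the carrying capacity.
* γ6 — the non-union indicator: 0 (bony union) iff a connected path of
  bone-positive cells bridges from the cortical end face to the fracture
  mid-plane through the callus, else 1.
* γ7 — the Complication Index (CI), a severity score on [0, 1] combining
  γ4, γ5 and γ6.  The combination rule is configurable; the shipped default
  is their arithmetic mean, which keeps the intended bounds (0 for an
  uncomplicated union, 1 for a fully fibrotic non-union) and monotonicity
  in each input.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import CALLUS_CODES, DomainGrid
from .tissue import ModelParams, TissueState

TISSUES = ("bone", "fibrous", "cartilage")
_MATRIX_OF = {"bone": "m_b", "fibrous": "m_f", "cartilage": "m_c"}

DEFAULT_THRESHOLDS = {"bone": 0.1, "fibrous": 0.1, "cartilage": 0.1}

GAMMA_COLUMNS = [f"gamma{i}" for i in range(1, 8)]


def binarize(state: TissueState, thresholds: dict | None = None) -> dict:
    """Per-tissue presence grids: present iff matrix density >= threshold
    (inclusive)."""
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    if any(v < 0 for v in thr.values()):
        raise ValueError("thresholds must be non-negative")
    return {t: getattr(state, _MATRIX_OF[t]) >= thr[t] for t in TISSUES}


def tissue_fractions(binary: dict, gap_mask: np.ndarray) -> tuple:
    """(γ1, γ2, γ3): equal-weight area fractions in the gap, in percent.

    A gap cell containing k >= 1 tissues contributes 1/k of its area to each
    present tissue; empty cells contribute to none.
    """
    if not np.any(gap_mask):
        raise ValueError("gap region is empty")
    present = np.stack([binary[t] & gap_mask for t in TISSUES])
    k = present.sum(axis=0)
    weight = np.zeros(k.shape, dtype=float)
    nonzero = k > 0
    weight[nonzero] = 1.0 / k[nonzero]
    total = float(gap_mask.sum())
    fractions = tuple(100.0 * float((present[i] * weight).sum()) / total
                      for i in range(3))
    return fractions  # (bone, fibrous, cartilage)


def amounts(state: TissueState, gap_mask: np.ndarray,
            params: ModelParams | None = None) -> tuple:
    """(γ4, γ5): gap-mean fibrous matrix and fibroblast density, each
    normalized to [0, 1]."""
    p = params or ModelParams()
    if not np.any(gap_mask):
        raise ValueError("gap region is empty")
    g4 = float(np.clip(state.m_f[gap_mask].mean() / p.m_max, 0.0, 1.0))
    g5 = float(np.clip(state.c_f[gap_mask].mean() / p.cap, 0.0, 1.0))
    return g4, g5


def detect_nonunion(bone_binary: np.ndarray, domain: DomainGrid,
                    connectivity: int = 4) -> int:
    """γ6: 0 for bony union, 1 for non-union.

    Union requires a connected path of bone-positive callus/gap cells linking
    the cortical end face (the cells axially adjacent to the cortex across
    the gap) to the fracture mid-plane (the last axial cell row).  4-connected
    by default; 8-connected available in config.
    """
    callus = np.isin(domain.region, CALLUS_CODES)
    bone = np.asarray(bone_binary, bool) & callus
    if not bone.any():
        return 1
    structure = (np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]) if connectivity == 4
                 else np.ones((3, 3), int))
    labels, _ = ndimage.label(bone, structure=structure)
    # seed faces: cells just gap-ward of the cortical end face, and the
    # fracture mid-plane row
    iz_end = int(np.searchsorted(domain.z_centers, domain.cortical_end_z))
    iz_end = min(iz_end, domain.n_z - 1)
    start_labels = set(labels[iz_end, :][labels[iz_end, :] > 0])
    plane_labels = set(labels[-1, :][labels[-1, :] > 0])
    return 0 if (start_labels & plane_labels) else 1


def complication_index(g4: float, g5: float, g6: int,
                       method: str = "mean") -> float:
    """γ7: the Complication Index on [0, 1].

    Combines the fibrous-tissue amount, the fibroblast amount and the
    non-union indicator into one severity score: 0 for uncomplicated bony
    union with no fibrosis, 1 for a fully fibrotic non-union.  ``method``
    'mean' (default) is the arithmetic mean of the three inputs.
    """
    if not (0 <= g4 <= 1 and 0 <= g5 <= 1):
        raise ValueError("g4 and g5 must lie in [0, 1]")
    if g6 not in (0, 1):
        raise ValueError("g6 must be 0 or 1")
    if method == "mean":
        return (g4 + g5 + g6) / 3.0
    raise ValueError(f"unknown CI method: {method}")


def responses_for_state(state: TissueState, domain: DomainGrid,
                        params: ModelParams | None = None,
                        thresholds: dict | None = None,
                        connectivity: int = 4,
                        ci_method: str = "mean") -> dict:
    """All seven responses for one tissue snapshot."""
    binary = binarize(state, thresholds)
    g1, g2, g3 = tissue_fractions(binary, domain.gap_mask)
    g4, g5 = amounts(state, domain.gap_mask, params)
    g6 = detect_nonunion(binary["bone"], domain, connectivity)
    g7 = complication_index(g4, g5, g6, ci_method)
    return dict(zip(GAMMA_COLUMNS, (g1, g2, g3, g4, g5, g6, g7)))


def response_table(results, domain: DomainGrid,
                   params: ModelParams | None = None, **kwargs) -> pd.DataFrame:
    """Per-run, per-day response table for one or more simulation results.

    Columns: run_id, day, gamma1..gamma7, plus the scenario's eight factors.
    """
    from .driver import FACTOR_NAMES

    if not isinstance(results, (list, tuple)):
        results = [results]
    rows = []
    for run_id, res in enumerate(results):
        p = (params or ModelParams()).with_factors(res.scenario.factors)
        for day in res.days:
            row = {"run_id": run_id, "day": day}
            row.update(responses_for_state(res.snapshots[day]["tissue"],
                                           domain, p, **kwargs))
            row.update({name: res.scenario.factors[name] for name in FACTOR_NAMES})
            rows.append(row)
    return pd.DataFrame(rows)


def validate_response_row(row: dict) -> None:
    """Assert the admissible-range invariants of one response row."""
    g = [row[f"gamma{i}"] for i in range(1, 8)]
    assert all(0.0 <= x <= 100.0 for x in g[:3]), "fractions outside [0, 100]"
    assert g[0] + g[1] + g[2] <= 100.0 + 1e-9, "fractions sum beyond 100%"
    assert 0.0 <= g[3] <= 1.0 and 0.0 <= g[4] <= 1.0, "amounts outside [0, 1]"
    assert g[5] in (0, 1), "non-union flag not boolean"
    assert 0.0 <= g[6] <= 1.0, "CI outside [0, 1]"
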