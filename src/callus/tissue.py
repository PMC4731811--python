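"""Ten-field taxis-reaction-diffusion tissue model of fracture repair.

The continuum layer tracks four cell densities (mesenchymal stem cells
``c_m``, fibroblasts ``c_f``, chondrocytes ``c_c``, osteoblasts ``c_b``),
three matrix densities (fibrous ``m_f``, cartilage ``m_c``, bone ``m_b``),
two growth-factor concentrations (osteochondrogenic ``g_bc``, angiogenic
``g_v``) and the oxygen tension ``n``.  All fields are non-dimensional: cell
densities scale with 10^6 cells/ml and saturate at a carrying capacity of 1;
matrix densities scale with 0.1 g/ml and their sum saturates at ``m_max``;
oxygen scales with 1% tension, with a healthy level around 1.

Model structure
---------------
* Only MSCs and fibroblasts migrate (diffusion + chemotaxis/haptotaxis);
  chondrocytes and osteoblasts are immotile, matrices do not move.
* Differentiation from the MSC pool is driven by the generic
  osteochondrogenic growth factor, routed by the local oxygen tension:
  osteogenic in a normoxic window, chondrogenic in a hypoxic window, and
  fibroblastic by default wherever neither stimulus is active.
* Matrix production saturates as the total matrix density approaches
  ``m_max``; endochondral ossification converts cartilage matrix to bone
  matrix (and chondrocytes to osteoblasts) once a critical cartilage density
  is exceeded, at a rate gated by growth factor and oxygen.
* Angiogenic growth factor is produced under hypoxia; oxygen is supplied by
  the perfused vasculature and consumed by cells.

Eight of the rate constants are the NF1 study factors (fibroblast invasion
duration ``c_f_BC``, fibroblast proliferation ``A_f0``, fibroblastic
differentiation ``F_4``, osteogenic differentiation ``Y_11``, endochondral
ossification ``Y_3cb``, cartilage formation ``P_mc``, fibrous tissue
formation ``P_mf``, angiogenic growth-factor production ``G_gvc``); the
remaining coefficients are calibration defaults exposed in config.

Numerics: operator splitting per step — explicit sub-cycled reactions,
first-order upwind taxis with a CFL-limited sub-step, and an exact
matrix-exponential diffusion propagator on the active (callus) cells (a
Crank–Nicolson solve on grids too large to exponentiate densely).  Negative
undershoots are clipped to zero with the clipped mass logged; a step aborts
if clipping exceeds a relative tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields, replace

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import DomainGrid

FIELD_NAMES = ("c_m", "c_f", "c_c", "c_b", "m_f", "m_c", "m_b", "g_bc", "g_v", "n")
MOBILE_FIELDS = {"c_m": "D_m", "c_f": "D_f", "g_bc": "D_gbc", "g_v": "D_gv", "n": "D_n"}


class NumericalError(RuntimeError):
    """A field left the admissible range beyond the clipping tolerance."""


@dataclass
class TissueState:
    """The ten continuum fields on the domain grid (arrays ``[iz, ir]``)."""

    c_m: np.ndarray
    c_f: np.ndarray
    c_c: np.ndarray
    c_b: np.ndarray
    m_f: np.ndarray
    m_c: np.ndarray
    m_b: np.ndarray
    g_bc: np.ndarray
    g_v: np.ndarray
    n: np.ndarray

    @classmethod
    def zeros(cls, domain: DomainGrid) -> "TissueState":
        shape = (domain.n_z, domain.n_r)
        return cls(**{name: np.zeros(shape) for name in FIELD_NAMES})

    def copy(self) -> "TissueState":
        return TissueState(**{name: getattr(self, name).copy() for name in FIELD_NAMES})

    def total_matrix(self) -> np.ndarray:
        return self.m_f + self.m_c + self.m_b

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in FIELD_NAMES}

    def validate(self, params: "ModelParams", tol: float = 1e-9) -> None:
        for name in FIELD_NAMES:
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise NumericalError(f"field {name} contains non-finite values")
            if arr.min() < -tol:
                raise NumericalError(f"field {name} is negative beyond tolerance")
        if self.total_matrix().max() > params.m_max + 1e-6:
            raise NumericalError("total matrix density exceeds m_max")


@dataclass
class ModelParams:
    """Rate constants of the tissue model.

    The first eight entries are the NF1 study factors (in their conventional
    non-dimensional units); everything else is calibration.  ``y3_scale`` and
    ``g_gvc_scale`` map the nominal magnitudes of ``Y_3cb`` (0–1000) and
    ``G_gvc`` (10^3–10^5) onto per-day rates of order one.
    """

    # --- the eight NF1 factors (non-dimensional; normal-case defaults) ---
    c_f_BC: float = 3.0      # fibroblast invasion duration [days]
    A_f0: float = 0.1        # fibroblast proliferation rate [1/day]
    F_4: float = 0.01        # fibroblastic differentiation rate [1/day]
    Y_11: float = 20.0       # osteogenic differentiation rate (scaled by y1_scale)
    Y_3cb: float = 1000.0    # endochondral ossification rate (scaled by y3_scale)
    P_mc: float = 0.2        # cartilage formation rate [1/day]
    P_mf: float = 0.2        # fibrous tissue formation rate [1/day]
    G_gvc: float = 1e3       # angiogenic GF production rate (scaled by g_gvc_scale)

    # --- factor scalings to per-day rates ---
    y1_scale: float = 0.02
    y3_scale: float = 1e-3
    g_gvc_scale: float = 1e-4

    # --- mobility ---
    D_m: float = 0.02
    D_f: float = 0.02
    D_gbc: float = 0.05
    D_gv: float = 0.05
    D_n: float = 0.3
    chi_m: float = 0.01      # MSC chemotaxis weight (up the g_bc gradient)
    chi_f: float = 0.005     # fibroblast haptotaxis weight (up the m_f gradient)

    # --- proliferation / differentiation ---
    A_m0: float = 0.25       # MSC logistic proliferation [1/day]
    Y_12: float = 0.4        # chondrogenic differentiation [1/day]
    cap: float = 1.0         # cell carrying capacity (all cell fields)
    fibro_stim_cutoff: float = 1e-3  # osteo+chondro rate below which the
    # fibroblastic default pathway stays active [1/day]

    # --- matrix ---
    P_mb: float = 0.2        # bone matrix production by osteoblasts [1/day]
    m_max: float = 1.0
    m_c_crit: float = 0.1    # cartilage density gating endochondral ossification

    # --- growth factors ---
    K_gbc: float = 0.1       # Hill constant, differentiation activation
    K_g3: float = 0.1        # Hill constant, endochondral activation
    P_gbc: float = 0.5       # g_bc production by chondro/osteogenic cells [1/day]
    d_gbc: float = 1.0       # g_bc decay [1/day]
    d_gv: float = 1.0        # g_v decay [1/day]
    g_ceiling: float = 10.0  # clip ceiling for growth-factor fields

    # --- oxygen ---
    n_chondro_lo: float = 0.1   # hypoxic window for chondrogenesis
    n_chondro_hi: float = 0.5
    n_osteo_lo: float = 0.5     # normoxic window for osteogenesis
    n_osteo_hi: float = 2.5
    n_hypoxia: float = 0.5      # below: angiogenic GF production active
    n_ref: float = 1.0          # perfused supply drives oxygen toward this
    S_n: float = 10.0           # oxygen supply rate at perfused cells [1/day]
    q_n: float = 0.4            # consumption per unit total cell density [1/day]

    # --- boundary schedule (durations in days; clamp interval inclusive) ---
    c_m_BC: float = 14.0
    g_bc_BC: float = 21.0
    bc_c_m: float = 1.0
    bc_c_f: float = 1.0
    bc_g_bc: float = 1.0

    # --- numerics ---
    max_reaction_substep: float = 0.05  # max (rate*dt) per explicit sub-step
    clip_abort_fraction: float = 1e-6

    def factor_vector(self) -> np.ndarray:
        return np.array([self.c_f_BC, self.A_f0, self.F_4, self.Y_11,
                         self.Y_3cb, self.P_mc, self.P_mf, self.G_gvc])

    @classmethod
    def from_config(cls, cfg: dict | None = None) -> "ModelParams":
        cfg = cfg or {}
        valid = {f.name for f in dc_fields(cls)}
        unknown = set(cfg) - valid
        if unknown:
            raise KeyError(f"unknown tissue parameters: {sorted(unknown)}")
        return cls(**cfg)

    def with_factors(self, factors: dict) -> "ModelParams":
        return replace(self, **factors)


def hill(x: np.ndarray, K: float) -> np.ndarray:
    """Saturating activation x/(K+x)."""
    return x / (K + x)


def oxygen_window(n: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Indicator of the half-open oxygen band [lo, hi)."""
    return ((n >= lo) & (n < hi)).astype(float)


def _check_nonneg(*arrays) -> None:
    for a in arrays:
        if np.any(np.asarray(a) < 0):
            raise ValueError("inputs must be non-negative")


def endochondral_rate(n, g_bc, m_c, params: ModelParams) -> np.ndarray:
    """Local endochondral ossification rate Y_3 [1/day].

    Y_3 = y3_scale * Y_3cb * H(g_bc) * O_osteo(n) * 1[m_c >= m_c_crit]:
    cartilage converts to bone only where the critical cartilage density has
    been reached, in the normoxic-osteogenic oxygen band, under growth-factor
    activation; linear in the rate constant Y_3cb.
    """
    n, g_bc, m_c = np.asarray(n, float), np.asarray(g_bc, float), np.asarray(m_c, float)
    _check_nonneg(n, g_bc, m_c)
    gate = (m_c >= params.m_c_crit).astype(float)
    window = oxygen_window(n, params.n_osteo_lo, params.n_osteo_hi)
    return params.y3_scale * params.Y_3cb * hill(g_bc, params.K_g3) * window * gate


def differentiation_rates(state: TissueState, params: ModelParams) -> dict:
    """Per-cell MSC differentiation rates [1/day].

    Osteogenic and chondrogenic routes require growth-factor activation inside
    their respective oxygen windows; fibroblastic differentiation is the
    default pathway, active only where neither stimulus is.  The three routes
    are conservative: each MSC leaving ``c_m`` enters exactly one target
    population.
    """
    act = hill(state.g_bc, params.K_gbc)
    r_osteo = (params.y1_scale * params.Y_11 * act
               * oxygen_window(state.n, params.n_osteo_lo, params.n_osteo_hi))
    r_chondro = (params.Y_12 * act
                 * oxygen_window(state.n, params.n_chondro_lo, params.n_chondro_hi))
    stimulated = (r_osteo + r_chondro) > params.fibro_stim_cutoff
    r_fibro = np.where(stimulated, 0.0, params.F_4)
    return {"osteogenic": r_osteo, "chondrogenic": r_chondro, "fibroblastic": r_fibro}


def matrix_production(state: TissueState, params: ModelParams) -> dict:
    """Matrix production rates [density/day], saturating at total m_max.

    Includes the endochondral conversion term Y_3*m_c, which transfers
    cartilage matrix to bone matrix (conserving m_c + m_b locally).
    """
    room = np.clip(1.0 - state.total_matrix() / params.m_max, 0.0, None)
    y3 = endochondral_rate(state.n, state.g_bc, state.m_c, params)
    return {
        "dm_f": params.P_mf * state.c_f * room,
        "dm_c": params.P_mc * state.c_c * room - y3 * state.m_c,
        "dm_b": params.P_mb * state.c_b * room + y3 * state.m_c,
    }


def growth_factor_dynamics(state: TissueState, params: ModelParams) -> dict:
    """Local (reaction) rates for the two growth-factor fields [conc/day].

    g_v is produced by hypoxic cells of every type at a rate proportional to
    G_gvc; g_bc is produced by chondrocytes and osteoblasts.  Both decay
    first-order.  Diffusion is applied separately by the transport sub-step.
    """
    hypoxic = (state.n < params.n_hypoxia).astype(float)
    producers = state.c_m + state.c_f + state.c_c + state.c_b
    dg_v = (params.g_gvc_scale * params.G_gvc * hypoxic * producers
            - params.d_gv * state.g_v)
    dg_bc = params.P_gbc * (state.c_c + state.c_b) - params.d_gbc * state.g_bc
    return {"dg_bc": dg_bc, "dg_v": dg_v}


# ---------------------------------------------------------------------------
# transport operators
# ---------------------------------------------------------------------------


class _Transport:
    """Diffusion propagators and upwind taxis on the active (callus) cells.

    The Laplacian uses a 5-point stencil restricted to active cells with
    zero-flux (no transfer) across faces to inactive cells and across all
    outer edges — which makes the two mirror boundaries zero-flux by
    construction.  For small systems the diffusion sub-step applies the exact
    propagator expm(D*dt*L); larger systems use sub-cycled Crank–Nicolson.
    """

    DENSE_LIMIT = 2100

    def __init__(self, domain: DomainGrid):
        self.domain = domain
        mask = domain.callus_mask
        self.mask = mask
        self.idx = -np.ones(mask.shape, dtype=int)
        self.idx[mask] = np.arange(mask.sum())
        self.n_active = int(mask.sum())
        self._laplacian = self._build_laplacian()
        self._propagators: dict = {}
        self._cn_solvers: dict = {}

    def _build_laplacian(self) -> sp.csr_matrix:
        dom = self.domain
        rows, cols, vals = [], [], []
        hz2, hr2 = dom.h_z ** 2, dom.h_r ** 2
        nz, nr = dom.n_z, dom.n_r
        for iz in range(nz):
            for ir in range(nr):
                i = self.idx[iz, ir]
                if i < 0:
                    continue
                for dz, dr, w in ((1, 0, 1 / hz2), (-1, 0, 1 / hz2),
                                  (0, 1, 1 / hr2), (0, -1, 1 / hr2)):
                    jz, jr = iz + dz, ir + dr
                    if 0 <= jz < nz and 0 <= jr < nr and self.idx[jz, jr] >= 0:
                        j = self.idx[jz, jr]
                        rows += [i, i]
                        cols += [j, i]
                        vals += [w, -w]
        n = self.n_active
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    def diffuse(self, arr: np.ndarray, D: float, dt: float) -> np.ndarray:
        if D <= 0 or dt <= 0:
            return arr
        u = arr[self.mask]
        key = (round(D, 12), round(dt, 12))
        if self.n_active <= self.DENSE_LIMIT:
            P = self._propagators.get(key)
            if P is None:
                P = scipy.linalg.expm((D * dt) * self._laplacian.toarray())
                self._propagators[key] = P
            u = P @ u
        else:
            u = self._crank_nicolson(u, D, dt)
        out = arr.copy()
        out[self.mask] = u
        return out

    def _crank_nicolson(self, u: np.ndarray, D: float, dt: float, n_sub: int = 4):
        key = (round(D, 12), round(dt, 12), n_sub)
        solver = self._cn_solvers.get(key)
        if solver is None:
            A = D * (dt / n_sub) * self._laplacian
            I = sp.identity(self.n_active, format="csc")
            lhs = spla.splu((I - 0.5 * A).tocsc())
            rhs = (I + 0.5 * A).tocsr()
            solver = (lhs, rhs)
            self._cn_solvers[key] = solver
        lhs, rhs = solver
        for _ in range(n_sub):
            u = lhs.solve(rhs @ u)
        return u

    def upwind_taxis(self, c: np.ndarray, potential: np.ndarray, chi: float,
                     dt: float) -> np.ndarray:
        """Conservative first-order upwind advection of ``c`` with velocity
        chi * grad(potential), zero-flux at inactive faces, CFL sub-cycled."""
        if chi == 0 or dt <= 0:
            return c
        dom = self.domain
        mask = self.mask
        out = c.copy()

        def face_flux(carr):
            # velocities on interior faces from potential differences
            fz = np.zeros((dom.n_z - 1, dom.n_r))
            fr = np.zeros((dom.n_z, dom.n_r - 1))
            open_z = mask[:-1, :] & mask[1:, :]
            open_r = mask[:, :-1] & mask[:, 1:]
            vz = chi * (potential[1:, :] - potential[:-1, :]) / dom.h_z
            vr = chi * (potential[:, 1:] - potential[:, :-1]) / dom.h_r
            vz *= open_z
            vr *= open_r
            fz = np.where(vz > 0, vz * carr[:-1, :], vz * carr[1:, :])
            fr = np.where(vr > 0, vr * carr[:, :-1], vr * carr[:, 1:])
            return fz, fr, vz, vr

        # CFL: |v| dt_sub / h <= 0.5
        _, _, vz, vr = face_flux(out)
        vmax = max(np.abs(vz).max() / dom.h_z if vz.size else 0.0,
                   np.abs(vr).max() / dom.h_r if vr.size else 0.0, 1e-12)
        n_sub = max(1, int(np.ceil(dt * vmax / 0.5)))
        dts = dt / n_sub
        for _ in range(n_sub):
            fz, fr, _, _ = face_flux(out)
            div = np.zeros_like(out)
            div[:-1, :] += fz / dom.h_z
            div[1:, :] -= fz / dom.h_z
            div[:, :-1] += fr / dom.h_r
            div[:, 1:] -= fr / dom.h_r
            out = out - dts * div
            out[~mask] = 0.0
        return out


# ---------------------------------------------------------------------------
# full step
# ---------------------------------------------------------------------------


def _reaction_rates(state: TissueState, params: ModelParams,
                    oxygen_sources: np.ndarray) -> dict:
    diff = differentiation_rates(state, params)
    outflux = (diff["osteogenic"] + diff["chondrogenic"] + diff["fibroblastic"]) * state.c_m
    y3 = endochondral_rate(state.n, state.g_bc, state.m_c, params)
    mp = matrix_production(state, params)
    gf = growth_factor_dynamics(state, params)
    crowd_m = np.clip(1.0 - state.c_m / params.cap, 0.0, None)
    crowd_f = np.clip(1.0 - state.c_f / params.cap, 0.0, None)
    total_cells = state.c_m + state.c_f + state.c_c + state.c_b
    return {
        "c_m": params.A_m0 * state.c_m * crowd_m - outflux,
        "c_f": params.A_f0 * state.c_f * crowd_f + diff["fibroblastic"] * state.c_m,
        "c_c": diff["chondrogenic"] * state.c_m - y3 * state.c_c,
        "c_b": diff["osteogenic"] * state.c_m + y3 * state.c_c,
        "m_f": mp["dm_f"],
        "m_c": mp["dm_c"],
        "m_b": mp["dm_b"],
        "g_bc": gf["dg_bc"],
        "g_v": gf["dg_v"],
        "n": (params.S_n * oxygen_sources * np.clip(params.n_ref - state.n, 0.0, None)
              - params.q_n * total_cells * state.n),
    }


def step_tissue(state: TissueState, domain: DomainGrid, params: ModelParams,
                oxygen_sources: np.ndarray, dt: float,
                transport: _Transport | None = None,
                log: dict | None = None) -> TissueState:
    """Advance all ten fields by ``dt`` (operator splitting).

    Order: sub-cycled explicit reactions → upwind taxis for the motile cell
    populations → diffusion propagator for the mobile species.  Fields stay
    non-negative and bounded; undershoots are clipped with the clipped mass
    logged in ``log['clipped_mass']``, and a :class:`NumericalError` is raised
    if clipping exceeds ``clip_abort_fraction`` of the field total.
    """
    if transport is None:
        transport = _Transport(domain)
    mask = transport.mask
    new = state.copy()

    # --- reactions, sub-cycled so the stiffest rate sees a small step ---
    stiff = max(params.A_f0, params.A_m0, params.Y_12,
                params.y1_scale * params.Y_11, params.y3_scale * params.Y_3cb,
                params.P_mf, params.P_mc, params.P_mb, params.d_gbc, params.d_gv,
                params.g_gvc_scale * params.G_gvc, params.S_n,
                params.q_n * 4 * params.cap, params.F_4)
    n_sub = max(1, int(np.ceil(stiff * dt / params.max_reaction_substep)))
    dts = dt / n_sub
    clipped = 0.0
    for _ in range(n_sub):
        rates = _reaction_rates(new, params, oxygen_sources)
        for name in FIELD_NAMES:
            arr = getattr(new, name)
            arr += dts * rates[name]
            neg = arr < 0
            if neg.any():
                clipped += float(-arr[neg].sum())
                arr[neg] = 0.0
            arr[~mask] = 0.0
        # hard caps (production terms already saturate; guards roundoff)
        for cname in ("c_m", "c_f", "c_c", "c_b"):
            np.clip(getattr(new, cname), 0.0, params.cap, out=getattr(new, cname))
        for gname in ("g_bc", "g_v"):
            np.clip(getattr(new, gname), 0.0, params.g_ceiling, out=getattr(new, gname))
        total_m = new.total_matrix()
        over = total_m > params.m_max
        if over.any():
            scale = np.where(over, params.m_max / np.maximum(total_m, 1e-30), 1.0)
            for mname in ("m_f", "m_c", "m_b"):
                getattr(new, mname)[...] *= scale

    # --- taxis (motile cells only) ---
    new.c_m = transport.upwind_taxis(new.c_m, new.g_bc, params.chi_m, dt)
    new.c_f = transport.upwind_taxis(new.c_f, new.m_f, params.chi_f, dt)

    # --- diffusion ---
    for name, Dname in MOBILE_FIELDS.items():
        D = getattr(params, Dname)
        setattr(new, name, transport.diffuse(getattr(new, name), D, dt))

    # clip transport undershoots
    for name in FIELD_NAMES:
        arr = getattr(new, name)
        neg = arr < 0
        if neg.any():
            clipped += float(-arr[neg].sum())
            arr[neg] = 0.0

    if log is not None:
        log["clipped_mass"] = log.get("clipped_mass", 0.0) + clipped
    total = sum(float(getattr(new, f).sum()) for f in FIELD_NAMES)
    if total > 0 and clipped > params.clip_abort_fraction * max(total, 1.0):
        raise NumericalError(
            f"clipped mass {clipped:.3e} exceeds tolerance (step dt={dt})")
    new.validate(params)
    return new


def apply_dirichlet(state: TissueState, t: float, domain: DomainGrid,
                    params: ModelParams) -> TissueState:
    """Clamp the influx boundaries for as long as their schedule is active.

    MSCs and fibroblasts are clamped on the periosteum/soft-tissue/marrow
    source cells while ``t <= c_m_BC`` and ``t <= c_f_BC`` respectively
    (inclusive endpoints); the osteochondrogenic growth factor is clamped on
    the degrading bone ends and cortex surface while ``t <= g_bc_BC``.  After
    its duration each clamp is released and the boundary reverts to zero-flux.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    new = state.copy()
    msc = domain.source_masks["msc_fibroblast_sources"]
    gf = domain.source_masks["gf_sources"]
    if t <= params.c_m_BC:
        new.c_m[msc] = params.bc_c_m
    if t <= params.c_f_BC:
        new.c_f[msc] = params.bc_c_f
    if t <= params.g_bc_BC:
        new.g_bc[gf] = params.bc_g_bc
    return new
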