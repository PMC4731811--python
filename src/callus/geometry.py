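"""Axisymmetric quarter-callus domain.

The healing callus around a transverse long-bone fracture is modelled on a
quarter of the axial cross-section: by axisymmetry around the bone axis and
mirror symmetry across the fracture mid-plane, one quadrant determines the
whole geometry.  The coordinate origin sits in the bottom-left corner; ``z``
runs axially (increasing toward the fracture mid-plane at ``z = length``),
``r`` radially (``r = 0`` is the bone axis).

Four regions tile the domain:

* ``cortical_bone`` — the cortex, a radial band ``[marrow_radius,
  marrow_radius + cortex_thickness)`` ending at the fracture gap;
* ``intercortical_callus`` — the gap continuation of that band up to the
  mid-plane;
* ``endosteal_callus`` — the marrow cavity, ``r < marrow_radius``;
* ``periosteal_callus`` — the external callus bulge above the cortex, bounded
  by an ellipse arc centred on the fracture plane.

Cells outside the periosteal ellipse are ``outside`` and carry no tissue.
The fracture-gap mask collects the callus cells whose axial position lies
between the cortical end face and the mid-plane; tissue responses are
evaluated there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REGIONS = (
    "periosteal_callus",
    "intercortical_callus",
    "endosteal_callus",
    "cortical_bone",
    "outside",
)

# integer codes for the region array
PERIOSTEAL, INTERCORTICAL, ENDOSTEAL, CORTICAL, OUTSIDE = range(5)
CALLUS_CODES = (PERIOSTEAL, INTERCORTICAL, ENDOSTEAL)


class GeometryError(ValueError):
    """Invalid callus geometry configuration."""


@dataclass
class DomainGrid:
    """Rasterized quarter-callus domain.

    Arrays are indexed ``[iz, ir]`` (axial index first).  ``region`` holds the
    integer region codes above; ``callus_mask`` marks the cells where the
    continuum fields live; ``gap_mask`` the fracture-gap subset used for
    response extraction.
    """

    n_z: int
    n_r: int
    h_z: float
    h_r: float
    length: float
    radius: float
    region: np.ndarray
    gap_mask: np.ndarray
    source_masks: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    @property
    def callus_mask(self) -> np.ndarray:
        return np.isin(self.region, CALLUS_CODES)

    @property
    def z_centers(self) -> np.ndarray:
        return (np.arange(self.n_z) + 0.5) * self.h_z

    @property
    def r_centers(self) -> np.ndarray:
        return (np.arange(self.n_r) + 0.5) * self.h_r

    @property
    def cortical_end_z(self) -> float:
        return self.length - self.config["half_gap"]

    @property
    def symmetry_edges(self) -> dict:
        # mirror planes of the quarter symmetry: bone axis and fracture plane
        return {"axis": "r=0", "fracture_plane": f"z={self.length}"}

    def region_counts(self) -> dict:
        return {
            name: int(np.count_nonzero(self.region == code))
            for code, name in enumerate(REGIONS)
        }


DEFAULT_GEOMETRY = {
    "length": 1.0,          # axial half-length, far end to fracture mid-plane
    "radius": 1.0,          # outer radial extent of the modelled quadrant
    "marrow_radius": 0.25,  # bone axis to endosteal cortex surface
    "cortex_thickness": 0.15,
    "half_gap": 0.2,        # cortical end face to fracture mid-plane
    "n_z": 64,
    "n_r": 64,
}


def build_domain(config: dict | None = None) -> DomainGrid:
    """Rasterize the stylized quarter-callus geometry onto a cell-centred grid.

    Parameters not supplied fall back to :data:`DEFAULT_GEOMETRY`.  Raises
    :class:`GeometryError` naming the offending parameter for degenerate
    geometries (absent cortex, zero callus thickness, gap wider than the
    domain).
    """
    cfg = dict(DEFAULT_GEOMETRY)
    if config:
        cfg.update(config)

    n_z, n_r = int(cfg["n_z"]), int(cfg["n_r"])
    if n_z <= 0 or n_r <= 0:
        raise GeometryError("grid counts n_z/n_r must be positive")
    L, R = float(cfg["length"]), float(cfg["radius"])
    if L <= 0 or R <= 0:
        raise GeometryError("length/radius must be positive")
    r_m = float(cfg["marrow_radius"])
    t_c = float(cfg["cortex_thickness"])
    hg = float(cfg["half_gap"])
    if t_c <= 0:
        raise GeometryError("cortex_thickness must be positive (cortex absent)")
    if r_m <= 0:
        raise GeometryError("marrow_radius must be positive (endosteal callus absent)")
    if not (0 < hg < L):
        raise GeometryError("half_gap must lie in (0, length)")
    peri_thickness = R - (r_m + t_c)
    if peri_thickness <= 0:
        raise GeometryError(
            "radius - marrow_radius - cortex_thickness must be positive "
            "(periosteal callus has zero thickness)"
        )

    h_z, h_r = L / n_z, R / n_r
    z = (np.arange(n_z) + 0.5) * h_z
    r = (np.arange(n_r) + 0.5) * h_r
    zz, rr = np.meshgrid(z, r, indexing="ij")

    z_end = L - hg  # axial position of the cortical end face

    region = np.full((n_z, n_r), OUTSIDE, dtype=np.int8)
    cortex_band = (rr >= r_m) & (rr < r_m + t_c)
    region[cortex_band & (zz < z_end)] = CORTICAL
    region[cortex_band & (zz >= z_end)] = INTERCORTICAL
    region[rr < r_m] = ENDOSTEAL
    # periosteal bulge: ellipse arc centred on the fracture plane at the
    # periosteal cortex surface, thickest at the fracture, tapering to the
    # far end
    above = rr >= r_m + t_c
    ell = ((zz - L) / L) ** 2 + ((rr - (r_m + t_c)) / peri_thickness) ** 2
    region[above & (ell <= 1.0)] = PERIOSTEAL

    for code, name in enumerate(REGIONS[:4]):
        if not np.any(region == code):
            raise GeometryError(f"region {name} is empty at this resolution")

    callus = np.isin(region, CALLUS_CODES)
    gap_mask = callus & (zz >= z_end)

    domain = DomainGrid(
        n_z=n_z, n_r=n_r, h_z=h_z, h_r=h_r, length=L, radius=R,
        region=region, gap_mask=gap_mask, config=cfg,
    )
    domain.source_masks = _build_source_masks(domain)
    return domain


def _adjacent_to(region: np.ndarray, mask_codes, code) -> np.ndarray:
    """Cells with region in ``mask_codes`` 4-adjacent to a cell of ``code``."""
    target = region == code
    neigh = np.zeros_like(target)
    neigh[1:, :] |= target[:-1, :]
    neigh[:-1, :] |= target[1:, :]
    neigh[:, 1:] |= target[:, :-1]
    neigh[:, :-1] |= target[:, 1:]
    return np.isin(region, mask_codes) & neigh


def _build_source_masks(domain: DomainGrid) -> dict:
    region = domain.region
    callus = domain.callus_mask
    n_z, n_r = domain.n_z, domain.n_r

    # MSC / fibroblast sources: periosteum and surrounding soft tissue (outer
    # surface of the periosteal callus, i.e. cells adjacent to 'outside' or on
    # the outer radial edge) and the marrow border (far axial face of the
    # marrow cavity).  The mirror boundaries (bone axis r=0, fracture plane
    # z=max) are never sources.
    msc = np.zeros((n_z, n_r), dtype=bool)
    msc |= _adjacent_to(region, CALLUS_CODES, OUTSIDE)
    edge_far = np.zeros_like(msc)
    edge_far[0, :] = True        # z = 0 face (marrow + far callus border)
    edge_top = np.zeros_like(msc)
    edge_top[:, -1] = True       # r = radius face (outer soft tissue)
    msc |= (edge_far | edge_top) & callus
    msc[-1, :] = False           # exclude fracture mid-plane cells

    # growth-factor sources: callus faces of the cortical bone (degrading
    # bone ends and cortex surface)
    gf = _adjacent_to(region, CALLUS_CODES, CORTICAL)

    return {"msc_fibroblast_sources": msc, "gf_sources": gf}


def gap_region(domain: DomainGrid) -> np.ndarray:
    """Index array ``(iz, ir)`` of the fracture-gap cells.

    These are exactly the callus cells whose axial position lies between the
    cortical end face and the fracture mid-plane — the region in which
    pseudarthrosis is assessed.
    """
    return np.argwhere(domain.gap_mask)


def gap_interior(domain: DomainGrid) -> np.ndarray:
    """Gap cells not on the gap's border (not grid-edge, not adjacent to a
    non-gap cell).  Source masks must not reach these."""
    g = domain.gap_mask
    interior = g.copy()
    interior[0, :] = interior[-1, :] = False
    interior[:, 0] = interior[:, -1] = False
    inner = g[:-2, 1:-1] & g[2:, 1:-1] & g[1:-1, :-2] & g[1:-1, 2:]
    interior[1:-1, 1:-1] &= inner
    return interior
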