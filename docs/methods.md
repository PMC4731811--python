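# Methods

## Scope and model structure

The package couples a continuum description of callus tissue dynamics with
a discrete model of sprouting angiogenesis on a stylized axisymmetric
quarter-callus, and layers a design-of-experiments (DOE) +
Gaussian-process (GP) sensitivity pipeline on top. It covers the repair
phase of healing only: the early inflammatory response, bone remodelling /
osteoclast activity, and mechanoregulation are deliberately outside the
model, and the mechanical environment is assumed permissive.

### Geometry

The domain is one quadrant of the fracture: `z` axial (0 at the far end,
`length` at the fracture mid-plane), `r` radial (0 on the bone axis). Four
regions are rasterized from a handful of named dimensions (marrow radius,
cortex thickness, half-gap width, callus extent): cortical bone, and
periosteal / intercortical / endosteal callus, with the periosteal bulge
bounded by an ellipse arc centred on the fracture plane. The geometry is a
stylized rendering of a rat femoral callus at three weeks post-fracture; it
reproduces the topology (regions, gap, sources), which is what the analysis
depends on, not exact anatomical contours. All dimensions are
config entries. The fracture-gap mask — where every response is evaluated —
collects the callus cells between the cortical end face and the mid-plane.
Both mirror boundaries (bone axis, fracture plane) are zero-flux for every
field.

### Tissue continuum

Ten non-dimensional fields (cell densities scaled by 10^6 cells/ml, matrix
by 0.1 g/ml, oxygen by 1 % tension; one time unit = one day). Functional
forms:

* logistic proliferation for MSCs (`A_m0`) and fibroblasts (`A_f0`,
  an NF1 factor), carrying capacity 1;
* differentiation from the MSC pool with Hill activation in g_bc
  (half-saturation `K_gbc`) inside oxygen windows: osteogenic in
  [`n_osteo_lo`, `n_osteo_hi`) = [0.5, 2.5), chondrogenic in
  [`n_chondro_lo`, `n_chondro_hi`) = [0.1, 0.5); fibroblastic
  differentiation (`F_4`) is the default pathway wherever the combined
  osteo/chondrogenic rate falls below a small cutoff (`fibro_stim_cutoff`,
  10^-3/day) — without the cutoff, vanishing traces of diffused growth
  factor would switch the default pathway off everywhere;
* matrix production `P_mx · c_x · (1 − m/m_max)+` saturating in the total
  matrix density, with `P_mc` and `P_mf` NF1 factors;
* endochondral conversion `Y_3 = y3_scale·Y_3cb · H(g_bc) · O_osteo(n) ·
  1[m_c ≥ m_c_crit]` transferring cartilage matrix to bone (and
  chondrocytes to osteoblasts), conserving `m_c + m_b` locally;
* angiogenic growth-factor production by all hypoxic cells
  (`g_gvc_scale·G_gvc`, n < 0.5), first-order decay for both growth
  factors;
* oxygen supplied at perfused-vessel cells toward a reference level and
  consumed proportionally to total cell density.

The nominal magnitudes of two factors (Y_3cb up to 1000, G_gvc up to 10^5)
are mapped to per-day rates of order one by fixed scale factors
(`y3_scale` = 10^-3, `g_gvc_scale` = 10^-4); both factor dependencies stay
exactly linear, so the factor box is traversed faithfully.

The full coefficient calibration of this model class is not fixed by its
structure; every coefficient above is a named config entry and the defaults
are this package's own calibration,
chosen once so that on the reduced-resolution default domain the
normal-case factor column bridges the gap by day 21 while the NF1 column
forms a fibrous non-union. They are calibration values, not literature measurements.

Boundary schedule: MSCs and fibroblasts are clamped at density 1 on the
periosteum/soft-tissue/marrow source cells while `t ≤ c_m_BC` (14 d) and
`t ≤ c_f_BC` (an NF1 factor), the osteochondrogenic growth factor on the
bone-end/cortex faces while `t ≤ g_bc_BC` (21 d); clamp intervals are
inclusive, and after each duration the boundary reverts to zero-flux. The
MSC and growth-factor source durations are calibration assumptions.

### Vascular agents

Each endothelial cell carries exactly eight intracellular variables:
sensed VEGF, total and active VEGFR-2, Dll4, total and active Notch, actin
activity, and a tip-persistence timer. The kinetics are first-order
relaxation ODEs with two deliberate nonlinearities — cooperative Dll4
expression (∝ active-VEGFR-2²) and Hill-2 Notch suppression of VEGFR-2
activation — which make the symmetric two-cell state unstable so that
lateral inhibition resolves near-equal neighbours into a tip/stalk pair
(verified in the two-agent test). A cell becomes a tip iff its active
VEGFR-2 exceeds the threshold and strictly exceeds both segment
neighbours'; tips closer than the minimum spacing are thinned keeping the
higher activity, ties broken by agent id, so selection is deterministic.
Tip speed is Michaelis-saturating in active VEGFR-2; direction blends
chemotaxis up the angiogenic growth-factor gradient, haptotaxis toward an
intermediate matrix density (quadratic preference around `m_pref`),
persistence and small seeded noise, with step length capped at one grid
spacing. Stalk cells are inserted behind a tip whenever its distance to the
last stalk exceeds the endothelial spacing. A tip within the capture radius
of a foreign segment fuses to it; a tip leaving the domain becomes a
boundary anastomosis — counted as a perfusion entry point (a modelling
choice exposed in the perfusion routine). A segment is perfused iff it lies
on a cycle of the graph augmented with a super-node joining all roots and
boundary anastomoses; dead-end sprouts never perfuse. The initial
vasculature is a pair of perfused root-vessel lines along the endosteal and
periosteal cortex surfaces; root agents never migrate — a winning root
sprouts a daughter tip instead.

### Responses and the Complication Index

Matrix fields are binarized with tissue-specific thresholds (default
0.1·m_max each — scale-free against the 0–1 non-dimensionalization, and
config-exposed; thresholds are a calibration choice). Gap
fractions use equal weighting: a cell holding k tissues contributes area/k
to each. Amounts γ4/γ5 are gap *means* normalized by m_max and the carrying
capacity (an integral reading would differ only by the fixed gap area).
Union is a 4-connected bone path from the cortical end face to the fracture
plane (8-connectivity available). The combination rule behind the
Complication Index is configurable; the shipped default is the arithmetic
mean (γ4 + γ5 + γ6)/3, chosen for its clean properties: range [0,1], zero
at all-zero inputs, monotone in each input.

## Numerics

Operator splitting per step (default dt = 0.25 d): explicit reactions
sub-cycled so the stiffest configured rate sees at most 0.05 per sub-step;
conservative first-order upwind taxis with its own CFL sub-cycling;
diffusion by the exact matrix-exponential propagator of the masked 5-point
Laplacian (dense, cached per diffusivity) on domains up to ~2000 active
cells, and sub-cycled Crank–Nicolson above that. Negative undershoots are
clipped to zero with the clipped mass logged; a step aborts if clipping
exceeds 10^-6 of the total field mass, so the non-negativity invariant is
testable rather than silently enforced. The vascular sub-model advances
with the tissue step; perfusion and the oxygen source field are recomputed
every coupling interval (default 0.25 d). All randomness flows from one
`numpy` generator per run; identical (scenario, config, seed) runs are
bit-identical.

## DOE + GP pipeline

* **Design**: `scipy.stats.qmc.LatinHypercube` with `random-cd`
  (centered-L2 discrepancy) optimization, scaled to the factor box;
  200 runs by default. The tests require the optimized design to beat the
  mean discrepancy of 100 random designs.
* **Surrogate**: anisotropic squared-exponential kernel × signal variance
  + white-noise nugget (floor 10^-8 of the response variance), inputs
  scaled to the unit box, response standardized, marginal-likelihood
  maximization with 8 seeded restarts (`sklearn` GP regression underneath).
* **Diagnostics**: leave-one-out predictions in closed form at the fitted
  hyperparameters (`mu_i = y_i − [K⁻¹y]_i/[K⁻¹]_ii`); the brute-force
  check refits without each point holding hyperparameters fixed —
  re-optimizing per fold would conflate hyperparameter instability with
  prediction error. Responses with fewer than half the points near the
  45-degree line are flagged `poor_fit` and excluded from interpretation.
* **Main effects**: first-order Sobol shares of the prediction function via
  the pick-freeze scheme with the centered (Janon) estimator on a
  scrambled-Sobol quasi-Monte-Carlo block pair (default 2^13 points; the
  validation suite uses 2^14). The estimator accepts a fitted surrogate or
  any callable, so it is validated directly against the analytic first-order
  indices of the Sobol g-function and the Ishigami function (within 3
  percentage points) independently of the GP. First-order shares are
  reported; a total-effect variant can be layered on the same estimator.
* **Marginal profiles**: the prediction averaged over the other factors at
  each grid value of one factor, with the raw scatter returned for overlay.

## Synthetic fixtures

`tiny_config` (16×16 domain, 21-day horizon) is the problem size used
throughout the test-suite and for the paired normal-vs-NF1 contrast runs
(a full coupled run takes a few seconds). `tissue_pattern` provides states
with known responses (bridged, empty, fibrous hamartoma, three-tissue
mixture). `ci_mimic` is a synthetic severity surface — threshold terms in
the cartilage-formation (< 0.05) and endochondral-ossification (< 200)
factors with weights 0.35/0.35, a fibroblast-invasion ramp saturating at
10 with weight 0.3, and a small smooth background — built as test
scaffolding for the pipeline's ranking behaviour, not as a fit to the
mechanistic model.

What the generator does *not* emulate: production-resolution spatial
fields, the full 49-day horizon at scale, literature-calibrated
coefficients, inflammation, remodelling, mechanics. Passing tests
demonstrate the implementation's internal correctness and the qualitative
union-vs-pseudarthrosis contrast at reduced scale; they are not a
quantitative reproduction of full-scale results.

## Known limitations

* The Complication-Index combination (arithmetic mean) is a modelling
  choice; downstream rankings that depend only on monotonicity are
  insensitive to it, absolute CI values are not.
* Base-coefficient defaults are calibration, so absolute tissue fractions
  and timings on the tiny domain should be read qualitatively.
* The vascular model omits flow haemodynamics, vessel regression and
  oxygen carriage beyond a fixed per-length supply.
* First-order upwind taxis is diffusive; at the default resolution this is
  acceptable because taxis weights are small.
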