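# Methods

## Physical model

`ireplan` simulates irreversible electroporation (IRE) of liver tissue by
two parallel needle electrodes in a 2D plane and searches the protocol
space for the configuration that maximizes treatment intensity without
thermal damage.

### Modeling plane and geometry

The simulated plane is the longitudinal plane containing both needle axes:
x runs across the tissue, y downward from the surface. This is the only 2D
plane in which all five protocol factors are expressible — the active
(uninsulated) electrode length varies *along* the needles, so a transverse
cross-section could not represent it. In this plane each needle appears as
a 1 mm-wide strip: an insulated shaft from the surface down to the active
segment, and a conductive active segment of length L ending at the tip
(default insertion depth 20 mm). Neither the electrode diameter nor the
insertion depth or domain extent is fixed by the study design; the defaults
(1.0 mm diameter — a typical 18–19 G monopolar IRE needle — 20 mm depth,
60 × 60 mm domain) are exposed configuration knobs. A domain-doubling check
confirms the insulated outer boundary moves the inter-electrode field by
< 0.01 %, so the 60 mm extent is effectively infinite for this source.

### Electric problem

The potential obeys the quasi-static conservation law ∇·(σ∇V) = 0 with the
left active segment at the applied voltage, the right at ground, zero-flux
insulation on the outer boundary, and the shafts excluded from conduction.
Tissue conductivity is field-dependent: electroporation opens membrane
pores, so σ rises from a baseline 0.0650 S/m to a saturated 0.1483 S/m
with the local |E|. The exact shape of the transition is not published for
this tissue; the default curve is a symmetric smoothstep knot set rising
between 10 and 70 kV/m, shipped as a CSV (`data/sigma_vs_field.csv`) so it
can be recalibrated declaratively. A `constant_sigma` mode freezes σ at
its zero-field floor, reducing the problem to the linear Laplace equation;
it exists for verification (linearity and closed-form checks).

Discretization is finite-volume on a uniform node lattice (default
0.25 mm for verification runs, 0.5 mm for screening sweeps) with
harmonic-mean face conductivities — the harmonic mean makes a near-zero
shaft conductivity shut off flux exactly, which implements insulation
without special-casing the stencil. The nonlinearity is closed by Picard
iteration: solve the linear system (sparse LU), recompute |E| by central
differences, update σ(|E|) with under-relaxation 0.5, and stop when the
relative conservation residual of the freshly-updated conductivity field
falls below 1e-8 (default; a hard iteration cap of 100 raises a
convergence error carrying the residual history). Every solve asserts the
discrete maximum principle (0 ≤ V ≤ V₀).

### Thermal problem

Temperature follows the Pennes bioheat equation

ρc_p ∂T/∂t = ∇·(k(T)∇T) + Q_s + ρ_b c_{p,b} ω_b (T_b − T) + Q_met,

from a uniform 37 °C initial state, with zero-flux outer boundaries and the
electrodes thermally insulated (excluded from conduction the same way as in
the electric solve). There is no advective term — the tissue carries no
flow field. Perfusion is retained by default (ω_b = 5e-4 1/s) to match the
bioheat model the study used even for ex vivo tissue; `perfusion=False`
switches it off for ex vivo realism studies. Q_met defaults to zero.

The Joule source is duty-cycle averaged: N square pulses of width τ at
frequency f deposit mean volumetric power Q_s = (τf)·σ(|E|)|E|² over the
N/f-second treatment. At IRE duty cycles (4e-5 .. 1e-4) the averaged and
pulse-resolved solutions are indistinguishable on conduction time scales;
a `pulse_resolved` mode exists for sensitivity checks and agrees with the
averaged mode at end-of-treatment even at artificially inflated duty. The
field is solved once per treatment: the only stated electro-thermal
coupling channel is σ(|E|), so there is no temperature feedback on σ.

Time stepping is backward Euler (unconditionally stable) at dt = 0.1 s
with k lagged at the previous step's temperature; with the default
single-knot k(T) = 0.52 W/(m·°C) the system matrix is constant and
factorized once. Halving dt moves the centre-point end temperature by
< 0.1 °C; halving the grid spacing moves the centre |E| by < 0.01 %.

### Responses

* **Ablation area** — tissue area with |E| ≥ 800 V/cm (8.0e4 V/m), by cell
  counting, electrodes excluded. The literal unit "800 V/m" that appears
  once in the source material is numerically impossible: at 3000 V
  essentially the whole domain would exceed it, contradicting the printed
  areas (≤ 375 mm²); 800 V/cm is the standard lethal-field scale for liver
  IRE and is the only reading consistent with the data. The threshold is
  configurable.
* **Maximum temperature** — maximum over tissue nodes and all time steps
  (the centre-probe trace maximum is also recorded; the domain maximum is
  the tabulated response).
* **Thermal damage** — true iff the maximum temperature reaches 50 °C
  (boundary inclusive).

## Statistical pipeline

### Designs

The five factors (active length 10/15 mm; distance 10/15/20 mm; voltage
1000/2000/3000 V; pulse number 30/60/90; pulse width 40/70/100 µs at 1 Hz)
span 162 full-factorial combinations, screened in 18 runs by the standard
L18(2¹3⁷) orthogonal array (columns 1–5). Settings are carried in natural
and coded (−1..+1) units.

### Response surfaces and ANOVA

Each response is fit by OLS on coded units with intercept, linear terms for
all five factors and square terms for the four 3-level factors (10 terms,
8 residual df on 18 runs). Two-factor interactions are *not* included by
default: they are heavily aliased in an L18, and the pure quadratic already
reproduces the study's own optimum-point predictions to printed precision
(268.07 mm², 49.98 °C), which pins the model form. When requested,
interactions are added in lexicographic order and rank-pruned. Per-factor
significance uses partial F-tests (full model vs the model with all of that
factor's terms removed). On the screening table this flags electrode
distance and voltage for temperature (p = 0.043, 0.007) and voltage alone
for area (p < 1e-4), the same pattern the study reports; exact p-values
depend on the (unpublished) ANOVA convention of the original analysis and
are not claimed.

### Desirability optimization

Three responses drive a weighted Derringer–Suich geometric mean:

| response | shape | anchors | importance |
|---|---|---|---|
| field strength (max tissue \|E\|) | larger-is-better | observed min..max | 1 |
| max temperature | target at limit | 37 °C .. 50 °C | 1 |
| ablation area | larger-is-better | observed min..max | 0.25 |

Field strength is the primary intensity objective; its responses are
computed by the package's electric solver per design row (one solve per
distinct geometry/voltage triple) and fit on the geometry/voltage factors
only, since a static field cannot depend on the pulse schedule. The
temperature desirability is *target-type*: it rises linearly from 0 at
37 °C to 1 at the 50 °C damage limit and drops to 0 beyond — the optimal
protocol should spend the full thermal budget without crossing it. (An
upper-bound ramp that rewards *low* temperature instead drives the
optimizer to cold, weak protocols and cannot reproduce a solution whose
predicted temperature sits at 49.98 °C.) Ablation area enters at low
importance as a secondary criterion: field strength and temperature alone
leave a one-dimensional family of equally desirable pulse schedules along
the predicted-50 °C contour, and the area response selects among them. At
importance ≥ 0.5 the area term instead dominates the geometry choice and
pushes the optimum to long/wide electrode configurations, which the
printed areas favour; 0.25 keeps it subordinate to the field objective.

The optimizer enumerates the 2-level factor, scans a 13⁴ coded grid per
slice, polishes the best scan points plus 64 seeded random starts with
Nelder–Mead (the composite has clipping kinks and a hard zero above the
temperature limit, so a simplex method is more reliable than gradients),
and breaks exact ties toward the less energetic protocol (smaller voltage,
then fewer pulses). A property test holds the optimizer within 1e-3 of a
dense brute-force grid maximum on random synthetic models. The pulse
number is reported both continuous and rounded to the nearest multiple of
10 (the deliverable count).

On the shipped screening table this yields an optimum at active length
10 mm, distance 10 mm, 3000 V, 54.3 pulses (rounded to 50) of 40.0 µs,
with predicted area 269.8 mm² and predicted maximum temperature 50.0 °C;
re-simulating the rounded optimum at verification resolution gives
250–270 mm² and ≈ 46.6 °C — no thermal damage.

## What the shipped data does and does not cover

`data/screening_design_responses.csv` is the study's printed 18-run
design-plus-response table and makes the whole statistics half runnable
without any PDE solve; the PDE half is verified independently against
closed forms and discrete balances. The package's own screening
simulations reproduce the printed table's qualitative structure (trend
signs, voltage dominance, which runs overheat) but not its exact numbers —
the original mesh, property curves and electrode dimensions are not fully
published, and the defaults here are calibrated once against the study's
verification values (250.82 mm², 45.36 °C, reproduced within a few
percent) and then left alone.

## Numerical conventions and edge cases

* Property curves clamp to endpoint values outside their knots (prevents
  non-physical extrapolation, e.g. negative conductivity).
* Relative permittivity is stored but inert: nothing in a DC conduction
  problem consumes it. It is kept so tissue definitions remain complete.
* Zero applied voltage short-circuits the electric solve (V ≡ 0, |E| ≡ 0).
* A zero-pulse protocol has zero duration; the simulation returns the
  initial state.
* The ablation threshold comparison is inclusive (|E| ≥ threshold), as is
  the damage limit (T ≥ 50 °C).
* All randomness (optimizer multi-starts, synthetic-response noise) is
  seeded; the pipeline result is deterministic given a configuration, and
  the optimum itself is seed-independent because the multi-start search
  converges to the same box-constrained maximum from any seed.

## Known limitations

* 2D: out-of-plane spreading of current and heat is absent, so absolute
  areas and temperatures carry the plane approximation; 3D is out of scope.
* No vaporization/phase change (irrelevant below 100 °C here), no
  Arrhenius damage integral (the study applies only the 50 °C threshold),
  no temperature dependence of electrical conductivity, no electrode–tissue
  contact impedance, and no inter-pulse rest periods or non-square
  waveforms.
* The maximum tissue |E| used as the field-strength response concentrates
  at electrode corners and is therefore grid-resolution dependent; it is
  consistent across runs at a fixed screening resolution, which is all the
  response-surface ranking needs.
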