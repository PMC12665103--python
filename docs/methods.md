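# Methods

## The reduced-order device model

The physical device is a three-layer chip: organoid chambers (POC, LOC) in
the top layer, a 1.0 µm-pore PTFE membrane, and a 0.7 cm × 0.3 cm connecting
channel in the bottom layer through which a peristaltic pump recirculates
600 µL of media at 600 µL/min. We reduce it to five well-mixed compartments:

| id    | role             | default volume | rationale |
|-------|------------------|---------------:|-----------|
| POC   | organoid chamber | 300 µL         | chamber wells hold a few hundred µL; matches the 300 µL used in static assays |
| CC_P  | channel segment  | 50 µL          | channel fluid directly beneath the POC footprint |
| CC_L  | channel segment  | 50 µL          | likewise beneath the LOC |
| LOOP  | tubing + port    | 500 µL         | absorbs the rest of the stated 600 µL circulating volume |
| LOC   | organoid chamber | 300 µL         | symmetric with POC |

The stated channel cross-section extended over the whole chip length would
exceed the stated circulating volume, so compartment volumes are effective
quantities: the printed total (600 µL in the loop) is honored exactly and the
split is a modeling default.

Exchange edges carry a species of diffusivity *D*:

* **membrane**: `G_m = D ε A / (L_m τ_t)` with porosity ε = 0.8, thickness
  `L_m` = 50 µm (typical for 1 µm-pore PTFE; never stated, surfaced as a
  parameter), tortuosity τ_t = 1 (porosity-only correction), and an
  *effective* contact area A per chamber;
* **channel diffusion**: `G_c = D A_cc / L_path` with `A_cc` = 0.21 cm²; one
  path joins the two channel segments, a second (3× longer) joins the loop
  (injection port/inlet) to the channel — the port sits a few channel widths
  upstream of the first chamber;
* **convection**: the pump flow Q as a directed ring LOOP→CC_P→CC_L→LOOP.
  Flow-off removes every convective edge and nothing else.

Because chambers are well mixed, spatial detail inside the channel is gone;
the two free geometric parameters absorb it. They are calibrated by weighted
least squares against the three reported 4 kDa tracer summaries (percent
transferred at 180 min with and without flow, and the LOC fold enhancement
at 3 h): the fitted effective area (~0.14 cm² per chamber, smaller than any
plausible footprint) lumps Matrigel and unstirred-layer resistance, and the
fitted channel path (~0.08 cm, shorter than the physical gap) compensates the
lumped model's underestimate of early-time diffusive flux from a continuous
concentration profile. Glucose and 70 kDa transport metrics are computed from
this calibration without refitting, so they are genuine predictions; both
land inside the reported uncertainty. The reported 9.1-fold 70 kDa chamber
enhancement is internally inconsistent with the reported percentage pair
(15.9% → 70.6% is ≈ 4.4×); the model predicts ≈ 2.0× and the quantity is
reported without a band.

Tracer loadings follow the assay protocols: 4 kDa dextran loaded in the POC,
70 kDa in the LOC, and the glucose dose filling the circulating loop (the
injection-port protocol; under flow the loop homogenizes within a minute, and
without flow the dose must diffuse from the port side into the channel, which
is what makes convective delivery ~1.9× better). The model is linear in
concentration, so percent and fold metrics are independent of loading
magnitude.

## Numerical choices

The exchange system is linear but spans diffusivities from 9.58×10⁻¹⁰
(glucose) to 2.3×10⁻¹¹ m²/s (70 kDa dextran), so trajectories are integrated
with LSODA at rtol 10⁻⁸ / atol 10⁻¹² with the exact Jacobian supplied.
Round-off negatives smaller than 10⁻⁹ of the loading are clipped to zero;
anything larger raises an integrity error, as does a relative mass-balance
drift above 10⁻⁶. Test oracles use the matrix exponential of an independently
assembled rate matrix. Calibrations optimize log-parameters inside bounds
(areas 10⁻³–5 cm², paths 10⁻³–10 cm) with tight tolerances; per-parameter
sensitivities (Jacobian column norms) are reported so that flat directions
are flagged rather than silently pinned.

## The minimal glucose–insulin model

No kinetic equations are measured for the organoids, so the endocrine stage
is the smallest model able to express the observed features: biphasic
secretion, return to normoglycemia within 2 h, sustained hyperinsulinemia
under palmitate, and faster clearance with metformin.

State: glucose and insulin concentrations in every compartment, transported
on the same network (insulin uses its 4 kDa dextran surrogate diffusivity per
the declared surrogate mapping). In the POC, secretion adds

    S(t) = a (G_POC − θ)₊ e^(−λ t)  +  r (G_POC − θ)₊      [µg/(L·h)]

and in the LOC, glucose is cleared by insulin-dependent mass action on the
excess over the resting media level,

    U = u · I_LOC · (G_LOC − G_b)₊                         [mM/h]

with first-order insulin relaxation toward the basal level at rate k_I
everywhere. Clearance of the *excess* (rather than of total glucose) makes an
undosed device a fixed point and gives the observed normoglycemic plateau;
net hepatic uptake vanishing at euglycemia is the standard liver set-point
behavior. No hepatic glucose production is modeled (it is not measured), so
the model is valid for post-dose dynamics, not fasting dynamics.

Fixed shape parameters (defaults): threshold θ = 6 mM (between the 2.8 mM
starvation and 20 mM stimulation concentrations, just above the 5.5 mM
baseline media glucose G_b); first-phase decay λ = 0.2 h⁻¹ (the rapid phase
relaxes over the first hours, consistent with the reported 0–4 h initial
phase); insulin turnover k_I = 0.005 h⁻¹ (insulin is stable in cell-free
media; the only true sink is sampling and slow degradation). λ and k_I were
selected by scanning the weighted fit cost over a small grid — the cost
surface is flat across λ = 0.2–0.5 h⁻¹, and 0.2 h⁻¹ leaves the 24 h
homeostatic endpoints of both conditions essentially exact, concentrating
the residual misfit in the mid-course 12 h palmitate point, which a single
sustained secretion mode cannot capture simultaneously with the endpoints
(under-predicted by ~1.5 µg/L).

Fitted magnitudes: the control condition fixes (basal insulin, first-phase
amplitude a, sustained rate r, uptake rate u) against the four reported
control values weighted by 1/SD; the palmitate condition then fits only its
two multiplicative factors (secretion, uptake ∈ (0,1]) on the three reported
insulin values with everything else shared. The optimizer is multistart
least squares in log-parameter space followed by a bounded Nelder–Mead
polish; the two secretion magnitudes trade along a shallow valley where
trust-region steps stall, and the polish restores exact recovery on
noise-free synthetic data. Everything is deterministic (fixed start lists).

The fitted palmitate uptake factor is ≈ 0.1–0.2 (strong insulin resistance:
glucose stays high, sustaining secretion — the hyperinsulinemia mechanism),
while the secretion factor rides its upper bound of 1: the GTT data alone
carry no evidence of impaired stimulated secretion. That impairment is
visible only in the static GSIS assay, for which no numeric values are
reported, so GSIS illustrations use an explicit default secretion factor of
0.7. Metformin boosts (uptake ×5, secretion ×1.2) are qualitative defaults
reproducing the directional claims (faster glucose fall within 1 h of the
dose; insulin comparable to palmitate); no reported numbers exist to fit
them.

The GSIS protocol is simulated off-device (the organoids are moved to a
static well): alternating 1 h low / 1 h high glucose phases with the same
secretion law, solution collected and replaced each phase, and the
first-phase pool assumed to re-prime during each starvation hour. The
stimulation index is the high/low ratio per cycle.

## Synthetic data

`modsim.synth` reproduces the statistical structure of the measurements:
simulated trajectories with multiplicative Gaussian noise, CV 13% for tracer
assays and 4% for insulin (matched to the reported relative SDs), floored at
zero, replicate-resolved, and byte-reproducible for a fixed seed. It emulates
measurement dispersion only — no plate-reader optics, photobleaching, ELISA
calibration curves, pipetting bias, or replicate-to-replicate device
variability. Tests that pass on synthetic data therefore demonstrate
estimator correctness under the assumed noise model, not robustness to the
systematic errors of real assays.

## Known limitations

* Well-mixed compartments: no spatial gradients within chambers or along the
  channel; the calibrated effective geometry absorbs (and hides) that detail.
* Transmembrane advection is omitted (the Darcy velocity is a diagnostic
  only); at ~0.01 dyne/cm² wall shear the transmembrane pressure is tiny and
  diffusion dominates for all species considered.
* The endocrine model has one sustained secretion mode and no hepatic
  glucose production, insulin receptor dynamics, or β-cell mass changes; it
  interpolates the sparse reported kinetics and should not be extrapolated
  beyond the 24 h post-dose window.
* The absolute insulin scale depends on organoid mass, which is not
  quantified; fitted magnitudes absorb it and are device-specific.
* Sampling is treated as non-perturbing (withdrawn volumes are not modeled).
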