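# Methods

## The model

`saim` simulates translation-invariant object selection and identification
in small binary scenes by energy minimisation, in two architecturally
distinct variants that differ only in the sign and form of their top-down
coupling.

Three networks share one objective. The **Selection Network (SN)** has one
sigmoidal unit per valid placement of an M×M focus window on an N×N image
((N−M+1)² units); it implements a winner-take-all over candidate locations.
The **Contents Network (CN)** is the M×M focus-of-attention itself: linear
units whose output equals their potential. The **Knowledge Network (KN)**
has one sigmoidal unit per stored template. Rates and potentials are linked
by the logistic `y = 1/(1 + exp(−m (x − s)))`; every sigmoidal unit carries
a membrane energy `∫₀^y f⁻¹(z)dz` (closed form
`s·y + [y ln y + (1−y) ln(1−y)]/m`, validated against quadrature in the
tests), whose gradient yields leaky-integrator dynamics. The Contents
analogue is `x²/2`. Competing populations carry the WTA energy
`a/2 (Σy − 1)² − b Σ y·I`; flipping the sign of the input term turns the
winner-take-all into a loser-take-all.

The image enters through Sigma-pi (multiplicative) gating: the gated input
to the focus is `I[m,n] = Σ_rc y_SN[r,c] · image[r+m, c+n]`, i.e. the
selection-weighted average of all M×M windows. Selection units are indexed
by top-left window corners, so every product pairs a placement with a pixel
inside its window and no out-of-range index arises; the correlation term in
the Selection gradient is the exact adjoint of this gating (a property the
tests assert directly), which settles the index-convention question the
two-dimensional index arithmetic leaves open.

**Excitatory matching (EM).** The total energy couples the networks with
negative (excitatory) inter-network terms: the focus is driven by the gated
image and by a template-weighted top-down sum; the Selection layer by the
correlation of the focus with every window; the Knowledge layer by the
scalar product of the focus with each template's weights. Gradients of all
terms are taken analytically and verified against central finite
differences (worst relative error ~1e−9; tolerance 1e−6). The non-membrane
energy components, negated, read as a generative model: the focus/image
term is a log-likelihood and the normalisation quadratics are sparse
priors; `log_density_components` exposes this reading without extra
computation.

**Prediction error (PE).** Under Gaussian assumptions the inter-network
energies become half-squared prediction errors:
`ε_CN = I − x_CN` (the focus's prediction of the gated input) and
`ε_KN[k] = x_CN − y_k·w_k` (each template unit's prediction of the focus).
All gradients are the exact derivatives of this free energy; the
finite-difference oracle pins the assembly down. One sign deserves note:
because `ε_KN[k]` depends on `y_k` through the subtracted prediction, the
chain rule gives the Knowledge gradient the term `−b_KN Σ ε_KN[k]·w_k`,
and it is this sign that makes the best-predicting unit rise (its growing
prediction consumes its own error). With the opposite sign the
worst-matching template would win, which contradicts the behaviour this
family of models is defined to produce; the derivative-consistent sign is
therefore used. The Contents gradient's error sum over templates carries no
extra template weighting — that is already the exact derivative.

**Integration.** Both variants use the same explicit Euler rule
`x ← x − η·∇E + ξ`, `ξ ~ N(0, σ)` i.i.d. per unit and iteration (σ is
interpreted as a standard deviation; the noise is applied to every network,
including the Contents units, and is *not* scaled by η). The gradient is
taken with respect to rates but applied to potentials, which preserves the
Lyapunov property: at σ = 0, `dE/dt = −Σ f′(x) (∂E/∂y)² ≤ 0`, and the
discrete scheme inherits descent for small steps (checked over 100-step
runs; halving η must shrink any violation). All randomness flows through a
single seeded generator, so every run is bit-reproducible from
(configuration, seed).

**Initialisation** is unbiased: template rates 1/K, selection rates
1/(#placements) (potentials via the inverse sigmoid), and the focus set to
the mean of the template weight maps.

**Reaction time** is the first iteration at which any Knowledge unit's rate
reaches the threshold θ (0.9 for EM, 0.56 for PE); ties break toward the
lowest template index. A run that never crosses within `max_iters` is
flagged timed out with undefined RT.

## Stimuli

Templates are deterministic glyph constructions: a centred cross ("plus",
2M−1 pixels when thin; arm thickness configurable, including an
unequal-arms `(3,1)` form that carries exactly the 4M−3 pixels of the
digit) and a digit-2 ("two": top, middle and bottom bars plus two
descenders). Scenes stamp templates onto a zero background by elementwise
maximum, with 0-based (row, col) top-left coordinates; composition is
permutation-invariant and exactly translation-covariant. The reference
scenes are a centred single cross, a centred single two, and a two-object
scene with the cross left and the two right, disjoint, on a 21×21 image
with M = 7.

Template *weights* (the Knowledge synapses and top-down maps) are the
bitmaps scaled by `(ink)^−α`. The exponent α balances two standing
asymmetries between glyphs of unequal ink: at α = ½ all self-matches are
equal; larger α handicaps heavier templates' bottom-up match; α = 0 keeps
raw pixel counts. It is part of each variant's calibrated reference
configuration.

## Calibration and reference configurations

The original study's scalar parameter values are not publicly available,
so each variant ships a reference configuration calibrated once against
the study's *qualitative* criteria —
correct noiseless winners on single-object scenes; over 20-run seeded
batches, two-object scenes slowest with significant contrasts; zero
single-stimulus errors — and, where attainable, the printed reaction-time
scale. `saim.calibrate` exposes the evaluation and a grid search so the
procedure is reproducible.

**EM reference** (`reference_params("em")`): thick cross (33 px) vs two
(25 px), α = 0.8, m = 5.2, s = 0, b_CN = 0.15, b_KN = 2.5, a_SN = 2,
a_KN = 4.5, η = 0.0157, σ = 0.0025, θ = 0.9. Mechanistically, the heavier
cross wins the location competition while the sub-linear weight scaling
keeps the Knowledge race close, producing the ordering
RT(+) < RT(2) < RT(+/2) at roughly the published magnitudes, zero errors,
and an always-cross two-object outcome. The two-object cost arises from a
slow overtaking race: early in the run the blended focus actually favours
the two's template; the cross's unit overtakes only once selection has
concentrated on its location.

**PE reference** (`reference_params("pe")`): equal-ink glyphs (cross
`(3,1)`, 25 px each), raw binary weights, m = 4, s = 0, b_CN = 30,
b_KN = 10, a_SN = 5, a_KN = 3000, η = 1e−4, σ = 0.005, θ = 0.56. The stiff
Knowledge normalisation pins the rate sum at one without stiffening the
decision (difference) mode; θ sits just above the winners' deterministic
attractors, so crossing is noise-assisted first passage — fast where the
stimulus evidence is strong (singles), very slow where the two objects
balance (two-object scenes). RT distributions are therefore passage-time
shaped: right-skewed with standard deviations comparable to their means.

Known limitations of the PE calibration, established by systematic
exploration rather than assumed: (i) error-driven selection is homeostatic
(its drive vanishes as predictions match input), capping selection
concentration and hence the bottom-up Knowledge evidence; (ii) the initial
combined-template prediction biases the Knowledge race toward whichever
glyph absorbs the blend better, so with unequal-ink glyphs single-object
identification and the two-object cross preference cannot both be
satisfied, and with equal-ink glyphs the two-object winner is left to
noise (roughly even split). Consequently the PE variant reproduces the
cost, the zero single-stimulus error rate and the significant
two-object-vs-cross contrast, but not a deterministic cross win nor the
published exemplar reaction-time magnitudes. The neuronal-response
directions (falling EM, rising PE summed activation) are likewise
amplitude-regime properties that this calibration inverts: our EM starts
well below its attractor's drive scale and grows; our PE opens with a
large unmatched-prediction transient and decays.

## Experiments and summaries

`run_batch` runs seeds `base_seed … base_seed+n−1`; `compare_study` runs
the three reference conditions (20 runs each by default) and applies
two-sided pooled-variance t-tests (df = n_a + n_b − 2, matching the
published df = 38), implemented from the pooled formula and cross-checked
against an independent statistical library in the tests.
`neuronal_response` sums, per iteration and per layer (Selection and
Knowledge; Contents excluded as pixel-driven), the output rates plus the
magnitude of the b-weighted between-network drive terms — leak and
normalisation terms are excluded as stand-ins for local interneuron
activity. Summing signed rather than rectified drives is a switch
(`rectified=False`); rectified is the default.

The PE/EM winner-agreement property on noiseless single-object scenes is
checked through the PE variant's leading template unit (argmax of the
converged rates), since the PE reference's threshold crossing is
noise-assisted and does not occur at σ = 0.

## Numerical choices and edge cases

Logistic evaluation clips the exponent argument at ±500; the inverse
sigmoid and the membrane energy reject rates at {0, 1} (the energy
diverges there). Gradient non-finiteness aborts a run with the offending
network named; the run is reported as timed out/diverged rather than
raising into batch aggregation. Exact translation invariance holds for
objects whose full placement neighbourhood lies inside the grid (at least
M−1 pixels from the border); nearer the border the competitive surround is
clipped and reaction times shift slightly. Batch seeds are consecutive
integers from one base seed; per-condition blocks in the acceptance script
are disjoint.

## What the synthetic stimuli do and do not show

The generator emulates the published paradigm exactly as specified — small
binary glyph scenes with perfectly matching templates — which is also its
limit: conclusions about noisy, greyscale, cluttered or non-matching
stimuli, perceptual grouping, or more than two templates (supported
generically but not exercised by the reference study) do not follow from
these tests.
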