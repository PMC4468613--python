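# Methods

## Signal model

Each channel's oxy-hemoglobin series on the sample grid `t_k = k/fs`
(seconds) is modelled as a linear combination of a task-evoked response,
three physiological sinusoids and a baseline:

    y(k) = a0 + a1·HRF(k)
         + a_c sin(2π f_c t_k) + a_r sin(2π f_r t_k) + a_m sin(2π f_m t_k)
         + ε(k),        ε ~ N(0, σ²) i.i.d.

`HRF(k) = (h ∗ u)(k)` is the causal discrete convolution of the canonical
double-gamma HRF `h` with the 0/1 boxcar `u`, both sampled on the paradigm
grid and truncated to its length.  Two conventions are fixed once and used
identically by the generator and the fitter, so the scale of `a1` is
internally consistent:

- no Δt scaling and no HRF normalisation is applied to the convolution;
- time in the sinusoids is in seconds, so all three frequencies are in Hz
  (the admissible cardiac band 0.5–1.5 only makes physiological sense in
  Hz).

`h(t) = t^(α1−1) β1^α1 e^(−β1 t)/Γ(α1) − t^(α2−1) β2^α2 e^(−β2 t)/(6 Γ(α2))`.
The 1/6 undershoot divisor is part of the model definition.  At β2 = 0 the
undershoot term is defined as identically zero (the continuous limit of
β2^α2 → 0 for α2 ≥ 6), avoiding 0^0-style indeterminacy.  `h` is evaluated
on the full paradigm grid with no separate truncation window: the series is
only 50 s, and a shorter support would distort the undershoot.

### Parameters and bounds

All twelve free parameters, canonical order and default box:

| parameter | meaning | bounds | unit |
|---|---|---|---|
| α1 | delay of response | [2, 10] | shape (s-scale) |
| α2 | delay of undershoot | [6, 20] | shape (s-scale) |
| β1 | dispersion of response | [0.5, 2] | 1/s |
| β2 | dispersion of undershoot | [0, 1.5] | 1/s |
| a0 | baseline | [0, 20] | signal units |
| a1 | activity strength | [0, 15] | signal units |
| a_c, a_m, a_r | sinusoid amplitudes | [0, 2] | signal units |
| f_c | cardiac frequency | [0.5, 1.5] | Hz |
| f_r | respiratory frequency | [0.2, 0.3] | Hz |
| f_m | Mayer-wave frequency | [0.09, 0.1] | Hz |

The default paradigm is a single 10 s rest / 10 s task / 30 s rest block
sampled at 1.81 Hz (90 samples).  Note that the Nyquist frequency is then
0.905 Hz while the cardiac band extends to 1.5 Hz: super-Nyquist cardiac
components alias onto `fs − f` with a sign flip.  The model is fitted as
written; aliasing is documented, not corrected.

## Optimization

`J(x) = Σ_k (y(k) − ŷ_x(k))²` is minimised over the box by a from-scratch
Nelder–Mead simplex:

- **Normalisation.** The search runs in box-normalised coordinates (each
  parameter mapped to [0, 1]), so a single scalar simplex edge length is
  meaningful across parameters whose ranges differ by two orders of
  magnitude.  Zero-width bounds freeze a parameter.
- **Initial simplex.** Spendley's regular simplex of edge `a` (default 0.1
  normalised): vertex j = x0 + p·e_j + Σ_{k≠j} q·e_k with
  p = a/(n√2)(√(n+1)+n−1), q = a/(n√2)(√(n+1)−1); x0 is kept as the
  (n+1)-th vertex; vertices are clipped to the box.
- **Step logic.** Standard ordering / centroid-of-all-but-worst /
  reflection–expansion–contraction–shrink with coefficients
  (δ1, δ2, δ3, δ4) = (1, 2, 0.5, 0.5).  The textbook forms
  x_r = x̄ + δ1(x̄ − x_h) and x_i ← x_l + δ4(x_i − x_l) are used; the
  frequently reprinted variant x_r = x̄ + δ1(x_h − x̄) is degenerate (it
  returns the worst vertex itself at δ1 = 1) and is deliberately not
  implemented.  Every candidate is projected componentwise onto the box
  *before* evaluation, so the cost is never evaluated outside the bounds;
  non-finite costs are treated as +∞ (candidate rejected).  Ties in the
  vertex ordering break by vertex index (stable sort).
- **Restart polishing.** A single simplex collapse in 12 dimensions
  routinely stalls short of the optimum.  Each start is therefore an
  *iterated* NM: run to the tol_x/tol_f stopping rule, re-seed a fresh
  simplex at the incumbent, keep the edge length while rounds improve
  materially (> 0.1% of J) and otherwise shrink it by 4× down to a floor
  of 1e−5, within a per-start budget of `max_iter` (default 5000)
  iterations.  Uninterrupted rounds matter: the simplex must be allowed to
  adapt to valley anisotropy before it is re-seeded.
- **Multi-start.** `n_restarts` (default 10) starts: the default start
  (literature HRF shape α1 = 6, α2 = 16, β1 = β2 = 1; a0 = mean(y);
  a1 = 1; amplitudes 0.5; band-midpoint frequencies), followed by
  data-informed starts, then uniform draws inside the box from the seeded
  generator.  The best final cost wins.  Identical seeds give bit-identical
  results.
- **Convergence.** tol_x = 1e−6 on the normalised simplex diameter and
  tol_f = 1e−10 on the value spread.

### Data-informed starts

The cost surface is severely multimodal in the cardiac frequency: over a
50 s record the valley around the true f_c is only ~±0.02 Hz wide within a
1 Hz admissible band, so uniformly drawn starts almost never land in it
and plain multi-start NM converges to minima with the cardiac term zeroed.
`fit_single_channel` therefore seeds two extra starts per channel: each
frequency is located by scanning its band on a fine grid and scoring the
squared projection of the de-trended data (baseline + default-shape evoked
response removed by least squares) onto the sampled sine — a scan that
handles super-Nyquist aliasing automatically — and the five linear
coefficients are then set by ordinary least squares at the default HRF
shape, clipped to the box.  The two best-scoring, well-separated cardiac
candidates hedge against the alias ambiguity.  These are starting points
only; the bounded simplex still fits all 12 parameters jointly from every
start.

## Activation statistics

Channel activation is a one-sided test of H0: a1 = 0 against a1 > 0
(activation increases HbO and the fit constrains a1 ≥ 0):

    t = a1* / SE(a1*),   significant ⟺ t > t_crit(α) and p < α  (strict).

SE(a1*) comes from the model linearized at the fitted nonlinear
parameters: with shape and frequencies fixed at their optima the model is
OLS in the five linear coefficients with design
X = [1, HRF*, sin(2π f_c* t), sin(2π f_r* t), sin(2π f_m* t)], and

    SE(a1*) = sqrt(σ̂² [(XᵀX)⁻¹]_HRF),   σ̂² = SSR/(N − p),  p = 12.

Charging all 12 fitted parameters to the residual dof is conservative.  A
perfect fit (SSR = 0) is reported with the sentinel t = +∞.  Coincident
fitted frequencies make X rank deficient and raise an explicit
collinearity error.  No multiple-comparison correction is applied by
default (an optional Bonferroni flag divides α by the channel count).

Two caveats are inherent to the procedure and deliberately not patched:

- the constraint a1 ≥ 0 truncates the null distribution of a1* at zero, so
  the nominal one-sided test is only exactly calibrated for the linearized
  (unconstrained) estimator — which is what the type-I calibration test
  exercises;
- the 12-parameter shape search can align the evoked regressor with noise
  on null channels, inflating their t-values (measured: null t up to ~2.2
  at a nominal t_crit of 1.66).  Detection contrasts remain huge (an
  injected active channel reaches t in the hundreds at high SNR); screens
  over a montage should use the Bonferroni flag.

## Synthetic data

`simulate` adds i.i.d. N(0, σ²) noise to the noiseless model signal;
identical seeds give bit-identical series.  `reference_suite` generates the 15
packaged reference parameter sets (spanning response delays 3–9 s,
undershoot delays 7–18, baselines 7–15, strengths 3–10, and physiological
frequencies f_c 0.7–1.2 Hz, f_r 0.2–0.3 Hz, f_m 0.02–0.09 Hz), splitting
one master seed into independent per-dataset streams.  The default noise
sd is 0.2 signal units — small relative to the activity strengths (3–10)
— and is configurable.

Two modelling facts shape what recovery experiments can show:

- **Truth outside the fit box.** Thirteen of the 15 reference Mayer
  frequencies lie below the admissible band [0.09, 0.1] Hz (and the
  generator intentionally does not clip truth to the fit box).  For those
  datasets the constrained optimum cannot reproduce the generated signal:
  even noiseless fits have J of order 3–50, and the optimizer compensates
  the unmatchable slow Mayer component by bending the undershoot, which
  displaces α2 (often to its bound) and drags α1/β1 with it.  Recovery of
  the undershoot on such datasets is structurally impossible under the
  box; only datasets 2 and 10 (truth fully inside the box) admit exact
  noiseless self-consistency, and the fitter reaches J ~ 1e−10 with shape
  errors ~1e−4 on them.
- **Weak identifiability at finite noise.** On a single 50 s block the
  undershoot parameters are nearly flat directions of J: moving α2 from 17
  to 20 (all else at truth) changes J by ~1.1, while noise at sd 0.2
  contributes ~3.6 ± 1.7.  At that noise level the global minimiser's α2
  therefore scatters by several units across noise seeds no matter how
  good the optimizer is (cross-checked against differential evolution,
  which attains equal or lower J with no smaller parameter errors).  The
  baseline and activity strength, by contrast, recover to ~0.02–0.05.
  Tight recovery of all six shape/linear parameters is only observed as
  noise → 0.

The generator emulates stationary sinusoidal physiology and white Gaussian
noise; real fNIRS data additionally contain serially correlated (1/f)
noise, motion artifacts, frequency drift of the physiological rhythms and
superficial-layer contamination.  Passing recovery tests on these
simulations validates the estimation machinery, not robustness to those
real-data features.

## MBLL preprocessing

Dual-wavelength optical-density changes are converted to relative ΔHbO/ΔHbR
via the closed-form two-wavelength modified Beer–Lambert solution with the
shared denominator l·(ε_HbR^λ1 ε_HbO^λ2 − ε_HbR^λ2 ε_HbO^λ1).  Defaults:
extinction coefficients 1.486/3.843 (760 nm HbO/HbR) and 2.231/1.791
(830 nm), printed without units in the instrument literature — outputs are
therefore in arbitrary relative concentration units, which is sufficient
because only relative changes enter the model; differential pathlength
factors 7.25/6.38 (760/830 nm, configurable — the conversion is
DPF-agnostic in structure); source–detector separation 3 cm, overridable
per channel.  A singular extinction pair (wavelengths that cannot separate
the chromophores) raises an explicit error.

## Problem sizes and runtime choices

Tests and the acceptance script use the native study scale: 90-sample
series, 12-dimensional fits, best-of-10 restarts (~4 s per channel fit on
one core).  The seed-robustness checks use 10 noise seeds per dataset; the
type-I calibration uses 1000 linearized simulations; the Monte-Carlo SE
scaling check uses 100 seeds; multi-channel map checks use 16 channels
with a reduced restart count (2–3), which is ample at their high SNR.

## Known limitations

- Single-block box-car designs only; no event-related basis sets or
  multi-condition designs.
- HbR series are produced by the MBLL step but the model is fitted to HbO.
- No serial-correlation correction (pre-whitening) in the t-statistics.
- Physiological frequencies near or above Nyquist are reported as fitted,
  aliasing included; interpret f_c with care at low sampling rates.
- The grid map renderer draws the 16-channel montage; it performs no
  anatomical registration.
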