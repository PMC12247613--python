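# Methods

## Signal model

The tissue is modelled as two well-mixed exchanging water pools in the
barrier-limited (Kärger) regime. Pool magnetizations evolve as
**S**′(t) = −**M S**(t) with

    M = [ q²·D_i·u² + k_ie     −k_ei        ]
        [ −k_ie                q²·D_e + k_ei ],

where u = g·n is the cosine between gradient and stick axis, q² = b/t_d
(narrow-pulse convention, t_d ≡ Δ; the finite gradient duration δ is
carried only as protocol metadata), and the exchange rates obey detailed
balance, k_ie = (1−f)/t_ex, k_ei = f/t_ex, so that 1/t_ex = k_ie + k_ei.
The directional signal is 1ᵀ·exp(−M·t_d)·(f, 1−f)ᵀ, evaluated in closed
form from the 2×2 eigenstructure: with x = (a−d)/2 and
s = √(x² + k_ie·k_ei),

    S(u) = (E₋+E₊)/2 − C·(E₋−E₊)/(2s),    E∓ = e^{−λ∓ t_d},  λ∓ = (a+d)/2 ∓ s,
    C    = f·q²·D_i·u² + (1−f)·q²·D_e − (a+d)/2.

Both eigenvalues are non-negative, so only decaying exponentials appear
and no overflow is possible. When s·t_d < 10⁻⁹ (coincident eigenvalues,
reachable only in degenerate limits) the difference quotient is replaced
by its limit t_d·e^{−(a+d)t_d/2}. The implementation is verified against
a generic matrix-exponential oracle to ≤10⁻¹⁰ over the full parameter box.

The powder-average (spherical-mean) signal is ∫₀¹ S(u) du, computed by
fixed-order Gauss–Legendre quadrature mapped to [0, 1] (default 64 nodes;
64 vs 501 nodes agree to ≤10⁻⁹ over the studied b ≤ 7.5 ms/µm² range).
Because the weights sum to one, S̄(b=0) = 1 exactly.

**Dot compartment.** A stationary pool of fraction f_dot adds an offset:
S̄_dot = (1−f_dot)·S̄ + f_dot. The asymptote S̄_dot → f_dot is approached
at the stick powder-average rate √(π/(4 b D_i)) ∝ b^{−1/2}, not
exponentially — relevant when interpreting high-b tails.

**Rician mean.** For magnitude data with normalized Gaussian noise level
σ per channel, the expected magnitude of a signal S is
√(π/2)·σ·L_{1/2}(−S²/(2σ²)). L_{1/2}(−t) is evaluated as
e^{−t/2}[(1+t)·I₀(t/2) + t·I₁(t/2)] with exponentially scaled Bessel
functions (no overflow at any SNR); below S/σ = 10⁻⁶ the floor
√(π/2)·σ is returned directly. The transform's high-SNR bias follows
σ²/(2S); note that at σ = 0.03 the bias at S = 20σ is still ≈ 7.5×10⁻⁴,
i.e. the "identity regime" is approached only quadratically in 1/SNR.

**Variants.** NEXI (4 parameters), NEXI_dot (5), and their Rician-mean
versions NEXI_RM / NEXI_dot_RM, which wrap the corresponding noise-free
prediction in the transform above with σ a *fixed input*, never a fitted
parameter.

### Validity of the barrier-limited regime

`exchange_validity_times` reports the characteristic compartment
equilibration times for neurite diameter d: t_c,i = d²/(2·D_i) (≈0.25 ms
for d = 1 µm, D_i = 2 µm²/ms) and t_c,e = d²/(2·D_e)·π/f (≈7.5 ms for
cortical values D_e ≈ 0.7, f ≈ 0.3). The printed source of the
extra-neurite expression is typographically ambiguous; the form above is
the one consistent with the quoted ≈7.5 ms, and the alternative reading
d²/(2·D_e·π·f) is available via `extra_neurite_form="inverse"`. The
Kärger description requires both ≪ t_ex.

## Synthetic data

`connectom_protocol()` encodes the study protocol: b = 1, 2.5, 4, 6,
7.5 ms/µm² with 13/25/25/32/65 directions at each of Δ = 20, 29, 39,
49 ms plus 15 b = 0 volumes per Δ (700 volumes; 112 at b ≤ 1), δ = 9 ms.

Three ground-truth families (uniform draws):

| dataset | t_ex (ms) | D_i | D_e | f | f_dot |
|---|---|---|---|---|---|
| 1 (broad) | [1, 150] | [0.1, 3.5] | [0.1, 3.5], D_i > D_e by rejection | [0.1, 0.9] | — |
| 2 (cortex-like) | [1, 110] | [2.5, 3.5] | [0.5, 1.5] | [0.3, 0.5] | — |
| 3 (cortex + dot) | [1, 110] | [2.5, 3.5] | [0.5, 1.5] | [0.3, 0.5] | [0, 0.1] |

Noise emulates powder averaging of magnitude images: per shell, 20
independent Rician realizations √((S̄+n₁)² + n₂²), n₁,n₂ ~ N(0, σ²), are
averaged. Averaging reduces the variance ∝ 1/20 but leaves the mean at
the Rician expectation of S̄ — the floor is *not* averaged away, which is
the premise of the RM variants. The default noise level is σ = 0.03
(SNR ≈ 34); a per-truth SNR sampler can be plugged in via `snr_sampler`.
What the generator does **not** emulate: per-direction signals (noise is
applied to the spherical mean directly), spatially correlated noise,
partial-volume mixing, or any residual preprocessing artifacts — so
passing tests bound estimator behaviour under ideal powder-averaged
conditions, not under full in-vivo nuisance structure. The fixed default
SNR also matters quantitatively: dot-model recovery errors shrink by
roughly a third when the SNR of the generator is raised from 34 to 50,
so absolute error tables are only comparable at matched SNR.

Reproducibility is per-truth: a master seed spawns one independent
`SeedSequence` child per ground truth, so truth *i* and its noise stream
are invariant to the total dataset size and to parallelism.

## Fitting

The objective is the mean squared error between the measured 20-point
powder-average vector and the model prediction. Minimization is
L-BFGS-B within box bounds (defaults t_ex [1, 150] ms, D_i and D_e
[0.1, 3.5] µm²/ms, f [0.1, 0.9], f_dot [10⁻⁴, 0.3]), with both function
and gradient tolerances set to 10⁻¹⁴ and parameters internally rescaled
to the unit box so those tolerances act uniformly. The D_i > D_e
constraint applies to ground-truth *sampling* only, never to fitting
(box bounds only) — the asymmetry is intentional and mirrors how such
fits are run in practice.

Initialization is a Cartesian grid over the box (t_ex log-spaced, 12
points; diffusivities and f linear, 8 points; f_dot 4), evaluated fully
vectorized; the NLS is refined from the k = 5 best nodes and the lowest
final MSE wins (`n_starts=1` recovers plain single-start behaviour).
These densities were chosen because coarser grids with a single start
measurably inflate parameter errors through local-minimum trapping —
with the settings above, noise-free recovery is exact to ≲10⁻⁵ relative
and noisy-data error medians are limited by the information content of
the data, not the optimizer. Grid ties are broken by the first node in
lexicographic order. Gradients use the analytic Jacobian of the closed
form (chain-ruled through the dot offset and the Rician mean via
dE/dS = √(π/2)·S/(2σ)·e^{−h}[I₀+I₁](h), h = S²/(4σ²)); it matches
central finite differences to ≤4×10⁻¹⁰ and is ~6× faster, which is what
makes multistart affordable. `gradient="numeric"` selects central
differences behind the same interface.

For RM variants σ is fixed per item (scalar, per-truth, or σ map). The
σ-overestimation study refits the same signals with σ scaled by 1.1/1.2/
1.5. Each `FitResult` carries estimates, MSE/RSS, AICc computed on the
n = 20 nonzero shells with k = 4 or 5 free parameters (σ not counted),
convergence metadata, and which parameters sit exactly on a bound.

## Kurtosis route to the exchange time

Per diffusion time, the powder-average signal at b ≤ 2.5 ms/µm²
(including the exact normalized b = 0 point) is fit to the cumulant form
ln S = ln S₀ − b·MD + (b²/6)·MD²·MK by iterated weighted linear least
squares (weights = squared predicted signals, two iterations). The decay
of MK with t_d is then fit as MK(t_d) ≈ K0·K_KM(t_d; t_ex) with

    K_KM(t) = 2·(t_ex/t)·[1 − (t_ex/t)·(1 − e^{−t/t_ex})],

which → 1 as t/t_ex → 0 and → 2·t_ex/t in the long-time limit. The
exponent is negative: the alternative sign printed in some sources
diverges with time and contradicts the defining decay of exchange
kurtosis. A free amplitude K0 is required — the printed shape is the
normalized kurtosis (→1 at t→0) and four MK values generically admit no
amplitude-free solution. Initialization scans 50 log-spaced t_ex
candidates with the closed-form-optimal K0 (the model is linear in K0),
followed by a bounded trust-region refinement; t_ex at its 300 ms upper
bound is flagged (`at_upper_bound`), which is the deterministic outcome
for time-independent MK.

**Limitation (spherical-mean reduction).** The cumulant of the powder
average contains a time-independent orientation-dispersion kurtosis
(variance of D_i·u² across directions) on top of the exchange decay.
Fitting the pure K0·K_KM shape therefore overestimates t_ex when the
stick fraction is large (≈3× at f = 0.4), while recovery is quantitative
(≲25%) in the low-dispersion regime. Full directional DKI, whose mean
kurtosis excludes inter-direction ADC variance, does not share this
bias; directional tensor estimation is out of scope here.

## Evaluation statistics

* **MedAE** — per-parameter median of |estimate − truth|; robust to the
  heavy-tailed errors bounded estimators produce near their box edges.
* **Binned error summaries** — median and IQR of the signed error in 10
  equal-width bins of the truth (count configurable), with the
  feasibility envelope (bound − bin center) reported per bin; bins near
  a bound show the expected asymmetric, envelope-clipped distributions.
* **AICc** — n·ln(rss/n) + 2k + 2k(k+1)/(n−k−1) on the 20 shell points;
  at equal RSS the 5-parameter dot variants are penalized by
  construction, so nested noiseless data never prefer them.
* **Dot-vs-floor diagnostic** — fitted f_dot against √(π/2)·σ: Pearson r,
  two-sample Kolmogorov–Smirnov statistic with the classical asymptotic
  Kolmogorov p (implemented directly; the statistic matches scipy
  exactly, the p-value differs from scipy's finite-n refinement only at
  O(n^{−1/2})), mean difference and limits of agreement. On dot-free
  cortex-like data the fitted f_dot tracks σ and sits systematically
  below the floor — the signature that the dot pool is absorbing the
  un-modelled Rician bias.
* **Bland–Altman** — mean difference and mean ± 1.96·SD limits of paired
  estimates, with per-pair means retained for plotting; the synthetic
  scan-rescan surrogate refits two independent noise realizations of the
  same truths.

## Problem sizes and numerical defaults

The shipped test suite regenerates the study at reduced scale — n = 1000
broad-prior truths (with the 1.0/1.1/1.2/1.5 σ-inflation refits) and
n = 500 cortex-like truths per dataset for the four-variant cross table —
sizes at which the reported medians are stable to a few percent while the
whole suite runs in minutes on one CPU. Quadrature order 64,
L-BFGS-B ftol = gtol = 10⁻¹⁴, max 500 iterations, grid/multistart
defaults as above. The compiled (numba) kernel and the pure-numpy
reference implement identical arithmetic and are cross-checked in the
tests; without numba everything runs, only slower.

## Known limitations

* Narrow-pulse mapping b = q²·Δ ignores the finite δ = 9 ms; kernels with
  explicit pulse-duration dependence are out of scope.
* Soma compartments (and their exchange) are not modelled; their signal
  is absorbed into the extra-neurite pool.
* σ must be supplied (map or scalar); Rician maximum-likelihood fitting
  and noise-map estimation are out of scope.
* The in-vivo pipeline expects preprocessed, powder-averaged-ready data;
  denoising, Gibbs/eddy/distortion correction and parcellation are
  upstream of this package.
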