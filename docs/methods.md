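# Methods

## The avalanche-superposition (CD) generator

The recorded signal is X(t) = Σ_s Σ_{i=1..q} h_{s,i} a_{s,i}(t − s), where at
every integer time step q avalanches start. Each avalanche has

* a lifetime L drawn from the density ∝ L^(−α) truncated to [1, L_c], sampled
  by inverse CDF: L = (1 − u(1 − L_c^(1−α)))^(1/(1−α)), u ~ U(0,1). Lifetimes
  are kept real-valued; the sample count is ⌈L⌉, while the height uses the
  unrounded L (this preserves the continuous power law at small L);
* a deterministic height h = L^β;
* a unit-mean profile a(t) = b(t)(1 + ε(t)), with b the parabola
  −4(t−1/2)² + 1 evaluated at window midpoints t_i = (i−1/2)/⌈L⌉ and
  normalized so the discrete mean is exactly 1 (so L = 1 is a single unit
  sample), the variance profile c = b, and ε zero-mean, unit-variance colored
  noise with power spectrum ∝ ω^(−β−1) — the within-avalanche fluctuation
  spectrum of a critical system. ε is synthesized spectrally (FFT of white
  noise, amplitude ∝ f^(−(β+1)/2), DC zeroed) at length ⌈L⌉ and regenerated
  independently per avalanche; below 4 samples the synthesis is degenerate and
  the profile is used noise-free.

Stationarity: avalanches are also initiated over the L_c steps before the
retained window (an avalanche can span at most L_c samples, so the retained
segment is exactly stationary); on top of that, the first `burn_in` retained
samples (default L_c) are discarded. Simulation is vectorized by grouping
avalanches by integer length — batched noise synthesis per length, then one
`bincount` scatter-add per ~4M sample-contributions. Expected cost is
q·(T + L_c)·E[L] sample-contributions; E[L] grows like L_c^(2−α) for α < 2,
which is why MU1 runs dominate the runtime.

`active_counts` reproduces the same lifetime draws and returns the number of
avalanches covering each retained time step (interval difference-array +
cumulative sum); its stationary mean is q·E[⌈L⌉], and for α < 2 it scales as
L_c^(2−α).

## The passive-filtering (PF) generator

Exponentially distributed bursts have the long-range behavior of white noise,
so the PF observable is modelled directly as Gaussian white noise shaped to a
1/ω^γ spectrum by the same spectral-synthesis filter, standardized to unit
variance. γ = 0 reduces to white noise; the raw DFA exponent follows
H = (γ + 1)/2.

## Narrowband components and envelopes

Band-passing uses Butterworth filters (SOS form), default order 2 per pass,
applied forward–backward (`sosfiltfilt`), so the effective order is 4 and the
phase is zero — the cross-correlation between input and output peaks at lag 0.
Envelopes are |analytic signal| via `scipy.signal.hilbert`. Band edges are
specified in one of three units (fraction of Nyquist, fraction of sampling
rate, hertz) because study protocols mix all three conventions; the internal
canonical unit is fraction of Nyquist. No edge-trimming is applied by default.

Spectra are Welch averaged periodograms (satisfying Parseval within a few
percent); the alpha-SNR surrogate is the ratio of integrated 8–13 Hz power to
integrated 5–16 Hz power — 5/11 ≈ 0.455 for a flat spectrum, → 1 for a pure
alpha oscillation.

## DFA, DCCA, ρ_DCCA

Profile: cumulative sum of the mean-subtracted series. Windows: disjoint,
taken from the start, trailing remainder discarded (⌊N/n⌋ windows of length
n); window sizes are log-spaced deduplicated integers. Detrending: ordinary
least squares polynomial of degree d (default 1) per window, computed via a QR
factorization of the Vandermonde basis on an abscissa scaled to [0, 1] for
conditioning. F²(n) is the grand mean of squared residuals; DCCA replaces
squares with cross-products (signed), so `dcca(x, x)` reproduces the DFA F²(n)
bit-for-bit. The Hurst estimate is the unweighted OLS slope of log F against
log n over the fit range (natural logs), with its standard error.

ρ(n) = F²_xy / √(F²_x F²_y) is clipped only within 1e−9 numerical slack; a
genuine violation of |ρ| ≤ 1 raises, since the grand-aggregated residual inner
products obey Cauchy–Schwarz exactly. Windows whose denominator vanishes
(constant profile) yield NaN. The tail gradient is the OLS slope of ρ against
log n over the largest k = 11 scales (all scales if fewer are available).

With d = 1, exponents up to ≈ 2 are measurable; H_raw formulas exceeding 2
(far MU1 corner) saturate. DFA-1 also underestimates slightly at very small
windows (n ≲ 30), so default grids start at n = 16 but validation fits use
n ≥ 32–100.

## Meta-universality classes

Boundary ties follow the defining inequalities (MU1 includes α = 2; MU3
includes β = α − 3; MU4 includes β = (α−3)/2); theoretical H_raw and H_amp are
continuous across the MU2/MU3 and MU3/MU4 boundaries. Derived exponents:
α′ = α, β′ = β/2 for filtered avalanches, and size exponents from
(α − 1)/(τ − 1) = β + 1 (primed analogue for τ′). Within MU2 the relations
invert: β = 2(H_raw − H_amp), α = 2(β + 2 − H_raw).

`consistent_classes` operationalizes inference from estimates: H_amp above
0.5 + band (default band 0.05) pins {MU2} (no other class can produce it);
H_amp ≈ 0.5 with largest-scale ρ ≥ 0.5 and non-negative gradient matches MU3
(subject to a permissive low-frequency qualifier, configurable, because the
MU3 ρ limit holds only for bands far below the 1/L_c scale); H_amp ≈ 0.5 with
small ρ leaves {PF, MU1, MU4}, which these statistics cannot separate. The
thresholds are configuration, chosen from the sampling variability seen in the
replicated studies, not constants of the theory.

## Study presets and problem sizes

* Examples (`fig6_config`): T = 40000, CD cases at L_c = 10⁴ (q = 5,
  β = 1, α ∈ {2.5, 1.5}), PF at γ = 1.9; bands [0.68, 0.72] and [0.78, 0.82]
  of Nyquist, envelope DFA windows 1000–9000, ρ grid 20–9000.
* PF replication: T = 15000, bands 0.29–0.31 and 0.39–0.41 of the sampling
  rate, γ ∈ {0.8, 1.8}, order ∈ {2, 4}, windows 10³–10⁴, 100 replications.
* Class sweep: α = 1.5…6.5, β = 0.25…3, T = 300000, L_c = 100000, q = 5,
  windows 100 to half the retained length (the nominal 2·10⁵ ceiling equals
  the retained length; half is the default cap, overridable). A `scale`
  parameter shrinks T, L_c and the window ceiling together for scaled-down
  runs; the window floor stays at 100 samples because it is set by the
  envelope decorrelation scale, not by T.
* Component protocol: bands 35–40, 60–65, 72–77 Hz at 200 Hz sampling,
  windows 1000–25000, tail gradient over the 11 largest scales; summaries use
  an exact binomial sign test for the fraction of H_amp > 0.5 and Spearman
  rank correlations.

Tests and the acceptance script run these at the smallest replication counts
that give stable means (chosen from the observed seed-to-seed spread: envelope
Hurst estimates scatter with σ ≈ 0.05–0.07 per run at T = 40000; largest-scale
ρ with σ ≈ 0.3 when only 3–4 windows fit).

## The synthetic component generator

`make_synthetic_components` emulates spatially filtered EEG components:
a unit-variance broadband core (CD- or PF-generated, default PF γ = 1.9,
200 Hz, 15 min), plus an `alpha_amp`-scaled 10 Hz tone whose amplitude is
modulated by sub-0.5 Hz low-passed noise (rectified at zero), plus white
measurement noise. The noise variance is solved in closed form from the
Welch PSD of the noiseless component so that the alpha-SNR surrogate hits the
requested target; targets outside the interval bounded by the noiseless ratio
and the white-noise value 5/11 raise with the feasible range. What it does not
emulate: spatial mixing and SSD filtering, line noise, artifacts,
non-stationary alpha power, or 1/f knees — so passing fixture tests show the
pipeline's statistical behavior, not robustness to real-EEG nuisances.

A practically important property (visible in the fixture tests): because the
1/f^γ core has little power above ~30 Hz, even modest white noise dominates
the high-frequency analysis bands and drives H_amp and ρ to their null values
long before it is obvious in the raw trace. This is the mechanism behind
correlating ρ with the alpha-SNR surrogate, and why the MU2 fixture checks use
noise-free components.

## Finite-size behavior and known limitations

* **MU2 envelope signature** is robust at desk scale: H_amp ≈ 1.0–1.15
  (theory 1.25) and largest-scale ρ ≈ 0.95–1.0 at T = 3·10⁵, L_c = 10⁵.
* **Raw-signal exponents converge much more slowly.** The within-avalanche
  noise of the numerous short avalanches forms a lower-H fluctuation floor at
  small scales, and window sizes approaching L_c sit in the cutoff-saturation
  regime, so fitted H_raw at accessible scales is well below β − α/2 + 2 with
  the noise term on. The formula is verified on the noise-free profile
  superposition with windows ≪ L_c (measured 1.64 ± 0.07 vs 1.75 at
  (α, β) = (2.5, 1), L_c = 10⁵). Consequently, inverting (Ĥ_raw, Ĥ_amp) for
  (α, β) in MU2 is strongly biased at desk scale — consistent with the known
  point that noise skews measured exponents toward 0.5.
* **The MU1 null is asymptotic in L_c.** At the example configuration
  (L_c = 10⁴, windows up to 9000), envelope co-fluctuations from cutoff-scale
  avalanches have not fully averaged out: a 100-seed ensemble gives mean
  H_amp = 0.542 and mean largest-scale ρ = 0.17 rather than exactly (0.5, 0).
  At L_c = 10⁵ the ρ bias is consistent with zero but the estimate keeps a
  seed-to-seed σ ≈ 0.23 because only 3–4 windows fit at the largest scale.
* ρ between envelopes of a single realization at the largest scale rests on
  ⌊N/n⌋ ≤ 4 windows in the example protocols; single-run values are
  qualitative, replicated means are the quantitative statements.
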