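# critband

Criticality vs. passive filtering in macroscopic neural signals, tested through
the long-range dynamics of narrowband amplitude envelopes.

## The problem

EEG/MEG power spectra follow a 1/f^γ power law. Two competing explanations:

* **Critical dynamics (CD)** — the signal is a linear superposition of
  neuronal avalanches whose lifetimes follow a power law p(L) ∝ L^(−α)
  (truncated at a cutoff L_c set by system size) and whose heights scale as
  h = L^β.
* **Passive filtering (PF)** — cortical activity is short-memory, and the 1/f^γ
  shape arises from linear filtering through extracellular tissue.

Both reproduce the power spectrum, so the spectrum cannot decide between them.
The discriminating observables live in the **amplitude envelopes of narrowband
components**: g_ω(X) = |f_ω(X) + iH(f_ω(X))|, with f_ω a zero-phase band-pass
and H the Hilbert transform. Linear filtering only reweights narrowbands, so
envelope dynamics are invariant under the PF filter — any long-range structure
in them must come from the generating process itself.

Two statistics quantify that structure:

* **DFA** (detrended fluctuation analysis): F²(n) is the grand mean of squared
  residuals of the degree-d detrended cumulative profile over disjoint windows
  of length n; the log–log slope of F(n) estimates the Hurst exponent H.
  H > 0.5 means long-range temporal correlations (LRTC).
* **ρ_DCCA(n)**: the detrended cross-correlation coefficient
  ρ(n) = F²_DCCA(n) / (F_DFA(n; x) · F_DFA(n; y)), a scale-dependent,
  trend-robust analogue of the Pearson correlation between two envelopes.

The exponent pair (α, β) partitions into **meta-universality classes** with
distinct envelope signatures (H_amp = envelope Hurst, ρ = limiting ρ_DCCA
between envelopes of two disjoint bands):

| class | region                        | H_raw          | H_amp              | ρ limit |
|-------|-------------------------------|----------------|--------------------|---------|
| MU1   | α ≤ 2                         | β − α/2 + 2    | 0.5                | 0       |
| MU2   | α > 2, β > α − 3              | β − α/2 + 2    | β/2 − α/2 + 2      | 1       |
| MU3   | α > 2, (α−3)/2 < β ≤ α − 3    | β − α/2 + 2    | 0.5                | 1 (low ω) |
| MU4   | α > 2, β ≤ (α−3)/2            | 0.5            | 0.5                | 0       |
| PF    | —                             | > 0.5          | 0.5                | 0       |

Only MU2 produces H_amp > 0.5 — so an elevated envelope Hurst exponent in data
is evidence for criticality in MU2 that passive filtering cannot mimic.

The package provides: the CD simulator (superposed parabola-shaped avalanches
with within-avalanche colored noise of spectrum ω^(−β−1)), the PF simulator
(spectrally shaped white noise), band-pass/Hilbert-envelope transformers, DFA
and DCCA estimators in scikit-learn style, the class table with predictions
and inversion, replicated study runners, and a synthetic generator for
EEG-like spatially filtered components (200 Hz, ~15 min, alpha rhythm,
controlled alpha-SNR).

## Worked example

```python
import numpy as np
from critband import CDParams, simulate_cd, band_envelope, BandSpec, rho_dcca, dfa

sig = simulate_cd(CDParams(alpha=2.5, beta=1.0, L_c=10_000, q=5, T=40_000, seed=0))
bands = [BandSpec(0.68, 0.72, unit="nyquist"), BandSpec(0.78, 0.82, unit="nyquist")]
e1, e2 = (band_envelope(sig, b) for b in bands)
h = dfa(e1, n_min=1000, n_max=9000, num=12).hurst_
cc = rho_dcca(e1, e2, n_min=20, n_max=9000, num=30)
print(f"H_amp = {h:.2f}, rho at n={cc.window_sizes_[-1]} = {cc.rho_[-1]:.2f}")
```

prints

```
H_amp = 0.68, rho at n=9000 = 0.86
```

The envelope Hurst exponent 0.68 is above the 0.5 chance level (theory for
this MU2 exemplar: β/2 − α/2 + 2 = 1.25; single short runs scatter widely and
are biased toward 0.5 — the replicated studies average near 1.0), and the
cross-band envelope correlation approaches 1 at large scales. The same pipeline
on a passive-filtering surrogate (`simulate_pf(PFParams(gamma=1.9, T=40_000))`)
yields H_amp ≈ 0.5 and ρ ≈ 0: the two hypotheses separate cleanly even though
their power spectra match. Theory-side, `classify --alpha 2.5 --beta 1`:

```
{"mu": "MU2", "h_raw": 1.75, "h_amp": 1.25, "rho_limit": 1, ...}
```

A CLI mirrors the library: `critband simulate-cd|simulate-pf|band-envelope|
dfa|dcca|classify|run-experiment` (see `--help`).

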