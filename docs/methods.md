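# Methods

## Signal model and scope

The package assumes a real-time AFM record of a scalar mechanical quantity —
per-curve total adhesion force (pN) or E-modulus (kPa) — sampled at a slow,
nominally constant rate (default 0.5 Hz, one sample per indent–retract
cycle) for tens of minutes. The working model is

x(t) = offset + slope·t + Σⱼ Aⱼ·sin(2πfⱼt + φⱼ) + ε(t),

with a small number of stationary sinusoids in the mHz band
(f ≈ 0.002–0.03 Hz for live cells) and additive white Gaussian noise ε.
The pipeline estimates the (fⱼ, Aⱼ, φⱼ) and the mean level; it does not
model amplitude envelopes, frequency drift, or 1/f noise (see Limitations).

## Preprocessing

Uneven series are linearly interpolated onto a uniform grid anchored at the
first timestamp, never extrapolating beyond the recorded span. Linear
interpolation is used because it adds no model assumptions and is exact for
the linear drift removed next. Drift is removed by an ordinary
least-squares line; the residual is standardized by its mean and *sample*
(ddof = 1) standard deviation. Computing the moments on the detrended
residuals (rather than the raw data) makes the standardized mean exactly
zero; subtracting the raw mean after removing a fitted line would
double-count the intercept. The fitted `TrendModel` is stored so every
downstream component can be restored to physical units exactly. A series
that is an exact line has zero residual variance and is rejected as
degenerate.

## SSA core

**Embedding.** The forward-backward trajectory matrix stacks, for window
order p, the N−p reversed lag windows (x_{p+i−1},…,x_i) on the N−p direct
windows (x_{j+1},…,x_{j+p}), giving a 2(N−p) × p matrix. Doubling the rows
this way is the standard device for stabilizing autoregressive estimates on
short records; here it likewise stabilizes the empirical lag covariance.
Default p = ⌊N/2⌋ (the half-length convention; configurable, since the
off-by-one choice p = N/2 vs N/2+1 is a matter of convention).

**Decomposition.** Eigentriples (λᵢ, Uᵢ, Vᵢ) are obtained from the thin SVD
of T (λᵢ = σᵢ²). This is algebraically identical to the eigendecomposition
of the covariance T·T′ but solves the smaller min-dimension problem in one
numerically stable step. Eigenvalues below 1e−12·λ₁ are treated as exact
zeros (floating-point rank decision).

**Signal/noise split.** Eigenvalues are sorted descending and accumulated;
the smallest prefix whose cumulative fraction reaches the threshold
(inclusive) is the signal subspace. Shipped thresholds are 0.6 for
stiffness and 0.1 for adhesion — the adhesion instrument path carries much
more background noise, so the biological signal accounts for a smaller
share of total variance there. Both are configuration values, and they
*are* regime calibrations: the right threshold equals the fraction of
variance the signal actually holds in a given instrument setup.

**Grouping.** A stationary sinusoid spans a near-degenerate eigenvalue
*pair*, so leading eigentriples are grouped pairwise, non-overlapping:
(1,2), (3,4), …, with a trailing singleton if the count is odd. (A naive
sliding pairing (1,2), (2,3), … would double-count eigentriples and is not
used.)

**Diagonal averaging.** The left-right flip of the forward block is a
Hankel embedding of series positions 1…N−1; the backward block is a Hankel
embedding of positions 2…N. Each block of a grouped matrix Y_I is averaged
over its anti-diagonals and the two length-(N−1) estimates are averaged
elementwise where both exist (the first and last samples come from a single
block). This is the unique blockwise scheme consistent with the embedding,
and it satisfies the binding correctness property: summing the
diagonal-averaged components over *all* eigentriples reproduces the input
series to machine precision (enforced in tests at 1e−8, observed ~1e−14).

## Periodicity detection

The filtered series (sum of leading groups) is Fourier transformed;
candidate components are strict local maxima of the one-sided power
spectrum, DC excluded. Three plausibility filters follow, in order:
duplicate suppression (of any two peaks closer than `min_separation`,
default 5 FFT bins ≈ 2.8 mHz at N = 900, only the stronger is kept — peaks
that close are unresolved images of one component), a frequency cutoff
(`max_freq`, default 0.1 Hz — faster oscillations are instrument artifacts,
well above the mHz band of live-cell mechanics), and a count limit
(`max_count`, default 2 leading components). Running duplicate suppression
before the cutoff makes the returned set monotone in `max_freq`.

**Well-posedness guard.** When the detector is asked for m components, the
pipeline retains at least m eigentriple pairs from the SSA step
(k ≥ 2·max_count) even if the threshold alone keeps fewer. The eigenvalue
threshold encodes the *noise regime*; on data where the signal holds a
large variance share (e.g. clean or strongly oscillating recordings) a
low-noise-regime threshold like 0.1 can be crossed by the very first
eigentriple, which would leave later components unrepresented in the
filtered series regardless of their reality. The guard only ever extends
the leading set, is inactive in the high-noise regime the thresholds are
calibrated for, and applies in the pipeline only — the library-level
`select_leading`/`ssa_filter` default to the pure threshold semantics.

**Parameter estimation.** Spectra are computed on the standardized scale,
but amplitudes are read off the physical-scale filtered series (component
values × residual std), so they come out in pN/kPa; each component's offset
is the raw series mean, and when m components are summed each contributes
offset/m so components and their sum oscillate about the same average
level. Phase is taken from arg(X_k) (mapped to the sine convention); it is
required for any meaningful component-sum reconstruction. Group summaries
average frequency, amplitude and offset arithmetically per rank across
cells (rank 1 = highest power in each cell); no pooled re-fit is attempted.

## Force-curve front end

Rupture detection scores sample-to-sample deflection increments in the
retract segment against a local baseline: an event requires the increment,
relative to the median increment of the preceding 20 samples, to exceed 5×
the robust noise scale (1.4826·MAD) of that window; consecutive
above-threshold increments merge into one event. Median-referencing makes a
smooth drift produce no events; the 5× factor is a conventional robust
outlier threshold and is configurable. Rupture force = spring constant ×
jump height; per-curve totals feed the adhesion series.

Stiffness uses the spherical-indenter Hertz law
F = (4/3)·E/(1−ν²)·√R·δ^{3/2} with indentation δ = (z − z_c) − d, fitted
for (E, z_c) by nonlinear least squares over the whole segment (pre-contact
samples contribute zero model force). Defaults: R = 2500 nm (5 µm bead),
ν = 0.5 (incompressible cell). At E = 10 kPa and δ = 200 nm this gives
~2.5 nN of loading force — the physiological operating point. Curves whose
fit fails are skipped; the resulting gaps are closed by the resampler.

## Synthetic data

The generator draws from the signal model above, seeded and fully
deterministic. Preset study conditions (chosen once, stated here as the
package's reference regimes):

| preset | offset | tones (Hz, amplitude) | drift | noise σ |
|---|---|---|---|---|
| live_adhesion | 65 pN | (0.0027, 10 pN), (0.0186, 5 pN) | −0.004 pN/s | 7.91 pN (SNR 1) |
| fixed_adhesion | 20 pN | none | 0 | 3 pN |
| live_stiffness | 10 kPa | (0.0027, 2 kPa), (0.0186, 1 kPa) | −0.0005 kPa/s | 1.29 kPa |
| gel_stiffness | 16 kPa | none | 0 | 0.5 kPa |

All presets run 1800 s at 0.5 Hz (N = 900). Live tone frequencies sit at
the representative component values for vascular smooth muscle cells; live
adhesion noise is set for SNR 1, and live stiffness noise leaves the signal
at ~60% of detrended variance, the regime its threshold targets. Fixed and
gel presets differ from live ones exactly as the controls do: lower mean
adhesion (fixation destroys most integrin binding capacity), no oscillatory
component. An optional raised-cosine envelope (off by default) mimics the
waxing/waning component amplitude seen in real recordings, to probe how the
stationary-sinusoid estimates degrade.

What the generator does **not** emulate: 1/f or correlated noise, frequency
drift, missing-data bursts, heteroscedastic noise, or mechanistic
acto-myosin dynamics. Passing tests therefore demonstrate correctness of
the decomposition and estimation machinery under the stated model, not
robustness to every pathology of instrument data.

## Numerical choices and problem sizes

- Uniformity tolerance on time grids: 1e−6 s; resampling is idempotent on
  already-uniform input.
- Rank cutoff 1e−12·λ₁; SVD-oracle equivalence is asserted at N ≤ 64, where
  the explicit matrix is cheap to build row by row.
- Monte-Carlo suites in the tests use 50 seeds at N = 400–900 (SSA) and 20
  paired seeds for live-vs-fixed discrimination; a full run of suite plus
  acceptance script takes well under a minute on one CPU.
- Degenerate inputs: exact lines are rejected at standardization; an empty
  peak list is a logged warning (a flat control *should* return nothing),
  not an error; empty rupture lists give zero adhesion with
  `probability_flag = False`.

## Limitations

- Stationary sinusoid model only; amplitude envelopes are visible in SSA
  components but not parameterized.
- The eigenvalue-fraction threshold is a per-setup calibration, not a
  universal constant; defaults encode the adhesion/stiffness regimes above.
- The Hertz front end assumes a spherical probe and a homogeneous,
  incompressible half-space; no viscoelastic or tip-shape corrections.
- Plot generation is left to the user; all outputs are delimited text
  tables (plus an optional HDF5 bundle for intermediates).
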