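# Methods

This note documents the statistical models, algorithmic conventions and
numerical choices implemented in `smburst`, and what a green test
establishes (and does not).

## Data model and photon streams

A spot holds sorted 64-bit integer timestamps (0-based at acquisition
start, `timestamps_unit` seconds per tick, typically 10–50 ns), per-photon
detector labels (donor/acceptor emission) and, for ns-ALEX, TCSPC
nanotimes.  Alternation is defined by a period and two half-open integer
phase ranges `D_ON` and `A_ON`; half-open `[start, stop)` avoids
double-counting boundary phases (the endpoint convention is otherwise
arbitrary).  Applying the alternation labels photons by phase (timestamp
mod period for μs-ALEX, nanotime for ns-ALEX) and removes photons outside
both ranges; re-application is refused because removal is destructive —
reload the file to change the ranges.

Photon streams select photons by emission channel × excitation period.
Without ALEX there are 3 canonical streams (all, Dem, Aem); with ALEX, 5
(all, DexDem, DexAem, AexDem, AexAem).  The four period×channel masks
partition the post-alternation photon set; arbitrary unions are allowed.

The HDF5 layout is a minimal subset of the Photon-HDF5 conventions
(`/photon_data[N]/timestamps`, `detectors`,
`timestamps_specs/timestamps_unit`, optional `nanotimes`, a two-code
spectral-channel map, and the alternation metadata).  Full Photon-HDF5
validation is out of scope; unknown groups are ignored with a warning.

## Background estimation

Inter-photon delays mix a fast component (molecule transits) with an
exponential tail from the Poisson background.  For delays above a
threshold `tail_min`, the left-truncated exponential MLE of the rate is

    λ̂ = 1 / ( mean(d_i | d_i ≥ tail_min) − tail_min ),

which the tests verify against a numeric maximizer of the truncated
log-likelihood to 1e-6 relative.  A least-squares alternative fits
log(histogram) over nonzero tail bins.

The automatic threshold iterates T₀ = 10·median(d), λ_k = MLE(d, T_k),
T_{k+1} = c/λ_k with c = 3, stopping when λ changes < 1%; the fixed point
puts the threshold ≈ 3 mean background delays out, excluding burst photons.
The iterate is capped so at least 2× the minimum tail-sample size
(10 delays, configurable) remains above it, which keeps the heuristic
defined on sparse streams.  This heuristic is a stand-in for more rigorous
optimal-threshold schemes; it is validated empirically (3% on pure
exponential data, 10% on burst-contaminated mixtures), not optimal.

Rates are computed per stream in consecutive windows of `window_s`
(default 30 s) anchored at t = 0; a final partial window shorter than
half a window is merged into the previous one.  A window boundary belongs
to the later window.  Windows with too few photons inherit the neighboring
window's rate with a logged warning — never a silent NaN.  Rates for
streams not estimated directly are sums of single-channel component rates;
the donor-emission-during-acceptor-excitation stream (pure background)
falls back to the residual total minus the three signal streams.

## Burst search

Photon `i` starts a *valid window* when `t[i+m−1] − t[i] ≤ m/λ_thr(t[i])`
(the `≤` and the evaluation of the threshold at the window's **first**
photon are fixed conventions; the background period of a window is that of
its first photon).  The threshold is `F ×` the local background rate of the
searched stream (defaults F = 6, m = 10) or a fixed `min_rate_cps`.  Valid
windows that **overlap** (share at least one photon) merge into one burst;
windows that merely touch end-to-start do not merge — two 4-photon clusters
separated by a long gap must remain two bursts even though their window
index ranges are contiguous.  Overlap-merging also guarantees
non-overlapping output intervals.  The minimum burst size is therefore
exactly m, and every burst's triggering window has rate ≥ F × local
background, hence SBR ≥ F − 1.  No burst fusion post-processing is applied.

The AND-gate (DCBS) search runs two independent searches (defaults: all
Dex photons; AexAem photons) and intersects the burst time intervals
`[max(starts), min(stops)]`; counts are recomputed on the intersections and
indices mapped to the all-photons stream.  This suppresses donor-only and
acceptor-only artifacts such as blinking.

Raw per-stream burst counts use the closed time interval
`[t_start, t_stop]`; the reference-stream count is definitional
(istop − istart + 1).

## Corrections

Order: background subtraction (rate of the period containing `t_start`
times burst width, per stream) → leakage/direct excitation on the
Dex-acceptor count, `na ← na − lk·nd − dir·naa` → γ-weighted derived
quantities.  Corrected counts are real-valued and may be slightly
negative; they are never clamped during computation (clamping would bias
population estimates).

The proximity ratio E_PR = na/(na+nd) is deliberately uncorrected:
detected Dex photons partition binomially with success probability E_PR,
so fitting the E_PR histogram and correcting the *population-level* value
avoids distorting the per-burst distribution.  The closed form

    E = [E_PR(lk + d_T·γ + 1) − lk − d_T·γ] / [E_PR(lk − γ + 1) − lk + γ]

uses the direct-excitation coefficient in the **total-size convention**
d_T, defined by dir·naa = d_T·(γ·nd + na_corr); the per-burst conversion
from the counts-level naa convention is provided
(`dir_ex_total_convention`).  The formula was re-derived symbolically from
the counts model (the derivation is replayed by a sympy-based test) and the
counts-level and population-level paths agree to 1e-9 on random bursts;
both reduce to the identity at γ = 1, lk = dir = 0.

The simulator injects leakage as per-photon misassignment with probability
lk/(1+lk) — because the coefficient is defined relative to *detected*
donor counts — so correction round trips have exact ground truth.

## Selection

Rules (size with optional γ and naa, naa, width, E–S rectangle) keep
bursts with the statistic in the closed interval [th1, th2]; bounds are
inclusive, the E–S region is rectangular.  Rules compose sequentially and
commute.  FRET-population isolation: a Dex-size threshold removes
acceptor-only bursts, then an naa threshold removes donor-only bursts.

## Population fitting

Bursts are weighted by γ-corrected size: the PR variance of a burst scales
as 1/size, so size weights match the inverse-variance structure; other
weightings are not supported.  Histograms use half-open bins
[e, e+binwidth) left-anchored at 0 with binwidth 0.03 by default (34 bins
on [0, 1.02) for E).  Bin uncertainties are compound-Poisson,
σ_bin = √(Σ w²), reducing to √count for unit weights; the fit and its
reduced χ²/AIC/BIC use the nonzero-mass bins (empty tail bins carry no
error model and would deflate χ²).  AIC/BIC follow the Gaussian-residual
convention n·ln(χ²/n) + 2k and + k·ln(n).

Peak models: 1–3 Gaussians and two Gaussians bridged by a plateau, B(x) =
1 on [μ₁, μ₂] with Gaussian roll-offs (σ₁ left, σ₂ right) scaled by a
fitted bridge amplitude — an empirical device that keeps the two centers on
the populations when intermediate-FRET bursts connect the peaks.  Factory
initial values: centers at weighted 25th/75th percentiles, σ = 0.05,
bounds μ ∈ [−0.1, 1.1], σ ∈ [0.005, 0.5]; components are relabeled after
fitting so centers are non-decreasing.

Weighted EM treats weights as case multiplicities; the M-step uses
weighted closed forms, the weighted log-likelihood is monotone (asserted in
tests), initialization is deterministic (weighted quantiles), convergence
at relative Δll < 1e-8 or 500 iterations, and a collapsing component
(σ < 1e-4) triggers one perturbed restart before erroring.

## Burst variance analysis

Bursts are re-indexed onto the Dex photon stream; each is cut into
consecutive chunks of exactly n = 7 photons from the first photon, the
trailing remainder dropped.  The chunk PR is the acceptor fraction; s_E is
the **population** standard deviation (denominator = number of chunks) of
the chunk PRs, matching the reference implementation's convention.  Bursts
with fewer than 2 chunks are excluded and logged rather than reported as
degenerate zeros.  Background photons inside chunks are neglected (they
are a small fraction of burst counts).

Under a static E_p the chunk acceptor count is B(n, E_p), so
Std(E_sub) = √(E_p(1−E_p)/n) = 0.1890 at E_p = 0.5, n = 7.  Note a known
finite-sample effect: the population std of k chunks has expectation below
the asymptotic value by roughly √((k−1)/k), so calibration against the
curve needs bursts with many chunks — the calibration tests select bursts
of γ-corrected size ≥ 50 (≈ 14 chunks, ratio ≈ 0.92), and the static
"fraction above the curve" sits slightly below 1/2 for the same reason.
The dynamic flag (s_E above the curve at the burst's mean sub-burst PR) is
a pragmatic indicator, not a calibrated hypothesis test.

## Simulator: what it emulates, and what not

Emulated: per-stream homogeneous Poisson background (exponential delay
tails); Poisson burst arrivals (1/s default) with exponential transit
durations (1 ms mean) and constant within-burst rate (100 kcps default,
50× the 2 kcps default background); binomial D/A partitioning at E_p;
excitation-period split at S_p; per-photon leakage/direct-excitation
misassignment; μs-ALEX phase structure (period 4000 ticks at 12.5 ns/tick
= 50 μs, D_ON = (2100, 3900), A_ON = (100, 1900)); two-state CTMC dynamics
within bursts (defaults for the dynamic tests: E 0.2 ↔ 0.8, 0.5 ms dwell —
a few interconversions per transit, squarely in BVA's detection regime).

Not emulated: the diffusion-shaped intensity profile of real transits
(rectangular profile instead), out-of-window background photons (all
simulated photons land inside an ON range, so alternation application
removes nothing on simulated data), detector afterpulsing and dead time,
spectral crosstalk beyond the single leakage coefficient, and multispot
optics.  Consequently a green test establishes correctness of the
*analysis chain under its own statistical assumptions*; it does not
validate against instrument non-idealities.

## Defaults (and why)

| parameter | default | rationale |
|---|---|---|
| background window | 30 s | background drifts on tens of seconds |
| tail_min | auto (c = 3) | threshold ≈ 3 mean background delays |
| m | 10 | standard sliding-window size (5–15 typical) |
| F | 6 | SBR ≥ 5 guarantee; typical range 4–9 |
| γ, lk, dir | 1, 0, 0 | identity corrections until calibrated |
| binwidth | 0.03 E-units | standard FRET histogram resolution |
| KDE bandwidth | 0.03 | matches binwidth |
| BVA n | 7 | standard sub-burst size |

## Known limitations

- The auto tail threshold is a convergent heuristic, not an optimality
  result; heavily burst-dominated streams push it to the sample-size cap.
- Corrected counts can be negative on dim bursts; derived E/S for
  near-zero denominators are NaN ("undefined") and must be filtered by the
  caller (selection by size does this naturally).
- The plateau model's bridge shape is an empirical stand-in; only its
  qualitative purpose (keeping centers on the peaks) is tested.
- BVA's finite-chunk bias (above) is inherent to the population-std
  convention; comparisons to the shot-noise curve should use size-selected
  bursts.
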