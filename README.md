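# smburst

Burst analysis for freely-diffusing single-molecule FRET (smFRET)
measurements.

In a confocal smFRET experiment, single labeled molecules diffuse through a
femtoliter excitation volume and each transit produces a *burst* of photons
recorded as integer timestamps with donor/acceptor detector labels.  With
alternating-laser excitation (μs-ALEX) each photon additionally belongs to a
donor- or acceptor-excitation period.  `smburst` implements the complete
analysis chain for such photon-timestamp data, for spectroscopists who want
a scriptable, testable pipeline:

1. **Photon streams** — selection of photons by emission channel ×
   excitation period (3 canonical streams without ALEX, 5 with ALEX), with
   a reader/writer for a minimal Photon-HDF5-style layout.
2. **Background estimation** — the inter-photon delay distribution has an
   exponential tail of rate λ_bg; for delays above a threshold *T* the
   left-truncated-exponential MLE is λ̂ = 1/(mean(d | d ≥ T) − T), computed
   per photon stream in consecutive 30 s windows (an iterative heuristic
   chooses *T* automatically).
3. **Burst search** — sliding-window search: photon *i* opens a valid
   window when t[i+m−1] − t[i] ≤ m/λ_thr, with λ_thr = F·λ_bg(t) (defaults
   m = 10, F = 6, guaranteeing a signal-to-background ratio ≥ F − 1), or a
   fixed `min_rate_cps`; plus the dual-channel AND-gate (DCBS) search.
4. **Corrections** — background subtraction, donor leakage *lk*, acceptor
   direct excitation *dir*, and the γ factor, giving corrected counts
   n_d, n_a, n_aa, γ-corrected burst sizes n_dex = n_a + γ·n_d and
   n_t = n_dex + n_aa, proximity ratio E_PR = n_a/(n_a + n_d),
   stoichiometry S = (γ·n_d + n_a)/(γ·n_d + n_a + n_aa), and closed-form
   population-level E/S corrections.
5. **Selection** — composable burst filters (γ-corrected size, n_aa,
   width, E–S region), e.g. size ≥ 15 then n_aa ≥ 15 isolates the FRET
   population from donor-only and acceptor-only species.
6. **Population fitting** — size-weighted histograms, weighted Gaussian
   KDE, least-squares peak models (1–3 Gaussians, two Gaussians bridged by
   a plateau) with reduced χ²/AIC/BIC, and weighted EM for Gaussian
   mixtures.
7. **Burst variance analysis (BVA)** — sub-burst proximity-ratio standard
   deviation s_E per burst versus the shot-noise curve
   Std(E_sub) = √(E_p(1 − E_p)/n), flagging dynamics on the transit
   timescale.
8. **Simulator** — Poisson background streams, Poisson burst arrivals with
   binomial donor/acceptor partitioning, μs-ALEX period structure, static
   mixtures and two-state interconversion dynamics, with ground truth —
   used throughout the test suite.

## Worked example

Simulate a 300 s two-population ALEX measurement (E = 0.3 and 0.7, 2 kcps
background, 1 burst/s at 100 kcps) and fit the FRET histogram:

```python
import numpy as np
from smburst import simulate as sim, phcore, background as bg
from smburst import burstsearch as bs, corrections as corr, popfit
from smburst.selection import SelectionRule, select_chain

pops = (sim.Population(fraction=0.5, E=0.3, S=0.5),
        sim.Population(fraction=0.5, E=0.7, S=0.5))
cfg = sim.SimConfig(duration_s=300.0, seed=1, populations=pops)
measurement, truth = sim.simulate_measurement(cfg)

measurement = phcore.apply_alternation(measurement)
bg.estimate_background(measurement, window_s=30.0, tail_min="auto")
bs.burst_search(measurement, m=10, F=6.0)
corr.apply_corrections(measurement)

bursts = select_chain(measurement.bursts[0],
                      [SelectionRule("size", th1=15),
                       SelectionRule("naa", th1=15)])
E = corr.proximity_ratio(bursts.counts_bg)
w = popfit.burst_weights(bursts)
ok = np.isfinite(E)
print(popfit.fit_histogram(E[ok], w[ok], model="gauss2").report())
```

Output:

```
model: gauss2  (n_data=26)
  amp1         = 1224.03 +/- 203.8
  center1      = 0.309466 +/- 0.00655
  sigma1       = 0.0604968 +/- 0.005325
  amp2         = 1586.57 +/- 245.5
  center2      = 0.698899 +/- 0.00512
  sigma2       = 0.0490189 +/- 0.003207
  redchi = 1.21   aic = 10.14   bic = 17.69
```

315 bursts are found, 218 survive the FRET-population selection, and the
two fitted peak centers (0.309 ± 0.007 and 0.699 ± 0.005) recover the
simulated proximity ratios; reduced χ² ≈ 1 indicates the two-Gaussian model
describes the weighted histogram to within shot noise.

The same pipeline is available from the shell:

```bash
smburst simulate --out sim.h5 --duration 300 --seed 1 \
        --populations "0.5:0.3:0.5,0.5:0.7:0.5"
smburst run sim.h5 --out results --select "size:th1=15" \
        --select "naa:th1=15" --fit
```

## Acceptance script

`scripts/acceptance.py` recomputes the burst-search guarantee figures from
scratch: it simulates the 300 s / 2 kcps / 50×-background dataset, estimates
the background (MLE, 30 s windows), runs the default search (F = 6, m = 10)
and reports the minimum triggering-window rate relative to the local
background estimate and the minimum burst size:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

`docs/methods.md` describes the statistical models, parameter defaults,
numerical choices, what the simulator does and does not emulate, and known
limitations.
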