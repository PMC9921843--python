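# crosswave

Cross-wavelet and Hilbert phase analysis of antagonist-muscle EMG tremor.

## The problem

Parkinsonian (PD) and essential (ET) tremor both shake the wrist, but they
organize the *antagonist* muscles — the wrist flexor and extensor of one arm —
differently: bursts may be **synchronous** (inter-muscle phase shift near 0)
or **alternating** (near ±π), and the informative frequency band is not known
in advance.  `crosswave` implements an exploratory pipeline that localizes
such phase regularities in frequency (and in time) and quantifies how well
they separate two diagnostic groups, for researchers analysing paired surface
EMG recordings.

## The method

Surface EMG (500 Hz) is reduced to a *tremor signal*: notch filters at
50/100/150/200 Hz, an 8th-order Butterworth band-pass 60–240 Hz applied
forward and reverse (zero phase), the Hilbert envelope, and decimation by 4.
Two routes then quantify the flexor–extensor phase relationship:

1. **Hilbert route.** Per frequency band, the instantaneous phase
   Ψ(t) = angle(hilbert(x(t))) of each envelope, the cyclic difference
   ΔΨ(t) = angle(e^{iΨ₁} − e^{iΨ₂}) (a vector-quotient variant is also
   provided), and its per-subject mean μ_ΔΨ = (1/N)ΣΔΨ(n).  Sweeping all
   bands (lo, hi) gives a triangular **phase-difference AUC diagram**: each
   cell holds the ROC area comparing the PD and ET score sets; cells near 0
   or 1 mark discriminative bands.
2. **Cross-wavelet route.** With the complex Morlet wavelet
   M(t) = (πF_b)^{-1/2} e^{2πiF_c t} e^{−t²/F_b} (F_b = F_c = 1), the
   cross-wavelet spectrum W_xy(t, s) = W_x(t, s)·W_y*(t, s) measures
   co-occurring power (|W_xy|) and phase shift (angle W_xy).  **Cross-wave
   trains** — strict local maxima of |W_xy| — are characterized by central
   frequency, peak PSD, duration (seconds and periods), bandwidth, and
   instantaneous phase, and counted per second of recording.  AUC diagrams
   over train attributes (frequency, PSD, duration, bandwidth) and a
   two-triangle cyclic **phase diagram** locate the discriminative train
   kinds; a greedy coordinate-descent fit sharpens a five-attribute filter
   to maximize |AUC − 0.5|.

Clinical recordings are not distributable, so a seeded synthetic generator
(`crosswave.synthetic`) plants the documented structure — e.g. the
`pd_like` preset carries a simultaneous alternating 4–6 Hz and synchronous
8–18 Hz component, `et_like` components at 2.2–3.9 Hz and 10–37 Hz — and
every claim in the test suite is a planted-parameter recovery or structural
property, not a clinical result.

## Worked example

```python
import numpy as np
from crosswave.synthetic import preset_cohort_spec, simulate_cohorts
from crosswave.cws import frequency_grid
from crosswave.cws_diagrams import (CohortTrains, attribute_cws_auc_diagram,
                                    fit_train_filter)
from crosswave.phase_diagram import extreme_cells
from crosswave.trains import TrainFilter

pos, neg = simulate_cohorts(preset_cohort_spec("pd_like", 10, seed=101),
                            preset_cohort_spec("et_like", 10, seed=202))
freqs = frequency_grid(2.0, 48.0, 0.5)
pd_trains = CohortTrains.from_pairs(pos, freqs, group="PD")
et_trains = CohortTrains.from_pairs(neg, freqs, group="ET")

grid = np.arange(2.0, 49.0, 2.0)
diagram = attribute_cws_auc_diagram(pd_trains, et_trains, "frequency", grid)
(band, auc) = extreme_cells(diagram, 1)[0]
print(f"most extreme cell: {band} Hz, AUC = {auc:.3f}")
i, j = list(grid).index(4.0), list(grid).index(6.0)
print(f"AUC in the 4-6 Hz cell: {diagram.matrix[j, i]:.3f}")

fit = fit_train_filter(pd_trains, et_trains, TrainFilter(freq=band))
print(fit.summary())
```

prints

```
most extreme cell: (2.0, 4.0) Hz, AUC = 0.000
AUC in the 4-6 Hz cell: 0.920
Cross-wave train filter fit
===========================
frequency range      : 2.5 - 4.375 Hz
PSD range            : 0.0003812 - 41.21
duration range       : 0.376 - 4140 periods
bandwidth range      : 0.5 - 46.5 Hz
phase range (include): -3.142 - +3.142 rad
AUC                  : 0.0000
Mann-Whitney p       : 0.0001806
sweeps               : 1
n (pos, neg)         : 10, 10
```

Two regularities of opposite direction appear at once, as in real cohorts:
the most extreme cell is *blue* (AUC → 0) — the ET-like cohort's planted
2.2–3.9 Hz trains are ET-typical, absent in the PD-like group — while the
4–6 Hz cell is red (AUC 0.92), the PD-typical alternating tremor band.
Fitting from the blue cell sharpens a filter that separates the 10 + 10
subjects perfectly in the ET direction (AUC 0, Mann-Whitney p ≈ 2·10⁻⁴).

The same pipeline is scriptable from the shell:

```bash
crosswave simulate --preset pd_like --n 10 --seed 1 --out pd/
crosswave cws --in pd/pd00.tsv --flo 2 --fhi 48 --fstep 0.5 --out pd00.npz
crosswave detect-trains --in pd00.npz --out pd00.trains.tsv --subject-id pd00
crosswave all --seed 1 --out demo/        # end-to-end demonstration
```

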