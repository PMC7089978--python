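# zmwfcs

Quantifying dye-induced DNA adhesion inside zero-mode waveguides (ZMWs)
from single-molecule fluorescence data: fluorescence correlation
spectroscopy (FCS) with a diffusion + dark-state model, and time-correlated
single-photon-counting (TCSPC) lifetime analysis with instrument-response
reconvolution — plus a photon-stream simulator of diffusion with transient
surface adsorption to exercise the whole pipeline end to end.

## The problem

A ZMW is a ~110 nm aperture in a 100 nm aluminum film that confines the
detection volume to attoliters, enabling single-molecule fluorescence at
up-to-micromolar concentrations.  Labelled DNA can, however, adhere
non-specifically to the aperture surface; whether it does is driven largely
by the fluorescent label itself (positively charged, hydrophobic dyes such
as Atto 550/647N promote sticking; net-negative hydrophilic Alexa 546/647
do not).  Adhesion corrupts both FCS observables (diffusion time, molecule
number, brightness) and the apparent fluorescence lifetime (extra metal
quenching).  This package implements the two quantitative assays used to
detect and benchmark adhesion and surface passivation:

1. **FCS sticking fractions.**  Intensity traces are autocorrelated
   (multi-tau) and fitted with a 3D Brownian diffusion model with a
   dark-state (blinking) term,

   G(τ) = (1/N) · [1 + T_ds/(1−T_ds) · exp(−τ/τ_ds)] ·
   Σᵢ αᵢ (1+τ/τ_D,i)⁻¹ (1+τ/(κ²τ_D,i))⁻¹ᐟ²,   κ = 1,

   with one species for free diffusion or two species when adhesion adds a
   slow component.  The relative amplitude of the slow component
   (`slow_fraction`, in %) is the adhesion metric: ≈20 % on bare aluminum
   for a sticky dye, ≈10 % under BSA or PEG 500, ≈0 under PEG 1000 or PVPA.

2. **Lifetime fold changes.**  TCSPC histograms are fitted by iterative
   reconvolution with the IRF (Poisson maximum likelihood, 95 % time gate,
   exclusion of the ~5 ps laser back-reflection spike), summarized by the
   intensity-weighted average lifetime τ̄ = Σaᵢτᵢ²/Σaᵢτᵢ.  The ratio
   τ⁰/τ^ZMW between the confocal reference and the in-aperture lifetime is
   ≈2 in the absence of adhesion and grows to ≈3 when molecules adsorb on
   the metal.

The simulator (`zmwfcs.simulate`) generates time-tagged time-resolved
(TTTR) photon streams with the statistical structure the analysis assumes:
diffusion-limited bursts through an evanescent detection profile, rare
adsorption events producing >100 ms fluorescence spikes, microsecond
blinking, and state-dependent exponential decays convolved with the IRF.

## Worked example

```bash
zmwfcs simulate --seed 3 --duration 8 --out trace.h5
zmwfcs correlate trace.h5 --out curve.csv
zmwfcs fit-fcs curve.csv --out fit.json
zmwfcs fit-decay trace.h5 --n-exp 1 --out decay.json
```

prints (seed 3, 8 s acquisition, default no-sticking configuration):

```
INFO zmwfcs: wrote 54056 photons to trace.h5
INFO zmwfcs: correlated 54056 photons into 128 lags
INFO zmwfcs: N=0.0352 tauD=0.000189 s fast/slow=100.0/0.0% redchi=8.42
INFO zmwfcs: tau_bar=1.747 ns over 1 components (redchi 1.1)
```

Reading: at 100 nM in the attoliter aperture volume the average occupancy
is far below one molecule (N ≈ 0.035), transits take ≈0.19 ms, the slow
(adhesion) amplitude is 0 % as configured, and the fitted intensity-weighted
lifetime 1.75 ns matches the configured in-aperture decay of 1.74 ns.
The same stages run as library calls (`simulate_experiment`,
`bin_intensity`, `correlate_multitau`, `fit_fcs`, `fit_decay`), and
`zmwfcs benchmark --dye Atto647N --out bench/` runs the full dye ×
passivation comparison table ranked by sticking fraction.

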