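# ssvepflow

Model-driven and data-driven causality analysis of steady-state visual
evoked potentials (SSVEP).

When a flickering stimulus drives the visual system, only certain
frequencies (classically those below ~30 Hz, e.g. 8 Hz) evoke a strong
steady-state response, and the response involves frontal as well as
occipital cortex.  `ssvepflow` implements two complementary ways of asking
*which directed interaction* between visual cortex and frontal area changes
with the stimulation frequency, for researchers analysing multichannel
electrophysiology (intracranial EEG / LFP) recorded under flicker
stimulation:

1. **Model-driven:** invert a coupled double-column Jansen–Rit neural mass
   model against a two-channel recording.  Column 1 (occipital) and
   column 2 (frontal) each contain pyramidal cells plus excitatory and
   inhibitory interneurons with PSP kinetics
   `h_e(t) = A a t e^{-at}`, `h_i(t) = B b t e^{-bt}` and the firing
   sigmoid `S(v) = 2 e_0 / (1 + e^{r (v_0 - v)})`.  The free parameters are
   the intra-column connectivities `C1, C2` and the directed inter-column
   gains `K1` (occipital → frontal) and `K2` (frontal → occipital).  A
   particle swarm optimizer (swarm 60, 100 generations) adjusts
   `(C1, C2, K1, K2)` inside the box `[60,120]² × [1500,3000] × [100,600]`
   to minimise the summed relative error
   `RE = ‖U − u‖/‖U‖` between simulated and recorded channels.
2. **Data-driven:** fit a multivariate autoregression (order chosen by AIC
   in 5–20) over the electrode montage, evaluate partial directed coherence
   `π_ij(f) = |A_ij(f)| / ‖a_j(f)‖` with
   `A(f) = I − Σ_r A_r e^{−i2πfr/fs}`, average over 6–92 Hz, and aggregate
   the resulting directed edge strengths into four area-level flows:
   VC→FA, FA→VC, within-VC, within-FA (visual cortex = V1_L, V1_R, V2_L,
   V2_R; frontal area = FrA_L, FrA_R).

Both routes feed a one-way repeated-measures ANOVA (Greenhouse–Geisser
corrected) with Bonferroni-corrected paired-t post-hocs across stimulation
conditions (control, 8, 44, 84 Hz).

Because the original animal recordings are not public, the package ships a
first-class synthetic-data module that emulates the study design — 10
subjects × 4 conditions × five 3 s segments at 1000 Hz — from the
double-column model (with the 8 Hz condition's `K1` elevated) and from VAR
processes with known directed structure, so every analysis can be validated
against planted ground truth.

## Worked example

Simulate an 8 Hz recording with known parameters and invert it:

```python
from ssvepflow import (DoubleColumnParams, PSOConfig, StimulusSpec,
                       generate_inversion_fixture, invert_segment)

truth = DoubleColumnParams(C1=90, C2=85, K1=2200, K2=300)
fx = generate_inversion_fixture(truth, StimulusSpec(condition="8"), seed=11)
res = invert_segment(fx.segment, "8", fx,
                     config=PSOConfig(swarm_size=60, max_generations=100),
                     seed=1)
print({k: round(v, 1) for k, v in res.as_dict()["params"].items()})
print({c: f"{re:.2e}" for c, re in res.relative_errors.items()})
```

prints

```
{'C1': 96.1, 'C2': 120.0, 'K1': 2776.0, 'K2': 373.0}
{'u1': '4.50e-03', 'u2': '2.38e-03'}
```

Both channels are fitted to a relative error well below the 0.01 working
bound, while the recovered `K1` sits several hundred units from the
generating 2200: near-identical waveforms arise along a (C1, K1)
compensation ridge, which is why the pipeline averages parameters across
the five segments of each subject before group statistics (see
`docs/methods.md`).

The same analyses are scriptable from the shell:

```sh
ssvepflow synth study --seed 1 --out study/            # emulated data set
ssvepflow run-study --seed 1 --out results/            # invert + PDC + stats
ssvepflow pdc --segment study/sub01/8/seg1.lfp.tsv --band 6:92 --out flows.json
```

`run-study` writes per-subject parameter and flow tables
(`tables/params.csv`, `tables/flows.csv`), the ANOVA and post-hoc results
per measure (`stats.json`) and a `summary.json` of condition means, all
reproducible byte-for-byte from the configuration and seed.

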