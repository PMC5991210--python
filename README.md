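# ildpipe

Analysis pipeline for two-photon calcium imaging studies of binaural
hearing in auditory cortex: from raw per-neuron fluorescence traces to
interaural level difference (ILD) tuning, binaural interaction
categories, opponent-channel population decoding of sound laterality,
and statistics of the spatial organization of tuning — plus a synthetic
experiment generator that provides ground truth for every stage.

It is written for systems-neuroscience labs that image layer II/III
somata with GCaMP-family indicators while presenting dichotic stimuli
(noise bursts varying in ILD and average binaural level, monaural bursts
per ear, and pure tones over a frequency × level grid), and for
methodologists who want a tested, reproducible reference implementation
of this analysis family.

## What it computes

Given traces F(t) (frames × neurons), neuropil traces, neuron positions,
and a trial table, the pipeline:

1. **Signal extraction** — high-pass at 0.02 Hz (zero-phase), baseline
   F0 = median of the 10th–70th percentile of samples,
   ΔF/F0 = (F − F0)/F0, neuropil correction (− r·neuropil, r = 0.6), and
   the per-trial response: peak ΔF/F0 in the 14 frames from stimulus
   onset minus the peak in the 14 frames before onset.
2. **Tuning statistics** — responsiveness (one-tailed paired t-tests,
   α = 0.01), ILD sensitivity (one-way ANOVA per ABL, α = 0.05), peak
   ILD, contiguous-ILD slopes, and the weighted ILD preference
   (centroid) Σᵢ ILDᵢ·r̄ᵢ / Σᵢ r̄ᵢ; frequency response areas, two-way
   frequency × level ANOVA, best frequency with a 3-SD validity check,
   the tonotopic axis by 1° rotation search, and the field BF variation
   in octaves.
3. **Binaural categories** — EO / OE / EE / OO-F monaural classes and
   the binaural interaction index BII = diotic/(contra+ipsi), with
   facilitation (>1.2), inhibition (<0.8), occlusion (EE/O), and
   no-interaction bands, per ABL.
4. **Population decoding** — PCA of the neurons × (7 ILD × 3 ABL)
   normalized response matrix, and an opponent-channel decoder: the
   difference between the mean normalized responses of
   contralateral- and ipsilateral-preferring channels classifies the ILD
   of single trials by nearest leave-one-out reference, scored as the
   mean unsigned error (MUE, dB) versus population size.
5. **Spatial statistics** — pairwise signal and noise correlations with
   shuffle-bootstrap nulls, correlation-versus-distance fits, and the
   bootstrapped clustering test (local ≤150 µm pairs versus the fifth
   percentile of distant-pair resamples) for weighted ILD, BF, and
   binaural category maps.

The synthetic generator (`ildpipe.synthetic`) simulates the matching
experiment — 7 ILDs × 2–3 ABLs × 12 noise repetitions plus monaural
bursts, 18 tone frequencies × 4 levels × 10 repetitions, at 0.65 Hz on a
30 Hz frame clock — with Poisson spiking, a GCaMP6m-like double-
exponential kernel, neuropil contamination, shared trial-to-trial noise,
and plantable ILD tuning, binaural classes, tonotopic gradients, and
spatial clusters. See `docs/methods.md` for the model, its assumptions,
and known limitations.

## Worked example

```python
import ildpipe as ip

# simulate a 120-neuron field with a tonotopic gradient planted at 20°
pop = ip.make_population(120, seed=1)
pop = ip.plant_spatial_structure(pop, seed=1, gradient_angle_deg=20.0,
                                 bf_jitter_oct=0.4)
exp = ip.simulate_fluorescence(pop, ip.SimParams(), seed=1)
ip.save_experiment(exp, "example.h5")

# run every stage
cfg = ip.RunConfig(seed=1, decoder_resamples=100)
report, art = ip.run_pipeline(cfg, input_path="example.h5")
```

Printed summaries from this exact run:

```
responsive % by ABL: {'abl40': 89.2, 'abl60': 97.5, 'abl80': 99.2}
ILD-sensitive % by ABL: {'abl40': 60.8, 'abl60': 69.2, 'abl80': 78.3}
PCA variance, top 3 components: 75.6%
decoder MUE (dB) by population size: {'10': 11.4, '25': 8.4, '50': 6.8}
tonotopic axis: 24 deg (r = -0.92, n = 120)
```

Reading the numbers: nearly all synthetic neurons respond to noise (and
more at louder ABLs); 60–78% pass the ILD ANOVA; three principal
components capture ~76% of the population response variance; the
opponent decoder's single-trial ILD error falls from ~11 dB with 10
neurons to ~7 dB with 50 (chance is ~22.9 dB on this 7-ILD task); and
the planted 20° tonotopic axis is recovered at 24° with a strong
negative correlation between position and log2(BF).

The same run from a shell:

```bash
ildpipe simulate -o example.h5 --neurons 120 --seed 1 --gradient-angle 20
ildpipe all example.h5 -o results/ --seed 1 --figures
```

which writes per-stage CSVs, `report.json` (counts, exclusions, summary
tables, timings, config hash), and optionally the report figures.

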