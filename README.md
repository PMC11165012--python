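# neuroscreen

Analysis pipeline for image-based phenotypic screening in stem-cell-derived
neuronal disease models, built around the readouts used to characterize and
pharmacologically rescue SHANK3-deficiency phenotypes:

- **High-content imaging features** — nuclei segmentation into live/dead/debris
  classes, Ki67 (proliferation) and HuC/D (neuronal differentiation) positivity
  by nucleus–marker mask overlap, MAP2 neurite skeletonization, synaptic
  punctum detection, and synapse calling by *triple colocalization*
  (a Synapsin1 punctum and a SHANK3 punctum, colocalized with each other and
  with the neurite skeleton), plus two-channel area-overlap colocalization
  (e.g. ARPC2 over ß-actin).
- **Screening statistics** — per-plate median normalization on DMSO control
  wells, Z′-factor plate QC, a two-metric 3-SD hit window with a live-cell
  toxicity cutoff, replicate concordance, dose-response trend testing with
  exact permutation p-values, mutant-line specificity selection, ΔΔCt qPCR
  quantification and Welch's t-test.
- **MEA activity metrics** — activity (mean firing rate), synchrony
  (baseline-normalized cross-correlogram area over electrode pairs) and
  oscillation (ISI coefficient of variation), with 5.5-SD threshold spike
  detection from voltage traces and activity-based well filtering.
- **Synthetic data generators** with known ground truth for all of the above:
  rendered fluorescence fields, full-scale 384-well screens, dose-response
  sets and (optionally correlated or bursting) spike trains.

## Core statistics

For a plate with positive-control values $x_+$ and DMSO values $x_-$ the
assay quality score is the Z′ factor

$$Z' = 1 - \frac{3(\sigma_+ + \sigma_-)}{|\mu_+ - \mu_-|},$$

and plates with $Z' < 0.2$ on either metric are discarded. A compound is a
**hit** when its replicate-averaged, plate-normalized Ki67 ratio exceeds the
pooled DMSO median by more than $3\sigma$ *and* its HuC/D ratio falls more
than $3\sigma$ below it, unless its mean live-nucleus count is below 2,000
(toxic). Dose dependence is Spearman rank correlation of response against
log dose with an exact one-sided permutation p-value (full 7! enumeration at
seven doses); a compound is *mutant-specific* when the trend is significant
in the SHANK3-deficient line and not in the isogenic control.

## Worked example

```python
from neuroscreen import ScreenModel
from neuroscreen.io import load_fixture
from neuroscreen.simulate import simulate_screen

cfg = load_fixture("screen_sim.yaml")        # 7,120 compounds in duplicate
table, truth = simulate_screen(cfg, seed=1)  # long well table, ground truth
res = ScreenModel(table).fit()
print(res.summary())
```

prints

```
Screen hit-calling summary
==========================
wells:    15584   plates: 42 (passing: 42, excluded pre-QC: 0)
mean Z' (Ki67):    0.554
mean Z' (HuC/D):   0.480
replicate r (Ki67):   0.849
replicate r (HuC/D):  0.789
hit window: > median + 3 SD (Ki67) and < median - 3 SD (HuC/D), global SD
toxicity: mean nuclei < 2000
compounds tested: 7120
toxic compounds:  30
hits: 42
```

All 42 planted active compounds are recovered (`set(res.hits) ==
set(truth.active_ids)`); the 30 planted toxic compounds sit in the hit
quadrant but are removed by the live-count filter. The mean Z′ of ~0.55
says positive-control and DMSO wells are well separated on the Ki67 ratio,
and the replicate correlation of ~0.85 reflects the latent per-compound
effects shared between the two screening runs.

The same objects are scriptable from the shell:

```bash
neuroscreen simulate --what screen --config src/neuroscreen/fixtures/screen_sim.yaml \
    --seed 1 --out out/
neuroscreen screen --wells out/screen_wells.csv --out out/hits.csv
```

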