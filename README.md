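# topohrv

Topological analysis of heart-rate variability (HRV) for sleep-stage
classification.

Heart rhythm carries information about sleep: wake is fast and irregular,
non-REM sleep slow and strongly modulated by respiration.  `topohrv` turns
the instantaneous heart rate (IHR) signal derived from ECG R-peak times into
*topological* descriptors and uses them to classify 30-s epochs as
wake/sleep, REM/NREM, or wake/REM/NREM — for researchers working on
HRV-based sleep staging and, more generally, on persistent-homology features
for physiological time series.

## Method

For each labeled 30-s epoch, a 90-s IHR window **x** ∈ ℝ³⁶⁰ (the epoch plus
its two predecessors, 4 Hz, median-centered) is summarized through two
filtrations:

1. **Sub-level set filtration** of **x**: its dim-0 persistence diagram
   P₀(**x**) pairs each local minimum with the local maximum at which its
   valley merges into an older one (elder rule), capturing the oscillation
   pattern of the IHR.
2. **Vietoris–Rips filtration** of the Takens delay embedding
   R_{p,τ}(**x**) ⊂ ℝ^p with (p, τ) = (120, 1): the diagrams
   P₀(R_{120,1}(**x**)) and P₁(R_{120,1}(**x**)) describe cluster and loop
   structure of the reconstructed dynamics.  A simplex σ enters the
   filtration at ε = diam(σ)/2.

Each diagram is condensed into the multisets M = {(b+d)/2} (midpoints) and
L = {d−b} (lifespans) over its finite points, and each multiset into eight
**persistence statistics** — mean, sd, skewness, kurtosis, 25th/50th/75th
percentile, persistent entropy E = Σ −(v/S)·log(v/S) with S = Σ v — giving a
16-vector Φ^(PS) per diagram and a 48-feature vector per epoch:

    [Φ^(PS)(P₀(x)), Φ^(PS)(P₀(R₁₂₀,₁(x))), Φ^(PS)(P₁(R₁₂₀,₁(x)))]

A linear-kernel SVM (C = 1; one-vs-one for three classes) is trained on a
class-balanced pool (majority classes down-sampled to the minority size with
a fixed seed) and evaluated *unbalanced* with sensitivity, positive
predictivity, F1, accuracy, Cohen's kappa, and AUC, pooled and as
per-subject mean ± sd.

The persistent-homology engines are part of the package: a generic Z2
boundary-matrix reduction with an exact bottleneck distance (desk scale), a
union-find sub-level engine, and a flag-complex Rips engine (union-find
dim 0 with clearing, apparent pairs, lazy-heap coboundary reduction) fast
enough for 241-point clouds in ℝ¹²⁰ in well under a second.

## Worked example

Five synthetic subjects (wake onset followed by NREM sleep; the generator
plants the physiological wake/sleep contrast), three used for training and
two held out:

```python
import numpy as np
import topohrv as th
from topohrv import PipelineConfig, run_pipeline

subjects = []
for k in range(5):
    rng = np.random.default_rng(100 + k)
    stages = ["W"] * int(rng.integers(4, 7))
    stages += ["N"] * (16 - len(stages))
    times, labels = th.synthetic_recording(
        th.SyntheticRecordingSpec(stages=stages, seed=200 + k))
    subjects.append((f"s{k:02d}", times, labels))

result = run_pipeline(PipelineConfig(seed=1), subjects[:3], subjects[3:])
pooled = result["report"]["pooled"]
print(f"Acc={pooled['Acc']:.3f}  Kappa={pooled['Kappa']:.3f}  "
      f"AUC={pooled['AUC']:.3f}  n={pooled['n']}")
```

prints

```
Acc=0.917  Kappa=0.704  AUC=0.968  n=24
```

i.e. on the 24 held-out epochs, 91.7 % are classified correctly, far above
the chance agreement (kappa 0.70), and the SVM scores rank wake above sleep
epochs with probability 0.968.  Lower-level pieces are just as direct:

```python
filt = th.worked_filtration()            # 5-step worked filtration, 4 vertices
d = th.compute_persistence(filt, 1).drop_zero_persistence()
d.in_dimension(0)                      # [[1., inf]]  component born at step 1
d.in_dimension(1)                      # [[3., 5.]]   loop born at 3, filled at 5
th.betti_numbers(filt, 3)[:2]          # (1, 1)
```

The sklearn-style pieces (`PersistenceFeaturizer`, `SleepStageClassifier`)
compose with sklearn pipelines and model selection.

## Command line

```bash
topohrv simulate --subjects 5 --epochs 20 --seed 1 --out-dir sim/
topohrv run --train-recording sim/subject00_rpeaks.csv:sim/subject00_labels.csv \
            --test-recording  sim/subject04_rpeaks.csv:sim/subject04_labels.csv \
            --task ws --seed 1 --out-dir out/
```

`out/` then holds the feature tables, the fitted model, and `report.json`
with the full metric suite and the configuration embedded.  Real recordings
enter as a single-column R-peak CSV (`time_s`, seconds) plus a label CSV
(`epoch_index,label` with labels W/R/N per 30-s epoch); `preprocess`,
`features`, `train`, and `evaluate` expose the intermediate stages.

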