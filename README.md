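# fcparc

Individual-level functional-connectivity parcellation of surface fMRI,
with a synthetic-cohort validation battery.

Group-average atlases of cortical areas blur real inter-individual
differences in functional organization — nowhere more so than in higher-order
auditory cortex on the superior temporal cortex (STC), where network
boundaries shift substantially from person to person. `fcparc` implements a
two-stage approach for researchers who need subject-specific network maps
from resting-state fMRI sampled on a shared cortical surface mesh:

1. **Group atlas.** Each ROI vertex gets a *functional connectivity
   profile* — the vector of Pearson correlations between its time course
   and every cortical vertex's time course (band-passed 0.01–0.08 Hz,
   nuisance-regressed). Profiles are averaged across subjects and clustered
   into K networks by spherical k-means (cosine similarity, best of 500
   random restarts by aggregate distance Σ(1 − cos)). Model order is chosen
   at interior local maxima of the product of split-half Dice and
   silhouette over K = 2..24; spatial clusters of ≤ 10 mm² are absorbed by
   neighbor majority vote (profile correlation breaks ties).

2. **Individualization.** Per subject, network *reference signals* (mean
   member time courses under the group atlas) seed an iterative loop: each
   vertex is reassigned to the network whose reference it correlates with
   most; a *confidence ratio* r₁/r₂ (largest over second-largest
   correlation) > 1.3 selects unambiguous vertices, whose average — the
   *high-confidence signal* — is blended equally with the current reference
   to form the next iteration's reference. Ten iterations yield the
   individual parcellation.

Validation tools: network-wise Dice 2·V_overlap/(V₁+V₂) (parcellation value
= unweighted network mean), size-weighted connectional homogeneity
Σ ρ_l·|l| / Σ|l| (mean within-network pairwise Fisher-z correlation),
size-weighted functional inhomogeneity Σ sd_l·|l| / Σ|l| of task z-maps,
percent-of-total task effect per network, Mantel permutation tests against
anatomy-similarity matrices, Friedman/Wilcoxon/Benjamini-Hochberg
comparisons, and seed-based connectivity maps with one-sample t and
sign-flip cluster-extent correction.

Because suitable public data with per-subject ground truth do not exist,
the package ships a first-class synthetic cohort generator
(`fcparc.synth`): icosphere meshes with a contiguous ROI cap, contiguous
group network templates, subject-specific boundary jitter, band-limited
correlated network latents with controllable SNR, task z-maps, and anatomy
fields independent of network membership. Every downstream claim is tested
against this known truth.

## Worked example

```python
import numpy as np
from fcparc import SyntheticCohortSpec
from fcparc.pipeline import run_study

spec = SyntheticCohortSpec(seed=7)          # 8 subjects, 2 sessions, SNR 1
study = run_study(spec, atlas_seed=11)

print(f"group atlas vs subject truth : {study.mean('dice_group'):.3f}")
print(f"individualized vs truth      : {study.mean('dice_individual'):.3f}")
print(f"iteration 9 vs 10 stability  : {study.mean('stability'):.3f}")
intra = np.mean(list(study.variability.intra.values()))
inter = np.mean(list(study.variability.inter.values()))
print(f"intra-subject session Dice   : {intra:.3f}")
print(f"inter-subject Dice           : {inter:.3f}")
print(f"connectional homogeneity     : own {study.mean('conn_hom_own'):.3f} "
      f"vs group {study.mean('conn_hom_group'):.3f}")
```

prints

```
group atlas vs subject truth : 0.802
individualized vs truth      : 1.000
iteration 9 vs 10 stability  : 1.000
intra-subject session Dice   : 1.000
inter-subject Dice           : 0.702
connectional homogeneity     : own 0.884 vs group 0.667
```

Reading: the group atlas explains a subject's true layout only up to the
20% boundary jitter baked into the cohort (Dice ≈ 0.80), while the
individualized parcellation recovers each subject's own network layout
(Dice 1.0) and is internally more coherent (higher connectional
homogeneity) than the group atlas — the core claim the method makes.
Parcellations from two sessions of the same subject agree far better than
parcellations from different subjects.

## Command line

Each stage reads a YAML config and a `--seed`, and writes bit-reproducible
outputs:

```sh
fcparc simulate     --config cohort.yaml --seed 7 --out cohort/
fcparc group-atlas  --config atlas.yaml  --seed 3 --out atlas/
fcparc individualize --config indiv.yaml --seed 0 --out indiv/
fcparc metrics      --config metrics.yaml --out metrics/
fcparc mantel       --config mantel.yaml --seed 2 --out mantel.tsv
fcparc seedconn     --config seed.yaml   --seed 1 --out seedconn/
```

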