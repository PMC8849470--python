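# semrsa

Representational similarity analysis (RSA) of semantic brain
representations: cross-validated neural RDMs, searchlight model–brain
mapping with partial-correlation nuisance control, sign-permutation
group statistics (cluster-extent FWE and TFCE), skip-gram
distributional-semantics model families, and a synthetic-data generator
with planted ground truth.

## Who this is for

Researchers in multivariate fMRI analysis who want to test whether the
similarity structure of evoked activity patterns — for example, the
pairwise geometry of abstract nouns embedded in an ongoing mental
narrative — matches the structure predicted by a distributional model
of word meaning, and who want every statistical step of that pipeline
to be verifiable against simulations with known ground truth.

## The method

Neural dissimilarity between conditions *i* and *j* is the
**cross-validated correlation distance**: over all unordered 50/50
splits of the runs into halves *A* and *B* (patterns averaged within
each half),

```
d(i, j) = mean over splits of  (within − between)
within  = ½ [ corr(i_A, i_B) + corr(j_A, j_B) ]
between = ½ [ corr(i_A, j_B) + corr(j_A, i_B) ]
```

with Pearson correlation across voxels.  Because the halves carry
independent noise the estimate is unbiased around zero for
indistinguishable conditions (entries may be negative).  Model RDMs are
1 − r between feature vectors (word embeddings, DNN activations) or
absolute differences of scalar properties (valence, arousal, log
frequency).  Neural and model RDMs are compared by correlating their
lower triangles, Fisher-transformed (z = atanh r), optionally as a
partial correlation controlling for nuisance RDMs.  A searchlight
repeats this in a sphere around every voxel; group inference uses
one-sided t-tests with cluster-extent FWE (sign-flip permutation null
of the maximum extent) or TFCE with a rank-based permutation z.  ROI
model families — skip-gram embeddings trained on nested corpus
prefixes or on abstract-only/concrete-only corpora — are tested with
FDR across the family and paired comparisons against the full model,
with a circularity guard for the model that defined the ROI.

See `docs/methods.md` for assumptions, parameter defaults, and what the
synthetic generator does and does not emulate.

## Worked example

Simulate eight subjects with a planted 5×5×5 signal region whose
pattern geometry follows a known reference RDM (per-voxel SNR 1), map
it with a searchlight, and test the group:

```python
import numpy as np
from semrsa import *

truth = generate_geometry(n_conditions=12, pattern_dim=6, seed=1)
region = block_region((4, 4, 4), (5, 5, 5))
cfg = SimulationConfig(
    n_conditions=12, n_runs=4, volume_shape=(14, 14, 14),
    signal_region=region, noise_sd=1.0, pattern_dim=6, n_subjects=8,
    signal_scale=signal_scale_for_snr(1.0, 1.0, region.shape[0], 6), seed=1,
)
zmaps = []
for s in range(cfg.n_subjects):
    betas, grid = generate_subject_patterns(truth, cfg, subject_seed=100 + s)
    res = searchlight_rsa(betas, truth.reference_rdm.condition_labels, grid,
                          truth.reference_rdm, radius=2)
    zmaps.append(res.zmap)
tmap, pmap = group_ttest_map(zmaps)
clusters = cluster_threshold(tmap, zmaps, voxel_p=0.001, cluster_alpha=0.05,
                             n_permutations=1000, seed=1)
print(clusters.table.to_string(index=False))
```

Output:

```
 cluster_id  n_voxels  peak_x  peak_y  peak_z  peak_stat    p_fwe  significant
          1       272       5       7       6  37.695628 0.007782         True
          2         1       6       1       3   5.382560 0.844358        False
```

One large cluster survives the permutation familywise-error threshold;
its peak (5, 7, 6) lies inside the planted block (4–8 on each axis).
The 272-voxel extent exceeds the block's 125 voxels because every
searchlight sphere overlapping the region carries signal.  The stray
single-voxel cluster is a chance suprathreshold voxel and is correctly
non-significant (p_fwe = 0.84).

The same workflow is available from the shell:

```
semrsa simulate --out data --seed 3
semrsa searchlight --betas data/sub00 --model-rdm data/reference_rdm.tsv \
    --radius 3 --out sub00_z.nii.gz
semrsa group cluster --maps zmaps/ --voxel-p 0.001 --alpha 0.05 \
    --n-perm 1000 --seed 0 --out clusters.tsv
semrsa pipeline run --config config.yaml
```

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end analysis from scratch: it generates
a clustered Zipfian corpus and matching brain data with planted
geometry, trains a skip-gram model family on nested corpus prefixes,
runs the searchlight against the largest model's RDM, performs
permutation cluster inference, and evaluates the model family in the
resulting ROI — all seeded from `--seed` — and writes the results JSON
to `--out`.
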