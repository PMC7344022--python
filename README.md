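# sampenmap

Voxelwise **sample entropy** mapping for 4D fMRI, with parcel-level
aggregation and the group statistics used in BOLD-complexity studies:
Pearson correlation matrices across scans, paired t-tests with Bonferroni
correction, balanced two-factor ANOVA, and ICC(3,1) test-retest
reliability. A synthetic 4D cohort generator with known ground truth makes
the whole pipeline testable without access to restricted neuroimaging
data.

## Who this is for

Researchers analyzing the temporal complexity of BOLD signals — for
example comparing resting-state and task scans across brain networks or
cortical/subcortical regions — who want a reproducible, scriptable
implementation of the entropy-mapping workflow, and a way to validate it
against simulated cohorts where the true effect structure is known.

## The statistic

For a voxel time series x = [x₁, …, x_N], templates of m consecutive
points are compared under the Chebyshev distance. With

- B = number of ordered template pairs (i ≠ j, i, j = 1 … N−m) whose
  m-point windows agree within tolerance r, and
- A = the count for the same pairs with windows extended to m+1 points,

sample entropy is

```
SampEn(m, r, N, x) = −ln(A / B)
```

Lower values indicate a more regular, predictable signal. Defaults are
m = 3 and r = 0.6 × SD of each voxel's series (sample SD, n−1
denominator), making the statistic invariant to affine rescaling of the
signal. Degenerate voxels (constant series, series too short, or no
template matches) are reported as explicitly missing with a reason code,
never replaced by a substitute value.

Entropy is computed **voxelwise first** and then averaged within each
parcel of an integer label atlas (mean of voxel entropies, not entropy of
the mean signal). The resulting scans × ROIs table feeds the group-level
battery.

## Worked example

Simulate a small cohort (8 subjects × 2 rest + 2 task scans, 405
volumes each, on an 8×8×8 grid with 7 network parcels plus
cortical/subcortical region groups), map it, aggregate, and run the
statistics:

```sh
sampenmap simulate --config cohort.yaml --out cohort
sampenmap map --manifest cohort/manifest.csv --atlas cohort/atlas.nii \
              --m 3 --r-factor 0.6 --out maps
sampenmap aggregate --maps maps --atlas cohort/atlas.nii --out table.csv
sampenmap stats --table table.csv --families networks=7,classes=1 --out stats
```

`stats/table2_network_summary.csv` from this run (seed 7):

```
          network  rest_mean  rest_sd  task_mean  task_sd  p_adjusted
           visual     0.9771   0.0328     0.9111   0.0454      0.0000
      somatomotor     0.9520   0.0383     0.9190   0.0466      0.0251
 dorsal_attention     0.9737   0.0308     0.9407   0.0417      0.0117
ventral_attention     0.9725   0.0329     0.9283   0.0485      0.0008
           limbic     0.9668   0.0353     0.9053   0.0535      0.0004
   frontoparietal     0.9904   0.0312     0.9274   0.0438      0.0000
     default_mode     0.9745   0.0303     0.9306   0.0417      0.0005
```

Every network shows higher entropy at rest than during the simulated
task (the planted direction), significant after Bonferroni correction
over the 7 networks. The class summary from the same run shows the
planted subcortical > cortical entropy ordering:

```
      class condition   mean     sd  n_scans
   cortical      rest 0.9712 0.0334       16
   cortical      task 0.9166 0.0481       16
subcortical      rest 1.0284 0.0226       16
subcortical      task 0.9936 0.0331       16
```

and the group-level scan-1 vs scan-2 consistency correlation of network
means is 0.968 (rest) and 0.944 (task). The same stages are available as
library calls (`sampenmap.pipeline.run_simulate`, `run_map`,
`run_aggregate`, `run_stats`) and all of the underlying operations
(`sample_entropy`, `sample_entropy_map`, `build_cohort_table`,
`paired_ttest`, `two_factor_anova`, `icc_3_1`, …) are importable from
`sampenmap` directly.

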