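# pharmconn

Drug-vs-placebo resting-state connectomics: per-subject Fisher-Z
connectomes, edge-wise paired contrasts with FDR thresholding,
signed-modularity fractionation of the default mode network (DMN) into
sub-networks, stability assessment by normalized mutual information, and
brain–behavior correlation — together with a synthetic-data generator that
plants known structure so every stage can be validated end to end.

## The problem

Pharmacological resting-state fMRI studies ask how an acute drug dose
reshapes the brain's intrinsic connectivity networks. A typical
within-subject crossover design yields, for each participant, one scan under
placebo and one under drug. The analysis chain this package implements:

1. **Connectome construction.** For parcellated BOLD time series (after
   nuisance regression, linear detrending and 0.008–0.09 Hz band-pass), the
   edge between nodes *i*, *j* is the Fisher-Z transformed Pearson
   correlation *z*<sub>ij</sub> = artanh(*r*<sub>ij</sub>). With a 300-node
   atlas and 12 "unassigned" nodes excluded, each subject and condition
   yields a 288 × 288 matrix.
2. **Edge-wise paired contrast.** For every edge linking a DMN node to a
   node of one of the 12 other networks, the per-subject difference
   *d* = *z*<sub>drug</sub> − *z*<sub>placebo</sub> is tested with a paired
   *t*-test (df = *n* − 1), giving a 65 × 223 difference matrix that is
   thresholded by Benjamini–Hochberg FDR jointly across all cells.
   Surviving mean differences feed network-wise and overall one-sample
   *t*-tests (df = surviving-edge count − 1, Bonferroni over the 12
   networks).
3. **DMN fractionation.** Each DMN node's response profile (its masked row
   of *t* statistics) is compared with every other's; the resulting signed
   similarity graph is partitioned by maximising signed modularity

   *Q* = *Q*⁺ − (*v*⁻/(*v*⁺+*v*⁻)) *Q*⁻,  *Q*<sup>±</sup> = (1/*v*<sup>±</sup>) Σ<sub>ij same community</sub> [*W*<sup>±</sup><sub>ij</sub> − γ *s*<sup>±</sup><sub>i</sub>*s*<sup>±</sup><sub>j</sub>/*v*<sup>±</sup>]

   with a Louvain-style optimizer (γ = 1 by default, plus a resolution
   sweep). Repeating the optimisation with many seeds and computing all
   pairwise NMI values probes whether the partition is stable.
4. **Brain–behavior correlation.** Per-subject change scores (mean
   *z* difference over surviving sub-network × target-network edges) are
   correlated with impulsivity (BIS-11 total and subscales), reporting
   Pearson *r*, uncorrected *p* and BH *q* side by side.

Because real participant data of this kind is rarely shareable, the
`synth` module generates panels from multivariate normal signals whose
correlation structure plants two opposing DMN sub-communities (one
decreasing connectivity with several target networks under drug, one
increasing it with another) plus behavioral scores coupled to the
subject-level effect — ground truth against which recovery is scored.

## Worked example

```python
import pharmconn as pc

report, result = pc.run_all(pc.RunConfig(preset="toy", seed=11, iterations=50))
print(report["partition"])
print(report["stability"])
print(report["recovery"])
```

prints (toy preset: 60 nodes, 5 networks, 20 DMN nodes split 8 + 12,
12 subjects):

```
{'n_communities': 2, 'sizes': [8, 12], 'q_value': 0.36235320492635337, 'gamma': 1.0}
{'n_iterations': 50, 'min_pairwise_nmi': 1.0, 'mean_pairwise_nmi': 1.0}
{'partition_nmi': 1.0, 'sign_agreement': 1.0, 'behavior_r_estimated': -0.1786, ...}
```

The pipeline fractionated the DMN into exactly the planted 8 + 12
communities (`partition_nmi` 1.0), all 50 repeated optimisations agreed
(`min_pairwise_nmi` 1.0), and every planted effect direction was recovered
(`sign_agreement` 1.0). Each script in `examples/` demonstrates one stage
the same way; a thin CLI (`pharmconn simulate|preprocess|connectivity|run`)
wraps the library for shell use.

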