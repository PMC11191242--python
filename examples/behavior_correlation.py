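"""Correlate drug-induced connectivity change with impulsivity scores.

Simulated impulsivity (BIS-11 total, 30 items rated 1-4) is coupled to each
subject's realized connectivity shift toward TargetA with a generating
correlation of -0.4.  The pipeline recovers a per-subject change score (mean
Fisher-Z difference over FDR-surviving sub-network edges) and its Pearson
correlation with the scores; expect r in the neighbourhood of -0.4,
attenuated toward zero by single-session measurement noise."""

import numpy as np

from pharmconn import (
    build_dmn_graph,
    change_scores,
    connectivity_matrix,
    correlate_behavior,
    louvain_signed,
    pair_by_subject,
)
from pharmconn.stats import extract_difference_matrix, paired_edge_tests
from pharmconn import synth

cfg = synth.toy_config(seed=8, n_subjects=55)
parc = synth.make_parcellation(cfg)
panel, truth = synth.simulate_panel(cfg)
behavior = synth.simulate_behavior(cfg, truth)

matrices = connectivity_matrix(panel, parc)
placebo, drug, defined, node_ids = pair_by_subject(matrices, panel.condition_names)
t, p, delta, df = paired_edge_tests(placebo, drug, defined)
diff = extract_difference_matrix(t, p, delta, df, node_ids, parc)
partition = louvain_signed(build_dmn_graph(diff), seed=0)

scores = change_scores(placebo, drug, panel.subject_ids, diff, parc, partition)
table = correlate_behavior(scores, behavior)
print("change-score vs BIS-11 correlations (uncorrected p and BH q):")
for _, row in table[table["measure"] == "bis_total"].iterrows():
    print(f"  {row['score']:14s} r = {row['r']:+.3f}  p = {row['p']:.3f}  "
          f"q = {row['q']:.3f}  (n = {row['n']})")
print("the sub-community coupled to behaviour should show r near -0.4;")
print("uncoupled score columns hover near zero")
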