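"""Brain-behavior correlation: drug-induced connectivity change vs impulsivity.

For each subject, a change score summarises the drug-minus-placebo Fisher-Z
difference over the FDR-surviving edges linking a DMN node set (the whole DMN
or one of its sub-networks) to one target network.  Change scores are then
correlated (Pearson) with the BIS-11 total and subscale scores.  Because such
exploratory correlations rarely survive correction, uncorrected p and BH q
are reported side by side rather than gating output on significance.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import BIS_COLUMNS, BehaviorTable, Parcellation
from .graph import Partition
from .stats import DifferenceMatrix, bh_fdr

__all__ = ["change_scores", "correlate_behavior"]

logger = logging.getLogger(__name__)


def change_scores(
    placebo: np.ndarray,
    drug: np.ndarray,
    subject_ids: Sequence[str],
    diff: DifferenceMatrix,
    parcellation: Parcellation,
    partition: Partition | None = None,
) -> pd.DataFrame:
    """Per-subject mean surviving-edge Fisher-Z change, per node set x network.

    ``placebo``/``drug`` are the stacked (subjects, n, n) connectivity arrays
    over assigned nodes, in the same node order used to build ``diff``.
    Columns are named ``DMN|<network>`` for whole-DMN scores and
    ``sub<k>|<network>`` for each sub-network of ``partition``.  Empty edge
    sets yield NaN for that column (logged).
    """
    assigned = parcellation.assigned_nodes
    pos = {int(n): i for i, n in enumerate(assigned)}
    row_idx = np.array([pos[int(n)] for n in diff.rows])
    col_idx = np.array([pos[int(n)] for n in diff.cols])
    d = drug - placebo  # (S, n, n)

    node_sets: dict[str, np.ndarray] = {"DMN": np.arange(diff.rows.size)}
    if partition is not None:
        for label in range(partition.n_communities):
            node_sets[f"sub{label + 1}"] = partition.members(label)

    out: dict[str, np.ndarray] = {}
    for set_name, rows in node_sets.items():
        for network in parcellation.target_networks:
            cols = diff.column_indices_of(network)
            cell_mask = diff.mask[np.ix_(rows, cols)]
            if not cell_mask.any():
                logger.info("no surviving edges for %s|%s", set_name, network)
                out[f"{set_name}|{network}"] = np.full(len(subject_ids), np.nan)
                continue
            sub = d[:, row_idx[rows][:, None], col_idx[cols][None, :]]
            out[f"{set_name}|{network}"] = sub[:, cell_mask].mean(axis=1)
    frame = pd.DataFrame(out)
    frame.insert(0, "subject_id", [str(s) for s in subject_ids])
    return frame


def correlate_behavior(
    scores: pd.DataFrame,
    behavior: BehaviorTable,
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pearson r, two-sided p and BH q per (change score, BIS measure) pair.

    ``columns`` restricts the score columns tested (e.g. to the networks the
    group-level tests flagged significant); default is every score column.
    Pairs with fewer than 4 complete subjects or zero variance are skipped
    with a log message.
    """
    merged = scores.merge(behavior.frame, on="subject_id", how="inner")
    score_cols = [c for c in scores.columns if c != "subject_id"]
    if columns is not None:
        score_cols = [c for c in score_cols if c in set(columns)]
    rows = []
    for col in score_cols:
        for measure in BIS_COLUMNS:
            pair = merged[[col, measure]].dropna()
            n = len(pair)
            if n < 4:
                logger.info("%s vs %s: only %d complete pairs, skipped", col, measure, n)
                continue
            x = pair[col].to_numpy(dtype=float)
            y = pair[measure].to_numpy(dtype=float)
            if x.std() == 0 or y.std() == 0:
                logger.info("%s vs %s: zero variance, correlation undefined", col, measure)
                continue
            r, p = sps.pearsonr(x, y)
            rows.append({"score": col, "measure": measure, "n": n, "r": float(r), "p": float(p)})
    table = pd.DataFrame(rows, columns=["score", "measure", "n", "r", "p"])
    if len(table):
        q, _ = bh_fdr(table["p"].to_numpy())
        table["q"] = q
    else:
        table["q"] = pd.Series(dtype=float)
    return table
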