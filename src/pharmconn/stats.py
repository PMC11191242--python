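"""Edge-wise paired drug-vs-placebo inference and network-wise tests.

The group contrast is computed edge by edge: for each pair of assigned nodes,
the per-subject difference d_i = z_drug - z_placebo is tested against zero
with a paired t-test (df = n_subjects - 1).  The DMN x other-networks block
of the resulting grids is then extracted (65 x 223 at the scale of a 300-node
atlas with 12 unassigned and 65 DMN nodes), Benjamini-Hochberg FDR is applied
jointly across all its cells, and the surviving mean differences feed the
network-wise, overall and sub-network one-sample tests whose degrees of
freedom equal surviving-edge counts minus one.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import ConnectivityMatrix, Parcellation

__all__ = [
    "DifferenceMatrix",
    "NetworkTestResult",
    "pair_by_subject",
    "paired_edge_tests",
    "bh_fdr",
    "extract_difference_matrix",
    "networkwise_tests",
    "overall_test",
    "difference_matrix_pipeline",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class DifferenceMatrix:
    """DMN-rows x other-node-columns grid of paired t statistics.

    ``rows`` are DMN node ids and ``cols`` assigned non-DMN node ids (original
    parcellation indexing).  ``mask`` marks edges surviving BH-FDR at
    ``alpha``; undefined edges carry NaN in ``t``/``p``/``q``.
    """

    rows: np.ndarray
    cols: np.ndarray
    col_networks: tuple[str, ...]
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    mask: np.ndarray
    delta_mean: np.ndarray
    df: int
    alpha: float

    def __post_init__(self) -> None:
        shape = (self.rows.size, self.cols.size)
        for name in ("t", "p", "q", "mask", "delta_mean"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        defined = np.isfinite(self.t)
        if np.any(self.mask & ~defined):
            raise ValueError("mask selects undefined edges")
        if np.any(self.q[self.mask] > self.alpha + 1e-12):
            raise ValueError("mask selects edges with q above alpha")
        sign_clash = self.mask & (np.sign(self.t) != np.sign(self.delta_mean))
        if np.any(sign_clash & (self.delta_mean != 0)):
            raise ValueError("t and delta_mean disagree in sign on surviving edges")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows.size, self.cols.size)

    @property
    def n_surviving(self) -> int:
        return int(self.mask.sum())

    def column_indices_of(self, network: str) -> np.ndarray:
        return np.nonzero(np.asarray(self.col_networks) == network)[0]


@dataclasses.dataclass
class NetworkTestResult:
    """One-sample test of surviving mean edge differences for one network."""

    network: str
    n_edges: int
    t: float | None
    df: int | None
    p_uncorrected: float | None
    p_bonf: float | None
    direction: int  # sign of the mean surviving difference; 0 if not testable
    subnetwork: int | None = None

    @property
    def testable(self) -> bool:
        return self.t is not None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def pair_by_subject(
    matrices: Sequence[ConnectivityMatrix], condition_names: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack matrices into (placebo, drug) arrays of shape (S, n, n).

    Returns (placebo, drug, defined, node_ids); ``defined`` is the AND of the
    per-matrix defined masks across subjects and conditions.
    """
    placebo_name, drug_name = condition_names
    by_key = {(m.subject_id, m.condition): m for m in matrices}
    subjects = sorted({m.subject_id for m in matrices})
    pairs = [
        (by_key.get((s, placebo_name)), by_key.get((s, drug_name))) for s in subjects
    ]
    missing = [s for s, (a, b) in zip(subjects, pairs) if a is None or b is None]
    if missing:
        raise ValueError(f"subjects missing a condition: {missing}")
    node_ids = pairs[0][0].node_ids
    placebo = np.stack([a.values for a, _ in pairs])
    drug = np.stack([b.values for _, b in pairs])
    defined = np.logical_and.reduce(
        [a.defined & b.defined for a, b in pairs]
    )
    return placebo, drug, defined, node_ids


def paired_edge_tests(
    placebo: np.ndarray, drug: np.ndarray, defined: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Edge-wise paired t over subjects; returns (t, p, delta_mean, df).

    Edges masked undefined, or whose differences have zero variance, get NaN
    t and p and are excluded from any later FDR step.
    """
    placebo = np.asarray(placebo, dtype=float)
    drug = np.asarray(drug, dtype=float)
    if placebo.shape != drug.shape or placebo.ndim != 3:
        raise ValueError("expected matching (subjects, n, n) arrays")
    n_sub = placebo.shape[0]
    if n_sub < 3:
        raise ValueError("need at least 3 subjects for the paired test")
    d = drug - placebo
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n_sub))
    df = n_sub - 1
    zero_var = sd == 0.0
    if defined is None:
        defined = np.ones_like(zero_var, dtype=bool)
    bad = zero_var & defined
    if bad.any():
        logger.warning("%d edges with zero-variance differences excluded", bad.sum())
    t[~defined | zero_var] = np.nan
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p[~np.isfinite(t)] = np.nan
    return t, p, mean, df


def bh_fdr(
    p_values: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (q_values, reject flags).

    NaN entries are excluded from the family and returned NaN / not rejected.
    """
    p = np.asarray(p_values, dtype=float)
    flat = p.ravel()
    finite = np.isfinite(flat)
    if np.any((flat[finite] < 0) | (flat[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(flat.shape, np.nan)
    reject = np.zeros(flat.shape, dtype=bool)
    if finite.any():
        rej, qvals, *_ = multipletests(flat[finite], alpha=alpha, method="fdr_bh")
        q[finite] = qvals
        reject[finite] = rej
    return q.reshape(p.shape), reject.reshape(p.shape)


def extract_difference_matrix(
    t: np.ndarray,
    p: np.ndarray,
    delta_mean: np.ndarray,
    df: int,
    node_ids: np.ndarray,
    parcellation: Parcellation,
    alpha: float = 0.05,
) -> DifferenceMatrix:
    """Restrict edge grids to DMN rows x assigned-non-DMN columns and apply
    BH-FDR jointly across all retained cells.

    ``node_ids`` maps grid axes to parcellation node indices (the assigned
    nodes, in order); DMN-DMN and unassigned edges never enter the matrix.
    """
    node_ids = np.asarray(node_ids)
    pos = {int(n): i for i, n in enumerate(node_ids)}
    dmn = [n for n in parcellation.dmn_nodes if int(n) in pos]
    others = [
        int(n)
        for n in parcellation.assigned_nodes
        if parcellation.network[int(n)] != parcellation.dmn_name and int(n) in pos
    ]
    if not dmn:
        raise ValueError("no DMN nodes present in the grids")
    if not others:
        raise ValueError("no non-DMN assigned nodes present in the grids")
    ri = [pos[int(n)] for n in dmn]
    ci = [pos[n] for n in others]
    sub = np.ix_(ri, ci)
    t_sub, p_sub, d_sub = t[sub], p[sub], delta_mean[sub]
    q_sub, reject = bh_fdr(p_sub, alpha)
    return DifferenceMatrix(
        rows=np.asarray(dmn, dtype=int),
        cols=np.asarray(others, dtype=int),
        col_networks=tuple(parcellation.network[n] for n in others),
        t=t_sub,
        p=p_sub,
        q=q_sub,
        mask=reject,
        delta_mean=d_sub,
        df=df,
        alpha=alpha,
    )


def _one_sample(values: np.ndarray) -> tuple[float, int, float]:
    """Closed-form one-sample t against 0: (t, df, two-sided p)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    mean = values.mean()
    sd = values.std(ddof=1)
    if sd == 0.0:
        t = 0.0 if mean == 0.0 else np.inf * np.sign(mean)
    else:
        t = mean / (sd / np.sqrt(n))
    df = n - 1
    p = float(2.0 * sps.t.sf(abs(t), df))
    return float(t), df, p


def networkwise_tests(
    diff: DifferenceMatrix,
    parcellation: Parcellation,
    rows: np.ndarray | None = None,
    bonferroni: int | None = None,
    use_t_values: bool = False,
    subnetwork: int | None = None,
) -> list[NetworkTestResult]:
    """One-sample t per target network over its surviving edge differences.

    The Bonferroni factor defaults to the number of target networks derived
    from the parcellation (12 for the 14-network atlas after dropping the DMN
    and the unassigned set).  ``rows`` optionally restricts to a DMN
    sub-network's rows; ``use_t_values`` tests the per-edge t statistics
    instead of the mean differences.
    """
    targets = parcellation.target_networks
    m = bonferroni if bonferroni is not None else len(targets)
    row_sel = np.arange(diff.rows.size) if rows is None else np.asarray(rows)
    source = diff.t if use_t_values else diff.delta_mean
    results = []
    for network in targets:
        cols = diff.column_indices_of(network)
        cell_mask = diff.mask[np.ix_(row_sel, cols)]
        values = source[np.ix_(row_sel, cols)][cell_mask]
        if values.size < 2:
            logger.info("network %s: %d surviving edges, not testable", network, values.size)
            results.append(
                NetworkTestResult(network, int(values.size), None, None, None, None, 0,
                                  subnetwork)
            )
            continue
        t, df, p = _one_sample(values)
        results.append(
            NetworkTestResult(
                network=network,
                n_edges=int(values.size),
                t=t,
                df=df,
                p_uncorrected=p,
                p_bonf=min(1.0, p * m),
                direction=int(np.sign(values.mean())),
                subnetwork=subnetwork,
            )
        )
    return results


def overall_test(diff: DifferenceMatrix, use_t_values: bool = False) -> NetworkTestResult:
    """One-sample t over all surviving DMN x other edge differences."""
    source = diff.t if use_t_values else diff.delta_mean
    values = source[diff.mask]
    if values.size < 2:
        return NetworkTestResult("overall", int(values.size), None, None, None, None, 0)
    t, df, p = _one_sample(values)
    return NetworkTestResult(
        network="overall",
        n_edges=int(values.size),
        t=t,
        df=df,
        p_uncorrected=p,
        p_bonf=p,
        direction=int(np.sign(values.mean())),
    )


def difference_matrix_pipeline(
    matrices: Sequence[ConnectivityMatrix],
    parcellation: Parcellation,
    condition_names: tuple[str, str],
    alpha: float = 0.05,
) -> DifferenceMatrix:
    """Convenience: pair matrices, run edge tests, extract the DMN block."""
    placebo, drug, defined, node_ids = pair_by_subject(matrices, condition_names)
    t, p, delta, df = paired_edge_tests(placebo, drug, defined)
    return extract_difference_matrix(t, p, delta, df, node_ids, parcellation, alpha)
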