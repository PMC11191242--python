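"""Per-subject Fisher-Z connectivity matrices over assigned nodes.

Edge weight between two nodes is the Fisher Z transform (artanh) of the
Pearson correlation of their preprocessed series.  Perfect correlations are
clamped to 1 - 1e-7 in magnitude before the transform so every downstream
statistic stays finite; nodes with zero-variance series have their edges
masked undefined (matrix shape is preserved across subjects).  Unassigned
atlas nodes are excluded before computation, so a 300-node atlas with 12
unassigned nodes yields 288 x 288 matrices.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import ConnectivityMatrix, Parcellation, TimeSeriesPanel

__all__ = ["fisher_z", "connectivity_matrix"]

logger = logging.getLogger(__name__)

CLAMP = 1e-7


def fisher_z(r):
    """Variance-stabilising artanh transform, finite for |r| = 1.

    Accepts scalars or arrays; |r| > 1 is an error.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1 + 1e-12):
        raise ValueError("correlation outside [-1, 1]")
    clamped = np.clip(arr, -1 + CLAMP, 1 - CLAMP)
    z = np.arctanh(clamped)
    return float(z) if np.isscalar(r) or arr.ndim == 0 else z


def connectivity_matrix(
    panel: TimeSeriesPanel, parcellation: Parcellation
) -> list[ConnectivityMatrix]:
    """One symmetric Fisher-Z matrix per (subject, condition).

    Matrices are ordered subject-major, placebo-role condition first.
    """
    if panel.n_nodes != parcellation.n_nodes:
        raise ValueError("panel node axis does not match the parcellation")
    assigned = parcellation.assigned_nodes
    out: list[ConnectivityMatrix] = []
    for si, subject in enumerate(panel.subject_ids):
        for ci, condition in enumerate(panel.condition_names):
            series = panel.data[si, ci][assigned]
            out.append(_single_matrix(series, subject, condition, assigned))
    return out


def _single_matrix(
    series: np.ndarray, subject: str, condition: str, node_ids: np.ndarray
) -> ConnectivityMatrix:
    n = series.shape[0]
    sd = series.std(axis=1)
    degenerate = sd == 0.0
    if degenerate.any():
        logger.warning(
            "%s/%s: %d zero-variance node series masked", subject, condition,
            int(degenerate.sum()),
        )
    good = ~degenerate
    r = np.zeros((n, n))
    if good.sum() >= 2:
        r_good = np.corrcoef(series[good])
        r[np.ix_(good, good)] = r_good
    z = fisher_z(np.clip(r, -1.0, 1.0))
    z = (z + z.T) / 2.0
    defined = np.outer(good, good)
    np.fill_diagonal(defined, False)
    np.fill_diagonal(z, 0.0)
    z[~defined] = 0.0
    return ConnectivityMatrix(
        values=z,
        subject_id=subject,
        condition=condition,
        node_ids=node_ids,
        defined=defined,
    )
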