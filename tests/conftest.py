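import numpy as np
import pytest

import pharmconn as pc
from pharmconn import synth


@pytest.fixture(scope="session")
def toy_parcellation():
    """10 nodes: 3 DMN, 5 auditory-like targets, 2 unassigned."""
    return pc.Parcellation(
        node_id=np.arange(10),
        label=tuple(f"n{i}" for i in range(10)),
        network=("DefaultMode",) * 3 + ("Auditory",) * 5 + ("Unassigned",) * 2,
        dmn_name="DefaultMode",
        unassigned_name="Unassigned",
    )


@pytest.fixture(scope="session")
def toy_run():
    """One full toy-scale pipeline run shared across tests."""
    cfg = pc.RunConfig(preset="toy", seed=7, iterations=10)
    report, result = pc.run_all(cfg)
    return report, result


@pytest.fixture(scope="session")
def paper_parcellation():
    return synth.make_parcellation(synth.paper_config())


def make_diff(t, mask=None, col_networks=None, df=9, alpha=0.05):
    """Hand-build a DifferenceMatrix for unit tests (q set consistent with mask)."""
    t = np.asarray(t, dtype=float)
    n_rows, n_cols = t.shape
    mask = (
        np.ones_like(t, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    )
    mask &= np.isfinite(t)
    q = np.where(mask, alpha / 2, 1.0)
    q[~np.isfinite(t)] = np.nan
    p = q.copy()
    if col_networks is None:
        col_networks = tuple("Net" for _ in range(n_cols))
    return pc.DifferenceMatrix(
        rows=np.arange(n_rows),
        cols=np.arange(n_rows, n_rows + n_cols),
        col_networks=tuple(col_networks),
        t=t,
        p=p,
        q=q,
        mask=mask,
        delta_mean=np.where(np.isfinite(t), t, np.nan) * 0.05,
        df=df,
        alpha=alpha,
    )
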