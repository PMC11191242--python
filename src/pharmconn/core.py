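"""Shared domain types and tabular I/O.

Every stage of the pipeline exchanges data through a handful of containers:
a :class:`Parcellation` (node -> network lookup for the atlas), a
:class:`TimeSeriesPanel` (subjects x conditions x nodes x timepoints BOLD-like
signal), per-subject :class:`ConnectivityMatrix` objects, and a
:class:`BehaviorTable` of impulsivity scores.  All on-disk formats are
tab-separated UTF-8 text with a header row (matrices carry row/column labels)
or JSON for statistical reports, so that artifacts diff cleanly and round-trip
without locale ambiguity.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Parcellation",
    "TimeSeriesPanel",
    "ConnectivityMatrix",
    "BehaviorTable",
    "read_parcellation",
    "write_parcellation",
    "read_panel",
    "write_panel",
    "read_matrix",
    "write_matrix",
    "write_report",
    "read_report",
    "read_behavior",
    "write_behavior",
]

# number format guaranteeing float64 round-trip through text
_FLOAT_FMT = "%.17g"


@dataclasses.dataclass(frozen=True)
class Parcellation:
    """Atlas table mapping each node to exactly one named network.

    One network name is designated the DMN (the fractionation target) and at
    most one the "unassigned" network, which is retained here but excluded by
    every downstream computation.  Node ids are 0-based and contiguous;
    ``label`` carries any external numbering.
    """

    node_id: np.ndarray  # int, contiguous from 0
    label: tuple[str, ...]
    network: tuple[str, ...]
    dmn_name: str
    unassigned_name: str | None = None
    coords: np.ndarray | None = None  # (n, 3) MNI mm, optional

    def __post_init__(self) -> None:
        ids = np.asarray(self.node_id, dtype=int)
        object.__setattr__(self, "node_id", ids)
        n = ids.size
        if len(set(ids.tolist())) != n:
            dup = [i for i in ids.tolist() if ids.tolist().count(i) > 1]
            raise ValueError(f"duplicate node id: {sorted(set(dup))}")
        if n == 0 or not np.array_equal(np.sort(ids), np.arange(n)):
            raise ValueError("node ids must be unique and contiguous from 0")
        if len(self.label) != n or len(self.network) != n:
            raise ValueError("label/network length mismatch with node ids")
        if self.dmn_name not in self.network:
            raise ValueError(
                f"DMN network {self.dmn_name!r} not present in parcellation"
            )
        if self.coords is not None:
            coords = np.asarray(self.coords, dtype=float)
            if coords.shape != (n, 3):
                raise ValueError("coords must be (n_nodes, 3)")
            object.__setattr__(self, "coords", coords)

    @property
    def n_nodes(self) -> int:
        return self.node_id.size

    @property
    def networks(self) -> list[str]:
        """Distinct network names in first-appearance order."""
        return list(dict.fromkeys(self.network))

    def nodes_of(self, network: str) -> np.ndarray:
        order = np.argsort(self.node_id)
        net = np.asarray(self.network)[order]
        return order[net == network]

    @property
    def dmn_nodes(self) -> np.ndarray:
        return self.nodes_of(self.dmn_name)

    @property
    def assigned_nodes(self) -> np.ndarray:
        """Node indices excluding the unassigned network, ascending."""
        net = np.asarray(self.network)
        keep = np.ones(self.n_nodes, dtype=bool)
        if self.unassigned_name is not None:
            keep &= net != self.unassigned_name
        return np.nonzero(keep)[0]

    @property
    def target_networks(self) -> list[str]:
        """Non-DMN, non-unassigned networks — the Bonferroni family."""
        return [
            name
            for name in self.networks
            if name != self.dmn_name and name != self.unassigned_name
        ]


@dataclasses.dataclass
class TimeSeriesPanel:
    """Subjects x conditions x nodes x timepoints signal array.

    ``condition_names`` holds exactly two names, placebo-role first,
    drug-role second; ``tr_seconds`` is the sampling interval.
    """

    data: np.ndarray
    condition_names: tuple[str, str]
    tr_seconds: float
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("panel data must be 4-dimensional")
        if len(self.condition_names) != 2:
            raise ValueError("exactly two conditions (placebo-role, drug-role)")
        self.condition_names = tuple(self.condition_names)
        self.subject_ids = tuple(str(s) for s in self.subject_ids)
        s, c, _, t = self.data.shape
        if s != len(self.subject_ids):
            raise ValueError("subject axis length != len(subject_ids)")
        if c != 2:
            raise ValueError("condition axis length must be 2")
        if t < 16:
            raise ValueError("need >= 16 timepoints for a meaningful band-pass")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("panel contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[2]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclasses.dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-Z connectivity over assigned (non-unassigned) nodes.

    The diagonal is undefined: stored as 0 with ``defined`` False.  Edges of
    zero-variance nodes are likewise masked undefined rather than dropped, so
    the matrix keeps its shape across subjects.
    """

    values: np.ndarray
    subject_id: str
    condition: str
    node_ids: np.ndarray  # original parcellation indices of the rows
    defined: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity values must be square")
        if self.defined is None:
            self.defined = ~np.eye(v.shape[0], dtype=bool)
        self.defined = np.asarray(self.defined, dtype=bool)
        if not np.allclose(v, v.T, atol=0.0, rtol=0.0, equal_nan=True):
            raise ValueError("connectivity matrix must be exactly symmetric")
        if np.any(np.diag(self.defined)):
            raise ValueError("diagonal must be masked undefined")
        if not np.all(np.isfinite(v[self.defined])):
            raise ValueError("defined entries must be finite")
        v = v.copy()
        np.fill_diagonal(v, 0.0)
        self.values = v
        self.node_ids = np.asarray(self.node_ids, dtype=int)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


# BIS-11 subscale item counts: attentional 8, motor 11, non-planning 11.
BIS_SUBSCALE_ITEMS = {"bis_attentional": 8, "bis_motor": 11, "bis_nonplanning": 11}
BIS_COLUMNS = ("bis_total", "bis_attentional", "bis_motor", "bis_nonplanning")


@dataclasses.dataclass
class BehaviorTable:
    """Per-subject impulsivity scores: 30-item total (range 30-120, items
    rated 1-4) plus attentional, motor and non-planning subscales that sum
    to the total."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.frame).copy()
        required = ("subject_id",) + BIS_COLUMNS
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"behavior table missing columns: {missing}")
        df["subject_id"] = df["subject_id"].astype(str)
        for c in BIS_COLUMNS:
            df[c] = df[c].astype(int)
        total = df["bis_total"].to_numpy()
        if np.any(total < 30) or np.any(total > 120):
            raise ValueError("bis_total outside the admissible range [30, 120]")
        subsum = (
            df["bis_attentional"] + df["bis_motor"] + df["bis_nonplanning"]
        ).to_numpy()
        if np.any(subsum != total):
            raise ValueError("BIS subscales must sum to bis_total")
        self.frame = df.reset_index(drop=True)

    @property
    def subject_ids(self) -> list[str]:
        return self.frame["subject_id"].tolist()

    def scores(self, column: str) -> np.ndarray:
        return self.frame[column].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_parcellation(
    path: str | Path,
    dmn_name: str = "DefaultMode",
    unassigned_name: str | None = "Unassigned",
) -> Parcellation:
    """Read a tab-separated atlas table (node_id, label, network[, x, y, z])."""
    df = pd.read_csv(path, sep="\t", dtype={"label": str, "network": str})
    required = {"node_id", "label", "network"}
    if not required.issubset(df.columns):
        raise ValueError(f"parcellation must have columns {sorted(required)}")
    coords = None
    if {"x", "y", "z"}.issubset(df.columns):
        coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    if unassigned_name is not None and unassigned_name not in set(df["network"]):
        unassigned_name = None
    return Parcellation(
        node_id=df["node_id"].to_numpy(dtype=int),
        label=tuple(df["label"]),
        network=tuple(df["network"]),
        dmn_name=dmn_name,
        unassigned_name=unassigned_name,
        coords=coords,
    )


def write_parcellation(parc: Parcellation, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "node_id": parc.node_id,
            "label": list(parc.label),
            "network": list(parc.network),
        }
    )
    if parc.coords is not None:
        df[["x", "y", "z"]] = parc.coords
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def _panel_file(directory: Path, subject: str, condition: str) -> Path:
    return directory / f"{subject}_{condition}.tsv"


def write_panel(panel: TimeSeriesPanel, directory: str | Path) -> Path:
    """Write one nodes x timepoints TSV per subject per condition."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for si, subject in enumerate(panel.subject_ids):
        for ci, condition in enumerate(panel.condition_names):
            np.savetxt(
                _panel_file(directory, subject, condition),
                panel.data[si, ci],
                fmt=_FLOAT_FMT,
                delimiter="\t",
            )
    meta = {
        "subject_ids": list(panel.subject_ids),
        "condition_names": list(panel.condition_names),
        "tr_seconds": panel.tr_seconds,
    }
    (directory / "panel.json").write_text(json.dumps(meta, indent=2))
    return directory


def read_panel(
    directory: str | Path,
    parcellation: Parcellation,
    condition_names: Sequence[str] | None = None,
    tr_seconds: float | None = None,
) -> TimeSeriesPanel:
    """Assemble a panel from ``<subject>_<condition>.tsv`` matrix files.

    Conditions and TR default to the sidecar ``panel.json`` written by
    :func:`write_panel`.  Subjects missing either condition are reported.
    """
    directory = Path(directory)
    meta_path = directory / "panel.json"
    if (condition_names is None or tr_seconds is None) and meta_path.exists():
        meta = json.loads(meta_path.read_text())
        condition_names = condition_names or meta["condition_names"]
        tr_seconds = tr_seconds or meta["tr_seconds"]
    if condition_names is None or tr_seconds is None:
        raise ValueError("condition_names and tr_seconds required (no panel.json)")
    condition_names = tuple(condition_names)

    pattern = re.compile(
        r"^(?P<subject>.+)_(?P<condition>" + "|".join(map(re.escape, condition_names)) + r")\.tsv$"
    )
    subjects: dict[str, set[str]] = {}
    for f in sorted(directory.glob("*.tsv")):
        m = pattern.match(f.name)
        if m:
            subjects.setdefault(m.group("subject"), set()).add(m.group("condition"))
    complete = sorted(s for s, conds in subjects.items() if len(conds) == 2)
    incomplete = sorted(set(subjects) - set(complete))
    if incomplete:
        raise ValueError(
            f"subjects missing a condition file: {incomplete} (need both of {condition_names})"
        )
    if not complete:
        raise ValueError(f"no panel files found under {directory}")

    arrays = []
    for subject in complete:
        per_cond = []
        for condition in condition_names:
            mat = np.loadtxt(_panel_file(directory, subject, condition), delimiter="\t", ndmin=2)
            if mat.shape[0] != parcellation.n_nodes:
                raise ValueError(
                    f"{subject}_{condition}: {mat.shape[0]} rows, expected "
                    f"{parcellation.n_nodes} nodes"
                )
            per_cond.append(mat)
        arrays.append(per_cond)
    return TimeSeriesPanel(
        data=np.asarray(arrays, dtype=float),
        condition_names=condition_names,  # type: ignore[arg-type]
        tr_seconds=float(tr_seconds),
        subject_ids=tuple(complete),
    )


def write_matrix(
    values: np.ndarray,
    path: str | Path,
    row_labels: Sequence | None = None,
    col_labels: Sequence | None = None,
) -> Path:
    """Write a labelled matrix as TSV; round-trips float64 exactly."""
    values = np.asarray(values)
    path = Path(path)
    n_rows, n_cols = values.shape
    row_labels = list(row_labels) if row_labels is not None else list(range(n_rows))
    col_labels = list(col_labels) if col_labels is not None else list(range(n_cols))
    df = pd.DataFrame(values, index=row_labels, columns=col_labels)
    df.to_csv(path, sep="\t", index_label="row", float_format=_FLOAT_FMT)
    return path


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]


def write_report(obj: dict, path: str | Path) -> Path:
    """Serialise a statistical report as JSON (numpy scalars coerced)."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default))
    return path


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_behavior(table: BehaviorTable, path: str | Path) -> Path:
    table.frame.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_behavior(path: str | Path) -> BehaviorTable:
    return BehaviorTable(pd.read_csv(path, sep="\t"))
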