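"""Synthetic two-condition panels with planted DMN sub-communities.

The generator emulates the study design the pipeline targets: a within-subject
placebo/drug crossover in which a stimulant shifts the resting-state coupling
of part of the default mode network (DMN).  Node signals are drawn from a
multivariate normal whose correlation matrix has ``rho_within`` inside each
atlas network and ``rho_between`` across networks.  The DMN is secretly split
into two sub-communities; in the drug condition each (sub-community, target
network) pair listed in ``effect_map`` has its cross-correlations shifted by a
subject-specific delta (mean ``delta``, SD ``sigma_delta``), so one
sub-community decreases and the other increases its coupling with specific
networks — the structure the downstream fractionation must recover.
Behavioral impulsivity scores are coupled to each subject's realized shift
toward a designated target network.

Timepoints are i.i.d. across time by default (an optional AR(1) flag adds
temporal smoothness); the analysis consumes only correlations, so white
series keep the generator transparent and exactly analysable.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .core import (
    BIS_SUBSCALE_ITEMS,
    BehaviorTable,
    Parcellation,
    TimeSeriesPanel,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "toy_config",
    "paper_config",
    "make_parcellation",
    "build_condition_covariance",
    "draw_subject_deltas",
    "simulate_panel",
    "simulate_behavior",
    "behavior_beta_for_correlation",
]

DMN_NAME = "DefaultMode"
UNASSIGNED_NAME = "Unassigned"


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Scenario description for the synthetic generator.

    ``network_spec`` lists (network name, node count); the DMN's hidden split
    is given by ``dmn_split`` (sizes of sub-communities 1 and 2, summing to
    the DMN node count).  ``effect_map`` lists (sub_community, target network,
    delta) correlation shifts applied in the drug condition only.
    """

    network_spec: tuple[tuple[str, int], ...]
    dmn_split: tuple[int, int]
    rho_within: float = 0.3
    rho_between: float = 0.05
    effect_map: tuple[tuple[int, str, float], ...] = ()
    sigma_delta: float = 0.1
    n_subjects: int = 55
    n_timepoints: int = 234
    tr_seconds: float = 2.0
    behavior_beta: float = 0.0
    behavior_noise_sd: float = 6.0
    behavior_target: tuple[int, str] | None = None
    behavior_intercept: float = 60.0
    ar_coefficient: float = 0.0  # optional AR(1) smoothness; 0 = white
    seed: int = 0

    def __post_init__(self) -> None:
        names = [n for n, _ in self.network_spec]
        if DMN_NAME not in names:
            raise ValueError(f"network_spec must include {DMN_NAME!r}")
        counts = dict(self.network_spec)
        if sum(self.dmn_split) != counts[DMN_NAME]:
            raise ValueError("dmn_split must sum to the DMN node count")
        if any(s <= 0 for s in self.dmn_split):
            raise ValueError("dmn_split sizes must be positive")
        for rho in (self.rho_within, self.rho_between):
            if not abs(rho) < 1:
                raise ValueError("|rho| must be < 1")
        for sub, target, delta in self.effect_map:
            if sub not in (1, 2):
                raise ValueError("sub-community ids are 1 or 2")
            if target not in counts or target in (DMN_NAME, UNASSIGNED_NAME):
                raise ValueError(f"effect target {target!r} is not a target network")
            if not abs(delta) < 1:
                raise ValueError("|delta| must be < 1")
            if not -1 < self.rho_between + delta < 1:
                raise ValueError("delta pushes a correlation outside (-1, 1)")
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")
        if self.n_timepoints < 16:
            raise ValueError("need at least 16 timepoints")

    @property
    def n_nodes(self) -> int:
        return sum(c for _, c in self.network_spec)


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """Planted structure the pipeline is scored against.

    ``sub_community_of`` maps each DMN node index (parcellation indexing) to
    sub-community 1 or 2; ``subject_deltas`` holds the realized per-subject
    correlation shift for each (sub_community, target network) pair;
    ``behavior_latent`` is the pre-discretization behavioral score.
    """

    sub_community_of: dict[int, int]
    subject_deltas: dict[tuple[int, str], np.ndarray]
    effect_map: tuple[tuple[int, str, float], ...]
    behavior_latent: np.ndarray | None = None

    @property
    def dmn_labels(self) -> np.ndarray:
        """Community labels ordered by DMN node index."""
        nodes = sorted(self.sub_community_of)
        return np.array([self.sub_community_of[n] for n in nodes], dtype=int)


def toy_config(**overrides) -> SimConfig:
    """Desk-scale preset: 60 nodes, 5 networks, DMN 20 = 8 + 12, 12 subjects."""
    defaults = dict(
        network_spec=(
            (DMN_NAME, 20),
            ("TargetA", 14),
            ("TargetB", 12),
            ("TargetC", 10),
            (UNASSIGNED_NAME, 4),
        ),
        dmn_split=(8, 12),
        effect_map=(
            (1, "TargetA", -0.3),
            (1, "TargetB", -0.3),
            (2, "TargetC", 0.3),
        ),
        n_subjects=12,
        n_timepoints=120,
        behavior_target=(1, "TargetA"),
        behavior_beta=behavior_beta_for_correlation(-0.4, 0.1, 6.0),
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def paper_config(**overrides) -> SimConfig:
    """Study-scale preset: 300-node, 14-network atlas, 65 DMN nodes split
    28 + 37, 55 subjects, 234 timepoints at TR 2 s.  Sub-community 1
    decreases coupling with the somatomotor-dorsal, cinguloopercular and
    auditory networks; sub-community 2 increases coupling with the
    parietomedial network."""
    defaults = dict(
        network_spec=(
            (DMN_NAME, 65),
            ("SomatomotorDorsal", 38),
            ("SomatomotorLateral", 8),
            ("CinguloOpercular", 30),
            ("Auditory", 24),
            ("ParietoMedial", 5),
            ("Visual", 39),
            ("FrontoParietal", 27),
            ("Salience", 8),
            ("VentralAttention", 23),
            ("DorsalAttention", 16),
            ("MedialTemporal", 3),
            ("Reward", 2),
            (UNASSIGNED_NAME, 12),
        ),
        dmn_split=(28, 37),
        effect_map=(
            (1, "SomatomotorDorsal", -0.15),
            (1, "CinguloOpercular", -0.15),
            (1, "Auditory", -0.15),
            (2, "ParietoMedial", 0.15),
        ),
        n_subjects=55,
        n_timepoints=234,
        behavior_target=(1, "CinguloOpercular"),
        behavior_beta=behavior_beta_for_correlation(-0.4, 0.1, 6.0),
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def make_parcellation(cfg: SimConfig) -> Parcellation:
    """Atlas implied by the scenario: nodes laid out network-by-network."""
    networks: list[str] = []
    labels: list[str] = []
    for name, count in cfg.network_spec:
        for k in range(count):
            networks.append(name)
            labels.append(f"{name}_{k:03d}")
    unassigned = UNASSIGNED_NAME if UNASSIGNED_NAME in dict(cfg.network_spec) else None
    return Parcellation(
        node_id=np.arange(len(networks)),
        label=tuple(labels),
        network=tuple(networks),
        dmn_name=DMN_NAME,
        unassigned_name=unassigned,
    )


def _sub_community_nodes(cfg: SimConfig, parc: Parcellation) -> dict[int, np.ndarray]:
    dmn = parc.dmn_nodes
    n1 = cfg.dmn_split[0]
    return {1: dmn[:n1], 2: dmn[n1:]}


def build_condition_covariance(
    cfg: SimConfig,
    condition: str,
    subject_deltas: Mapping[tuple[int, str], float] | None = None,
    parcellation: Parcellation | None = None,
) -> np.ndarray:
    """Correlation matrix for one condition of one subject.

    Baseline: ``rho_within`` inside each network, ``rho_between`` across
    networks, unit diagonal.  In the drug condition each (sub-community,
    target) block additionally receives the subject's realized delta.  The
    result is projected to the nearest positive semi-definite matrix by
    clipping eigenvalues at 1e-10 and re-normalising to unit diagonal.
    """
    if condition not in ("placebo", "drug"):
        raise ValueError("condition must be 'placebo' or 'drug'")
    parc = parcellation if parcellation is not None else make_parcellation(cfg)
    net = np.asarray(parc.network)
    same = net[:, None] == net[None, :]
    cov = np.where(same, cfg.rho_within, cfg.rho_between).astype(float)

    if condition == "drug":
        deltas = subject_deltas or {}
        subs = _sub_community_nodes(cfg, parc)
        for (sub, target), delta in deltas.items():
            rows = subs[sub]
            cols = parc.nodes_of(target)
            new = cfg.rho_between + delta
            if not -1 < new < 1:
                raise ValueError(
                    f"delta {delta} pushes ({sub}, {target}) correlation to {new}"
                )
            cov[np.ix_(rows, cols)] = new
            cov[np.ix_(cols, rows)] = new
    np.fill_diagonal(cov, 1.0)
    return _nearest_psd_correlation(cov)


def _nearest_psd_correlation(cov: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    """Eigenvalue clipping followed by re-normalisation to unit diagonal.

    If the matrix is already PSD this is the identity up to floating error.
    """
    w, v = np.linalg.eigh(cov)
    if w.min() >= floor:
        return cov
    w = np.clip(w, floor, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    fixed = (fixed + fixed.T) / 2.0
    np.fill_diagonal(fixed, 1.0)
    return fixed


def draw_subject_deltas(
    cfg: SimConfig, rng: np.random.Generator
) -> dict[tuple[int, str], np.ndarray]:
    """Realized per-subject shifts: delta + N(0, sigma_delta), clipped so the
    shifted correlation stays inside (-1, 1)."""
    out: dict[tuple[int, str], np.ndarray] = {}
    lo = -0.999 - cfg.rho_between
    hi = 0.999 - cfg.rho_between
    for sub, target, delta in cfg.effect_map:
        draws = rng.normal(delta, cfg.sigma_delta, size=cfg.n_subjects)
        out[(sub, target)] = np.clip(draws, lo, hi)
    return out


def simulate_panel(cfg: SimConfig) -> tuple[TimeSeriesPanel, GroundTruth]:
    """Draw the full two-condition panel and its ground truth.

    Deterministic given ``cfg.seed``: the same configuration yields a
    bit-identical panel.
    """
    rng = np.random.default_rng(cfg.seed)
    parc = make_parcellation(cfg)
    deltas = draw_subject_deltas(cfg, rng)

    placebo_cov = build_condition_covariance(cfg, "placebo", parcellation=parc)
    placebo_chol = np.linalg.cholesky(_jitter(placebo_cov))

    n = cfg.n_nodes
    data = np.empty((cfg.n_subjects, 2, n, cfg.n_timepoints))
    for si in range(cfg.n_subjects):
        subject_deltas = {key: float(vals[si]) for key, vals in deltas.items()}
        drug_cov = build_condition_covariance(
            cfg, "drug", subject_deltas, parcellation=parc
        )
        drug_chol = np.linalg.cholesky(_jitter(drug_cov))
        for ci, chol in enumerate((placebo_chol, drug_chol)):
            white = rng.standard_normal((n, cfg.n_timepoints))
            if cfg.ar_coefficient:
                white = _ar1(white, cfg.ar_coefficient)
            data[si, ci] = chol @ white

    panel = TimeSeriesPanel(
        data=data,
        condition_names=("placebo", "drug"),
        tr_seconds=cfg.tr_seconds,
        subject_ids=tuple(f"sub{si:03d}" for si in range(cfg.n_subjects)),
    )
    subs = _sub_community_nodes(cfg, parc)
    truth = GroundTruth(
        sub_community_of={int(node): sub for sub, nodes in subs.items() for node in nodes},
        subject_deltas=deltas,
        effect_map=cfg.effect_map,
    )
    return panel, truth


def _jitter(cov: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    # tiny ridge so Cholesky succeeds on eigenvalue-clipped matrices
    return cov + eps * np.eye(cov.shape[0])


def _ar1(white: np.ndarray, phi: float) -> np.ndarray:
    out = np.empty_like(white)
    out[:, 0] = white[:, 0]
    scale = np.sqrt(1.0 - phi**2)
    for t in range(1, white.shape[1]):
        out[:, t] = phi * out[:, t - 1] + scale * white[:, t]
    return out


def behavior_beta_for_correlation(
    r: float, sigma_delta: float, noise_sd: float
) -> float:
    """Coupling slope giving generating correlation ``r`` between scores and
    realized deltas: r = beta*sigma_delta / sqrt(beta^2 sigma_delta^2 + sd^2)."""
    if not -1 < r < 1:
        raise ValueError("target correlation must be in (-1, 1)")
    if r == 0:
        return 0.0
    return r * noise_sd / (sigma_delta * np.sqrt(1.0 - r**2))


def simulate_behavior(cfg: SimConfig, truth: GroundTruth) -> BehaviorTable:
    """Impulsivity scores coupled to the subject's realized shift.

    The continuous score is ``intercept + beta * (delta_i - mean delta) +
    noise``; it is rounded, clipped to [30, 120], and partitioned into the
    three BIS-11 subscales proportionally to their item counts (largest-
    remainder rounding so the subscales sum exactly to the total).
    """
    rng = np.random.default_rng(_derive_seed(cfg.seed, "behavior"))
    if cfg.behavior_target is not None and cfg.behavior_target in truth.subject_deltas:
        deltas = truth.subject_deltas[cfg.behavior_target]
    elif truth.subject_deltas:
        deltas = next(iter(truth.subject_deltas.values()))
    else:
        deltas = np.zeros(cfg.n_subjects)
    centered = deltas - deltas.mean()
    noise = rng.normal(0.0, cfg.behavior_noise_sd, size=deltas.size)
    latent = cfg.behavior_intercept + cfg.behavior_beta * centered + noise
    total = np.clip(np.rint(latent), 30, 120).astype(int)

    rows = []
    item_counts = np.array(list(BIS_SUBSCALE_ITEMS.values()), dtype=float)
    names = list(BIS_SUBSCALE_ITEMS)
    for si, t in enumerate(total):
        parts = _largest_remainder(t * item_counts / item_counts.sum())
        # each subscale must stay within [items, 4*items]
        parts = _repair_bounds(parts, item_counts.astype(int))
        rows.append(
            {"subject_id": f"sub{si:03d}", "bis_total": int(t)}
            | {name: int(p) for name, p in zip(names, parts)}
        )
    import pandas as pd

    table = BehaviorTable(pd.DataFrame(rows))
    object.__setattr__(truth, "behavior_latent", latent)
    return table


def _largest_remainder(real_parts: np.ndarray) -> np.ndarray:
    floors = np.floor(real_parts).astype(int)
    short = int(round(real_parts.sum())) - floors.sum()
    order = np.argsort(-(real_parts - floors))
    out = floors.copy()
    out[order[:short]] += 1
    return out


def _repair_bounds(parts: np.ndarray, items: np.ndarray) -> np.ndarray:
    lo, hi = items, 4 * items
    parts = parts.copy()
    for _ in range(200):
        below, above = parts < lo, parts > hi
        if not below.any() and not above.any():
            break
        if above.any():
            i = int(np.argmax(parts - hi))
            j = int(np.argmin(parts - hi))
            parts[i] -= 1
            parts[j] += 1
        else:
            i = int(np.argmin(parts - lo))
            j = int(np.argmax(parts - lo))
            parts[i] += 1
            parts[j] -= 1
    return parts


def _derive_seed(master: int, stage: str) -> int:
    import hashlib

    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
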