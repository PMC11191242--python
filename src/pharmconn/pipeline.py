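"""End-to-end orchestration: simulate/load -> preprocess -> connectivity ->
edge-wise contrast -> DMN fractionation -> brain-behavior correlation.

A single :class:`RunConfig` drives every stage; one master seed is split into
per-stage seeds by stable hashing of (seed, stage name), so stochastic stages
are isolated from one another and an identical config + seed reproduces a
byte-identical report.  When the input is simulated, the planted ground truth
travels alongside the outputs and :func:`recover_ground_truth` scores the run
against it (partition NMI, sign agreement of the sub-network tests, error of
the behavioral correlation).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from . import behavior as behavior_mod
from . import graph as graph_mod
from . import stats as stats_mod
from .connectivity import connectivity_matrix
from .core import (
    BehaviorTable,
    Parcellation,
    TimeSeriesPanel,
    read_behavior,
    read_panel,
    read_parcellation,
    write_report,
)
from .preprocess import PreprocessConfig, preprocess_panel
from .synth import (
    GroundTruth,
    SimConfig,
    make_parcellation,
    paper_config,
    simulate_behavior,
    simulate_panel,
    toy_config,
)

__all__ = ["RunConfig", "PipelineResult", "run_all", "recover_ground_truth"]

logger = logging.getLogger(__name__)

PRESETS = {"toy": toy_config, "paper": paper_config}


@dataclasses.dataclass
class RunConfig:
    """Everything a run needs: input source, thresholds, seeds, toggles."""

    preset: str | None = "toy"
    input_dir: str | Path | None = None
    out_dir: str | Path | None = None
    alpha: float = 0.05
    gamma: float = 1.0
    iterations: int = 100
    seed: int = 0
    band_low_hz: float = 0.008
    band_high_hz: float = 0.09
    condition_names: tuple[str, str] = ("placebo", "drug")
    run_modularity: bool = True
    run_behavior: bool = True
    gamma_sweep: tuple[float, ...] = ()
    sim_overrides: dict = dataclasses.field(default_factory=dict)

    def validate(self) -> None:
        missing: list[str] = []
        if self.preset is None and self.input_dir is None:
            missing.append("either preset or input_dir")
        if self.preset is not None and self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.input_dir is not None:
            root = Path(self.input_dir)
            if not (root / "parcellation.tsv").exists():
                missing.append(str(root / "parcellation.tsv"))
            if not list(root.glob("*_*.tsv")):
                missing.append(f"panel files under {root}")
            if self.run_behavior and not (root / "behavior.tsv").exists():
                missing.append(str(root / "behavior.tsv"))
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.iterations < 2:
            raise ValueError("iterations must be >= 2")
        if missing:
            raise FileNotFoundError(f"unresolvable pipeline inputs: {missing}")


@dataclasses.dataclass
class PipelineResult:
    """In-memory handles on every stage output (the report is the JSON view)."""

    parcellation: Parcellation
    panel: TimeSeriesPanel
    diff: stats_mod.DifferenceMatrix
    network_results: list[stats_mod.NetworkTestResult]
    overall: stats_mod.NetworkTestResult
    partition: graph_mod.Partition | None = None
    stability: graph_mod.StabilityReport | None = None
    subnetwork_results: list[stats_mod.NetworkTestResult] | None = None
    change_scores: object | None = None
    behavior_corr: object | None = None
    truth: GroundTruth | None = None
    placebo_stack: np.ndarray | None = None
    drug_stack: np.ndarray | None = None


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_all(cfg: RunConfig) -> tuple[dict, PipelineResult]:
    """Execute every enabled stage; returns (JSON-ready report, result)."""
    cfg.validate()
    report: dict = {
        "config": {
            "preset": cfg.preset,
            "alpha": cfg.alpha,
            "gamma": cfg.gamma,
            "iterations": cfg.iterations,
            "seed": cfg.seed,
            "band": [cfg.band_low_hz, cfg.band_high_hz],
        },
        "stages": [],
    }

    # --- input: simulate or load -------------------------------------------
    truth: GroundTruth | None = None
    behavior_table: BehaviorTable | None = None
    if cfg.input_dir is not None:
        root = Path(cfg.input_dir)
        parcellation = read_parcellation(root / "parcellation.tsv")
        panel = read_panel(root, parcellation, cfg.condition_names)
        if cfg.run_behavior:
            behavior_table = read_behavior(root / "behavior.tsv")
        sim_cfg = None
        report["stages"].append("load")
    else:
        sim_cfg = PRESETS[cfg.preset](
            seed=_stage_seed(cfg.seed, "simulate"), **cfg.sim_overrides
        )
        parcellation = make_parcellation(sim_cfg)
        panel, truth = simulate_panel(sim_cfg)
        if cfg.run_behavior:
            behavior_table = simulate_behavior(sim_cfg, truth)
        report["stages"].append("simulate")
    report["panel_checksum"] = _checksum(panel.data)
    report["n_subjects"] = panel.n_subjects

    # --- preprocess --------------------------------------------------------
    pre_cfg = PreprocessConfig(cfg.band_low_hz, cfg.band_high_hz)
    panel = preprocess_panel(panel, pre_cfg)
    report["stages"].append("preprocess")

    # --- connectivity ------------------------------------------------------
    matrices = connectivity_matrix(panel, parcellation)
    report["stages"].append("connectivity")
    report["matrix_size"] = matrices[0].n_nodes

    # --- edge-wise contrast ------------------------------------------------
    placebo, drug, defined, node_ids = stats_mod.pair_by_subject(
        matrices, panel.condition_names
    )
    t, p, delta, df = stats_mod.paired_edge_tests(placebo, drug, defined)
    diff = stats_mod.extract_difference_matrix(
        t, p, delta, df, node_ids, parcellation, cfg.alpha
    )
    network_results = stats_mod.networkwise_tests(diff, parcellation)
    overall = stats_mod.overall_test(diff)
    report["stages"].append("diff")
    report["diff_shape"] = list(diff.shape)
    report["n_surviving_edges"] = diff.n_surviving
    report["bonferroni_comparisons"] = len(parcellation.target_networks)
    report["network_tests"] = [r.to_dict() for r in network_results]
    report["overall_test"] = overall.to_dict()

    result = PipelineResult(
        parcellation=parcellation,
        panel=panel,
        diff=diff,
        network_results=network_results,
        overall=overall,
        truth=truth,
        placebo_stack=placebo,
        drug_stack=drug,
    )

    # --- modularity --------------------------------------------------------
    if cfg.run_modularity:
        dmn_graph = graph_mod.build_dmn_graph(diff)
        stability = graph_mod.stability_analysis(
            dmn_graph,
            gamma=cfg.gamma,
            n_iterations=cfg.iterations,
            seed=_stage_seed(cfg.seed, "modularity"),
            gammas=np.array(cfg.gamma_sweep) if cfg.gamma_sweep else None,
        )
        partition = stability.consensus
        sub_results = graph_mod.subnetwork_tests(diff, partition, parcellation)
        result.partition = partition
        result.stability = stability
        result.subnetwork_results = sub_results
        report["stages"].append("modularity")
        sizes = np.bincount(partition.labels).tolist()
        report["partition"] = {
            "n_communities": partition.n_communities,
            "sizes": sizes,
            "q_value": partition.q_value,
            "gamma": partition.gamma,
        }
        report["stability"] = {
            "n_iterations": stability.n_iterations,
            "min_pairwise_nmi": stability.min_pairwise_nmi,
            "mean_pairwise_nmi": stability.mean_pairwise_nmi,
        }
        if stability.gamma_sweep:
            report["gamma_sweep"] = [
                {"gamma": g, "nmi_vs_reference": v, "n_communities": k}
                for g, v, k in stability.gamma_sweep
            ]
        report["subnetwork_tests"] = [r.to_dict() for r in sub_results]

    # --- behavior ----------------------------------------------------------
    if cfg.run_behavior and behavior_table is not None:
        scores = behavior_mod.change_scores(
            placebo,
            drug,
            panel.subject_ids,
            diff,
            parcellation,
            partition=result.partition,
        )
        significant = [
            r.network
            for r in network_results
            if r.testable and r.p_bonf is not None and r.p_bonf < cfg.alpha
        ]
        columns = [
            c
            for c in scores.columns
            if c != "subject_id" and c.split("|")[1] in significant
        ] or None
        corr = behavior_mod.correlate_behavior(scores, behavior_table, columns)
        result.change_scores = scores
        result.behavior_corr = corr
        report["stages"].append("behavior")
        report["behavior_correlations"] = corr.to_dict(orient="records")

    if truth is not None and result.partition is not None:
        report["recovery"] = recover_ground_truth(result, truth, sim_cfg)

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(report, out / "report.json")
    return report, result


def _align_communities(
    partition: graph_mod.Partition, truth: GroundTruth
) -> dict[int, int]:
    """Map each planted sub-community (1, 2) to its best-overlap recovered
    label by greedy maximum overlap."""
    truth_labels = truth.dmn_labels
    mapping: dict[int, int] = {}
    taken: set[int] = set()
    for sub in sorted(set(truth_labels.tolist())):
        overlaps = {
            lab: int(np.sum((truth_labels == sub) & (partition.labels == lab)))
            for lab in range(partition.n_communities)
            if lab not in taken
        }
        if overlaps:
            best = max(overlaps, key=lambda k: (overlaps[k], -k))
            mapping[sub] = best
            taken.add(best)
    return mapping


def recover_ground_truth(
    result: PipelineResult, truth: GroundTruth, sim_cfg: SimConfig | None = None
) -> dict:
    """Score a simulated run against its planted structure.

    Returns partition NMI, the sign-agreement fraction of the sub-network
    tests over planted (sub-community, target) pairs, and — when the
    behavioral stage ran — the estimated coupling correlation next to the
    generating one.
    """
    if result.partition is None:
        raise ValueError("modularity stage did not run")
    partition = result.partition
    truth_labels = truth.dmn_labels
    if truth_labels.size != partition.labels.size:
        raise ValueError("partition and ground truth cover different node sets")
    metrics: dict = {"partition_nmi": graph_mod.nmi(partition.labels, truth_labels)}

    mapping = _align_communities(partition, truth)
    agreements = []
    by_key = {}
    for r in result.subnetwork_results or []:
        by_key[(r.subnetwork, r.network)] = r
    for sub, target, delta in truth.effect_map:
        r = by_key.get((mapping.get(sub), target))
        if r is None or not r.testable:
            agreements.append(0.0)
        else:
            agreements.append(float(np.sign(r.t) == np.sign(delta)))
    if agreements:
        metrics["sign_agreement"] = float(np.mean(agreements))

    if (
        result.behavior_corr is not None
        and sim_cfg is not None
        and sim_cfg.behavior_target is not None
        and len(result.behavior_corr)
    ):
        sub, target = sim_cfg.behavior_target
        lab = mapping.get(sub)
        corr = result.behavior_corr
        pick = corr[
            (corr["score"] == f"sub{lab + 1}|{target}") & (corr["measure"] == "bis_total")
        ]
        if lab is not None and len(pick):
            est = float(pick["r"].iloc[0])
            sd = sim_cfg.behavior_beta * sim_cfg.sigma_delta
            gen = (
                sd / np.sqrt(sd**2 + sim_cfg.behavior_noise_sd**2)
                if (sd or sim_cfg.behavior_noise_sd)
                else 0.0
            )
            metrics["behavior_r_estimated"] = est
            metrics["behavior_r_generating"] = float(gen)
            metrics["behavior_r_error"] = float(est - gen)
    return metrics
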