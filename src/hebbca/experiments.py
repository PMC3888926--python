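"""End-to-end spontaneous-ignition experiments.

One experiment runs: build network -> generate pattern pairs -> Hebbian
training -> membership probe -> spontaneous (noise-only) recording ->
ignition detection -> ASI extraction and baseline alignment -> per-step
repeated-measures ANOVA with planned comparisons.  Three variants are
supported: ``full`` (all links, noise on), ``no_jumping`` (serial
connectivity), and ``no_noise`` (noise switched off for the spontaneous
phase only; training is unchanged).
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import io as hio
from .analysis import (
    ASI,
    CAMembership,
    IgnitionEvent,
    align_baseline,
    ca_size_table,
    detect_ignitions,
    events_table,
    extract_asi,
    identify_ca_cells,
)
from .architecture import AREAS, CENTRALITY, Network, audit_graph, build_network
from .config import ExperimentConfig
from .dynamics import Simulator
from .stats import activation_onset_summary, anova_per_step
from .training import (
    PatternPair,
    generate_pattern_pairs,
    probe_responses,
    run_training,
)

logger = logging.getLogger("hebbca")


@dataclass
class RunRecord:
    """All products of one experiment run."""

    config: ExperimentConfig
    network: Network
    patterns: List[PatternPair]
    training_log: pd.DataFrame
    profile: np.ndarray
    membership: CAMembership
    recording: np.ndarray
    events: List[IgnitionEvent]
    asis: Dict[int, ASI]
    windows: np.ndarray
    window_ca_ids: List[int]
    anova: Optional[pd.DataFrame]
    onsets: Dict[str, Optional[int]]
    timings: Dict[str, float] = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def n_igniting_cas(self) -> int:
        return len({ev.ca_id for ev in self.events})

    def mean_ca_size_per_area(self) -> pd.Series:
        sizes = np.array(
            [
                self.membership.size_per_area(w)
                for w in range(self.membership.n_patterns)
            ]
        )
        return pd.Series(sizes.mean(axis=0), index=list(AREAS), name="mean_ca_size")


def _spawn_seeds(seed: int, n: int) -> List[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def run_experiment(
    config: ExperimentConfig,
    outdir: Optional[Path] = None,
    keep_recording: bool = True,
) -> RunRecord:
    """Execute one full experiment and (optionally) persist its artifacts.

    All randomness derives from ``config.seed`` through independent
    child streams for network construction, pattern generation, the
    training schedule, training noise, probe noise, and the spontaneous
    recording; identical configurations therefore reproduce identical
    event tables and statistics.
    """
    config.validate()
    t_all = time.time()
    timings: Dict[str, float] = {}
    (
        s_net, s_pat, s_sched, s_train, s_probe, s_rec,
    ) = _spawn_seeds(config.seed, 6)

    def stage(name):
        timings[name] = time.time()
        logger.info("stage %s", name)

    stage("build")
    net = build_network(config.graph_variant, config.architecture, seed=s_net)
    patterns = generate_pattern_pairs(
        config.patterns.n_patterns,
        config.patterns.cells_per_pattern,
        config.patterns.overlap_cells,
        area_size=config.architecture.cells_per_area,
        seed=s_pat,
    )
    timings["build"] = time.time() - timings["build"]

    stage("train")
    sim = Simulator(net, config.dynamics, seed=s_train)
    training_log = run_training(
        sim, patterns, config.schedule, config.plasticity, seed=s_sched
    )
    timings["train"] = time.time() - timings["train"]

    stage("probe")
    sim_probe = Simulator(net, config.dynamics, seed=s_probe)
    profile = probe_responses(sim_probe, patterns, config.schedule, config.probe)
    membership = identify_ca_cells(profile, gamma=config.analysis.gamma)
    timings["probe"] = time.time() - timings["probe"]

    stage("record")
    rec_dyn = dataclasses.replace(config.dynamics)
    if config.variant == "no_noise":
        rec_dyn.k2 = 0.0   # spontaneous phase only; training was noisy
    sim_rec = Simulator(net, rec_dyn, seed=s_rec)
    recording = sim_rec.record_spontaneous(
        config.recording_steps, settle=config.settle_steps
    )
    timings["record"] = time.time() - timings["record"]

    stage("analyze")
    events = detect_ignitions(recording, membership, config.analysis)
    asis = extract_asi(recording, events, membership, config.analysis)
    windows, ca_ids, _origins = align_baseline(asis, config.analysis)
    timings["analyze"] = time.time() - timings["analyze"]

    stage("stats")
    anova = None
    onsets: Dict[str, Optional[int]] = {
        "primary": None, "secondary": None, "central": None,
    }
    if windows.shape[0] >= 2 and not np.isnan(windows).any():
        anova = anova_per_step(windows)
        onsets = activation_onset_summary(anova)
    timings["stats"] = time.time() - timings["stats"]
    timings["total"] = time.time() - t_all

    record = RunRecord(
        config=config,
        network=net,
        patterns=patterns,
        training_log=training_log,
        profile=profile,
        membership=membership,
        recording=recording if keep_recording else np.empty((0, net.n_cells)),
        events=events,
        asis=asis,
        windows=windows,
        window_ca_ids=ca_ids,
        anova=anova,
        onsets=onsets,
        timings=timings,
    )
    if outdir is not None:
        write_run_artifacts(record, Path(outdir))
    return record


def write_run_artifacts(rec: RunRecord, outdir: Path) -> None:
    """Persist a run: config YAML, network/recording HDF5, events CSV,
    membership JSON, ASI NPZ, stats CSV and a Markdown report."""
    outdir.mkdir(parents=True, exist_ok=True)
    rec.config.to_yaml(outdir / "config.yaml")
    hio.save_network(rec.network, outdir / "network.h5")
    if rec.recording.size:
        hio.save_recording(
            rec.recording, outdir / "recording.h5", rec.network.cells_per_area
        )
    events_table(rec.events).to_csv(outdir / "events.csv", index=False)
    hio.save_membership(rec.membership, outdir / "membership.json")
    if rec.asis:
        hio.save_asis(rec.asis, outdir / "asi.npz")
    rec.training_log.to_csv(outdir / "training_log.csv", index=False)
    degree, links = audit_graph(rec.network)
    degree.to_csv(outdir / "audit_degrees.csv", index=False)
    links.to_csv(outdir / "audit_links.csv", index=False)
    ca_size_table(rec.profile).to_csv(outdir / "ca_sizes.csv")
    if rec.anova is not None:
        rec.anova.to_csv(outdir / "anova.csv", index=False)
    (outdir / "report.md").write_text(render_report(rec))


def render_report(rec: RunRecord) -> str:
    """Markdown summary of one run."""
    lines = [
        "# Spontaneous ignition run report",
        "",
        f"- variant: {rec.config.variant} (graph: {rec.config.graph_variant})",
        f"- scale: {rec.config.scale}, seed: {rec.config.seed}",
        f"- recording steps: {rec.config.recording_steps}",
        f"- ignition events: {rec.n_events} across {rec.n_igniting_cas} CAs "
        f"(of {rec.membership.n_patterns} trained)",
        "",
        "## Mean CA size per area",
        "",
        rec.mean_ca_size_per_area().to_frame().to_markdown(),
        "",
        "## First significant above-baseline step per centrality level",
        "",
    ]
    for lev in ("central", "secondary", "primary"):
        lines.append(f"- {lev}: {rec.onsets.get(lev)}")
    lines.append("")
    lines.append("## Stage timings (s)")
    lines.append("")
    for k, v in rec.timings.items():
        lines.append(f"- {k}: {v:.2f}")
    lines.append("")
    return "\n".join(lines)


def record_without_noise(
    rec: RunRecord, steps: Optional[int] = None, seed: int = 0
) -> List[IgnitionEvent]:
    """Re-record a trained network's spontaneous phase with noise off.

    Sets k2 = 0 for the spontaneous phase only (training is untouched:
    the already-trained weights are reused) and returns the ignition
    events detected in the noise-free recording.
    """
    dyn = dataclasses.replace(rec.config.dynamics, k2=0.0)
    sim = Simulator(rec.network, dyn, seed=seed)
    silent = sim.record_spontaneous(
        steps or rec.config.recording_steps, settle=rec.config.settle_steps
    )
    return detect_ignitions(silent, rec.membership, rec.config.analysis)


def onset_majority(
    onsets_per_seed: List[Dict[str, Optional[int]]], level: str
) -> Optional[int]:
    """Majority vote of first-significant steps across seeds (ties break
    toward the smaller step; None votes are ignored)."""
    votes = [o[level] for o in onsets_per_seed if o.get(level) is not None]
    if not votes:
        return None
    vals, counts = np.unique(votes, return_counts=True)
    return int(vals[np.argmax(counts)])
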