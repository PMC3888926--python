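"""Sensorimotor pattern pairs, the training protocol, and the
post-training probe.

Training repeatedly co-activates one sensory pattern (cells in area P1)
with its paired motor pattern (cells in M1), interleaving the pattern
pairs in random order with variable inter-stimulus intervals, while the
Hebbian rule shapes every excitatory link.  Repetition grows a
pair-specific cell assembly (CA) spanning all six areas, such that
presenting only one component reactivates the whole circuit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .config import PlasticityParams, ProbeParams, TrainingSchedule
from .dynamics import Simulator


@dataclass
class PatternPair:
    """One sensorimotor association: cell indices within P1 and M1 grids."""

    id: int
    p1_cells: np.ndarray   # flat indices within the P1 grid
    m1_cells: np.ndarray   # flat indices within the M1 grid

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "p1_cells": [int(c) for c in self.p1_cells],
            "m1_cells": [int(c) for c in self.m1_cells],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PatternPair":
        return cls(
            id=int(d["id"]),
            p1_cells=np.asarray(d["p1_cells"], dtype=np.int64),
            m1_cells=np.asarray(d["m1_cells"], dtype=np.int64),
        )


def save_patterns(patterns: Sequence[PatternPair], path) -> None:
    with open(path, "w") as fh:
        json.dump([p.to_dict() for p in patterns], fh, indent=1)


def load_patterns(path) -> List[PatternPair]:
    with open(path) as fh:
        return [PatternPair.from_dict(d) for d in json.load(fh)]


def _ring_sets(
    n_patterns: int, cells: int, overlap: int, area_size: int,
    rng: np.random.Generator,
) -> List[np.ndarray]:
    """Sample ``n_patterns`` index sets of size ``cells`` from one grid.

    Patterns are arranged on a ring; consecutive patterns share exactly
    ``overlap`` cells, non-consecutive patterns are disjoint.  With two
    patterns a single shared block is used; with one, no sharing."""
    if overlap == 0 or n_patterns == 1:
        total = n_patterns * cells
        if total > area_size:
            raise ValueError("patterns do not fit in the area")
        pool = rng.choice(area_size, size=total, replace=False)
        return [pool[k * cells:(k + 1) * cells] for k in range(n_patterns)]
    if n_patterns == 2:
        if cells < overlap:
            raise ValueError("overlap exceeds pattern size")
        total = 2 * cells - overlap
        if total > area_size:
            raise ValueError("patterns do not fit in the area")
        pool = rng.choice(area_size, size=total, replace=False)
        shared = pool[:overlap]
        u = cells - overlap
        return [
            np.concatenate([shared, pool[overlap:overlap + u]]),
            np.concatenate([shared, pool[overlap + u:]]),
        ]
    if cells < 2 * overlap:
        raise ValueError("pattern size must be at least twice the overlap")
    unique = cells - 2 * overlap
    total = n_patterns * (overlap + unique)
    if total > area_size:
        raise ValueError("patterns do not fit in the area")
    pool = rng.choice(area_size, size=total, replace=False)
    blocks = [pool[k * overlap:(k + 1) * overlap] for k in range(n_patterns)]
    off = n_patterns * overlap
    sets = []
    for k in range(n_patterns):
        own = pool[off + k * unique: off + (k + 1) * unique]
        nxt = blocks[(k + 1) % n_patterns]
        sets.append(np.concatenate([blocks[k], own, nxt]))
    return sets


def generate_pattern_pairs(
    n_patterns: int = 12,
    cells_per_pattern: int = 20,
    overlap_cells: int = 4,
    area_size: int = 625,
    seed: int = 0,
) -> List[PatternPair]:
    """Generate the to-be-memorised sensorimotor pattern pairs.

    Each pair identifies ``cells_per_pattern`` cells in P1 and the same
    number in M1.  Patterns overlap partially: each shares
    ``overlap_cells`` cells with its ring-neighbouring pattern(s) in each
    area, mimicking shared perceptual/motor features across action
    schemata.  Deterministic under ``seed``.
    """
    if cells_per_pattern < 1 or n_patterns < 1:
        raise ValueError("need at least one pattern with at least one cell")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_p1, rng_m1 = (np.random.default_rng(c) for c in ss.spawn(2))
    p1 = _ring_sets(n_patterns, cells_per_pattern, overlap_cells, area_size, rng_p1)
    m1 = _ring_sets(n_patterns, cells_per_pattern, overlap_cells, area_size, rng_m1)
    return [
        PatternPair(id=k + 1, p1_cells=np.sort(p1[k]), m1_cells=np.sort(m1[k]))
        for k in range(n_patterns)
    ]


def pattern_stimulus(
    sim: Simulator, pattern: PatternPair, amplitude: float
) -> np.ndarray:
    """Additive-input vector activating one pattern's P1 and M1 cells."""
    p1 = sim.net.area_slice("P1").start + pattern.p1_cells
    m1 = sim.net.area_slice("M1").start + pattern.m1_cells
    return sim.stimulus_vector(np.concatenate([p1, m1]), amplitude)


def run_training(
    sim: Simulator,
    patterns: Sequence[PatternPair],
    schedule: TrainingSchedule,
    plasticity: PlasticityParams,
    seed: int = 0,
    checkpoint_callback=None,
) -> pd.DataFrame:
    """Run the full training protocol on a fresh (tabula-rasa) network.

    Presents every pattern pair ``presentations_per_pattern`` times in
    globally random order.  Each presentation drives the pair's P1 and M1
    cells with the stimulus amplitude for ``stimulus_steps`` steps and is
    followed by an inter-stimulus interval drawn uniformly from
    ``isi_range``; plasticity acts throughout.  Returns the training log
    (one row per presentation).  If activity diverges the run aborts with
    the last checkpoint retained (via ``checkpoint_callback``).
    """
    schedule.validate()
    rng = np.random.default_rng(seed)
    order = np.repeat(
        np.arange(len(patterns)), schedule.presentations_per_pattern
    )
    rng.shuffle(order)
    isis = rng.integers(
        schedule.isi_range[0], schedule.isi_range[1] + 1, size=order.size
    )
    stims = [
        pattern_stimulus(sim, p, schedule.stimulus_amplitude) for p in patterns
    ]
    log = {
        "presentation": np.arange(order.size),
        "pattern_id": np.array([patterns[k].id for k in order]),
        "isi": isis,
        "mean_output": np.zeros(order.size),
    }
    for n, (k, isi) in enumerate(zip(order, isis)):
        sim.run(schedule.stimulus_steps, stim=stims[k], plasticity=plasticity)
        log["mean_output"][n] = sim.O_exc.mean()
        sim.run(int(isi), plasticity=plasticity)
        if (
            schedule.checkpoint_every
            and checkpoint_callback is not None
            and (n + 1) % schedule.checkpoint_every == 0
        ):
            checkpoint_callback(sim, n + 1)
    return pd.DataFrame(log)


def probe_responses(
    sim: Simulator,
    patterns: Sequence[PatternPair],
    schedule: TrainingSchedule,
    probe: Optional[ProbeParams] = None,
) -> np.ndarray:
    """Measure each excitatory cell's time-averaged response per pattern.

    With plasticity frozen and the network reset to rest before every
    probe, each pattern is presented ``probe.n_reps`` times; the cell's
    output is averaged over ``probe.window_len`` steps starting
    ``probe.window_offset`` steps after stimulus onset, then across
    repetitions.  Returns an array of shape ``(n_patterns, n_cells)``
    with values in [0, 1].
    """
    probe = probe or ProbeParams()
    n_steps = probe.window_offset + probe.window_len
    profile = np.zeros((len(patterns), sim.N))
    for k, pat in enumerate(patterns):
        stim = pattern_stimulus(sim, pat, schedule.stimulus_amplitude)
        for _ in range(probe.n_reps):
            sim.reset()
            acc = np.zeros(sim.N)
            for s in range(n_steps):
                # stimulus stays on for the scheduled duration only
                on = stim if s < schedule.stimulus_steps else None
                sim.step(stim=on)
                if s >= probe.window_offset:
                    acc += sim.O_exc
            profile[k] += acc / probe.window_len
        profile[k] /= probe.n_reps
    sim.reset()
    return profile
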