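"""Cell-assembly membership, spontaneous-ignition detection, and
event-aligned trial averaging (ASI).

A cell belongs to the CA of pattern w in area A when its probe-averaged
response reaches ``gamma`` times the maximal single-cell average
response to w in that area.  During spontaneous (noise-driven) activity,
a CA counts as *active* at a step when at least half of its member cells
(pooled over all six areas) fire above the same area- and
pattern-specific threshold; maximal runs of active steps are ignition
events.  The average spontaneous ignition (ASI) of a CA is the per-area
mean time course of above-threshold member counts over all its events,
each aligned 10 steps before onset in a 40-step trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .architecture import AREAS
from .config import AnalysisParams


@dataclass
class CAMembership:
    """Membership of every pattern's CA, per area.

    ``thresholds[w, a]`` is ``theta_w(A) = gamma * max`` of pattern w's
    average response in area a; ``members[w]`` is a boolean mask over all
    excitatory cells; ``empty[w]`` flags patterns whose probe profile was
    all-zero in some area (no meaningful threshold there).
    """

    gamma: float
    areas: Tuple[str, ...]
    cells_per_area: int
    thresholds: np.ndarray        # (n_patterns, n_areas)
    members: np.ndarray           # (n_patterns, n_cells) bool
    empty: np.ndarray             # (n_patterns,) bool

    @property
    def n_patterns(self) -> int:
        return self.thresholds.shape[0]

    def member_indices(self, w: int) -> np.ndarray:
        return np.flatnonzero(self.members[w])

    def cell_thresholds(self, w: int) -> np.ndarray:
        """Per-cell threshold vector (each cell gets its area's theta)."""
        return np.repeat(self.thresholds[w], self.cells_per_area)

    def size_per_area(self, w: int) -> np.ndarray:
        return self.members[w].reshape(len(self.areas), -1).sum(axis=1)

    def to_dict(self) -> dict:
        return {
            "gamma": self.gamma,
            "areas": list(self.areas),
            "cells_per_area": self.cells_per_area,
            "patterns": [
                {
                    "pattern": w + 1,
                    "thresholds": [float(t) for t in self.thresholds[w]],
                    "members": [int(c) for c in self.member_indices(w)],
                    "empty": bool(self.empty[w]),
                }
                for w in range(self.n_patterns)
            ],
        }


def identify_ca_cells(
    profile: np.ndarray,
    gamma: float = 0.5,
    areas: Tuple[str, ...] = AREAS,
) -> CAMembership:
    """Threshold probe profiles into CA membership.

    ``profile`` has shape ``(n_patterns, n_cells)`` with the areas
    concatenated in order.  Per pattern and area the threshold is
    ``gamma`` times the area's maximal average response; members are the
    cells at or above it.  A pattern with an all-zero profile in an area
    gets no members there and is flagged ``empty``.
    """
    if not 0 <= gamma <= 1:
        raise ValueError("gamma must be in [0, 1]")
    n_patterns, n_cells = profile.shape
    n_areas = len(areas)
    if n_cells % n_areas:
        raise ValueError("profile width not divisible by the number of areas")
    A = n_cells // n_areas
    by_area = profile.reshape(n_patterns, n_areas, A)
    area_max = by_area.max(axis=2)                       # (w, a)
    thresholds = gamma * area_max
    members = by_area >= thresholds[:, :, None]
    # an all-zero area profile would make every cell a "member" at
    # threshold 0; such CAs are empty there instead, and flagged
    dead = area_max <= 0.0
    members &= ~dead[:, :, None]
    return CAMembership(
        gamma=gamma,
        areas=tuple(areas),
        cells_per_area=A,
        thresholds=thresholds,
        members=members.reshape(n_patterns, n_cells),
        empty=dead.any(axis=1),
    )


def ca_size_table(
    profile: np.ndarray,
    gammas: Sequence[float] = (0.01, 0.02, 0.04, 0.05, 0.1, 0.2, 0.4, 0.5),
    areas: Tuple[str, ...] = AREAS,
) -> pd.DataFrame:
    """Mean CA size (member count) per area across membership thresholds.

    Rows are areas, one column per ``gamma``; each entry is the member
    count averaged over patterns.
    """
    cols = {}
    for g in gammas:
        m = identify_ca_cells(profile, gamma=g, areas=areas)
        sizes = np.array([m.size_per_area(w) for w in range(m.n_patterns)])
        cols[g] = sizes.mean(axis=0)
    df = pd.DataFrame(cols, index=list(areas))
    df.index.name = "area"
    return df


@dataclass
class IgnitionEvent:
    """One maximal episode of CA activity (steps inclusive)."""

    ca_id: int
    onset: int
    offset: int
    peak_fraction: float

    @property
    def duration(self) -> int:
        return self.offset - self.onset + 1


def active_fraction(
    recording: np.ndarray, membership: CAMembership, w: int
) -> np.ndarray:
    """Per-step fraction of pattern w's CA cells firing above threshold.

    CA cells are pooled over all six areas; each cell is compared with
    its own area's threshold ``theta_w(A)``.
    """
    cells = membership.member_indices(w)
    if cells.size == 0:
        return np.zeros(recording.shape[0])
    theta = membership.cell_thresholds(w)[cells]
    above = recording[:, cells] >= theta
    return above.sum(axis=1) / cells.size


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal runs of True as (start, stop) inclusive."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    brk = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[brk + 1]])
    stops = np.concatenate([idx[brk], [idx[-1]]])
    return list(zip(starts.tolist(), stops.tolist()))


def detect_ignitions(
    recording: np.ndarray,
    membership: CAMembership,
    params: Optional[AnalysisParams] = None,
    ca_ids: Optional[Sequence[int]] = None,
) -> List[IgnitionEvent]:
    """Find spontaneous ignition events of every CA in a recording.

    ``recording`` is the excitatory output time series, shape
    ``(steps, n_cells)``.  A CA is active at a step iff at least
    ``ignition_fraction`` (default 50%) of its member cells fire at or
    above their area's threshold; events are maximal runs of active
    steps, with runs separated by at most ``min_gap`` silent steps merged.
    """
    params = params or AnalysisParams()
    events: List[IgnitionEvent] = []
    ws = range(membership.n_patterns) if ca_ids is None else ca_ids
    for w in ws:
        frac = active_fraction(recording, membership, w)
        runs = _runs(frac >= params.ignition_fraction)
        if params.min_gap > 0 and len(runs) > 1:
            merged = [runs[0]]
            for s, e in runs[1:]:
                if s - merged[-1][1] - 1 <= params.min_gap:
                    merged[-1] = (merged[-1][0], e)
                else:
                    merged.append((s, e))
            runs = merged
        for s, e in runs:
            events.append(
                IgnitionEvent(
                    ca_id=w + 1,
                    onset=int(s),
                    offset=int(e),
                    peak_fraction=float(frac[s:e + 1].max()),
                )
            )
    return events


def events_table(events: Sequence[IgnitionEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ca_id": ev.ca_id,
                "onset": ev.onset,
                "offset": ev.offset,
                "duration": ev.duration,
                "peak_fraction": ev.peak_fraction,
            }
            for ev in events
        ],
        columns=["ca_id", "onset", "offset", "duration", "peak_fraction"],
    )


@dataclass
class ASI:
    """Average spontaneous ignition of one CA.

    ``counts[a, t]`` is the mean (over trials) number of the CA's member
    cells in area a firing above threshold at trial step t; trials are
    ``trial_len`` steps, aligned ``pre_onset`` steps before event onset.
    ``normalized`` divides each area's trace by that area's CA size
    (NaN where the CA has no cells in an area).
    """

    ca_id: int
    counts: np.ndarray        # (n_areas, trial_len)
    normalized: np.ndarray    # (n_areas, trial_len)
    n_trials: int
    pre_onset: int


def extract_asi(
    recording: np.ndarray,
    events: Sequence[IgnitionEvent],
    membership: CAMembership,
    params: Optional[AnalysisParams] = None,
) -> Dict[int, ASI]:
    """Build per-CA, per-area ASI traces from detected events.

    Every event whose window ``[onset - pre_onset, onset + trial_len -
    pre_onset)`` lies inside the recording contributes one trial; CAs
    with no usable trial are excluded (only CAs that ignited at least
    once enter the analysis).
    """
    params = params or AnalysisParams()
    T = recording.shape[0]
    n_areas = len(membership.areas)
    out: Dict[int, ASI] = {}
    by_ca: Dict[int, List[IgnitionEvent]] = {}
    for ev in events:
        by_ca.setdefault(ev.ca_id, []).append(ev)
    for ca_id, evs in sorted(by_ca.items()):
        w = ca_id - 1
        cells = membership.member_indices(w)
        if cells.size == 0:
            continue
        theta = membership.cell_thresholds(w)[cells]
        area_of_cell = cells // membership.cells_per_area
        sizes = membership.size_per_area(w).astype(float)
        trials = []
        for ev in evs:
            start = ev.onset - params.pre_onset
            stop = start + params.trial_len
            if start < 0 or stop > T:
                continue
            above = recording[start:stop, cells] >= theta     # (len, cells)
            counts = np.zeros((n_areas, params.trial_len))
            for a in range(n_areas):
                counts[a] = above[:, area_of_cell == a].sum(axis=1)
            trials.append(counts)
        if not trials:
            continue
        counts = np.mean(trials, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            normalized = np.where(
                sizes[:, None] > 0, counts / sizes[:, None], np.nan
            )
        out[ca_id] = ASI(
            ca_id=ca_id,
            counts=counts,
            normalized=normalized,
            n_trials=len(trials),
            pre_onset=params.pre_onset,
        )
    return out


def align_baseline(
    asis: Dict[int, ASI],
    params: Optional[AnalysisParams] = None,
) -> Tuple[np.ndarray, List[int], List[int]]:
    """Extract the critical ignition window from each CA's ASI.

    For every CA, time 0 is the last pre-onset step at which the average
    number of active CA cells is still exactly zero in all areas; the
    window covers ``critical_window`` consecutive steps from there (on
    the normalized traces).  CAs without an all-zero pre-onset step, or
    whose window would overrun the trial, are excluded.

    Returns ``(windows, ca_ids, origins)`` with ``windows`` of shape
    ``(n_kept, n_areas, critical_window)``.
    """
    params = params or AnalysisParams()
    windows, kept, origins = [], [], []
    for ca_id, asi in sorted(asis.items()):
        zero = (asi.counts == 0).all(axis=0)   # all areas silent
        pre = np.flatnonzero(zero[: asi.pre_onset + 1])
        if pre.size == 0:
            continue
        t0 = int(pre[-1])
        if t0 + params.critical_window > asi.counts.shape[1]:
            continue
        windows.append(asi.normalized[:, t0:t0 + params.critical_window])
        kept.append(ca_id)
        origins.append(t0)
    if windows:
        return np.array(windows), kept, origins
    return (
        np.empty((0, len(next(iter(asis.values())).counts) if asis else 0,
                  params.critical_window)),
        kept,
        origins,
    )
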