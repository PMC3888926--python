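"""Repeated-measures ANOVA and planned comparisons on critical-window
ignition data.

The design treats each cell assembly as a subject measured once in every
area; the six areas cross two within-subject factors, centrality
(primary = {P1, M1}, secondary = {HP, PM}, central = {PA, PF}) and
frontality (posterior = {P1, HP, PA}, anterior = {M1, PM, PF}).  One
two-way repeated-measures ANOVA is run per time step of the critical
window, with planned one-degree-of-freedom contrasts (each centrality
level against the zero baseline, and pairwise between levels) computed
from per-subject contrast scores, so an analysis over n subjects yields
F(1, n-1) statistics.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .architecture import AREAS, CENTRALITY, FRONTALITY

CENTRALITY_LEVELS: Tuple[str, ...] = ("primary", "secondary", "central")
FRONTALITY_LEVELS: Tuple[str, ...] = ("posterior", "anterior")

#: column index of each area in a (subject, area) value matrix
AREA_INDEX = {a: i for i, a in enumerate(AREAS)}


def _factor_cube(values: np.ndarray, areas: Sequence[str] = AREAS) -> np.ndarray:
    """Reshape (n_subjects, n_areas) values into (n, centrality, frontality)."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    cube = np.empty((n, len(CENTRALITY_LEVELS), len(FRONTALITY_LEVELS)))
    for j, area in enumerate(areas):
        a = CENTRALITY_LEVELS.index(CENTRALITY[area])
        b = FRONTALITY_LEVELS.index(FRONTALITY[area])
        cube[:, a, b] = values[:, j]
    return cube


def rm_anova(values: np.ndarray, areas: Sequence[str] = AREAS) -> pd.DataFrame:
    """Two-way fully-within repeated-measures ANOVA.

    ``values`` has shape ``(n_subjects, 6)`` with one observation per
    subject and area.  Each effect is tested against its own
    effect-by-subject interaction.  Returns a table with rows
    ``centrality``, ``frontality`` and ``interaction`` and columns
    ``F``, ``df1``, ``df2``, ``p``.
    """
    Y = _factor_cube(values, areas)
    n, a, b = Y.shape
    if n < 2:
        raise ValueError("repeated-measures ANOVA needs at least 2 subjects")
    g = Y.mean()
    A = Y.mean(axis=(0, 2))      # centrality means
    B = Y.mean(axis=(0, 1))      # frontality means
    S = Y.mean(axis=(1, 2))      # subject means
    AB = Y.mean(axis=0)
    AS = Y.mean(axis=2)
    BS = Y.mean(axis=1)

    ss_a = n * b * ((A - g) ** 2).sum()
    ss_b = n * a * ((B - g) ** 2).sum()
    ss_ab = n * ((AB - A[:, None] - B[None, :] + g) ** 2).sum()
    ss_as = b * ((AS - A[None, :] - S[:, None] + g) ** 2).sum()
    ss_bs = a * ((BS - B[None, :] - S[:, None] + g) ** 2).sum()
    resid = (
        Y
        - AB[None, :, :]
        - AS[:, :, None]
        - BS[:, None, :]
        + A[None, :, None]
        + B[None, None, :]
        + S[:, None, None]
        - g
    )
    ss_abs = (resid ** 2).sum()

    rows = []
    for name, ss_eff, df1, ss_err, df2 in (
        ("centrality", ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        ("frontality", ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        ("interaction", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)),
    ):
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        # scale-aware zero guard: exactly-degenerate designs (no variance
        # in the error term) would otherwise divide rounding dust
        eps = 1e-12 * max(float(np.abs(Y).max()) ** 2, 1.0)
        if ms_err > eps:
            F = ms_eff / ms_err
            p = float(sps.f.sf(F, df1, df2))
        else:
            F = 0.0 if ms_eff <= eps else np.inf
            p = 1.0 if ms_eff <= eps else 0.0
        rows.append({"effect": name, "F": F, "df1": df1, "df2": df2, "p": p})
    return pd.DataFrame(rows).set_index("effect")


def planned_contrast(scores: np.ndarray) -> Dict[str, float]:
    """One-df contrast test from per-subject contrast scores.

    Tests the mean of ``scores`` against zero (equivalent to a paired /
    one-sample t-test), reported as F(1, n-1) with a two-sided p.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n < 2:
        raise ValueError("contrast needs at least 2 subjects")
    mean = scores.mean()
    var = scores.var(ddof=1)
    eps = 1e-12 * max(float(np.abs(scores).max()) ** 2, 1e-300)
    if var > eps:
        F = n * mean ** 2 / var
        p = float(sps.f.sf(F, 1, n - 1))
    else:
        F = 0.0 if mean == 0 else np.inf
        p = 1.0 if mean == 0 else 0.0
    return {"F": float(F), "df1": 1, "df2": n - 1, "p": p}


def centrality_scores(values: np.ndarray, level: str,
                      areas: Sequence[str] = AREAS) -> np.ndarray:
    """Per-subject mean over the two areas of one centrality level."""
    cols = [j for j, ar in enumerate(areas) if CENTRALITY[ar] == level]
    return np.asarray(values, dtype=float)[:, cols].mean(axis=1)


def anova_per_step(
    windows: np.ndarray,
    areas: Sequence[str] = AREAS,
) -> pd.DataFrame:
    """Per-time-step ANOVA and planned comparisons on critical-window data.

    ``windows`` has shape ``(n_subjects, n_areas, n_steps)`` (normalized
    ASI values).  For each step the two-way RM-ANOVA main effects and
    interaction are computed, plus planned contrasts: each centrality
    level against baseline 0, central vs secondary, and secondary vs
    primary.  Returns a long table with one row per step and test.
    """
    windows = np.asarray(windows, dtype=float)
    n, n_areas, n_steps = windows.shape
    rows: List[dict] = []
    for t in range(n_steps):
        vals = windows[:, :, t]
        an = rm_anova(vals, areas)
        for effect, r in an.iterrows():
            rows.append(
                {"step": t, "test": f"main:{effect}", "F": r.F,
                 "df1": int(r.df1), "df2": int(r.df2), "p": r.p}
            )
        level_means = {
            lev: centrality_scores(vals, lev, areas) for lev in CENTRALITY_LEVELS
        }
        for lev in CENTRALITY_LEVELS:
            c = planned_contrast(level_means[lev])
            rows.append(
                {"step": t, "test": f"vs_baseline:{lev}", **c}
            )
        for lev_a, lev_b in (("central", "secondary"), ("secondary", "primary")):
            c = planned_contrast(level_means[lev_a] - level_means[lev_b])
            rows.append(
                {"step": t, "test": f"pairwise:{lev_a}-{lev_b}", **c}
            )
    return pd.DataFrame(rows)


def activation_onset_summary(
    anova_table: pd.DataFrame, alpha: float = 0.05
) -> Dict[str, Optional[int]]:
    """First time step at which each centrality level is significantly
    above baseline (contrast p < alpha); None when never significant."""
    out: Dict[str, Optional[int]] = {}
    for lev in CENTRALITY_LEVELS:
        sub = anova_table[anova_table["test"] == f"vs_baseline:{lev}"]
        sig = sub[sub["p"] < alpha]
        out[lev] = int(sig["step"].min()) if len(sig) else None
    return out
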