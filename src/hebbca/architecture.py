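"""Six-area network graph with sparse, patchy, topographic projections.

The six model areas form a chain P1 - HP - PA - PF - PM - M1 of
reciprocally linked neighbours; the *full* variant adds reciprocal
"jumping" links that skip one intermediate area (P1-PA, HP-PF, PA-PM,
PF-M1), giving between-area partner counts 4 : 3 : 2 for central
(PA, PF) : secondary (HP, PM) : primary (P1, M1) areas.  The *serial*
variant keeps only the chain (2 : 2 : 1).

Each area holds one excitatory and one inhibitory cell grid (default
25 x 25).  Excitatory projections (within- and between-area) are sampled
inside an ``n x n`` topographic neighbourhood with a Gaussian
distance fall-off; each inhibitory cell pools excitatory output from a
small local neighbourhood and inhibits the single excitatory cell at its
own grid position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import ArchitectureParams

AREAS: Tuple[str, ...] = ("P1", "HP", "PA", "PF", "PM", "M1")

CENTRALITY: Dict[str, str] = {
    "P1": "primary", "M1": "primary",
    "HP": "secondary", "PM": "secondary",
    "PA": "central", "PF": "central",
}
FRONTALITY: Dict[str, str] = {
    "P1": "posterior", "HP": "posterior", "PA": "posterior",
    "M1": "anterior", "PM": "anterior", "PF": "anterior",
}

#: reciprocal links between chain-adjacent areas
CHAIN_LINKS: Tuple[Tuple[str, str], ...] = (
    ("P1", "HP"), ("HP", "PA"), ("PA", "PF"), ("PF", "PM"), ("PM", "M1"),
)
#: reciprocal links skipping one intermediate area
JUMPING_LINKS: Tuple[Tuple[str, str], ...] = (
    ("P1", "PA"), ("HP", "PF"), ("PA", "PM"), ("PF", "M1"),
)


def adjacency_pairs(variant: str) -> Tuple[Tuple[str, str], ...]:
    """Unordered between-area link pairs for a connectivity variant."""
    if variant == "full":
        return CHAIN_LINKS + JUMPING_LINKS
    if variant == "serial":
        return CHAIN_LINKS
    raise ValueError(f"unknown variant {variant!r}; expected 'full' or 'serial'")


def make_projection(
    rows: int,
    cols: int,
    n: int,
    sigma: float,
    p0: float,
    rng: np.random.Generator,
    exclude_self: bool = False,
    w_max: float = 0.1,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample one topographic sparse projection between two equally sized
    grids.

    A source cell at (i, j) may connect to target cells inside the
    ``n x n`` square centred on (i, j); each candidate pair is linked
    independently with probability ``p0 * exp(-d^2 / (2 sigma^2))`` where
    ``d`` is the grid distance, and receives a weight drawn uniformly
    from ]0, w_max].  Neighbourhoods are clipped (not wrapped) at the
    grid border.

    Returns ``(pre, post, w)`` flat-index arrays (row-major grid order).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not 0 < p0 <= 1:
        raise ValueError("p0 must be in (0, 1]")
    if n % 2 == 0:
        raise ValueError("neighbourhood size n must be odd")
    half = n // 2
    pre_parts: List[np.ndarray] = []
    post_parts: List[np.ndarray] = []
    ii, jj = np.mgrid[0:rows, 0:cols]
    for di in range(-half, half + 1):
        for dj in range(-half, half + 1):
            if exclude_self and di == 0 and dj == 0:
                continue
            p = p0 * np.exp(-(di * di + dj * dj) / (2.0 * sigma * sigma))
            # valid source cells whose shifted target stays in the grid
            mask = (
                (ii + di >= 0) & (ii + di < rows) & (jj + dj >= 0) & (jj + dj < cols)
            )
            src = (ii[mask] * cols + jj[mask]).ravel()
            hit = rng.random(src.size) < p
            if hit.any():
                src = src[hit]
                pre_parts.append(src)
                post_parts.append(src + di * cols + dj)
    if pre_parts:
        pre = np.concatenate(pre_parts)
        post = np.concatenate(post_parts)
    else:  # pragma: no cover - degenerate parameters
        pre = np.empty(0, dtype=np.int64)
        post = np.empty(0, dtype=np.int64)
    # uniform on ]0, w_max]: 1 - U[0,1) lies in ]0, 1]
    w = w_max * (1.0 - rng.random(pre.size))
    return pre, post, w


@dataclass
class Network:
    """A realised six-area network.

    ``W_ee`` maps the excitatory output vector to excitatory input
    (``W_ee[post, pre]``; within- plus between-area links).  ``W_ei``
    maps excitatory output to inhibitory-cell input (block-diagonal per
    area).  Each inhibitory cell feeds back onto the excitatory cell at
    its own grid position with weight ``w_ie`` (applied with negative
    sign by the simulator).
    """

    params: ArchitectureParams
    variant: str
    W_ee: sp.csr_matrix
    W_ei: sp.csr_matrix
    w_ie: float
    areas: Tuple[str, ...] = AREAS

    @property
    def cells_per_area(self) -> int:
        return self.params.cells_per_area

    @property
    def n_cells(self) -> int:
        return len(self.areas) * self.cells_per_area

    @property
    def area_of(self) -> np.ndarray:
        """Area index of every excitatory cell (flat global order)."""
        return np.repeat(np.arange(len(self.areas)), self.cells_per_area)

    def area_slice(self, area: str) -> slice:
        a = self.areas.index(area)
        n = self.cells_per_area
        return slice(a * n, (a + 1) * n)

    def partners(self, area: str) -> List[str]:
        """Between-area partners of an area under this variant."""
        out = []
        for a, b in adjacency_pairs(self.variant):
            if a == area:
                out.append(b)
            elif b == area:
                out.append(a)
        return sorted(out)

    def edge_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        """Per-edge (pre, post) global indices aligned with ``W_ee.data``."""
        indptr = self.W_ee.indptr
        post = np.repeat(np.arange(self.n_cells), np.diff(indptr))
        pre = self.W_ee.indices.copy()
        return pre, post

    def edge_list(self) -> pd.DataFrame:
        """Excitatory edge list with area names and grid coordinates."""
        pre, post = self.edge_arrays()
        n, cols = self.cells_per_area, self.params.cols
        df = pd.DataFrame(
            {
                "source_area": [self.areas[k] for k in pre // n],
                "source_i": (pre % n) // cols,
                "source_j": (pre % n) % cols,
                "target_area": [self.areas[k] for k in post // n],
                "target_i": (post % n) // cols,
                "target_j": (post % n) % cols,
                "weight": self.W_ee.data,
            }
        )
        return df


def build_network(
    variant: str = "full",
    params: Optional[ArchitectureParams] = None,
    seed: int = 0,
) -> Network:
    """Construct the six-area network for a connectivity variant.

    Within each area: excitatory->excitatory links in the ``n_exc``
    neighbourhood (no self-links) and excitatory->inhibitory links in the
    ``n_inh`` neighbourhood.  Between areas: reciprocal excitatory
    projections per the variant's adjacency, sampled independently per
    direction.  All sampling is driven by a single master seed.
    """
    params = params or ArchitectureParams()
    params.validate()
    pairs = adjacency_pairs(variant)
    areas = AREAS
    A = params.cells_per_area
    N = len(areas) * A
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)

    pre_parts: List[np.ndarray] = []
    post_parts: List[np.ndarray] = []
    w_parts: List[np.ndarray] = []
    ei_pre: List[np.ndarray] = []
    ei_post: List[np.ndarray] = []
    ei_w: List[np.ndarray] = []

    # deterministic child-seed order: 6 within + 6 local-inh + directed pairs
    directed = []
    for a, b in pairs:
        directed.append((a, b))
        directed.append((b, a))
    children = ss.spawn(2 * len(areas) + len(directed))
    it = iter(children)

    for ai, area in enumerate(areas):
        rng = np.random.default_rng(next(it))
        pre, post, w = make_projection(
            params.rows, params.cols, params.n_exc, params.sigma("exc"),
            params.p0_within, rng, exclude_self=True, w_max=params.w_init_max,
        )
        pre_parts.append(pre + ai * A)
        post_parts.append(post + ai * A)
        w_parts.append(w)
    for ai, area in enumerate(areas):
        rng = np.random.default_rng(next(it))
        pre, post, w = make_projection(
            params.rows, params.cols, params.n_inh, params.sigma("inh"),
            params.p0_ei, rng, exclude_self=False, w_max=params.w_init_max,
        )
        ei_pre.append(pre + ai * A)
        ei_post.append(post + ai * A)
        ei_w.append(w * params.g_ei)
    for src, dst in directed:
        rng = np.random.default_rng(next(it))
        pre, post, w = make_projection(
            params.rows, params.cols, params.n_exc, params.sigma("exc"),
            params.p0_between, rng, exclude_self=False, w_max=params.w_init_max,
        )
        pre_parts.append(pre + areas.index(src) * A)
        post_parts.append(post + areas.index(dst) * A)
        w_parts.append(w)

    W_ee = sp.csr_matrix(
        (
            np.concatenate(w_parts),
            (np.concatenate(post_parts), np.concatenate(pre_parts)),
        ),
        shape=(N, N),
    )
    W_ei = sp.csr_matrix(
        (np.concatenate(ei_w), (np.concatenate(ei_post), np.concatenate(ei_pre))),
        shape=(N, N),
    )
    W_ee.sum_duplicates()
    W_ei.sum_duplicates()
    return Network(params=params, variant=variant, W_ee=W_ee, W_ei=W_ei,
                   w_ie=params.w_ie)


def audit_graph(net: Network) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Summarise the between-area wiring of a built network.

    Returns ``(degree_table, link_table)``: per-area between-area partner
    counts with centrality labels, and per-area mean in/out between-area
    link counts per cell.
    """
    A = net.cells_per_area
    area_of = net.area_of
    pre, post = net.edge_arrays()
    between = area_of[pre] != area_of[post]
    rows = []
    for ai, area in enumerate(net.areas):
        rows.append(
            {
                "area": area,
                "centrality": CENTRALITY[area],
                "frontality": FRONTALITY[area],
                "partners": len(net.partners(area)),
            }
        )
    degree_table = pd.DataFrame(rows)
    link_rows = []
    for ai, area in enumerate(net.areas):
        n_in = int(np.count_nonzero(between & (area_of[post] == ai)))
        n_out = int(np.count_nonzero(between & (area_of[pre] == ai)))
        link_rows.append(
            {
                "area": area,
                "centrality": CENTRALITY[area],
                "between_links_in": n_in,
                "between_links_out": n_out,
                "mean_in_per_cell": n_in / A,
                "mean_out_per_cell": n_out / A,
            }
        )
    return degree_table, pd.DataFrame(link_rows)
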