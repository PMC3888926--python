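"""HDF5 / NPZ / JSON / TSV persistence for networks, recordings and
analysis products."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import h5py
import numpy as np
import scipy.sparse as sp

from .architecture import AREAS, Network
from .config import ArchitectureParams


def save_network(net: Network, path) -> None:
    """Persist a realised network (weights + parameters) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["variant"] = net.variant
        f.attrs["w_ie"] = net.w_ie
        pgrp = f.create_group("params")
        for k, v in vars(net.params).items():
            pgrp.attrs[k] = "none" if v is None else v
        for name, W in (("W_ee", net.W_ee), ("W_ei", net.W_ei)):
            g = f.create_group(name)
            g.create_dataset("data", data=W.data)
            g.create_dataset("indices", data=W.indices)
            g.create_dataset("indptr", data=W.indptr)
            g.attrs["shape"] = W.shape


def load_network(path) -> Network:
    with h5py.File(path, "r") as f:
        raw = {k: (None if isinstance(v, str) and v == "none" else v)
               for k, v in f["params"].attrs.items()}
        for k in ("rows", "cols", "n_exc", "n_inh"):
            raw[k] = int(raw[k])
        params = ArchitectureParams(**raw)
        mats = {}
        for name in ("W_ee", "W_ei"):
            g = f[name]
            mats[name] = sp.csr_matrix(
                (g["data"][:], g["indices"][:], g["indptr"][:]),
                shape=tuple(g.attrs["shape"]),
            )
        return Network(
            params=params,
            variant=str(f.attrs["variant"]),
            W_ee=mats["W_ee"],
            W_ei=mats["W_ei"],
            w_ie=float(f.attrs["w_ie"]),
        )


def save_recording(recording: np.ndarray, path, cells_per_area: Optional[int] = None) -> None:
    """Write an excitatory-output time series to HDF5.

    Stores one ``O_exc`` dataset per area plus a uint16 step index.
    """
    steps, n_cells = recording.shape
    A = cells_per_area or n_cells // len(AREAS)
    with h5py.File(path, "w") as f:
        f.create_dataset("step", data=np.arange(steps, dtype=np.uint16))
        for i, area in enumerate(AREAS):
            f.create_dataset(
                f"O_exc/{area}",
                data=recording[:, i * A:(i + 1) * A].astype(np.float32),
                compression="gzip",
            )


def load_recording(path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        parts = [f[f"O_exc/{area}"][:] for area in AREAS]
    return np.concatenate(parts, axis=1)


def save_membership(membership, path) -> None:
    with open(path, "w") as fh:
        json.dump(membership.to_dict(), fh, indent=1)


def save_asis(asis: Dict[int, "object"], path) -> None:
    """ASI traces to NPZ with labelled CA and area axes."""
    ca_ids = sorted(asis)
    counts = np.array([asis[c].counts for c in ca_ids])
    normalized = np.array([asis[c].normalized for c in ca_ids])
    n_trials = np.array([asis[c].n_trials for c in ca_ids])
    np.savez(
        path,
        ca_ids=np.array(ca_ids),
        areas=np.array(AREAS),
        counts=counts,
        normalized=normalized,
        n_trials=n_trials,
    )


def export_edge_list(net: Network, path) -> None:
    """Excitatory edge list as TSV (areas, grid coordinates, weight)."""
    net.edge_list().to_csv(path, sep="\t", index=False)
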