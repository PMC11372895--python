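"""Plain-text serialization of networks and run outputs.

A network directory holds:
  edges.tsv      tab-separated 0-based edge list with a metadata header line
                 ``# N=<N> n1=<n1> n2=<n2> n3=<n3> H=<H> k=<k> gamma=<g> seed=<s>``
  partition.tsv  one row per layer, N columns of 1-based block ids
  adjacency.mtx  Matrix Market coordinate, symmetric pattern
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import scipy.io
import scipy.sparse as sp

from .netgen import (
    ConnectionProbabilities,
    HierarchicalNetwork,
    HierarchyShape,
)

__all__ = ["save_network", "load_network"]


def save_network(network: HierarchicalNetwork, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"N": network.N}
    if network.shape is not None:
        meta.update(n1=network.shape.n1, n2=network.shape.n2, n3=network.shape.n3)
    if network.probs is not None:
        meta.update(
            H=network.probs.H, k=network.probs.k_target, gamma=network.probs.gamma
        )
    if network.seed is not None:
        meta["seed"] = network.seed
    header = "# " + " ".join(f"{k}={v}" for k, v in meta.items())
    edges = np.argwhere(np.triu(network.adjacency, k=1))
    with open(out / "edges.tsv", "w") as fh:
        fh.write(header + "\n")
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")
    np.savetxt(out / "partition.tsv", network.partition, fmt="%d", delimiter="\t")
    scipy.io.mmwrite(
        out / "adjacency.mtx",
        sp.coo_matrix(network.adjacency.astype(np.int8)),
        symmetry="symmetric",
        field="pattern",
    )
    return out


def _parse_header(line: str) -> dict:
    fields = {}
    for token in line.lstrip("#").split():
        key, _, val = token.partition("=")
        fields[key] = val
    return fields


def load_network(net_dir) -> HierarchicalNetwork:
    net = Path(net_dir)
    with open(net / "edges.tsv") as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("edge list must start with a metadata header line")
        meta = _parse_header(header)
        pairs = [line.split() for line in fh if line.strip()]
    N = int(meta["N"])
    A = np.zeros((N, N), dtype=np.uint8)
    for u, v in pairs:
        A[int(u), int(v)] = A[int(v), int(u)] = 1
    partition = np.loadtxt(net / "partition.tsv", dtype=np.int64, delimiter="\t", ndmin=2)
    shape: Optional[HierarchyShape] = None
    if {"n1", "n2", "n3"} <= meta.keys():
        shape = HierarchyShape(int(meta["n1"]), int(meta["n2"]), int(meta["n3"]))
    probs: Optional[ConnectionProbabilities] = None
    if "H" in meta and shape is not None and meta.get("gamma") not in (None, "None"):
        from .netgen import connection_probabilities

        probs = connection_probabilities(
            float(meta["H"]), shape, gamma=float(meta["gamma"])
        )
        if meta.get("k") not in (None, "None"):
            probs = ConnectionProbabilities(
                H=probs.H, gamma=probs.gamma, p1=probs.p1, p2=probs.p2, p3=probs.p3,
                k_target=float(meta["k"]),
            )
    seed = int(meta["seed"]) if "seed" in meta else None
    return HierarchicalNetwork(
        adjacency=A, partition=partition, shape=shape, probs=probs, seed=seed
    )
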