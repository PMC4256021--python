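"""Genotype graphs: components, neutral sets and neutral networks.

Viable (non-degenerate) sequences form a graph with edges between
sequences at Hamming distance 1. Three nested partitions describe a
sequence-structure map's architecture:

* *genotype components* -- connected components of the whole viable graph;
* *neutral sets* -- all viable sequences sharing a native structure
  (their size is that phenotype's *designability*);
* *neutral networks* -- connected components of a neutral set's induced
  subgraph (their size is the network's *neutrality*).

Every neutral network lies inside exactly one component and one neutral
set. A sequence's neutrality is the fraction of its L single-point mutants
that stay on its own neutral network; for binary alphabets the
random-graph connectivity threshold for this quantity is
``LAMBDA_STAR = 0.5``.

The decomposition also accepts arbitrary labelled graphs (node ids instead
of sequence codes), which supports abstract textbook-style fixtures;
Hamming-based quantities are then unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "GPDecomposition",
    "LAMBDA_STAR",
    "build_and_decompose",
    "decompose_graph",
    "sequence_neutrality",
    "expected_size",
    "cluster_diameter",
    "geodesic_diameter",
    "hamming_adjacency",
]

#: critical per-sequence neutrality for network percolation, binary alphabet
LAMBDA_STAR = 0.5


def hamming_adjacency(codes: np.ndarray, L: int) -> csr_matrix:
    """Sparse adjacency of the Hamming-1 graph over the given codes."""
    codes = np.asarray(codes, dtype=np.int64)
    n = len(codes)
    pos = {}
    pos_arr = np.full(1 << L, -1, dtype=np.int64) if L <= 26 else None
    if pos_arr is not None:
        pos_arr[codes] = np.arange(n)
    else:  # pragma: no cover - large-L fallback
        pos = {int(c): i for i, c in enumerate(codes)}
    rows, cols = [], []
    for b in range(L):
        nb = codes ^ (1 << b)
        if pos_arr is not None:
            j = pos_arr[nb]
        else:  # pragma: no cover
            j = np.array([pos.get(int(x), -1) for x in nb])
        ok = j >= 0
        rows.append(np.flatnonzero(ok))
        cols.append(j[ok])
    rows = np.concatenate(rows) if rows else np.empty(0, dtype=np.int64)
    cols = np.concatenate(cols) if cols else np.empty(0, dtype=np.int64)
    data = np.ones(len(rows), dtype=np.int8)
    return csr_matrix((data, (rows, cols)), shape=(n, n))


def _canonical_labels(raw: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Relabel component ids: 0, 1, ... by decreasing size, ties broken by
    the smallest member code. Deterministic across reruns."""
    out = np.empty_like(raw)
    labels = np.unique(raw)
    keyed = sorted(
        labels,
        key=lambda l: (-(raw == l).sum(), codes[raw == l].min()),
    )
    for new, old in enumerate(keyed):
        out[raw == old] = new
    return out


@dataclass
class GPDecomposition:
    """Three-level partition of the viable sequences of one map."""

    codes: np.ndarray  # viable sequence codes (or abstract node ids)
    phenotype: np.ndarray  # native phenotype label per viable sequence
    component_id: np.ndarray
    network_id: np.ndarray
    adjacency: csr_matrix
    L: int | None  # chain length; None for abstract graphs

    def __post_init__(self) -> None:
        # refinement invariants: each network inside one component & one set
        for nid in np.unique(self.network_id):
            sel = self.network_id == nid
            assert len(np.unique(self.component_id[sel])) == 1
            assert len(np.unique(self.phenotype[sel])) == 1

    @property
    def n_viable(self) -> int:
        return len(self.codes)

    @property
    def component_sizes(self) -> np.ndarray:
        """Sizes of genotype components, largest first."""
        return np.bincount(self.component_id)

    @property
    def neutral_sets(self) -> dict:
        """phenotype label -> array of member codes."""
        order = np.argsort(self.phenotype, kind="stable")
        out = {}
        for ph in np.unique(self.phenotype):
            out[int(ph)] = self.codes[self.phenotype == ph]
        return out

    @property
    def neutral_set_sizes(self) -> dict:
        return {ph: len(v) for ph, v in self.neutral_sets.items()}

    @property
    def designability(self) -> dict:
        """Designability C of each phenotype = its neutral-set size."""
        return self.neutral_set_sizes

    @property
    def networks(self) -> list[dict]:
        """One entry per neutral network: phenotype, component, size, codes."""
        out = []
        for nid in range(int(self.network_id.max()) + 1 if len(self.network_id) else 0):
            sel = self.network_id == nid
            out.append(
                {
                    "network_id": nid,
                    "phenotype": int(self.phenotype[sel][0]),
                    "component_id": int(self.component_id[sel][0]),
                    "size": int(sel.sum()),
                    "codes": self.codes[sel],
                }
            )
        return out

    @property
    def network_sizes(self) -> np.ndarray:
        return np.bincount(self.network_id) if len(self.network_id) else np.empty(0, int)

    def summary(self) -> dict:
        comp = self.component_sizes
        ns = np.array(sorted(self.neutral_set_sizes.values()), dtype=np.int64)
        nn = self.network_sizes
        return {
            "n_viable": self.n_viable,
            "n_components": int(len(comp)),
            "n_neutral_sets": int(len(ns)),
            "n_neutral_networks": int(len(nn)),
            "expected_component_size": expected_size(comp) if len(comp) else 0.0,
            "expected_set_size": expected_size(ns) if len(ns) else 0.0,
            "expected_network_size": expected_size(nn) if len(nn) else 0.0,
        }


def _decompose(codes, phenotype, adj, L) -> GPDecomposition:
    n = len(codes)
    if n == 0:
        return GPDecomposition(
            codes=np.empty(0, np.int64),
            phenotype=np.empty(0, np.int64),
            component_id=np.empty(0, np.int64),
            network_id=np.empty(0, np.int64),
            adjacency=csr_matrix((0, 0)),
            L=L,
        )
    _, comp_raw = connected_components(adj, directed=False)
    comp = _canonical_labels(comp_raw, codes)

    net_raw = np.full(n, -1, dtype=np.int64)
    offset = 0
    for ph in np.unique(phenotype):
        idx = np.flatnonzero(phenotype == ph)
        sub = adj[idx][:, idx]
        _, lab = connected_components(sub, directed=False)
        net_raw[idx] = lab + offset
        offset += lab.max() + 1
    # canonical network ids: by size desc, then smallest member code
    nets = np.unique(net_raw)
    keyed = sorted(
        nets, key=lambda l: (-(net_raw == l).sum(), codes[net_raw == l].min())
    )
    net = np.empty(n, dtype=np.int64)
    for new, old in enumerate(keyed):
        net[net_raw == old] = new
    return GPDecomposition(
        codes=np.asarray(codes, dtype=np.int64),
        phenotype=np.asarray(phenotype, dtype=np.int64),
        component_id=comp,
        network_id=net,
        adjacency=adj,
        L=L,
    )


def build_and_decompose(map_result) -> GPDecomposition:
    """Decompose the viable-sequence graph of a folded map."""
    codes = map_result.V
    phenotype = map_result.native_idx[codes]
    adj = hamming_adjacency(codes, map_result.L)
    return _decompose(codes, phenotype, adj, map_result.L)


def decompose_graph(n_nodes: int, edges, phenotype: dict) -> GPDecomposition:
    """Decompose an explicit labelled graph.

    ``phenotype`` maps viable node id -> phenotype label; nodes absent from
    it are treated as degenerate (excluded). Edges between excluded nodes
    are ignored.
    """
    codes = np.array(sorted(phenotype), dtype=np.int64)
    pos = {int(c): i for i, c in enumerate(codes)}
    rows, cols = [], []
    for u, v in edges:
        if u in phenotype and v in phenotype:
            rows += [pos[u], pos[v]]
            cols += [pos[v], pos[u]]
    adj = csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(len(codes),) * 2
    )
    ph = np.array([phenotype[int(c)] for c in codes], dtype=np.int64)
    return _decompose(codes, ph, adj, None)


def sequence_neutrality(decomp: GPDecomposition, s: int) -> float:
    """Fraction of the L single-point mutants of ``s`` that belong to the
    same neutral network as ``s`` (degenerate mutants count against)."""
    if decomp.L is None:
        raise ValueError("sequence neutrality requires a Hamming-graph decomposition")
    idx = np.flatnonzero(decomp.codes == s)
    if len(idx) == 0:
        raise ValueError(f"sequence {s} is not viable in this map")
    i = int(idx[0])
    pos = {int(c): k for k, c in enumerate(decomp.codes)}
    same = 0
    for b in range(decomp.L):
        j = pos.get(int(s) ^ (1 << b))
        if j is not None and decomp.network_id[j] == decomp.network_id[i]:
            same += 1
    return same / decomp.L


def expected_size(sizes) -> float:
    """Sequence-weighted mean cluster size, sum(n_i^2) / sum(n_i).

    This is the expected size of the cluster containing a uniformly drawn
    member; it is >= the arithmetic mean, with equality iff all sizes are
    equal.
    """
    sizes = np.asarray(sizes, dtype=np.float64)
    if sizes.size == 0:
        raise ValueError("expected_size of an empty size list")
    if (sizes <= 0).any():
        raise ValueError("cluster sizes must be positive")
    return float((sizes**2).sum() / sizes.sum())


def cluster_diameter(codes) -> int:
    """Maximum pairwise Hamming distance within a set of sequences."""
    codes = np.asarray(codes, dtype=np.uint64)
    if codes.size == 0:
        raise ValueError("diameter of an empty sequence set")
    best = 0
    chunk = max(1, (1 << 22) // max(1, len(codes)))
    for lo in range(0, len(codes), chunk):
        x = codes[lo : lo + chunk, None] ^ codes[None, :]
        best = max(best, int(np.bitwise_count(x).max()))
    return best


def geodesic_diameter(decomp: GPDecomposition, network_id: int | None = None) -> int:
    """Longest shortest mutational path within a network (or the whole
    viable graph when ``network_id`` is None). Infinite distances between
    disconnected parts are ignored."""
    if network_id is None:
        adj = decomp.adjacency
    else:
        sel = np.flatnonzero(decomp.network_id == network_id)
        adj = decomp.adjacency[sel][:, sel]
    if adj.shape[0] == 0:
        raise ValueError("geodesic diameter of an empty graph")
    d = shortest_path(adj, method="D", unweighted=True, directed=False)
    finite = d[np.isfinite(d)]
    return int(finite.max())
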