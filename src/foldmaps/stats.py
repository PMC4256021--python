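"""Map-level statistics and cross-map comparisons.

Covers the observable summaries of a sequence-structure map (compositional
and compactness biases against resampled expectations, designability and
neutrality cumulative distributions, phenotypic diversity of sequence
neighbourhoods) and comparisons between maps (Jaccard similarity of their
genotype or phenotype sets, agglomerative clustering of the similarity
matrix).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .graphs import GPDecomposition

__all__ = [
    "DistributionReport",
    "DiversityCurve",
    "compositional_report",
    "compactness_report",
    "designability_cdf",
    "jaccard",
    "cluster_maps",
    "Dendrogram",
    "diversity_curve",
    "k_neighborhood_size",
    "neutral_set_max_distance",
]


@dataclass
class DistributionReport:
    """Observed counts per bin versus a seeded-resampling expectation."""

    bins: np.ndarray
    observed: np.ndarray
    expected_mean: np.ndarray
    expected_sd: np.ndarray
    replicates: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": self.bins,
                "observed": self.observed,
                "expected_mean": self.expected_mean,
                "expected_sd": self.expected_sd,
            }
        )


def compositional_report(map_result, replicates: int = 100, seed: int = 0) -> DistributionReport:
    """Viable sequences per compositional class (number of B monomers),
    against the null of the same number of sequences drawn uniformly from
    all of sequence space.

    With L positions there are L + 1 classes; class k holds at most
    C(L, k) sequences, so under the null the expectation is binomial.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates for an sd")
    L = map_result.L
    v = map_result.V
    observed = np.bincount(
        np.bitwise_count(v.astype(np.uint64)).astype(np.int64), minlength=L + 1
    )
    rng = np.random.default_rng(seed)
    n = 1 << L
    reps = np.empty((replicates, L + 1), dtype=np.int64)
    for r in range(replicates):
        draw = rng.choice(n, size=len(v), replace=False)
        reps[r] = np.bincount(
            np.bitwise_count(draw.astype(np.uint64)).astype(np.int64), minlength=L + 1
        )
    return DistributionReport(
        bins=np.arange(L + 1),
        observed=observed,
        expected_mean=reps.mean(axis=0),
        expected_sd=reps.std(axis=0, ddof=1),
        replicates=replicates,
        seed=seed,
    )


def compactness_report(
    map_result, inventory=None, replicates: int = 100, seed: int = 0
) -> DistributionReport:
    """Native phenotypes per contact number (compactness), against the null
    of the same number of conformations drawn uniformly from the
    potentially encodable (multiplicity-1) contact sets."""
    if replicates < 2:
        raise ValueError("need at least 2 replicates for an sd")
    inv = inventory if inventory is not None else map_result.inventory
    ncont = inv.n_contacts()
    unique_idx = np.flatnonzero(inv.counts == 1)
    kmax = int(ncont.max()) if len(ncont) else 0
    x = map_result.X
    observed = np.bincount(ncont[x], minlength=kmax + 1)
    rng = np.random.default_rng(seed)
    reps = np.empty((replicates, kmax + 1), dtype=np.int64)
    for r in range(replicates):
        draw = rng.choice(unique_idx, size=len(x), replace=False)
        reps[r] = np.bincount(ncont[draw], minlength=kmax + 1)
    return DistributionReport(
        bins=np.arange(kmax + 1),
        observed=observed,
        expected_mean=reps.mean(axis=0),
        expected_sd=reps.std(axis=0, ddof=1),
        replicates=replicates,
        seed=seed,
    )


def designability_cdf(decomp: GPDecomposition, level: str = "neutral_set"):
    """Sequence-weighted complementary CDF of cluster size.

    P(C >= C0) is the probability that a uniformly drawn viable sequence
    belongs to a neutral set (designability) or neutral network
    (neutrality) of size at least C0. Non-increasing, with P(C >= 1) = 1.

    Returns ``(C0, P)`` arrays with C0 = 1..max size.
    """
    if level == "neutral_set":
        sizes = np.array(sorted(decomp.neutral_set_sizes.values()), dtype=np.int64)
    elif level == "neutral_network":
        sizes = decomp.network_sizes
    else:
        raise ValueError("level must be 'neutral_set' or 'neutral_network'")
    if sizes.size == 0:
        raise ValueError("empty decomposition")
    total = sizes.sum()
    c0 = np.arange(1, sizes.max() + 1, dtype=np.int64)
    p = np.array([(sizes[sizes >= c] ).sum() for c in c0], dtype=np.float64) / total
    return c0, p


def jaccard(map_a, map_b, space: str = "phenotype") -> float:
    """Jaccard similarity |A ∩ B| / |A ∪ B| between two maps' viable
    sequence sets (``space='genotype'``) or accessible phenotype sets
    (``space='phenotype'``)."""
    if map_a.L != map_b.L:
        raise ValueError("maps must share the chain length and inventory")
    if space == "genotype":
        a, b = set(map_a.V.tolist()), set(map_b.V.tolist())
    elif space == "phenotype":
        a, b = set(map_a.X.tolist()), set(map_b.X.tolist())
    else:
        raise ValueError("space must be 'genotype' or 'phenotype'")
    union = a | b
    if not union:
        warnings.warn("both sets empty; defining J = 1", RuntimeWarning)
        return 1.0
    return len(a & b) / len(union)


def _newick(node, labels, parent_height):
    if node.is_leaf():
        name = labels[node.id].replace("'", "")
        return f"'{name}':{parent_height - 0.0:g}"
    left = _newick(node.left, labels, node.dist)
    right = _newick(node.right, labels, node.dist)
    return f"({left},{right}):{parent_height - node.dist:g}"


@dataclass
class Dendrogram:
    """Agglomerative clustering of a map-similarity matrix."""

    Z: np.ndarray  # scipy linkage matrix
    labels: list[str]
    method: str
    metadata: pd.DataFrame | None = None

    def newick(self) -> str:
        root = to_tree(self.Z)
        return f"({_newick(root.left, self.labels, root.dist)},{_newick(root.right, self.labels, root.dist)});"

    def merge_heights(self) -> np.ndarray:
        return self.Z[:, 2]


def cluster_maps(
    similarity: np.ndarray,
    method: str = "average",
    labels=None,
    metadata: pd.DataFrame | None = None,
) -> Dendrogram:
    """Hierarchical clustering of maps on distance 1 - J.

    ``method`` is one of average (group-average/UPGMA), single, complete.
    scipy's deterministic ordering breaks ties by leaf index.
    """
    s = np.asarray(similarity, dtype=np.float64)
    if s.ndim != 2 or s.shape[0] != s.shape[1] or not np.allclose(s, s.T):
        raise ValueError("similarity must be a square symmetric matrix")
    if not np.allclose(np.diag(s), 1.0):
        raise ValueError("similarity must have unit diagonal")
    if method not in ("average", "single", "complete"):
        raise ValueError("method must be average, single or complete")
    d = 1.0 - s
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method=method)
    if labels is None:
        labels = [str(i) for i in range(s.shape[0])]
    return Dendrogram(Z=z, labels=list(labels), method=method, metadata=metadata)


def k_neighborhood_size(L: int, k: int) -> int:
    """Number of sequences within Hamming distance k of a centre, centre
    excluded: sum_{i=1..k} C(L, i)."""
    from math import comb

    return sum(comb(L, i) for i in range(1, k + 1))


@dataclass
class DiversityCurve:
    """Phenotypic diversity u between pairs of k-neighbourhoods, binned by
    the Hamming distance d of their centres."""

    k: int
    d: np.ndarray
    mean_u: np.ndarray
    sd_u: np.ndarray
    n_pairs: np.ndarray
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"d": self.d, "mean_u": self.mean_u, "sd_u": self.sd_u, "n_pairs": self.n_pairs}
        )


def diversity_curve(
    map_result, k: int, n_sequences: int = 1000, seed: int = 0
) -> DiversityCurve:
    """Fraction of phenotypes unique to either of two k-neighbourhoods.

    Samples viable sequences without replacement; for every pair (s1, s2)
    computes u = 1 - |P1 ∩ P2| / |P1 ∪ P2| where P_i is the set of native
    phenotypes of viable sequences within Hamming distance k of s_i
    (centre excluded), and bins u by d = h(s1, s2). Neighbourhoods at
    d > 2k are vertex-disjoint (triangle inequality), though their
    phenotype sets may still overlap.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_sequences < 2:
        raise ValueError("need at least two sampled sequences")
    L = map_result.L
    v = map_result.V
    if n_sequences > len(v):
        warnings.warn(
            f"requested {n_sequences} sequences but only {len(v)} are viable; using all",
            RuntimeWarning,
        )
        sample = v.copy()
    else:
        rng = np.random.default_rng(seed)
        sample = rng.choice(v, size=n_sequences, replace=False)
    phen = map_result.native_idx
    neighborhoods = []
    for s in sample:
        dist = np.bitwise_count((v ^ s).astype(np.uint64))
        sel = (dist >= 1) & (dist <= k)
        neighborhoods.append(frozenset(phen[v[sel]].tolist()))
    n = len(sample)
    sums = np.zeros(L + 1)
    sq = np.zeros(L + 1)
    cnt = np.zeros(L + 1, dtype=np.int64)
    for i in range(n):
        pi = neighborhoods[i]
        for j in range(i + 1, n):
            pj = neighborhoods[j]
            d = int(bin(int(sample[i]) ^ int(sample[j])).count("1"))
            union = pi | pj
            u = 1.0 - (len(pi & pj) / len(union)) if union else 0.0
            sums[d] += u
            sq[d] += u * u
            cnt[d] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, sums / np.maximum(cnt, 1), np.nan)
        var = np.where(
            cnt > 1,
            (sq - sums**2 / np.maximum(cnt, 1)) / np.maximum(cnt - 1, 1),
            np.nan,
        )
    return DiversityCurve(
        k=k,
        d=np.arange(L + 1),
        mean_u=mean,
        sd_u=np.sqrt(np.maximum(var, 0.0)),
        n_pairs=cnt,
        seed=seed,
    )


def neutral_set_max_distance(decomp: GPDecomposition) -> dict:
    """Per-phenotype maximum pairwise Hamming distance (neutral-set
    diameter), as phenotype -> d_max."""
    from .graphs import cluster_diameter

    if decomp.L is None:
        raise ValueError("requires a Hamming-graph decomposition")
    return {ph: cluster_diameter(codes) for ph, codes in decomp.neutral_sets.items()}
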