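"""Reduced-scale fixtures and independent brute-force oracles.

Everything here is deliberately written *without* reusing the optimized
engines (`lattice`, `folding`, `graphs`), so it can serve as an
independent cross-check: the naive enumerator generates every rooted walk
and deduplicates by explicit symmetry images; the brute-force folder
minimizes energy conformation by conformation with exact rational
arithmetic; the breadth-first decomposition oracle walks the Hamming graph
by hand. These are practical up to L ~ 10-12.

Also provides the abstract worked-example genotype graph (192 nodes, 84
viable, three components) used to exercise the graph arithmetic, seeded
random potential generators, and a bundled synthetic 20x20 contact-energy
table.
"""

from __future__ import annotations

from collections import Counter, deque
from fractions import Fraction
from importlib import resources

import numpy as np

from .lattice import ContactInventory, Walk, pair_table
from .potentials import BinaryPotential

__all__ = [
    "naive_enumerate_walks",
    "naive_inventory",
    "reduced_model",
    "brute_force_fold",
    "bfs_decomposition_oracle",
    "random_potentials",
    "caricature_graph",
    "CARICATURE",
    "load_contact_table",
    "synthetic_contact_table",
    "AMINO_ACIDS",
]


# ---------------------------------------------------------------------------
# naive enumeration oracle
# ---------------------------------------------------------------------------

_DIRS = ((1, 0), (0, 1), (-1, 0), (0, -1))
_TRANSFORMS = [
    (a, b, c, d)
    for (a, b, c, d) in [
        (1, 0, 0, 1),
        (0, -1, 1, 0),
        (-1, 0, 0, -1),
        (0, 1, -1, 0),  # rotations
        (1, 0, 0, -1),
        (0, 1, 1, 0),
        (-1, 0, 0, 1),
        (0, -1, -1, 0),  # reflections
    ]
]


def _all_rooted_walks(L):
    """Every self-avoiding walk of L sites starting at the origin, all four
    first-step directions included."""
    walks = []
    path = [(0, 0)]
    used = {(0, 0)}

    def extend():
        if len(path) == L:
            walks.append(tuple(path))
            return
        x, y = path[-1]
        for dx, dy in _DIRS:
            q = (x + dx, y + dy)
            if q not in used:
                path.append(q)
                used.add(q)
                extend()
                path.pop()
                used.remove(q)

    extend()
    return walks


def _canonical_points(points):
    """Symmetry-minimal image of a rooted walk: apply each of the 8 lattice
    symmetries, re-root at the origin, and keep the image whose step
    sequence (coded E<N<W<S) is smallest."""
    dir_code = {d: i for i, d in enumerate(_DIRS)}
    best = None
    for a, b, c, d in _TRANSFORMS:
        img = [(a * x + b * y, c * x + d * y) for x, y in points]
        x0, y0 = img[0]
        img = [(x - x0, y - y0) for x, y in img]
        code = tuple(
            dir_code[(x1 - x0, y1 - y0)]
            for (x0, y0), (x1, y1) in zip(img, img[1:])
        )
        if best is None or code < best[0]:
            best = (code, tuple(img))
    return best[1]


def naive_enumerate_walks(L):
    """Distinct conformations of an L-mer by exhaustive rooted enumeration
    plus symmetry deduplication. Returns canonical point tuples."""
    if L < 2:
        raise ValueError("chain length must be at least 2")
    return sorted(set(_canonical_points(w) for w in _all_rooted_walks(L)))


def _walk_contacts(points):
    where = {p: i for i, p in enumerate(points)}
    out = set()
    for i, (x, y) in enumerate(points):
        for dx, dy in _DIRS:
            j = where.get((x + dx, y + dy))
            if j is not None and j - i >= 2:
                out.add((i, j))
    return frozenset(out)


def naive_inventory(L) -> ContactInventory:
    """Contact-set inventory built by the naive enumerator (oracle for the
    symmetry-reduced one). Slow beyond L ~ 12."""
    pairs = pair_table(L)
    bit = {(int(i), int(j)): b for b, (i, j) in enumerate(pairs)}
    tally = Counter()
    for pts in naive_enumerate_walks(L):
        mask = 0
        for ij in _walk_contacts(pts):
            mask |= 1 << bit[ij]
        tally[mask] += 1
    masks = np.array(sorted(tally), dtype=np.uint64)
    counts = np.array([tally[int(m)] for m in masks], dtype=np.int64)
    return ContactInventory(L=L, masks=masks, counts=counts, pairs=pairs)


def reduced_model(L) -> ContactInventory:
    """Desk-scale model instance built by the unreduced enumerator."""
    import warnings

    if L > 12:
        warnings.warn(f"naive enumeration at L={L} is very slow", RuntimeWarning)
    return naive_inventory(L)


# ---------------------------------------------------------------------------
# brute-force folding oracle (exact rational arithmetic)
# ---------------------------------------------------------------------------


def brute_force_fold(s: int, p: BinaryPotential, L: int, walks=None, walk_contacts=None):
    """Fold one sequence by direct minimization over every distinct
    conformation, with no contact-set grouping and exact Fraction
    arithmetic. Returns a dict with E_min, degeneracy, native contact set
    (or None) and foldability (or None).

    ``walk_contacts`` may carry precomputed per-conformation contact sets
    (as produced by repeated calls) to amortise the geometry scan.
    """
    if walks is None:
        walks = naive_enumerate_walks(L)
    e = {
        (0, 0): Fraction(p.e_AA).limit_denominator(10**9),
        (1, 1): Fraction(p.e_BB).limit_denominator(10**9),
        (0, 1): Fraction(p.e_AB).limit_denominator(10**9),
        (1, 0): Fraction(p.e_AB).limit_denominator(10**9),
    }
    if walk_contacts is None:
        walk_contacts = [_walk_contacts(pts) for pts in walks]
    energies = []
    csets = []
    for cs in walk_contacts:
        tot = Fraction(0)
        for i, j in cs:
            tot += e[(s >> i & 1, s >> j & 1)]
        energies.append(tot)
        csets.append(cs)
    emin = min(energies)
    hits = [c for E, c in zip(energies, csets) if E == emin]
    deg = len(hits)
    n = len(energies)
    mean = sum(energies, Fraction(0)) / n
    var = sum((E - mean) ** 2 for E in energies) / n
    if var == 0:
        fold = None
    else:
        fold = float(emin - mean) / float(var) ** 0.5
    return {
        "E_min": float(emin),
        "degeneracy": deg,
        "native": hits[0] if deg == 1 else None,
        "foldability": fold,
    }


def bfs_decomposition_oracle(codes, phenotype, L):
    """Independent decomposition of a viable-sequence set by hand-rolled
    breadth-first search. Returns (component sets, neutral-set dict,
    neutral-network list of frozensets)."""
    codes = [int(c) for c in codes]
    phen = {c: int(p) for c, p in zip(codes, phenotype)}
    pool = set(codes)

    def neighbours(c, allowed):
        for b in range(L):
            m = c ^ (1 << b)
            if m in allowed:
                yield m

    def comp_of(start, allowed):
        seen = {start}
        q = deque([start])
        while q:
            u = q.popleft()
            for w in neighbours(u, allowed):
                if w not in seen:
                    seen.add(w)
                    q.append(w)
        return frozenset(seen)

    components = []
    left = set(pool)
    while left:
        c = comp_of(min(left), pool)
        components.append(c)
        left -= c
    neutral_sets = {}
    for c in codes:
        neutral_sets.setdefault(phen[c], set()).add(c)
    networks = []
    for ph, members in neutral_sets.items():
        left = set(members)
        while left:
            c = comp_of(min(left), members)
            networks.append((ph, c))
            left -= c
    return components, {k: frozenset(v) for k, v in neutral_sets.items()}, networks


# ---------------------------------------------------------------------------
# random potentials
# ---------------------------------------------------------------------------


def random_potentials(n: int, seed: int = 0, distribution: str = "uniform", box=(-1.0, 1.0)):
    """Seeded random binary potentials, uniform over a box by default."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if distribution == "uniform":
        vals = rng.uniform(box[0], box[1], size=(n, 3))
    elif distribution == "normal":
        vals = rng.normal(0.0, (box[1] - box[0]) / 2, size=(n, 3))
    else:
        raise ValueError("distribution must be 'uniform' or 'normal'")
    vals = np.round(vals, 4)  # exactly representable as rationals
    return [
        BinaryPotential(*map(float, v), label=f"rand{seed}-{i}")
        for i, v in enumerate(vals)
    ]


# ---------------------------------------------------------------------------
# worked-example genotype graph
# ---------------------------------------------------------------------------

#: declared statistics of the worked-example graph
CARICATURE = {
    "n_nodes": 192,
    "n_viable": 84,
    "component_sizes": (53, 24, 7),
    "neutral_set_sizes": {"blue": 12, "green": 19, "orange": 15, "magenta": 23, "yellow": 15},
    "n_neutral_networks": 9,
    "expected_component_size": Fraction(3434, 84),
}

_PHENO_IDS = {"blue": 1, "orange": 2, "green": 3, "magenta": 4, "yellow": 5}


def caricature_graph():
    """The worked-example genotype network: 192 abstract nodes of which 84
    are viable, arranged in three components (53, 24, 7) over five
    phenotypes (neutral sets 12/19/15/23/15) forming nine neutral
    networks.

    Within a component, each neutral network is a path and consecutive
    networks are joined by a single edge, so same-phenotype patches
    separated by another phenotype stay disconnected in their induced
    subgraph (the magenta set contributes two networks inside the largest
    component). One phenotype (orange) appears in all three components and
    the smallest component is a single neutral network of it; blue spans
    the two largest components. Re-derivable statistics match
    :data:`CARICATURE` exactly.

    Returns ``(n_nodes, edges, phenotype)`` in the form accepted by
    :func:`foldmaps.graphs.decompose_graph`.
    """
    # (component, [(colour, patch size), ...]) -- order fixes connectors
    layout = [
        [("blue", 8), ("magenta", 13), ("green", 19), ("magenta", 10), ("orange", 3)],
        [("blue", 4), ("orange", 5), ("yellow", 15)],
        [("orange", 7)],
    ]
    edges = []
    phenotype = {}
    node = 0
    for comp in layout:
        prev_end = None
        for colour, size in comp:
            start = node
            for i in range(size):
                phenotype[node] = _PHENO_IDS[colour]
                if i > 0:
                    edges.append((node - 1, node))
                node += 1
            if prev_end is not None:
                edges.append((prev_end, start))
            prev_end = node - 1
    assert node == 84
    # degenerate nodes 84..191: an arbitrary chain, excluded from the map
    for u in range(84, 191):
        edges.append((u, u + 1))
    return 192, edges, phenotype


# ---------------------------------------------------------------------------
# synthetic 20x20 contact-energy table
# ---------------------------------------------------------------------------

AMINO_ACIDS = (
    "CYS MET PHE ILE LEU VAL TRP TYR ALA GLY THR SER ASN GLN ASP GLU HIS ARG LYS PRO"
).split()


def synthetic_contact_table(seed: int = 0):
    """SYNTHETIC stand-in for a statistical 20x20 contact-energy table.

    This is *not* a table derived from protein structures: it is a seeded
    construction with the statistical shape of quasi-chemical contact
    potentials -- an additive per-residue transfer term plus a smaller
    pair-specific excess, printed to two decimals (so exact zeros occur).
    It exercises the pairwise-decomposition machinery; conclusions about
    natural amino acids must not be read off it.

    Returns ``(names, matrix)``.
    """
    rng = np.random.default_rng(seed)
    h = rng.normal(-0.2, 0.8, size=20)  # per-residue transfer energies
    xs = rng.normal(0.0, 0.8, size=(20, 20))
    xs = (xs + xs.T) / 2.0
    m = np.round(h[:, None] + h[None, :] + xs, 2)
    return list(AMINO_ACIDS), m


def load_contact_table(path=None):
    """Load a 20x20 contact-energy table from CSV (first column residue
    names); defaults to the bundled synthetic table."""
    import pandas as pd

    if path is None:
        path = resources.files("foldmaps").joinpath("data/synthetic_mj_contact_energies.csv")
        with resources.as_file(path) as p:
            df = pd.read_csv(p, index_col=0)
    else:
        df = pd.read_csv(path, index_col=0)
    m = df.to_numpy(dtype=float)
    if m.shape != (len(df.index), len(df.index)):
        raise ValueError("contact table must be square")
    return list(df.index), m
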