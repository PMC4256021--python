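"""Enumeration of self-avoiding-walk conformations on the 2D square lattice.

A conformation of an L-mer is a self-avoiding walk (SAW) of L sites. Two
conformations are considered identical when related by a symmetry of the
square lattice (the 8-element dihedral group: 4 rotations x reflection);
chain reversal is *not* identified, so a walk and its reverse are distinct
conformations unless a lattice symmetry maps one onto the other.

The energy model only sees *contacts* -- pairs of residues that are lattice
neighbours but not chain neighbours -- so conformations are summarised by
their contact set. Several conformations (especially open, non-compact ones)
can share a contact set; the :class:`ContactInventory` records each distinct
contact set together with its multiplicity. Contact sets realised by exactly
one conformation are the *potentially encodable* phenotypes: only they can be
a unique ground state.

On the square lattice a contact (i, j) always satisfies j - i >= 3 and
j - i odd (the lattice is bipartite and chain neighbours are excluded),
which caps the number of admissible index pairs at 64 for L = 18 -- contact
sets are therefore packed into 64-bit masks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

__all__ = [
    "Walk",
    "ContactInventory",
    "canonical_form",
    "contacts",
    "enumerate_conformations",
    "pair_table",
    "STEPS",
]

#: step vectors for direction codes 0=E, 1=N, 2=W, 3=S (counter-clockwise)
STEPS = ((1, 0), (0, 1), (-1, 0), (0, -1))

_STEP_TO_DIR = {v: i for i, v in enumerate(STEPS)}


class InvalidWalkError(ValueError):
    """Raised for broken or self-intersecting chains."""


@dataclass(frozen=True)
class Walk:
    """A self-avoiding walk: an ordered tuple of integer lattice points.

    The first point is the origin (translation is quotiented out at
    construction time).
    """

    points: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        pts = tuple((int(x), int(y)) for x, y in self.points)
        if len(pts) < 1:
            raise InvalidWalkError("walk must contain at least one point")
        if len(set(pts)) != len(pts):
            raise InvalidWalkError("walk is self-intersecting")
        for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
            if abs(x1 - x0) + abs(y1 - y0) != 1:
                raise InvalidWalkError(
                    f"consecutive points {(x0, y0)} -> {(x1, y1)} are not "
                    "unit-distance lattice neighbours"
                )
        x0, y0 = pts[0]
        if (x0, y0) != (0, 0):
            pts = tuple((x - x0, y - y0) for x, y in pts)
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def steps(self) -> tuple[int, ...]:
        """Direction codes (0=E, 1=N, 2=W, 3=S) of the L-1 chain steps."""
        return tuple(
            _STEP_TO_DIR[(x1 - x0, y1 - y0)]
            for (x0, y0), (x1, y1) in zip(self.points, self.points[1:])
        )

    @classmethod
    def from_steps(cls, steps) -> "Walk":
        x = y = 0
        pts = [(0, 0)]
        for d in steps:
            dx, dy = STEPS[d]
            x, y = x + dx, y + dy
            pts.append((x, y))
        return cls(tuple(pts))


def canonical_form(walk: Walk) -> Walk:
    """Canonical representative of ``walk`` under the dihedral group D4.

    The representative is the image (among the 8 rotations/reflections,
    re-rooted at the origin) whose step-direction string is lexicographically
    minimal. The straight walk canonicalises to the +x ray; chain reversal is
    deliberately not part of the group, so a walk and its reverse generally
    have distinct canonical forms. Idempotent.
    """
    if len(walk) == 1:
        return walk
    steps = walk.steps
    best = None
    for rot in range(4):
        for refl in (False, True):
            img = tuple((4 - d) % 4 if refl else d for d in steps)
            img = tuple((d + rot) % 4 for d in img)
            if best is None or img < best:
                best = img
    return Walk.from_steps(best)


def contacts(walk: Walk) -> frozenset[tuple[int, int]]:
    """Contact set of a walk: index pairs (i, j), i < j, that are lattice
    neighbours but not adjacent along the chain (|i - j| >= 2; bipartite
    parity then forces j - i >= 3 and odd)."""
    where = {p: i for i, p in enumerate(walk.points)}
    out = set()
    for i, (x, y) in enumerate(walk.points):
        for dx, dy in STEPS:
            j = where.get((x + dx, y + dy))
            if j is not None and j - i >= 2:
                out.add((i, j))
    return frozenset(out)


def pair_table(L: int) -> np.ndarray:
    """Admissible contact pairs for chain length ``L``, as an (n_bits, 2)
    int array in bit order: all (i, j) with j - i >= 3 and j - i odd."""
    pairs = [
        (i, j)
        for i in range(L)
        for j in range(i + 3, L, 2)
    ]
    return np.array(pairs, dtype=np.int64).reshape(-1, 2)


def _pair_bit_matrix(L: int) -> np.ndarray:
    """(L, L) matrix of bit positions for admissible pairs, -1 elsewhere."""
    tab = np.full((L, L), -1, dtype=np.int64)
    for b, (i, j) in enumerate(pair_table(L)):
        tab[i, j] = b
        tab[j, i] = b
    return tab


# ---------------------------------------------------------------------------
# symmetry-reduced enumeration kernel
#
# Fixing the first step to E and the first turn (if any) to N selects exactly
# one rooted walk per dihedral equivalence class: the only rooted walk fixed
# by a non-trivial element of D4 is the straight one (a rotation changes the
# first step's direction; the reflection across the first step flips the
# first turn).
# ---------------------------------------------------------------------------


@njit(cache=True)
def _dfs(L, bitpos, out_masks, count_only):
    side = 2 * L + 1
    board = np.full(side * side, -1, dtype=np.int64)
    xs = np.empty(L, dtype=np.int64)
    ys = np.empty(L, dtype=np.int64)
    masks = np.zeros(L, dtype=np.uint64)
    trydir = np.zeros(L, dtype=np.int64)
    turned = np.zeros(L, dtype=np.uint8)

    # place the first two sites: origin and (1, 0)
    xs[0], ys[0] = L, L
    xs[1], ys[1] = L + 1, L
    board[L * side + L] = 0
    board[L * side + (L + 1)] = 1
    masks[1] = np.uint64(0)
    turned[1] = 0
    trydir[1] = 0

    dx = np.array([1, 0, -1, 0], dtype=np.int64)
    dy = np.array([0, 1, 0, -1], dtype=np.int64)

    n_found = 0
    depth = 1  # index of the last placed site
    if L == 2:
        if not count_only:
            out_masks[0] = np.uint64(0)
        return 1

    while depth >= 1:
        d = trydir[depth]
        if d == 4:
            # backtrack
            board[ys[depth] * side + xs[depth]] = -1
            depth -= 1
            continue
        trydir[depth] = d + 1
        if turned[depth] == 0 and d != 0 and d != 1:
            continue  # before the first turn only E (straight) or N (turn)
        nx = xs[depth] + dx[d]
        ny = ys[depth] + dy[d]
        cell = ny * side + nx
        if board[cell] != -1:
            continue
        k = depth + 1
        # accumulate contacts of the new site with earlier, non-adjacent sites
        m = masks[depth]
        for t in range(4):
            j = board[(ny + dy[t]) * side + (nx + dx[t])]
            if j >= 0 and j != depth:
                m |= np.uint64(1) << np.uint64(bitpos[j, k])
        if k == L - 1:
            if not count_only:
                out_masks[n_found] = m
            n_found += 1
            continue
        board[cell] = k
        xs[k], ys[k] = nx, ny
        masks[k] = m
        turned[k] = 1 if (turned[depth] == 1 or d == 1) else 0
        trydir[k] = 0
        depth = k
    # remove the anchored second site marker (board reset not needed further)
    return n_found


@dataclass
class ContactInventory:
    """Deduplicated contact sets of all distinct L-mer conformations.

    Attributes
    ----------
    L : chain length.
    masks : sorted unique uint64 bit-masks, one per distinct contact set
        (bit b set <=> pair ``pair_table(L)[b]`` is a contact).
    counts : multiplicity of each contact set (number of distinct
        conformations realising it).
    """

    L: int
    masks: np.ndarray
    counts: np.ndarray
    pairs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pairs is None:
            self.pairs = pair_table(self.L)
        if self.counts.sum() < len(self.masks):
            raise ValueError("multiplicities inconsistent with entry count")

    @property
    def n_conformations(self) -> int:
        return int(self.counts.sum())

    @property
    def n_contact_sets(self) -> int:
        return int(len(self.masks))

    @property
    def unique_ids(self) -> np.ndarray:
        """Masks realised by exactly one conformation (potentially
        encodable phenotypes)."""
        return self.masks[self.counts == 1]

    @property
    def n_unique(self) -> int:
        return int((self.counts == 1).sum())

    def n_contacts(self) -> np.ndarray:
        """Number of contacts of each entry (popcount of the mask)."""
        v = self.masks.copy()
        out = np.zeros(len(v), dtype=np.int64)
        while v.any():
            out += (v & np.uint64(1)).astype(np.int64)
            v >>= np.uint64(1)
        return out

    def decode(self, mask: int) -> frozenset[tuple[int, int]]:
        """Contact set (as index pairs) for a packed mask."""
        m = int(mask)
        return frozenset(
            (int(i), int(j))
            for b, (i, j) in enumerate(self.pairs)
            if m >> b & 1
        )

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        np.savez_compressed(path, L=self.L, masks=self.masks, counts=self.counts)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "L": self.L,
                    "n_conformations": self.n_conformations,
                    "n_contact_sets": self.n_contact_sets,
                    "n_unique": self.n_unique,
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, path) -> "ContactInventory":
        with np.load(Path(path).with_suffix(".npz")) as z:
            return cls(L=int(z["L"]), masks=z["masks"], counts=z["counts"])


def enumerate_conformations(L: int, progress: bool = False) -> ContactInventory:
    """Enumerate all distinct L-mer conformations and build the contact-set
    inventory.

    Walks are generated depth-first with the first step fixed to +x and the
    first turn fixed to +y, which yields exactly one representative per
    dihedral-symmetry class; results are independent of traversal order.
    """
    if L < 2:
        raise ValueError("chain length must be at least 2")
    if L > 18:
        warnings.warn(
            f"L={L} exceeds the packed-mask limit of the fast kernel (18); "
            "falling back to the naive enumerator, which is very slow",
            RuntimeWarning,
        )
        from .fixtures import naive_inventory

        return naive_inventory(L)

    bitpos = _pair_bit_matrix(L)
    n = _dfs(L, bitpos, np.empty(0, dtype=np.uint64), True)
    out = np.empty(n, dtype=np.uint64)
    n2 = _dfs(L, bitpos, out, False)
    assert n2 == n
    masks, counts = np.unique(out, return_counts=True)
    return ContactInventory(L=L, masks=masks, counts=counts.astype(np.int64))
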