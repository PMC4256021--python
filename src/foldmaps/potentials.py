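"""Binary contact potentials: types, decomposition, and the grid sample.

A binary (two-letter) contact potential is the triple
``(e_AA, e_AB, e_BB)`` of pairwise contact energies; negative values are
attractive, positive repulsive, zero neutral. Sign patterns partition
potential space into seven classes (types I-VII): the six non-redundant
strict-sign octants (homomonomeric energies are interchangeable, so octants
related by swapping e_AA and e_BB coincide) plus type VI, the boundary
planes where at least one energy is exactly zero. Type VII (all repulsive)
stabilises nothing.

Two potentials induce the same sequence-structure map whenever they are
related by

* positive scaling (the stability function is linear in the energies),
* the homomonomer swap (a, h, b) -> (b, h, a) composed with complementing
  every sequence, or
* for symmetric potentials (a, h, a), the homo/hetero exchange
  (a, h, a) -> (h, a, h): square-lattice contacts always join chain
  positions of opposite parity, so complementing every second position
  turns each homomonomeric contact into a heteromonomeric one and vice
  versa.

:func:`grid_sample` reduces the 9x9x9 energy grid by these identifications
(plus removal of uniform and all-non-negative triples) to the standard
245-potential sample; see :func:`redundant_grid_pairs` for the two
exchange-equivalent family pairs the sample deliberately retains.
"""

from __future__ import annotations

import csv
import itertools
import json
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from math import gcd, isfinite
from pathlib import Path

import numpy as np

__all__ = [
    "BinaryPotential",
    "PotentialDecomposition",
    "PotentialType",
    "DEFAULT_GRID",
    "HP",
    "AB",
    "SHIFTED_HP",
    "SHIFTED_AB",
    "CANONICAL",
    "classify_type",
    "decompose",
    "grid_sample",
    "redundant_grid_pairs",
    "map_equivalence_check",
    "natural_binary_potentials",
    "read_potentials_csv",
    "write_potentials_csv",
]

#: the standard nine-value energy grid
DEFAULT_GRID = (-1.00, -0.75, -0.50, -0.25, 0.00, 0.25, 0.50, 0.75, 1.00)


class PotentialType(Enum):
    """Sign-pattern class of a binary potential."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"
    VI = "VI"
    VII = "VII"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class BinaryPotential:
    e_AA: float
    e_AB: float
    e_BB: float
    label: str = ""

    def __post_init__(self) -> None:
        for v in (self.e_AA, self.e_AB, self.e_BB):
            if not isfinite(v):
                raise ValueError("contact energies must be finite")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.e_AA, self.e_AB, self.e_BB)

    def scaled(self, c: float) -> "BinaryPotential":
        if c <= 0:
            raise ValueError("scale factor must be positive")
        return BinaryPotential(c * self.e_AA, c * self.e_AB, c * self.e_BB, self.label)

    def swapped(self) -> "BinaryPotential":
        """Homomonomer-swapped potential (relabels A <-> B)."""
        return BinaryPotential(self.e_BB, self.e_AB, self.e_AA, self.label)

    def energy(self, s_i: int, s_j: int) -> float:
        """Pair energy e(s_i, s_j) for monomers coded 0 (A) / 1 (B)."""
        if s_i == s_j:
            return self.e_BB if s_i else self.e_AA
        return self.e_AB

    @property
    def type(self) -> PotentialType:
        return classify_type(self)

    def scaled_ints(self) -> tuple[tuple[int, int, int], int]:
        """Integer representation ``(ints, scale)`` with ints = scale * e.

        Grid potentials (quarters) scale by 4, two-decimal tables by 100;
        the smallest denominator up to 10^6 is used.
        """
        fracs = [Fraction(v).limit_denominator(10**6) for v in self.as_tuple()]
        den = 1
        for f in fracs:
            den = den * f.denominator // gcd(den, f.denominator)
        return tuple(int(f * den) for f in fracs), den


HP = BinaryPotential(-1.0, 0.0, 0.0, "HP")
AB = BinaryPotential(-1.0, 1.0, -1.0, "AB")
# mean-centred variants of the canonical models, rescaled onto the grid
SHIFTED_HP = BinaryPotential(-0.50, 0.25, 0.25, "shifted-HP")
SHIFTED_AB = BinaryPotential(-0.50, 1.00, -0.50, "shifted-AB")
CANONICAL = {p.label: p for p in (HP, AB, SHIFTED_HP, SHIFTED_AB)}


def classify_type(p: BinaryPotential) -> PotentialType:
    """Classify a potential into types I-VII.

    Any exact zero takes precedence (type VI, the boundary planes); the six
    strict-sign classes follow the octant sign pattern of
    (e_AA, e_AB, e_BB), with the two homomonomeric energies playing
    interchangeable roles.
    """
    a, h, b = p.e_AA, p.e_AB, p.e_BB
    if a == 0 or h == 0 or b == 0:
        return PotentialType.VI
    if a > 0 and h > 0 and b > 0:
        return PotentialType.VII
    if a < 0 and h < 0 and b < 0:
        return PotentialType.III
    if a < 0 and b < 0:  # h > 0
        return PotentialType.II
    if a > 0 and b > 0:  # h < 0
        return PotentialType.V
    # homomonomeric signs differ
    return PotentialType.I if h > 0 else PotentialType.IV


@dataclass(frozen=True)
class PotentialDecomposition:
    """Ideal/excess split of the heteromonomeric energy.

    ``e_ideal = (e_AA + e_BB) / 2`` is the heteromonomeric energy an ideal
    mixture would have; ``e_xs = e_AB - e_ideal`` is the genuinely
    non-additive part; ``additivity = e_AB / e_ideal`` equals 1 exactly for
    additive potentials and is undefined when ``e_ideal`` is zero.
    """

    e_ideal: float
    e_xs: float
    additivity: float  # nan when undefined
    additivity_defined: bool


def decompose(p: BinaryPotential) -> PotentialDecomposition:
    e_ideal = (p.e_AA + p.e_BB) / 2.0
    e_xs = p.e_AB - e_ideal
    if e_ideal == 0.0:
        return PotentialDecomposition(e_ideal, e_xs, float("nan"), False)
    return PotentialDecomposition(e_ideal, e_xs, p.e_AB / e_ideal, True)


# ---------------------------------------------------------------------------
# the grid sample
# ---------------------------------------------------------------------------


def _rationalise_grid(values) -> tuple[list[int], int]:
    fracs = [Fraction(v).limit_denominator(10**6) for v in values]
    den = 1
    for f in fracs:
        den = den * f.denominator // gcd(den, f.denominator)
    ints = [int(f * den) for f in fracs]
    if len(set(ints)) != len(ints):
        raise ValueError("energy grid contains duplicate values")
    return ints, den


def _orbit(t, limits, exchange=True):
    """Closure of integer triple ``t`` under positive in-grid scaling, the
    homomonomer swap, and (where allowed) the homo/hetero exchange."""
    lo, hi, grid = limits
    seen = set()
    stack = [t]
    while stack:
        a, h, b = stack.pop()
        if (a, h, b) in seen:
            continue
        if (a, h, b) not in grid:
            continue
        seen.add((a, h, b))
        stack.append((b, h, a))
        if exchange and a == b and a * h != 0 and a + h != 0:
            stack.append((h, a, h))
        g = gcd(gcd(abs(a), abs(h)), abs(b))
        if g:
            p = (a // g, h // g, b // g)
            k = 1
            while True:
                q = (p[0] * k, p[1] * k, p[2] * k)
                if not all(lo <= x <= hi for x in q):
                    break
                stack.append(q)
                k += 1
    return seen


def grid_sample(values=DEFAULT_GRID) -> list[BinaryPotential]:
    """The reduced sample of binary potentials on an energy grid.

    From all ``len(values)**3`` triples, drops (i) uniform triples, which
    make no interaction relatively favourable, and (ii) triples with only
    repulsive or neutral interactions; then keeps one representative per
    equivalence class under (iii) positive scaling, (iv) the homomonomer
    swap, and (v) the homo/hetero exchange of symmetric triples. The
    exchange is deliberately not applied to the two self-mirrored families
    (antisymmetric ``(e, -e, e)`` and single-component ``(e, 0, e)``), which
    the standard sample keeps as distinct entries (see
    :func:`redundant_grid_pairs`). On the default grid this yields exactly
    245 potentials.

    The representative of each class is the member with the largest maximum
    absolute energy (ties broken lexicographically); output is sorted.
    """
    ints, den = _rationalise_grid(values)
    grid = set(itertools.product(ints, ints, ints))
    lo, hi = min(ints), max(ints)
    limits = (lo, hi, grid)

    def excluded(t):
        return t[0] == t[1] == t[2] or all(x >= 0 for x in t)

    reps = []
    seen = set()
    for t in sorted(grid):
        if t in seen or excluded(t):
            continue
        orb = _orbit(t, limits)
        seen |= orb
        best_abs = max(max(abs(x) for x in m) for m in orb)
        rep = min(m for m in orb if max(abs(x) for x in m) == best_abs)
        reps.append(rep)

    out = []
    for rep in sorted(reps):
        e = tuple(x / den for x in rep)
        label = f"({e[0]:+.2f},{e[1]:+.2f},{e[2]:+.2f})"
        out.append(BinaryPotential(*e, label=label))
    return out


def redundant_grid_pairs(values=DEFAULT_GRID) -> list[tuple[BinaryPotential, BinaryPotential]]:
    """Exchange-equivalent pairs that :func:`grid_sample` retains.

    Both members of each returned pair induce identical maps (they are
    related by the homo/hetero exchange), but the standard sample counts
    them separately.
    """
    sample = {p.as_tuple(): p for p in grid_sample(values)}
    ints, den = _rationalise_grid(values)
    grid = set(itertools.product(ints, ints, ints))
    limits = (min(ints), max(ints), grid)
    pairs = []
    done = set()
    for t in sorted(grid):
        a, h, b = t
        if a != b or not (a * h == 0 or a + h == 0) or a == h:
            continue
        o1 = _orbit(t, limits, exchange=False)
        o2 = _orbit((h, a, h), limits, exchange=False)
        if o1 == o2:
            continue
        p1 = [sample[tuple(x / den for x in m)] for m in o1 if tuple(x / den for x in m) in sample]
        p2 = [sample[tuple(x / den for x in m)] for m in o2 if tuple(x / den for x in m) in sample]
        if p1 and p2:
            key = frozenset((p1[0].as_tuple(), p2[0].as_tuple()))
            if key not in done:
                done.add(key)
                pairs.append((p1[0], p2[0]))
    return pairs


# ---------------------------------------------------------------------------
# map equivalence (validation oracle for the grid identifications)
# ---------------------------------------------------------------------------


def map_equivalence_check(
    p: BinaryPotential, q: BinaryPotential, L: int = 10, inventory=None
) -> bool:
    """Whether ``p`` and ``q`` induce the same sequence-structure map at
    length ``L``, up to a monomer relabelling.

    The relabellings tried are the identity, the global complement (for
    swap-related potentials), the alternating-position complement (for
    exchange-related symmetric potentials), and their composition. Native
    assignments must agree contact-set for contact-set under the bijection.
    """
    from .folding import fold_map
    from .lattice import enumerate_conformations

    if inventory is None:
        inventory = enumerate_conformations(L)
    elif inventory.L != L:
        raise ValueError("inventory length does not match L")
    mp = fold_map(inventory, p)
    mq = fold_map(inventory, q)
    n = 1 << L
    codes = np.arange(n, dtype=np.int64)
    full = (1 << L) - 1
    alt = sum(1 << i for i in range(1, L, 2))
    for mask in (0, full, alt, full ^ alt):
        perm = codes ^ mask
        if np.array_equal(mp.native_idx, mq.native_idx[perm]):
            return True
    return False


# ---------------------------------------------------------------------------
# natural (20-letter) alphabets, pairwise
# ---------------------------------------------------------------------------


def natural_binary_potentials(matrix, names=None):
    """Decompose a 20x20 symmetric contact-energy table into the 190 binary
    potentials of unordered residue pairs.

    Each pair {X, Y} (X != Y) yields ``(e_XX, e_XY, e_YY)``. Returns the
    potentials and a Counter over :class:`PotentialType`.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("contact-energy table must be square")
    if not np.array_equal(m, m.T):
        raise ValueError("contact-energy table must be symmetric")
    n = m.shape[0]
    if names is None:
        names = [str(i) for i in range(n)]
    pots = []
    for i in range(n):
        for j in range(i + 1, n):
            pots.append(
                BinaryPotential(m[i, i], m[i, j], m[j, j], f"{names[i]}-{names[j]}")
            )
    hist = Counter(p.type for p in pots)
    return pots, hist


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def write_potentials_csv(potentials, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "e_AA", "e_AB", "e_BB", "type"])
        for p in potentials:
            w.writerow([p.label, p.e_AA, p.e_AB, p.e_BB, p.type.value])


def read_potentials_csv(path) -> list[BinaryPotential]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                BinaryPotential(
                    float(row["e_AA"]),
                    float(row["e_AB"]),
                    float(row["e_BB"]),
                    row.get("label", ""),
                )
            )
    return out


def write_potentials_json(potentials, path) -> None:
    Path(path).write_text(
        json.dumps(
            [
                {"label": p.label, "e_AA": p.e_AA, "e_AB": p.e_AB, "e_BB": p.e_BB}
                for p in potentials
            ],
            indent=2,
        )
    )
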