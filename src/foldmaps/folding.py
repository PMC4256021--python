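"""Exhaustive folding of binary sequences over a contact-set inventory.

The stability of sequence ``s`` on a conformation with contact set ``cs``
is the sum of pair energies over the contacts,

    E(s, cs) = n_AA * e_AA + n_AB * e_AB + n_BB * e_BB,

where the ``n`` are the pair-type counts of the sequence on that contact
set. A sequence folds (is *viable*, or non-degenerate) when exactly one
conformation attains its minimum energy; that conformation is its native
structure under the thermodynamic hypothesis. Degeneracy counts
*conformations*, not contact sets: a sequence whose unique minimal contact
set is realised by m > 1 conformations is degenerate. The contact-free
conformation pool (empty contact set, E = 0) is part of the ensemble, so
E_min <= 0 always.

Foldability is the z-score of the ground state within the full
conformational ensemble,

    F = (E_min - <E>) / sigma,

with the moments weighted by contact-set multiplicity (i.e. taken over all
conformations). F <= 0 when defined; it is undefined (NaN) for sequences
whose energy is constant across the ensemble.

Energies are computed in exactly-scaled integers (grid potentials x4,
two-decimal tables x100), so ties are exact and never tolerance-based.
Sequences are integers in [0, 2^L): bit i is the monomer at chain
position i (0 = A, 1 = B).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import ContactInventory
from .potentials import BinaryPotential

__all__ = [
    "FoldRecord",
    "MapResult",
    "energy",
    "fold_sequence",
    "fold_map",
    "foldability",
    "sequence_pair_masks",
    "popcounts",
]


def _bit_matrix(L: int, codes: np.ndarray) -> np.ndarray:
    """(n, L) uint8 matrix of monomer codes for the given sequence codes."""
    return (codes[:, None] >> np.arange(L)[None, :] & 1).astype(np.uint8)


def sequence_pair_masks(L: int, codes: np.ndarray, pairs: np.ndarray):
    """Packed pair-type masks for each sequence.

    For every admissible contact pair (bit b), classify it per sequence as
    AA, AB or BB and pack the classification into three uint64 masks. The
    pair-type counts of a sequence on a contact set are then popcounts of
    mask intersections.
    """
    bits = _bit_matrix(L, np.asarray(codes, dtype=np.int64))
    bi = bits[:, pairs[:, 0]]
    bj = bits[:, pairs[:, 1]]
    powers = np.uint64(1) << np.arange(len(pairs), dtype=np.uint64)
    m_bb = ((bi & bj).astype(np.uint64) * powers).sum(axis=1, dtype=np.uint64)
    m_ab = ((bi ^ bj).astype(np.uint64) * powers).sum(axis=1, dtype=np.uint64)
    m_aa = (((1 - bi) & (1 - bj)).astype(np.uint64) * powers).sum(axis=1, dtype=np.uint64)
    return m_aa, m_ab, m_bb


def popcounts(x: np.ndarray) -> np.ndarray:
    return np.bitwise_count(x).astype(np.int64)


@dataclass(frozen=True)
class FoldRecord:
    """Folding outcome of one sequence."""

    sequence: int
    E_min: float
    degeneracy: int
    native_id: int | None  # contact-set mask, present iff degeneracy == 1
    foldability: float | None  # None when sigma = 0
    comp_class: int  # number of B monomers

    @property
    def viable(self) -> bool:
        return self.degeneracy == 1


@dataclass
class MapResult:
    """Per-sequence folding results for one potential over all 2^L sequences.

    ``native_idx[s]`` indexes the inventory's contact-set arrays (-1 for
    degenerate sequences); ``E_min_scaled`` is in integer energy units
    (divide by ``energy_scale`` for the potential's own units).
    """

    inventory: ContactInventory
    potential: BinaryPotential
    E_min_scaled: np.ndarray
    degeneracy: np.ndarray
    native_idx: np.ndarray
    foldability: np.ndarray  # NaN where undefined
    energy_scale: int
    encodability_denominator: str = "unique"

    @property
    def L(self) -> int:
        return self.inventory.L

    @property
    def n_sequences(self) -> int:
        return len(self.E_min_scaled)

    @property
    def viable(self) -> np.ndarray:
        return self.degeneracy == 1

    @property
    def V(self) -> np.ndarray:
        """Codes of viable (non-degenerate) sequences."""
        return np.flatnonzero(self.viable).astype(np.int64)

    @property
    def X(self) -> np.ndarray:
        """Inventory indices of accessible phenotypes (native structures)."""
        return np.unique(self.native_idx[self.viable])

    @property
    def comp_class(self) -> np.ndarray:
        codes = np.arange(self.n_sequences, dtype=np.uint64)
        return np.bitwise_count(codes).astype(np.int64)

    @property
    def nu(self) -> float:
        """Non-degeneracy: fraction of sequence space that folds."""
        return float(self.viable.mean())

    @property
    def c(self) -> float:
        """Encodability: fraction of potentially encodable contact sets
        (or of all contact sets, per ``encodability_denominator``) that are
        some sequence's native structure."""
        if self.encodability_denominator == "unique":
            denom = self.inventory.n_unique
        elif self.encodability_denominator == "all":
            denom = self.inventory.n_contact_sets
        else:
            raise ValueError("encodability_denominator must be 'unique' or 'all'")
        return len(self.X) / denom

    @property
    def median_foldability(self) -> float:
        """Median F over viable sequences (degenerate and undefined-F
        sequences excluded)."""
        f = self.foldability[self.viable]
        f = f[~np.isnan(f)]
        return float(np.median(f)) if len(f) else float("nan")

    def record(self, s: int) -> FoldRecord:
        deg = int(self.degeneracy[s])
        nid = int(self.native_idx[s])
        f = float(self.foldability[s])
        return FoldRecord(
            sequence=int(s),
            E_min=float(self.E_min_scaled[s]) / self.energy_scale,
            degeneracy=deg,
            native_id=int(self.inventory.masks[nid]) if deg == 1 else None,
            foldability=None if np.isnan(f) else f,
            comp_class=int(bin(s).count("1")),
        )

    def summary(self) -> dict:
        return {
            "label": self.potential.label,
            "type": self.potential.type.value,
            "L": self.L,
            "nu": self.nu,
            "c": self.c,
            "n_viable": int(self.viable.sum()),
            "n_phenotypes": int(len(self.X)),
            "median_foldability": self.median_foldability,
        }


class PairCountCache:
    """Potential-independent pair-type counts, reusable across potentials.

    Stores, for every (sequence chunk, contact set), the AA and AB pair
    counts; the BB count follows from the contact number. Shared by all
    potentials in a survey so the expensive popcount pass runs once.
    """

    def __init__(self, inventory: ContactInventory, chunk: int | None = None):
        self.inv = inventory
        n = 1 << inventory.L
        self.chunk = chunk or max(1, min(n, (1 << 24) // max(1, inventory.n_contact_sets)))
        self._aa = None
        self._ab = None

    def counts(self):
        if self._aa is None:
            inv = self.inv
            n = 1 << inv.L
            n_sets = inv.n_contact_sets
            aa = np.empty((n, n_sets), dtype=np.int8)
            ab = np.empty((n, n_sets), dtype=np.int8)
            for lo in range(0, n, self.chunk):
                codes = np.arange(lo, min(lo + self.chunk, n), dtype=np.int64)
                m_aa, m_ab, _ = sequence_pair_masks(inv.L, codes, inv.pairs)
                aa[lo : lo + len(codes)] = popcounts(inv.masks[None, :] & m_aa[:, None])
                ab[lo : lo + len(codes)] = popcounts(inv.masks[None, :] & m_ab[:, None])
            self._aa, self._ab = aa, ab
        return self._aa, self._ab


def energy(s: int, cs, p: BinaryPotential, L: int | None = None, pairs=None) -> float:
    """Stability of sequence ``s`` on contact set ``cs``.

    ``cs`` may be an iterable of index pairs or a packed mask (requires
    ``L``/``pairs`` context for decoding in the latter case).
    """
    if isinstance(cs, (int, np.integer)):
        if pairs is None:
            raise ValueError("decoding a packed mask requires the pair table")
        m = int(cs)
        cs = [tuple(pairs[b]) for b in range(len(pairs)) if m >> b & 1]
    e = 0.0
    for i, j in cs:
        if i < 0 or j < 0 or (L is not None and (i >= L or j >= L)):
            raise IndexError(f"contact pair {(i, j)} out of range")
        e += p.energy(s >> i & 1, s >> j & 1)
    return e


def _fold_chunk(inv, ints, codes):
    """Scaled energies (chunk x n_sets) for the given sequence codes."""
    e_aa, e_ab, e_bb = ints
    m_aa, m_ab, _ = sequence_pair_masks(inv.L, codes, inv.pairs)
    n_aa = popcounts(inv.masks[None, :] & m_aa[:, None])
    n_ab = popcounts(inv.masks[None, :] & m_ab[:, None])
    n_all = popcounts(inv.masks)[None, :]
    return e_aa * n_aa + e_ab * n_ab + e_bb * (n_all - n_aa - n_ab)


def fold_map(
    inventory: ContactInventory,
    potential: BinaryPotential,
    encodability_denominator: str = "unique",
    chunk: int | None = None,
) -> MapResult:
    """Fold all 2^L sequences over the inventory under one potential.

    Deterministic and chunk-size-invariant: results are identical whatever
    the streaming granularity.
    """
    if inventory.n_contact_sets == 0:
        raise ValueError("empty inventory")
    ints, scale = potential.scaled_ints()
    L = inventory.L
    n = 1 << L
    counts = inventory.counts
    n_conf = inventory.n_conformations
    chunk = chunk or max(1, min(n, (1 << 24) // inventory.n_contact_sets))

    E_min = np.empty(n, dtype=np.int64)
    deg = np.empty(n, dtype=np.int64)
    native = np.empty(n, dtype=np.int64)
    fold = np.empty(n, dtype=np.float64)

    for lo in range(0, n, chunk):
        codes = np.arange(lo, min(lo + chunk, n), dtype=np.int64)
        E = _fold_chunk(inventory, ints, codes)
        emin = E.min(axis=1)
        at_min = E == emin[:, None]
        d = at_min @ counts
        nat = E.argmin(axis=1)
        countsf = counts.astype(np.float64)
        mean = (E @ countsf) / n_conf
        centred = E - mean[:, None]
        var = (centred**2 @ countsf) / n_conf  # two-pass: no cancellation
        sd = np.sqrt(var)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(sd > 0, (emin - mean) / sd, np.nan)
        sl = slice(lo, lo + len(codes))
        E_min[sl] = emin
        deg[sl] = d
        native[sl] = np.where(d == 1, nat, -1)
        fold[sl] = f

    return MapResult(
        inventory=inventory,
        potential=potential,
        E_min_scaled=E_min,
        degeneracy=deg,
        native_idx=native,
        foldability=fold,
        energy_scale=scale,
        encodability_denominator=encodability_denominator,
    )


def fold_sequence(s: int, inventory: ContactInventory, potential: BinaryPotential) -> FoldRecord:
    """Fold a single sequence exhaustively; see :func:`fold_map`."""
    if inventory.n_contact_sets == 0:
        raise ValueError("empty inventory")
    ints, scale = potential.scaled_ints()
    codes = np.array([s], dtype=np.int64)
    E = _fold_chunk(inventory, ints, codes)[0]
    emin = int(E.min())
    at_min = E == emin
    deg = int(inventory.counts[at_min].sum())
    counts = inventory.counts.astype(np.float64)
    n_conf = inventory.n_conformations
    mean = float(E @ counts) / n_conf
    var = float(((E - mean) ** 2) @ counts) / n_conf
    sd = var**0.5
    f = (emin - mean) / sd if sd > 0 else None
    native = int(inventory.masks[int(np.argmax(at_min))]) if deg == 1 else None
    return FoldRecord(
        sequence=int(s),
        E_min=emin / scale,
        degeneracy=deg,
        native_id=native,
        foldability=f,
        comp_class=int(bin(int(s)).count("1")),
    )


def foldability(s: int, inventory: ContactInventory, potential: BinaryPotential) -> float | None:
    """Ground-state z-score F = (E_min - <E>) / sigma of one sequence
    (None when the ensemble energy is constant)."""
    return fold_sequence(s, inventory, potential).foldability


def fold_map_many(
    inventory: ContactInventory,
    potentials,
    cache: PairCountCache | None = None,
    encodability_denominator: str = "unique",
):
    """Fold a collection of potentials reusing one pair-count pass.

    Yields :class:`MapResult` per potential in input order.
    """
    if cache is None:
        cache = PairCountCache(inventory)
    aa, ab = cache.counts()
    n_all = popcounts(inventory.masks)[None, :]
    counts = inventory.counts
    countsf = counts.astype(np.float64)
    n_conf = inventory.n_conformations
    for p in potentials:
        (e_aa, e_ab, e_bb), scale = p.scaled_ints()
        E = e_aa * aa.astype(np.int64) + e_ab * ab.astype(np.int64) + e_bb * (
            n_all - aa - ab
        )
        emin = E.min(axis=1)
        at_min = E == emin[:, None]
        d = at_min @ counts
        nat = E.argmin(axis=1)
        mean = (E @ countsf) / n_conf
        var = ((E - mean[:, None]) ** 2 @ countsf) / n_conf
        sd = np.sqrt(var)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(sd > 0, (emin - mean) / sd, np.nan)
        yield MapResult(
            inventory=inventory,
            potential=p,
            E_min_scaled=emin,
            degeneracy=d,
            native_idx=np.where(d == 1, nat, -1),
            foldability=f,
            energy_scale=scale,
            encodability_denominator=encodability_denominator,
        )
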