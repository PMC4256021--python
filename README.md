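# foldmaps

Exhaustive sequence–structure (genotype–phenotype) maps of binary
heteropolymers on the 2D square lattice.

`foldmaps` is for researchers studying how the form of a contact potential
shapes the architecture of protein-like sequence–structure maps: lattice
("simple exact") protein models, neutral networks and designability,
reduced amino-acid alphabets, and the statistics of genotype spaces. It
enumerates the *complete* conformational space of short chains, folds
*every* binary sequence under arbitrary pairwise potentials, and analyses
the induced maps as graphs — no sampling anywhere in the core pipeline.

## Model

A conformation of an L-mer is a self-avoiding walk on the square lattice;
walks related by one of the 8 lattice symmetries (rotations and
reflections, but *not* chain reversal) are the same conformation. Because
the energy only sees contacts — residue pairs (i, j) that are lattice
neighbours but not chain neighbours — conformations are summarised by
contact sets; contact sets realised by exactly one conformation are the
*potentially encodable* phenotypes. For L = 18 there are 5,808,335
conformations, 170,670 distinct contact sets, and 77,635 potentially
encodable ones.

A binary potential is the triple (e_AA, e_AB, e_BB). The stability of
sequence s on conformation x is

    E(s, x) = Σ_{(i,j) ∈ contacts(x)} e(s_i, s_j),

and, under the thermodynamic hypothesis, s *folds* iff exactly one
conformation attains min E (degeneracy g = 1); that conformation is its
native structure. Map-level summaries: non-degeneracy ν (viable fraction
of the 2^L sequences) and encodability c (fraction of the potentially
encodable conformations that are some native structure). A sequence's
foldability is the ground-state z-score over the full conformational
ensemble,

    F = (E_min − ⟨E⟩) / σ,

more negative meaning a steeper folding funnel. Viable sequences form a
graph (edges = point mutations), which decomposes into genotype
components ⊇ neutral networks, grouped into neutral sets per phenotype;
designability is neutral-set size, and the sequence-weighted expected
cluster size is Σn²/Σn.

Sign patterns split potential space into 7 types (I–VII): the six
non-redundant strict-sign octants — homomonomeric energies are
interchangeable — plus type VI (any energy exactly 0; the HP model
(−1, 0, 0) is type VI, the AB model (−1, 1, −1) type II). Type VII (all
repulsive) stabilises nothing. Reducing the 9×9×9 grid over
{−1.00, −0.75, …, 1.00} by uniform-triple and all-repulsive removal,
positive scaling, homomonomer swap, and the homo/hetero exchange of
symmetric triples leaves the standard sample of 245 potentials.

## Worked example

```python
from foldmaps import (AB, enumerate_conformations, fold_map,
                      build_and_decompose, expected_size)

inv = enumerate_conformations(10)
print(f"L=10: {inv.n_conformations} conformations, "
      f"{inv.n_contact_sets} contact sets, {inv.n_unique} potentially encodable")

res = fold_map(inv, AB)
print(f"AB map: nu = {res.nu:.4f}  c = {res.c:.3f}  "
      f"median F = {res.median_foldability:.2f}")

dec = build_and_decompose(res)
s = dec.summary()
print(f"{s['n_components']} components, {s['n_neutral_sets']} neutral sets, "
      f"{s['n_neutral_networks']} neutral networks; "
      f"expected component size {expected_size(dec.component_sizes):.2f}")
```

prints

```
L=10: 2034 conformations, 212 contact sets, 100 potentially encodable
AB map: nu = 0.0508  c = 0.180  median F = -4.02
28 components, 18 neutral sets, 40 neutral networks; expected component size 2.31
```

Read: of the 1,024 ten-mers, 5.1% fold uniquely under the AB potential;
they encode 18 of the 100 potentially encodable conformations (c = 0.18).
The viable graph is fragmented (28 components for 52 sequences), typical
of HP-like maps whose per-sequence neutrality sits far below the binary
percolation threshold λ* = 0.5.

## Analyses

Numbered drivers under `analysis/` reproduce the study pipeline at desk
scale and write tables under `results/`:

1. `01_enumerate_conformations.py` — conformation/contact-set census per L
   (`--full` includes L = 18).
2. `02_sample_potentials.py` — the 245-potential grid sample, type
   histogram, ideal/excess decomposition.
3. `03_fold_survey.py` — all 245 maps at L = 10: summaries, Jaccard
   matrices, group-average dendrogram, universally encoded phenotypes.
4. `04_graph_architecture.py` — components/sets/networks of the canonical
   HP/AB/shifted maps, expected sizes, diameters, neutrality.
5. `05_map_statistics.py` — compositional and compactness biases,
   designability CDFs, phenotypic-diversity curves, set diameters.
6. `06_natural_alphabet.py` — pairwise (190 binary potentials)
   decomposition of a 20×20 contact-energy table. The bundled table is a
   synthetic stand-in (see `docs/methods.md`); pass `--table` for a real
   statistical potential.

A `foldmaps` CLI wraps the same library calls (`foldmaps enumerate`,
`fold`, `graph`, `stats`, `compare`, `survey`, `audit`, `potentials …`,
`fixtures-build`).

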