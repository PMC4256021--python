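# Methods

## Model and conventions

**Conformations.** An L-mer conformation is a self-avoiding walk of L
sites on the integer square lattice. Two walks are the same conformation
iff one of the 8 elements of the square's dihedral group maps one onto
the other (after re-rooting at the origin). Chain reversal is *not* in
the symmetry group: the chain is oriented, and only this convention
reproduces the 18-mer census (5,808,335 conformations; a
reversal-inclusive quotient would give roughly half). The enumerator
fixes the first step to +x and the first turn to +y, which yields exactly
one representative per symmetry class — the only rooted walk fixed by a
non-trivial dihedral element is the straight one, which the scheme also
emits once. `canonical_form` (lexicographically minimal step string over
the 8 images; the straight walk canonicalises to the +x ray) is used for
verification and by the independent naive oracle, not by the fast kernel.

**Contacts.** A contact is a pair (i, j) of residues at unit lattice
distance with |i − j| ≥ 2; bipartiteness of the lattice forces
j − i ≥ 3 and odd. For L = 18 the admissible pairs number exactly 64, so
contact sets are packed into 64-bit masks; the packed-mask kernel
therefore supports L ≤ 18 (larger L falls back to the naive enumerator).
The empty contact set is a regular inventory entry — it aggregates all
contact-free conformations and guarantees the energy minimisation always
sees E = 0 states, hence E_min ≤ 0.

**Energies.** Potentials are rationalised to exact integers before
folding (grid potentials ×4, two-decimal tables ×100; generally the
smallest common denominator up to 10⁶). All minima, ties and degeneracy
counts are exact integer comparisons; no epsilon tolerances exist
anywhere in the pipeline. Degeneracy counts *conformations*: a sequence
whose unique minimal contact set has multiplicity m > 1 is degenerate,
which is why only multiplicity-1 contact sets are potentially encodable.

**Foldability.** F = (E_min − ⟨E⟩)/σ with moments weighted by contact-set
multiplicity, i.e. taken over all conformations including the
contact-free pool. The variance uses a centred two-pass formula (no
catastrophic cancellation); σ = 0 (constant ensemble energy, e.g. the
all-neutral sequence of the HP model) flags F undefined, and such
sequences — degenerate in every observed case, which the tests assert —
are excluded from median-foldability summaries. F is invariant under
positive scaling of the potential, as a z-score must be.

**Encodability denominator.** c divides the number of accessible
phenotypes |X| by the count of *potentially encodable* (multiplicity-1)
contact sets — 77,635 at L = 18; since every native structure is
necessarily multiplicity-1, this is the natural normalisation. The alternative denominator (all distinct contact sets) is
available via `encodability_denominator="all"`.

## Potential space

The type classification is total and deterministic: any exact zero →
type VI (the boundary planes take precedence over sign patterns); all
positive → VII; all negative → III; both homomonomers negative with
positive heteromonomer → II; the converse → V; mixed homomonomer signs →
I (heteromonomer positive) or IV (negative). One strict-sign
representative per octant gives types I:II:III:IV:V:VII = 2:1:1:2:1:1.

Three identifications are exact map equivalences, and
`map_equivalence_check` verifies each by exhaustive folding:

* positive scaling — stability is linear in the energies;
* homomonomer swap (a, h, b) → (b, h, a), equivalent under complementing
  every sequence;
* homo/hetero exchange (a, h, a) → (h, a, h) for symmetric potentials —
  square-lattice contacts always join chain positions of opposite
  parity, so complementing every second position turns each
  homomonomeric contact heteromonomeric and vice versa.

`grid_sample` reduces the 729 grid triples by removing uniform triples
and all-non-negative triples, then quotienting by the identifications
above. The full closure would leave 243 classes; the standard sample
size of 245 keeps both members of the two *self-mirrored* exchange
families — the antisymmetric potentials (e, −e, e) (the AB model and its
sign mirror) and the single-component potentials (e, 0, e)/(0, e, 0) —
so the exchange is applied only when e_AA·e_AB ≠ 0 and e_AA + e_AB ≠ 0.
The two retained pairs are genuinely redundant (their members induce
identical maps, as the tests verify) and are exposed by
`redundant_grid_pairs` so downstream analyses can account for them.
Class representatives are the member with the largest maximum absolute
energy, ties broken lexicographically; output order is sorted and
deterministic.

The shifted HP/AB variants bundled as canonical fixtures are defined
here as the mean-centred potentials rescaled onto the grid:
shifted-HP = (−0.50, +0.25, +0.25), shifted-AB = (−0.50, +1.00, −0.50).
They keep each model's excess part while removing the uniform offset.

## Graphs

Components are computed with sparse connected components over the
Hamming-1 adjacency; neutral networks as connected components of each
neutral set's induced subgraph. Labels are canonical — decreasing size,
ties by smallest member sequence — so reruns are bit-identical. Cluster
"diameter" is the maximum pairwise Hamming distance (the convention used
for the distribution summaries); the graph-geodesic diameter is exposed
separately as `geodesic_diameter`. Per-sequence neutrality divides by L
(all single-point mutants, including degenerate ones); the binary-alphabet
percolation threshold λ* = 0.5 is surfaced as a constant for comparison,
and no asymptotic percolation theory is implemented.

## Statistics

Expected compositional and compactness distributions are estimated by
seeded resampling (draws without replacement of |V| sequences from
sequence space, or |X| conformations from the encodable set), reported as
mean ± sd over replicates; the default of 100 replicates makes the
Monte-Carlo error on the mean an order of magnitude smaller than the
1-sd error bars reported. Designability/neutrality CDFs are
sequence-weighted: P(C ≥ C0) is the probability that a uniformly drawn
viable sequence lies in a cluster of size ≥ C0. Diversity curves sample
n viable sequences without replacement and evaluate all C(n, 2) pairs,
binned by exact Hamming distance; k-neighbourhoods exclude the centre
(|N_k| = Σ_{i=1..k} C(L, i), e.g. 18, 987 and 12,615 for k = 1, 3, 5 at
L = 18). Two k-balls are vertex-disjoint iff d > 2k, but their phenotype
sets may still overlap, so u < 1 beyond that threshold is meaningful.
Map clustering runs scipy's agglomerative linkage (group-average by
default; single/complete as alternatives) on distance 1 − J; dendrograms
serialise to Newick with quoted labels and a metadata side table.

## Synthetic fixtures and oracles

The fixture module is first-class, tested code. Its oracles share no
code with the engines: the naive enumerator generates every rooted walk
and deduplicates by explicit symmetry images; the brute-force folder
minimises conformation by conformation in exact rational arithmetic; the
decomposition oracle is a hand-rolled BFS. Oracle equivalence is asserted
exactly at L ≤ 8–10, where exhaustive enumeration is instant.

The worked-example genotype graph (192 abstract nodes, 84 viable,
components 53/24/7, neutral sets 12/19/15/23/15, nine neutral networks)
is an abstract labelled graph, not a lattice map; it exercises the graph
arithmetic only. The declared totals fix the marginal sizes but not the
per-component network split; the layout used here (blue 8+4, orange
3+5+7, green 19, magenta 13+10, yellow 15) reproduces every declared
count, including the largest component containing 4 neutral sets and 5
neutral networks. All declared statistics are re-derived and asserted on
load.

`synthetic_mj_contact_energies.csv` is a **synthetic stand-in** for a
statistical 20×20 contact-energy table, generated by a fixed-seed
construction (additive per-residue transfer term plus symmetric excess
noise, rounded to two decimals so exact zeros occur). It has the
qualitative shape of quasi-chemical potentials — mixed signs, a dominant
all-attractive class, a few neutral entries — and exists to exercise the
190-pair decomposition machinery; no conclusion about natural amino
acids should be read off it. Analyses of a real statistical potential
should load the published table via the same CSV layout.

## Problem sizes and defaults

The package's standard working scales: full enumeration and folding are
exact at any L ≤ 18; the bundled analyses run the complete 245-potential
survey at L = 10 and per-map examples at L ≤ 12, where every quantity is
still exhaustive (2^L sequences × all contact sets). The L = 18 survey
over 245 potentials is the same code path (`SurveyConfig(L=18, ...)`)
but is a cluster-scale computation; the L = 18 runs performed here are
the conformation-space census and single-sequence folds. Survey runs are
resumable (config-hashed manifest; mixed-config directories are
refused), worker-count-invariant, and auditable (`audit_survey` rederives
ν and c from the persisted per-sequence records).

## Known limitations

* 2D square lattice, binary alphabets (plus pairwise decomposition of
  larger alphabets); no 3D/FCC lattices, no Boltzmann ensembles or
  kinetics — ground states only.
* The packed-mask kernel caps at L = 18 (64 admissible pairs); beyond
  that only the impractically slow naive path exists.
* Desk-scale results (L ≤ 12) reproduce the *structure* of the study
  pipeline, not the L = 18 survey's numerical values: small-L maps have
  stronger finite-size effects (e.g. no universally encoded phenotype
  exists at L = 10, while a substantial intersection appears at L = 18).
* Resampled expectations assume uniform nulls; no other null models are
  provided.
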