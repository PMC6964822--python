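# Methods

## Model

`messar` treats substructure annotation as association rule mining over a
binary transaction table. Each transaction is one compound of a
structure-annotated MS/MS library, described by two item families:

* **Spectral features.** *Mass* items are neutral exact masses of
  formula-annotated fragments; *MDiff* items are mass differences. For
  training, only fragmentation-tree nodes and edges are used: an edge's
  parent−child difference is a neutral loss produced by a fragmentation
  reaction, whereas the full set of C(n,2) pairwise differences of an
  n-peak spectrum is dominated by structurally meaningless combinations
  (20 peaks already give 190 differences). Queries have no trees, so query
  feature sets use all fragments (neutralized by one proton under the
  [M+H]+ assumption) plus all pairwise and precursor−fragment differences.
* **Substructures.** Connected fragments with at least 2 heavy atoms,
  obtained (i) by matching a user-supplied pattern list (a curated default
  of ~55 functional groups and ring systems ships with the package) and
  (ii) by cleaving one or two acyclic single bonds of the molecule and
  collecting the resulting two or three fragments. C/H/O/N-only fragments
  with fewer than five carbon-plus-oxygen atoms are discarded as trivial;
  fragments containing rarer elements (halogens, S, P, ...) are always
  kept, whatever their size. A `brics_bonds` cleavage policy restricts
  cuts to BRICS link bonds; the default cuts every acyclic single bond.

A rule X ⇒ Y (body: 1–3 features; head: one substructure) is a binary
classifier of the library, with Supp(X) = TP+FP spectra containing the
body, Supp(Y) = TP+FN compounds containing the head, precision = TP/Supp(X)
and recall = TP/Supp(Y). Recall — the probability of observing the feature
set given the substructure — is the ranking and filtering statistic
throughout; precision is reported but is typically low and uninformative
for rule selection.

Bodies are enumerated apriori-style over features only and then crossed
with co-occurring heads. Keeping heads out of the itemset lattice
guarantees well-formed rules (bodies never contain substructures, heads are
single substructures) and keeps the enumeration small.

## Target–decoy filtering

A decoy library preserves every compound label and per-spectrum peak count
but replaces each record's peaks with a draw (without replacement) from the
pooled peaks of all other records. This destroys any feature–structure
coupling while conserving the mass distribution and library shape, so
rules mined from the decoy estimate the chance-association background.
Decoy feature sets are a 20% random sample of each decoy spectrum's
pairwise mass differences, which roughly balances the per-spectrum feature
load against tree-edge-based target features. The simple FDR at a recall
threshold t is `#{decoy recalls ≥ t} / #{target recalls ≥ t}` (0/0 → 0),
and the filter keeps target rules with recall *strictly above* the
smallest observed target recall whose FDR is at or below the requested
level. An optional cumulative-minimum q-value transform is available but
not applied by default.

## Recommendation

A rule matches a query if every body feature finds a query feature of the
same type within the ppm tolerance (conjunctive semantics — bodies are
sets of *co-occurring* features). Matched rules are ranked by recall and
aggregated. In `exhaustive` mode every pair of matched rules whose heads
have Tanimoto similarity above 0.5 contributes the pair's maximum common
substructure; identical MCS strings are merged and each contributing
rule's recall is counted once per distinct recommendation (several pairs
yielding the same MCS must not double-count a rule). Rules in no analogous
pair pass through with their own head. `fast` applies the same procedure
to the 20 highest-recall matches; `naive` only pools identical heads.
Recommendations with fewer than 5 heavy atoms are dropped at reporting
time (configurable), and ties are broken by heavy-atom count, then
lexicographic SMILES.

Motif annotation (for externally derived patterns of co-occurring
fragments/losses with probabilities) matches the 50 most probable motif
features against the database, keeps the highest-recall rule per distinct
body, resolves exact recall ties by the MCS of the tied heads, and reports
the most frequent resulting structure.

## Parameters

| parameter | default | meaning |
|---|---|---|
| mass rounding | 4 decimals | feature identity; formula-derived masses collide exactly |
| ppm window | 20 | query-to-rule feature matching tolerance |
| min Supp(X) | 5 | minimum spectra supporting a body |
| min TP | 5 | minimum co-occurrence count (also the evaluability bar on test data) |
| max body | 3 | maximum features per rule body |
| FDR level | 0.01 | target–decoy filtering level |
| decoy fraction | 0.2 | fraction of pairwise MDiffs sampled per decoy spectrum |
| Tanimoto threshold | 0.5 | "analogous rules" cutoff for MCS aggregation |
| fingerprint | path-based, 1024 bits, max path 7 | Tanimoto similarity basis |
| MCS budget | 1 s/pair | pairs exceeding it are skipped with a warning |
| small filter | 5 heavy atoms | minimum reported recommendation size |

All of these are carried in `PipelineConfig`; its fingerprint is embedded
in every output TSV header and mismatched fingerprints abort `filter`.

## Numerical and design choices

* **Fragment-duplicate identity** when merging spectra of one compound is
  equality after rounding to 4 decimals. Formula-derived neutral masses
  collide exactly at that precision; raw (non-tree) libraries should be
  pre-clustered, for which a greedy 20 ppm single-linkage utility
  (`cluster_features_ppm`) is provided.
* **Structure identity** is the InChIKey first block when available, else
  the canonical SMILES.
* **MCS semantics**: connected, element- and bond-order-matched, charge
  and stereo ignored, complete rings only. Allowing partial aromatic rings
  produces "common subgraphs" that cannot be rendered as embeddable
  fragments, breaking the invariant that an MCS is contained in both
  inputs.
* **Fingerprint choice matters** for which heads count as analogous: under
  the path fingerprint, benzene vs toluene scores 0.33 (not analogous)
  while toluene vs ethylbenzene scores 0.58. The choice is recorded in the
  config fingerprint.
* **Cleavage** is restricted to acyclic single bonds between heavy atoms:
  cutting a ring bond cannot split a molecule into two fragments. Cut
  pairs that fail to yield three fragments are skipped. `max_cuts=0`
  disables cleavage for pattern-only runs (used by the larger simulation
  studies, where enumerating all cut pairs of long-chain molecules
  dominates runtime without changing the statistic under study).
* **Rule ordering** is deterministic: (recall desc, precision desc, body
  size asc, head SMILES), with ids assigned in that order; re-running with
  equal inputs and config is byte-identical.
* **Degenerate inputs**: spectra without peaks are skipped and counted;
  tree edges with parent ≤ child or unknown masses are rejected; records
  without structures are excluded from transactions (warned); an empty
  decoy set makes the FDR identically zero and the threshold the smallest
  target recall.

## Synthetic fixtures

The generator emulates a curated training library. Compounds are real
small molecules; each spectrum is a star-shaped fragmentation tree rooted
at the molecular monoisotopic mass, with one edge per fragment, so every
planted mass difference is realizable as a tree-edge loss without
modelling fragmentation chemistry. A planted association injects a feature
into spectra of compounds containing a substructure with probability
`emit_prob` (the designed recall) and elsewhere with `leak_prob`
(controlling designed precision); uniform noise fragments are added on
top. Two ready-made families are provided: a chloride-loss library (30
chloroalkanes among 100 distinct compounds, HCl-loss MDiff planted) and a
four-family library (chloroalkanes, alkylphenols, alkylindoles, alkyl
benzoic acids with seven characteristic losses/fragment masses at designed
recall 0.8). By default compound pools are drawn without replacement so
each record is a distinct compound, making Supp(Y) interpretable directly;
sampling with replacement is available and interacts with
`merge_by_structure` as for real libraries.

What the fixtures do **not** emulate: intensity structure (all intensities
are 1), realistic fragmentation cascades (star trees only), isotope
patterns, adducts other than [M+H]+, and mass error (features collide
exactly at 4 decimals). Passing tests therefore demonstrate the
correctness of the mining/FDR/aggregation machinery and its statistical
calibration under the generative model — not robustness to instrument
noise or to imperfect fragmentation trees.

The simulation studies in the test suite use 100-compound libraries for
worked examples, 250-compound libraries across 100 replicates for
parameter recovery (mined recall within 3 binomial SDs of the planted
emission probability), and 100-compound four-family libraries for
target–decoy separation.

## Limitations

* The decoy generator is a peak-pool permutation, not a fragmentation-tree
  rearrangement: it preserves the null hypothesis (features decoupled from
  structures) but not the tree topology of each decoy spectrum, so decoy
  spectra are somewhat "noisier" than rearranged trees would be.
* The default pattern list is a small curated set; production use should
  supply a fingerprint-derived pattern collection.
* Only positive ion mode, [M+H]+ adducts, are assumed for queries.
* MCS aggregation merges by canonical MCS string at pair level; a
  component-level grouping of analogous rules could merge more
  aggressively and is not implemented.
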