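# Methods

This note documents the models and procedures implemented in `oreganokg`,
the parameters that matter, the design choices taken where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## 1. Graph model and schema

The knowledge graph is a directed labelled multigraph of
(subject, predicate, object) triples over typed entities. Eleven node kinds
exist (COMPOUND, TARGET, GENE, DISEASE, ATC, PHENOTYPE, PATHWAY, EFFECT,
ACTIVITY, INDICATION, SIDE_EFFECT) and 19 predicates, each with one fixed
(subject kind, object kind) pair — e.g. `has_target: COMPOUND → TARGET`,
`acts_within: GENE → PATHWAY`, `gene_product_of: TARGET → GENE`. The
predicate table is plain-text configuration (`schema.DEFAULT_PREDICATE_TABLE`
or any file in the same 3-column layout), so the vocabulary is data, not
code. `validate_triple` reports domain/range violations as data, never as
exceptions; the pipeline's output is schema-closed by construction and the
test suite asserts it.

Global identifiers are `KIND:serial` with per-kind counters that are never
reused. Two naming choices were open:

* the target kind appears in the wild both as `TARGET` (file name) and
  `PROTEIN` (identifier surface form). Canonical kind is TARGET; the TSV
  writer and reader accept a kind-alias map so `PROTEIN:<n>` output can be
  produced and parsed.
* ATC codes are self-identifying: the 7-character classification code is
  both the local and the global identifier (`ATC:A10BA02`), and no serial is
  minted. ATC is a classification, not a fused entity, and has no
  cross-reference table.

## 2. Wrappers and filter rules

Each source has its own dialect reader (XML-like records for the drug and
protein sources, row-typed TSV for the annotation-table sources, OBO for the
phenotype ontology, 3-column TSV for the two pivots). Readers skip and count
malformed records; an unreadable file is a hard error. A reader only accepts
link rows whose predicate is attributed to its source; the attribution lives
in `wrappers.SOURCE_PREDICATES`.

Filters are pure functions — output is an order-preserving subset of the
input, so they are idempotent and compose in any order within a source:

| rule | keep iff |
|------|----------|
| natural-compound organism | target organism is `Homo sapiens` (missing organism ⇒ dropped, conservative) |
| ATC code level | code has exactly 7 characters (shorter codes are drug classes) |
| pharmacogenomic evidence | clinical-annotation level ∈ {1A, 1B, 2A, 2B} |
| phenotype frequency | resolved frequency ≥ 0.30; if no frequency is given, evidence ∈ {TAS, PCS} |
| protein source | record is in the reviewed (Swiss-Prot) dataset; link endpoints resolve to nodes already in the graph |

Frequency strings are resolved as: `n/m` ratios → n/m; percentages →
value/100; qualitative band labels → the band's **lower bound** (Excluded 0,
Very rare 0.01, Occasional 0.05, Frequent 0.30, Very frequent 0.80,
Obligate 1.0). Comparing the lower bound against the 0.30 threshold keeps
exactly {Frequent, Very frequent, Obligate}, the conservative reading of a
threshold phrased on band boundaries. A row carrying both a sub-threshold
frequency and TAS/PCS evidence is dropped: the evidence rule is a fallback
for missing frequencies only. An unparseable frequency is treated as absent
(falls back to the evidence rule) and counted.

OMIM codes are attached to phenotype-source diseases only through the
concept pivot (`restrict_omim_via_umls`): an OMIM identifier is integrated
iff it is reachable from an integrated disease via a shared pivot concept.
A second pivot supplies rare-disease (Orphanet) identifiers the same way.

Integration order is configurable; the default
(drug → side-effect → pharmacogenomic → natural-compound → phenotype →
pathway → protein) puts the hub sources first and the protein source last,
because its links are restricted to endpoints already present. As a pipeline
policy, protein-source records are resolved with `require_match=True`: they
merge into an existing row or are skipped, never minting an orphan node.

## 3. Binder (entity resolution)

Fusion is strictly cross-reference based; names never participate.
Cross-reference keys are normalized deterministically (trim, case-fold the
namespace, strip a redundant `namespace:` prefix from the identifier).
Records are resolved one at a time:

1. candidates = existing rows **of the same kind** sharing ≥ `min_overlap`
   (default 1) normalized keys, sorted by overlap count descending, then by
   serial ascending (oldest row first — the deterministic tie-break);
2. if any candidate exists, the record merges into the first one, donating
   its local ID and any cross-reference keys not yet owned by another row of
   that kind (within a kind, a key belongs to exactly one row — the ledger
   invariant);
3. otherwise a fresh identifier is minted. A record with no cross-references
   always mints; it is never silently attached.

Matching per kind prevents compound/target collisions on shared chemical
identifiers; a key observed under two kinds is logged as a conflict. The
binder is greedy and sequential: when a later record shares keys with two
existing rows it merges into the best one and the bridging event is logged,
not applied — retro-merging existing rows is a documented extension point,
not implemented. Determinism: identical inputs in identical order give
byte-identical tables. The test suite checks the induced partition against
an independently implemented nested-loop oracle with the same declared rule.

## 4. Manager (rewriting and serialization)

Endpoints are resolved in this order: ATC literal → source-local index →
cross-reference index under the predicate's expected kind; a triple with any
unresolvable endpoint is dropped and counted by reason (a node is not
integrated if no linkage can be made for it). Output is deduplicated
preserving first occurrence.

Serialization choices (all open, all fixed for diffability):

* triple TSV: 3 tab-separated columns, no header (a `header` flag adds the
  `Subject/Predicate/Object` line), sorted lexicographically, UTF-8;
* Turtle: one project namespace with kind-prefixed local names
  (`…/COMPOUND_10025`), `rdfs:label` for display names, one `xref` literal
  statement per cross-reference; illegal IRI characters percent-encoded.
  The edge set recoverable from Turtle equals the TSV triple set;
* cross-reference tables: one TSV per kind; the first header cell is
  `ID_OREGANO:<n>` with `n` = number of data rows, remaining header cells
  name the sources; each row starts with the entity display name, then the
  global identifier, then `;`-separated local IDs per source (the in-cell
  delimiter is unspecified upstream; `;` chosen). ACTIVITY and EFFECT are
  name lists only.

## 5. Embedding models

Six families, implemented directly in NumPy (no autograd): TransE, TransH,
TransR, RotatE, ComplEx, DistMult, with the scoring functions listed in the
README. Loss assignment follows the families' origins: margin ranking
`max(0, γ + s(neg) − s(pos))` for the translation/rotation distances,
logistic `softplus(−y·s)` for the bilinear models. Negative sampling
corrupts head or tail with probability ½ each, drawing the replacement
uniformly from the other entities.

Gradients are derived by hand per family (e.g. for TransH,
∂s/∂w = (û·w)z + (wᵀz)û with û the normalized difference vector) and are
verified against central finite differences at random points in the test
suite (observed agreement ≈ 1e−9, asserted ≤ 1e−5 relative).

Numerical choices:

* initialisation: uniform Xavier-style `U(±6/√d)`; RotatE phases uniform on
  [0, 2π); TransR projections `I + 0.1·noise` so the map starts near
  identity; TransH normals renormalized to unit length after every step;
* optimizer: mini-batch SGD with optional Adagrad per-parameter scaling
  (default Adagrad, ε = 1e−10); all randomness flows from one seed, so
  identical seeds give bit-identical models;
* duplicate triples are removed before training, so a graph and its exact
  duplicate produce the same model;
* L2 distances guard against the zero-vector singular point; a non-finite
  loss aborts training with a diagnostic;
* defaults: d = 64, lr = 0.01, γ = 1, 1 negative per positive, batch 128,
  p = 1 for TransE/RotatE. These are package defaults, not claims about any
  external tuning.

## 6. Evaluation protocol

`split_graph` draws k (default 5) independent uniformly-random partitions at
the configured test fraction (default 0.1). Entity/relation coverage is
enforced by admission: a shuffled triple enters the test set only while all
of its elements retain another occurrence in the remaining train side, so
singleton entities stay in train (k independent resamples, not k-fold
cross-validation — the choice taken where either reading was possible).

Ranks are computed both directions (head and tail corruption), pooled, with
filtered ranking as the default (corruptions that are themselves known true
triples are removed; the filter set is the whole graph) and optimistic ties
(only strictly greater scores count); a raw mode and a pessimistic tie
policy exist for audit, and both choices are recorded in the report.
MRR = mean(1/rank); Hit@N = fraction(rank ≤ N); the report carries per-split
values and their arithmetic mean.

`predict_top_targets` trains on the whole graph, restricts candidates to
TARGET-kind entities (an `all_entities` flag lifts the restriction), removes
known true targets, and returns the top k (default 10) by descending score,
ties broken by identifier.

## 7. Synthetic suite: what it emulates and what it does not

The generator (`synth.generate_suite`) emits all source dumps plus the two
pivots with complete ground truth. Default conditions: ~490 planted entities
across the 11 kinds (plus the shared ATC hierarchy), ~2,700 post-filter
edges covering all 19 predicates; hub-cross-reference density 1.0 and
cross-reference noise 0.0 (each per-source record carries its entity's hub
key with probability `hub_density`, spurious keys are drawn from a small
shared pool at rate `xref_noise`); 4 latent blocks with within-block edge
preference 0.9; evidence levels with ≈ 55% of pharmacogenomic annotations at
1A–2B; 70% of phenotype links carrying a frequency (rendered as a ratio, a
percentage or a band label in equal parts), the rest carrying TAS/PCS/IEA
evidence; 85% of protein entries reviewed. Survivor sets for every filter
are recomputed inside the generator from its own knowledge of each row,
never via the wrapper code they test.

At full hub density with zero noise the planted identity partition is
recoverable exactly and the built graph equals the planted edge set — those
are the conditions under which the end-to-end tests assert exact agreement.
Lowering density/raising noise degrades recall gracefully while per-kind
matching keeps pairwise precision high (asserted > 0.9 at density 0.6,
noise 0.05).

The block structure makes held-out within-block edges statistically
learnable, which is what the planted-link protocol measures: ComplEx at
d = 32 trained 50 epochs (lr 0.3, 8 negatives, Adagrad — the package's own
tuning for this fixture) over 5 splits reaches averaged Hit@10 well above
5× the random-ranking expectation 10/|E|, while a frozen random model stays
within 3 binomial σ of that expectation. The suite is structural, not
statistical: identifiers are fabricated, size distributions are not mimicked
from any real source, and passing tests demonstrate correctness of the
machinery and learnability of planted structure — not biological validity or
the metric values attainable on real integrated sources.

## 8. Problem sizes

Tests and the acceptance script run the default fixture (~620 graph nodes,
~2,700 triples), the 5-split ComplEx protocol at d = 32 / 50 epochs, and all
six families at the reduced scale d = 16 / 10 epochs — sizes chosen so the
whole validation cycle completes in about a minute on one CPU while leaving
every measured property far from its decision boundary.

## 9. Known limitations

* No retro-merging of mapping-table rows (bridging is logged only), no
  probabilistic or string-similarity record linkage.
* No OWL semantics or reasoner integration; consistency means schema
  validation.
* The wrapper dialects are the package's own; real dumps would need a
  reader-spec mapping onto the same row shapes.
* No GPU path and no hyperparameter search driver; hyperparameters are
  explicit configuration.
* Metric values on the synthetic fixture are not comparable to values
  reported for any full-scale integrated graph.
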