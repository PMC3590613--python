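# Methods

## Data model

A clinical case table is a list of rows (disease `C`, syndrome `Q`,
symptom list `S`). Symptom labels are normalised by trimming,
case-folding and whitespace collapse only — no stemming, tokenisation or
translation — because every downstream comparison is textual
(letter-by-letter LCS), and a heavier normalisation would silently change
what "exact match" means. Duplicate rows are kept as separate cases:
repeated observations are additional support for the intersection.

## Library extraction

For each syndrome (and, independently, each disease) the k contributing
symptom sets are reduced to the elements present in at least
`t = min(k, max(t_min, ceil(alpha * k)))` of them.

* `alpha` (default 1.0): the fraction of cases a symptom must appear in.
  The default demands full intersection — the behaviour of the classic
  two-row worked example — and relies on the relaxation below for noisy
  groups. For noisy data `alpha ≈ 0.6` is the setting used throughout the
  synthetic study.
* `t_min` (default 1): floor on t, useful to stop tiny groups from
  degenerating to unions.
* `fallback_relax` (default on): if the thresholded intersection is
  empty, decrement t until it is not (or t = 1). This keeps every library
  entry non-empty, at the cost of admitting lower-support symptoms for
  heterogeneous groups.

Diseases and syndromes are extracted as two separate groupings (the
disease–symptom and syndrome–symptom relations), never jointly keyed.

The sorted-sequence path implements the adaptive intersection: a
candidate element is located in each set in turn by galloping (doubling
then binary) search; an overshoot becomes the new candidate. When every
input is shorter than a cutoff (default 16) the doubling search is
skipped for a linear merge — on tiny sets the galloping bookkeeping costs
more than it saves. The counting formulation (`threshold_intersect`) is
the reference the adaptive path is tested against; extraction itself uses
counting, which is exact for all t, while the adaptive routine covers the
t = k case where sorted inputs are available.

All returned sets are sorted lexicographically so outputs are
deterministic and diffable.

## Ontology

Three relations over syndrome classes:

* equivalence — unordered name pairs; closed
  reflexively/symmetrically/transitively at query time;
* inheritance — (child, parent) subclass edges forming a DAG (cycles are
  rejected at construction);
* subsume — (whole, part) edges; a compound syndrome captures the union
  of its parts' symptoms, recursively (a part may itself be compound;
  cycles are detected during traversal).

The *effective* symptom set of a name is the union of (a) the library
symptoms of every equivalent name, (b) the library symptoms of every
ancestor, and (c) the effective sets of every subsumed part. By default
equivalence contributes symptoms only — subclass/subsume edges of
equivalent names are not followed, since axiom propagation across
equivalence is a modelling choice, exposed as `merge_equivalents`.

RDF/XML is read with rdflib and reduced to these idioms: named
`owl:Class` declarations, `owl:equivalentClass` between named classes,
`rdfs:subClassOf` between named classes, and `owl:equivalentClass` to an
`owl:Restriction` whose `owl:onProperty` has local name `subsume` (any
namespace — published files vary) with `owl:someValuesFrom` a named
class. Restrictions on other properties are skipped with a warning. Class
names with spaces are tolerated (they occur in published files even
though they make invalid IRIs). Axiom statistics count named classes and
raw axioms as parsed, not closures or anonymous restriction classes. The
TSV triple dialect (`subject  predicate  object` with predicates
`equivalent`, `is_a`, `subsume`, plus `class` declarations for isolated
classes) round-trips all four axiom sets exactly and keeps fixtures free
of any RDF tooling.

No further OWL-DL reasoning (property chains, cardinality, disjointness)
is attempted; the three relations above are the ones the refinement
strategies consume.

## Similarity

`weight(a, b) = |lcs(a, b)| / max(|a|, |b|)` on the characters of the
normalised labels, spaces included. `sim(input, list)` pairs each input
word with its best list match (ties to the earliest list position) and
multiplies the weight sum by the exact-match count, divided by the
candidate list's size. Consequences of taking the formula literally:

* `sim` is not normalised — it equals m for a perfect match against an
  m-symptom entry. It is a ranking value only.
* Without any exact word match `sim = 0` regardless of partial weights.
  An additive-smoothing mode (`smoothing > 0` replaces the multiplier by
  `exact_count + smoothing`) is available and off by default.
* The divisor is the *candidate* entry's size, per the reading that the
  list being sized is the library entry; the alternative (input size)
  would only rescale scores per query and not change per-query ranking
  order, but would change cross-entry ranking, since the chosen divisor
  penalises long entries.

## Refinement

The crisp relation between input set S and top-candidate set T (exact
label equality; fuzzy weights decide ranking, not set algebra) selects
the strategy: equal → add equivalents; S ⊃ T → add subsuming compounds;
S ⊂ T → add superclasses; partial overlap (Jaccard ≥ `overlap_threshold`,
default 0.3 — a choice, no canonical value exists) → greedy
decomposition; disjoint → keep the candidate with a warning. All refined
candidates are re-scored against their effective symptom sets, which is
what lets a compound overtake its parts when the input covers the parts'
union. An optional fuzzy-membership mode for the set relations
(weight ≥ 0.8 counts as membership) was considered and rejected for the
default: crisp set algebra keeps the strategy selection auditable.

Decomposition greedily covers the input: rank all syndromes against the
unmatched remainder, keep the best (must score strictly above
`min_score`, default 0), remove the symptoms its effective set explains,
repeat until the remainder is exhausted, nothing qualifies, or
`max_components` (default 4) is reached. Greedy rather than exhaustive
cover: the remainder shrinks strictly each round, so termination is
structural, and exhaustive set cover would be exponential for no
demonstrated benefit on ranked libraries.

Only the top-ranked syndrome is refined by default (`refine_top_n`);
disease ranking is independent of syndrome refinement and is not re-run
afterwards.

## Synthetic data

The generator emulates a curated case database's structure: each
syndrome has a planted signature (default 6 symptoms drawn from a
300-token vocabulary for 30 syndromes — roughly 10 vocabulary symptoms
per syndrome, the same order as real databases' symptom-per-syndrome
ratios); each case keeps the signature minus independent drops
(`p_drop`, default 0.05, at least one symptom always kept) plus
Poisson-distributed noise symptoms (mean 3), with lengths clamped to
1–32, the range seen in real case databases. Ontology axioms are planted
on top: equivalence aliases (`p_equiv`), subclass chains whose child
signatures extend the parent's (`subclass_depth`), and compound
syndromes whose signature is the union of two parts (`p_subsume`). A
single integer seed fully determines truth and cases.

What this does *not* emulate: correlated symptom co-occurrence,
vocabulary misspellings in the case table itself (near-duplicate labels
are exercised by dedicated string fixtures in the tests), multi-syndrome
patients (one (C, Q) pair per row), and realistic TCM term text. Passing
recovery tests therefore show that extraction undoes independent
drop/add noise at the stated rates — not that it handles systematically
biased recording.

Recovery is measured as the fraction of syndromes whose extracted entry
equals the planted signature exactly, plus the mean Jaccard overlap. At
the study conditions (30 syndromes, 20 cases each, p_drop 0.05, mean 3
noise symptoms, alpha 0.6) a signature symptom survives in ≈19 of 20
cases while a given noise symptom recurs far below the t = 12 threshold,
so recovery is expected to be essentially perfect; the acceptance run
confirms ≥ 90% exact recovery per seed.

## Problem sizes and numerical notes

The randomized checks use 200 intersection instances (k ≤ 20 sets over a
50-symbol alphabet, all t), 500 LCS pairs of length ≤ 8 against
exhaustive subsequence enumeration, and three seeds × 30 syndromes × 20
cases for recovery — sizes at which the brute-force oracles are exact and
the whole suite runs in seconds. Score ties are broken by exact-match
count, then lexicographic name, so every ranking is deterministic.
Degenerate inputs fail loudly: empty queries, empty symptom sets, t out
of [1, k], unsorted input to the adaptive routine and cyclic class graphs
all raise.

## Known limitations

* The exact-match gate in the similarity makes the system blind to
  queries phrased entirely in unseen words; smoothing mode mitigates but
  changes the formula.
* Refinement trusts the ontology: a wrong subsume axiom will promote a
  wrong compound. There is no probabilistic weighting of axioms.
* Thresholds (`alpha`, `overlap_threshold`) are fixed, not learned.
* The extraction certifies only symptom membership frequencies; it does
  not model symptom intensity ("slight pain" vs "pain"), which is a
  separate fuzzy-logic problem deliberately out of scope.
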