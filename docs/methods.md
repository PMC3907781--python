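# Methods

This note records the model, the numerical conventions, and the design
choices made where the method's description left the design open.

## Data model and coordinates

The data space S is an ordered set of sequences over a finite alphabet Σ
(20 amino acids or 26 Latin letters).  All coordinates are 1-based and
inclusive; occurrence windows are `(sequence index, start, end)` triples.
Input is upper-cased on read; out-of-alphabet characters are rejected by
default.  A permissive mode keeps them in place as inert positions — they
preserve coordinates but no enumerated window may contain them.  Repeated
identical sequences are kept: they are distinct members of the data space
and legitimately inflate occurrence counts.

The window count N(n) = Σ_k max(0, |s^k| − n + 1) is the exact number of
Bernoulli trials of the i.i.d. occurrence model, and is the default
normalizer for expectations.  A `count_mode="total"` switch substitutes
the total residue count Σ_k |s^k| for comparison with the looser
convention.

## Pattern discovery

Enumeration is a length-stratified census: support is anti-monotone in
length, so enumeration stops at the first length with no substring
reaching the occurrence floor.  Overlapping occurrences within one
sequence all count; occurrence lists are exact window sets.

The background model is order-0 uniform, Pr(σ) = 1/|Σ|.  An empirical
per-symbol background (frequencies estimated from S) is available but off
by default: the uniform null is the model the scores are defined against,
and the empirical variant exists for sensitivity checks only.

Significance is the standard residual (o − e₀)/√e₀ with a default
acceptance threshold of 3.0 (a conventional ~3σ cut).  The √e denominator
is the standard-residual convention; a `residual_denominator="plain"`
switch preserves the alternative (o − e)/e reading.

Redundancy pruning has two stages:

* **Delta-closure** drops p when a strict super-string q in the
  significant set has occ(q) ≥ δ·occ(p).  The comparison is against a
  single super-pattern, not the union of several — the union reading
  degenerates once rare long extensions are admitted, because any single
  occurrence of a long string is "significant" under the uniform null.
* **Conditional redundancy** ("non-induced") drops p when its count is
  explained by the most explanatory *related* survivor q at the
  background rate.  For a sub-pattern q ⊂ p, each q occurrence extends to
  p by chance: e_cond = occ(q)·(1/|Σ|)^(|p|−|q|).  For a super-pattern
  q ⊃ p, every q occurrence forces a p occurrence and the remaining
  windows produce p at chance: e_cond = occ(q) + (N(|p|) − occ(q))·(1/|Σ|)^|p|.
  p is dropped when (o − e_cond)/√e_cond falls below the significance
  threshold.

The super-pattern direction is deliberate and matters in practice: a
short pattern can escape delta-closure because one stray background
occurrence pushes its count just past the δ ratio (in the packaged
ten-sequence example, the background happens to spell a sixth `ELLOW`
immediately after one `HELLO`), yet its excess over the forced count is
statistically nil.  Testing that excess against chance removes exactly
these fragments while leaving genuinely independent patterns untouched,
and is what makes the worked example resolve to its two planted words.

Output order is total: descending score, ties broken lexicographically by
pattern string.

## Clustering

Clusters are merged by single-linkage agglomeration over whole-cluster
similarity (the current clusters are compared, not the original pattern
pairs).  Cluster comparison is a global column alignment:

* match score = profile agreement Σ_σ Pr₁(c_i = σ)·Pr₂(c_j = σ), with
  residue probabilities count/m — gap and wildcard cells dilute the
  profile but contribute zero to agreement (they match nothing for
  scoring, though a wildcard matches everything for occurrence
  semantics);
* interior gap penalty −0.5 per column, end gaps free (realized as `*`
  padding).  Free end gaps are what produce the flanking-wildcard layout;
  the mild interior penalty concentrates unavoidable gaps into single
  columns rather than scattering them.  The dynamic program's traceback
  tie-break is fixed (diagonal, up, left) so alignments are
  deterministic.

The similarity reported to the clustering loop is a normalized Hamming
agreement over the aligned overlap: the fraction of aligned column pairs,
both holding residues, whose **majority-residue sets intersect**.  Using
majority *sets* rather than a single tie-broken consensus keeps the
measure symmetric and independent of member order; with any fixed
tie-break (alphabetical or first-row), the count of matching columns
changes with merge history, and the six-word worked example then fails
its final merge.  Intersection also makes self-similarity exactly 1.

A candidate merge must pass two heuristics before it competes: at least
`min_overlap_matches` exactly matching columns (default 3) and a mean
per-aligned-column profile agreement of at least `column_distribution_min`.
Defaults (termination 0.8, distribution 0.8) mirror a large-family run;
the small worked examples relax both scores to 0.3.  The termination
condition applies to the similarity, not the raw alignment objective.

Merging re-expresses every member row in the merged column system; per
row, positions outside its own residue span become `*` and interior
non-residues become `-`, which preserves the invariant that stripping
both symbols reproduces the source pattern.  Ties in merge order are
broken by the lexicographically smallest pair of first rows.  No
post-merge realignment is performed; merging is strictly progressive.

## Measures

Entropies are normalized by taking logarithms in base |Σ| for the run, so
an equiprobable column over the alphabet scores exactly 1; member-row
profiles may contain the two structural symbols on top of Σ, so the
normalized entropy is clipped at 1 to keep Q and R1 inside [0, 1].

Quality uses member-row profiles with `-` and `*` counted as observed
symbols (they carry alignment information); redundancy uses induced-data
profiles built from the deduplicated occurrence windows, which contain
residues only.  Coverage counts distinct sequences; the window count
|D(C)| is reported separately and never conflated with it.

The null column probability is Pr(c_j) = d/|Σ| for d distinct residues; a
wildcard in the column makes Pr = 1 (it matches anything), and a gap adds
one matching slot to d, capped at 1 — the method's description gives no
rule for gapped columns, and this choice keeps the expectation finite and
monotone.  The expectation multiplies over residue-bearing columns, with
the window length taken as their count (pure-`*` flanks are presentation
padding; merge normalization in fact removes any such column).

A redundancy value is reported as absent (None) for a column that no
induced window reaches — possible only when the sole residue-bearing
members of that column have empty occurrence lists.

## Synthetic data generator

`generate_embedded` emulates the worked construction: i.i.d. uniform
background letters with words planted at uniformly chosen,
mutually non-overlapping positions.  Defaults are the study conditions of
the illustrative setup — six words embedded five times each across thirty
sequences of length 20–31 (the packaged ten-sequence example spans lengths
17–31; the floor of 20 guarantees room for the longest word anywhere).
Every placement is recorded in a ledger and verified by substring
equality at generation time; output is byte-reproducible per seed.

The generator deliberately does **not** model realistic protein-family
evolution: no substitution matrices, no indels inside planted words, no
compositional bias.  Tests passing on its output therefore demonstrate
correct recovery under the method's own null model, not performance on
real families, where patterns vary across occurrences and discovery
difficulty is dominated by the substitution process.

## Problem sizes and determinism

The shipped examples and tests run at desk scale: tens of sequences,
hundreds of residues, pattern lists of at most a few dozen — sizes at
which the O(L²) census and O(k³) clustering loop are instantaneous and
every expected value in the tests can be recomputed by hand or by an
independent brute-force oracle.  All stages are deterministic for fixed
input and configuration (stable sorts, fixed tie-breaks, seeded
generator), which the byte-identity tests on the command-line pipeline
check directly.

## Known limitations

* The discovery filters are a concrete realization of "statistically
  significant and non-redundant"; the original four-condition test they
  stand in for is specified elsewhere and may differ in detail.
* The uniform null ignores residue composition; on biased families the
  standard residual inflates for patterns of common residues (the
  empirical background mitigates but is not the defined score).
* Single-linkage with heuristic gating can chain: two dissimilar patterns
  may share a cluster through intermediates.
* No p-value calibration is attached to the standard residual; it is a
  ranking score only.
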