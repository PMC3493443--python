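# Methods

This note records the models, conventions and design choices behind
`foxsurvey`, in the spirit of a methods appendix: what each stage
computes, which knobs matter, and what the synthetic benchmark does and
does not demonstrate.

## Pairwise alignment and search statistics

Local (Smith–Waterman) and global (Needleman–Wunsch) alignment use affine
gap penalties in which a gap of length *k* costs `gap_open + k·gap_extend`
— the opening charge and the first residue's extension are both applied.
The defaults mirror common protein-search practice: BLOSUM62 with gaps
11/1 for local search, and 10/1 for the global alignments behind identity
reports. The dynamic programming is delegated to Biopython's
`PairwiseAligner`; the test suite verifies both modes against an
exhaustive enumeration of alignment paths on short sequences, so the
delegation is checked, not assumed. Selenocysteine (U) is scored as
cysteine, the usual convention for matrices that predate it; X/B/Z use
their published BLOSUM62 rows.

Raw scores convert to bit scores via the Karlin–Altschul form
`S' = (λS − ln K)/ln 2` with λ = 0.267, K = 0.041 (the published gapped
BLOSUM62 11/1 constants), and E-values are `E = m·n·2^(−S')` with *m* the
query length and *n* the summed database length. The search filter keeps
hits with `E < 1e-2`, strict inequality. These statistics are the
small-database stand-in for a full heuristic search engine: there is no
word seeding or composition adjustment, so absolute E-values differ from
those a production search against a large database would print. The
pipeline only relies on the *filter behavior* (conserved-domain relatives
pass easily at desk scale; unrelated proteins do not), not on matching
any particular engine's E-values.

### Percent identity

The default denominator is **all alignment columns** of the global
domain-vs-domain alignment, gaps included; `ungapped` (both-residue
columns) and `shorter` (shorter ungapped sequence length) are available
because published identity figures rarely state their convention. The
identity report prints all three so the matching convention can be
recorded rather than guessed.

## Domain excision

The forkhead-like region of a candidate is the candidate-side span of the
optimal local alignment to a reference domain. Coverage is the aligned
fraction of the reference; hits under the 0.70 default are returned
flagged `partial` rather than dropped, because truncated gene models are
common and the longest available sequence is still informative. Exact
domain boundaries from alignment can differ from curated domain-database
boundaries by a few residues, which shifts downstream identity
percentages slightly; this is an inherent ambiguity, not a bug, and is
why the identity checks carry a ±2-point band. When a protein carries
tandem domains only the best-scoring one is excised.

## Progressive multiple alignment

The aligner exists to support distance estimation on a conserved domain,
not to compete with production MSA tools. A guide tree is built by
neighbor joining on pairwise global-alignment p-distances; profiles are
merged in postorder with profile–profile dynamic programming, scoring a
column pair as the arithmetic mean of residue-pair substitution scores
(gap–residue pairs excluded) and charging the same affine penalties at
profile level. Two sequences reduce exactly to the pairwise global
alignment. There is no iterative refinement, sequence weighting or
position-specific gap model; ties in the profile DP are broken
diagonal > up > left, and the result is deterministic for a fixed input
order. Content conservation (rows strip back to their inputs) and the
no-all-gap-column invariant are enforced by the `MultipleAlignment`
container itself.

## Distances, neighbor joining, bootstrap

Distances from an alignment use pairwise deletion by default (a column
counts for a pair only if neither row is gapped) because domain
alignments are short and complete deletion discards too much; a
`complete` rule is available. Models: p-distance and the Poisson
correction `−ln(1 − p)`, which errors on saturated pairs (p ≥ 1) instead
of fabricating a distance.

Neighbor joining is the standard Saitou–Nei agglomeration with the Q
criterion, terminated at three nodes with the closed-form star
resolution. Ties on Q are broken by the lexicographically smallest index
pair, making the topology deterministic; negative branch-length estimates
are clamped to zero with a logged warning (this alters lengths, never
topology). NJ is exact on additive matrices, and the suite verifies
recovery of the generating topology on random additive matrices as well
as agreement with an independent NJ implementation.

Bootstrap support resamples alignment columns with replacement, rebuilds
each replicate with NJ, and assigns each internal bipartition of the
point-estimate tree the percentage of replicates containing it
(bipartition matching against the point tree; no consensus tree is
formed). The default is 100 replicates from a mandatory seeded generator;
replicate counts and seeds are recorded in run metadata. Replicates in
which some pair loses all comparable columns are skipped with a warning
and excluded from the denominator.

## Clade query and decision rules

"Groups with the target subfamily" is operationalized as: some internal
edge separates the query together with at least one target-subfamily
reference from every reference of a different subfamily; among qualifying
edges the smallest such clade is taken and its bootstrap value reported.
This is one reasonable reading of a qualitative "grouped with" judgment
and is stated here explicitly because reasonable alternatives exist
(e.g. requiring monophyly with a single designated reference).

The reverse best hit assigns the subfamily of the best bit-scoring panel
entry, with the margin to the best entry of any other subfamily; margins
under 1 bit are called `ambiguous`, since sub-bit differences are noise.
The in-package reverse-hit database is the labeled reference panel rather
than a full non-redundant protein database — this preserves the logic
(best-subfamily assignment) at desk scale.

Decision rules, with the bootstrap threshold a parameter defaulting
to 95 (strict inequality): **definite** requires domain-phylogeny
grouping at support > 95. **candidate** requires at least one supporting
method among {reverse hit, domain phylogeny, full-length phylogeny};
single-method support is annotated as weak, and the report also tallies
the stricter ≥ 2-methods ("identifiable") rule separately, because
single-method evidence is treated inconsistently in practice — the
package exposes both tallies rather than choosing. Conflicting evidence
(reverse hit says one subfamily, phylogeny another) is recorded, never
auto-resolved. Raising the threshold can only shrink the definite set
(tested as a monotonicity property).

## Packaged evidence table

`data/foxj1_survey_evidence.tsv` encodes a published FoxJ1 survey's
evidence columns — 60 Fox-domain proteins across opisthokont proteomes,
with species paralogs as separate rows — as the loader's input schema.
Qualitative phylogeny cells map to flags: `FoxJ1`/`Foxj1` means grouped
with the target, `Sister to …`/`Unresolved` means not grouped, an empty
cell means the analysis was absent (full-length phylogeny was run only
for the fungal proteins). On this table the decision rules yield 60
identified proteins, 43 definite orthologs, 4 fungal species under the
two-of-three rule and 3 under the reverse-hit-and-domain-phylogeny rule.

## Synthetic family generator

The generator emulates the structure the survey assumes: a backbone tree
over subfamilies (default 5) with within-subfamily trees (default 8 taxa)
grafted onto its tips; random join topologies with exponential branch
lengths (means 0.15 backbone, 0.05 within, in substitutions/site units);
a root protein of flank (150) + domain (100) + flank (150) drawn from a
fixed background amino-acid composition; and evolution along the tree
under a 20-state equal-exchangeability Poisson model with the domain at
rate 1.0 and flanks at 2.5 substitutions/site/unit branch. Substitution
events arrive at `20r/19` per site and land uniformly on the 20 residues,
so expected identity at path length *t* is
`1/20 + (19/20)·exp(−20rt/19)` — the closed form the identity-decay
check uses. These defaults put within-subfamily domain identity around
0.8–0.9 and between-subfamily identity around 0.3–0.4, the range seen in
real forkhead-domain comparisons. Indels are off by default; when
enabled they apply to flanks only (geometric lengths, p = 0.5), keeping
recorded domain coordinates exact. Decoys are i.i.d. background-composition
proteins, 3 per proteome.

The on-disk fixture designates taxon 0 of each subfamily as the
"reference genome": its exact domain and full-length sequences form the
labeled panel. Recall/precision are scored against the generator's truth
labels, counting definite + candidate calls for the target subfamily.

**What passing the synthetic benchmark shows — and does not.** It shows
the stages compose correctly and the decision rules separate subfamilies
at realistic divergence under the generative model. It does not exercise
rate heterogeneity among sites, empirical substitution biases, domain
shuffling, alignment errors from indel-rich regions, fragmented gene
models, or contaminated proteomes — all present in real survey data.
Real-data bootstrap values and E-values also depend on database
composition and program versions and are not reproducible quantities;
the acceptance checks therefore target decision-logic counts and
model-level properties instead.

## Problem sizes and numerics

The standard end-to-end fixture is 5 subfamilies × 8 taxa with 3 decoys
per proteome and 100 bootstrap replicates, chosen to exercise every stage
at comfortably interactive runtime (seconds to tens of seconds on one
CPU). Exhaustive alignment-path oracles run at lengths ≤ 6 where full
enumeration is tractable; the local/global consistency property extends
the check to length 8 through the already-verified global aligner. All
randomness flows from explicit integer seeds through NumPy generators;
the survey pipeline derives every stochastic stage from one seeded
generator recorded in run metadata, so outputs are byte-stable across
reruns.

## Known limitations

- Search is exact Smith–Waterman without heuristics or composition-based
  statistics: fine at panel/proteome-file scale, not for whole-database
  scans, and E-values are not comparable to a production engine's.
- The MSA is a minimal progressive aligner; deep or indel-rich families
  deserve a dedicated tool, after which the downstream stages can consume
  the imported alignment directly.
- Trees are distance-based NJ only; no likelihood or Bayesian inference.
- The clade query assumes the panel labels are correct and complete; a
  mislabeled panel entry propagates into both reverse-hit and phylogeny
  evidence.
- Nucleotide input (six-frame translated search) is out of scope;
  proteins only.
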