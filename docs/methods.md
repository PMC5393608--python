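# Methods

`barcodekit` evaluates how well a panel of DNA barcodes (typically rbcL,
matK, trnH–psbA, ITS2 and ITS for plants) discriminates species and genera
in a multi-individual survey, and uses the same machinery to flag specimens
whose a priori identification their sequences contradict.  This note
documents the models, criteria, numerical choices and their limits.

## Evaluation criteria

**Tree-based (supported monophyly).**  For each marker set a
neighbour-joining tree is built from pairwise genetic distances and
bootstrapped by resampling alignment columns.  A taxon (species or genus)
succeeds when all of its individuals form a single clade — an unrooted
bipartition separating exactly those leaves from the rest — whose edge
support is *strictly greater* than the threshold (default 50).  Taxa with a
single individual in the tree cannot be tested for monophyly and are always
excluded from tree-based rates; the tree-based cohort is therefore n ≥ 2 by
construction.  In an unrooted tree a bipartition has two sides, so with only
two taxa each is the other's complement and both succeed or fail together;
this is a property of the criterion, not an implementation choice.

**Similarity-based (exclusive top hit).**  Every sequence is queried against
a local database of all the others.  A taxon succeeds when *every* one of
its individuals has an entire top-scoring hit set that is conspecific
(species level) or congeneric (genus level) — a tie between a conspecific
and a heterospecific hit fails the species criterion.  The query itself is
excluded from its hit list only when its species has two or more individuals
with data for the marker set; a singleton keeps its self-hit and succeeds
vacuously at species level.  Whether such vacuous successes belong in the
n ≥ 1 cohort is genuinely ambiguous; the `include_vacuous_singletons` switch
(default `True`, matching the self-hit retention rule) makes the choice
explicit.  At genus level any congeneric hit counts, including conspecific
ones.

**Cohorts.**  `n1` evaluates every taxon with data for the marker set; `n2`
restricts to taxa with at least two such individuals.  Dropped taxa are
logged, never silently discarded, because the cohort denominators are part
of the result.

## Distances and trees

Distances use pairwise deletion: a column contributes to a pair only when
both sequences have a determinate base (gaps, `N` and `?` are skipped).
Available models: uncorrected *p*, Jukes–Cantor, and Kimura two-parameter
(default — the convention in the barcoding literature when the original
software's setting is unknown).  A pair is undefined when no column is
comparable or the model's logarithm leaves its domain; the default policy
imputes such entries with the largest defined distance plus ε = 10⁻³ and
flags them, which keeps NJ runnable on sparse supermatrices while leaving an
audit trail.

Neighbour joining is the Saitou–Nei agglomeration with the standard
Q-criterion and branch-length formulas.  Negative estimated branch lengths
are clamped to zero (no length transfer; lengths play no role in the
success criteria).  Q-ties are broken by the lexicographically smallest
pair of cluster keys, a cluster's key being its smallest leaf id, so the
construction is fully deterministic.  Correctness is checked against (a)
exact recovery of topology and path lengths on random additive matrices and
(b) an exhaustive least-squares topology search for n ≤ 6, both in the test
suite and in the validation script.

Bootstrap: the reference tree is built from the full alignment; each of
`replicates` (default 1000; tests and the validation script use 100, which
saturates on the synthetic signal) replicates resamples columns with
replacement using a single seeded RNG, rebuilds NJ, and contributes its
bipartitions.  Support is the rounded percentage of replicates containing
the reference bipartition.  Supports are invariant to the order sequences
are listed in, given the same seed.

Performance: distance matrices are computed from bit-packed two-bit codes
with SWAR popcounts, and the NJ join sequence runs as a compiled kernel, so
a 100-replicate bootstrap of 120 sequences × 1.4 kb takes ~0.25 s on one
core.

## Similarity scores

Hits are ranked by a blastn-like local alignment score (match +1, mismatch
−2, gap open and extend −2.5) of gap-stripped sequences; E-values and word
seeding are not modelled because only the ranking matters.  For a
multi-locus marker set, per-locus scores are summed over the loci both
specimens carry; specimens sharing no locus are unrankable for that pair.
The kernel is a score-only Gotoh dynamic program with an optional band
(default half-width 50 columns around the length-adjusted diagonal).  The
banded score is a lower bound on the full score and equals it whenever the
optimal path stays within the band — which holds for near-full-length
homologous barcode sequences whose indels span a few dozen columns at most;
the tests verify exact agreement with an independent full-DP implementation
on both simulated and random sequences.  Set `band=None` for arbitrarily
divergent input.

## Supermatrices and indel coding

Concatenation lays loci left to right in input order, records each locus's
half-open column interval, and fills a missing specimen × locus block with
`?`.  Per-partition extraction inverts concatenation exactly.

Simple indel coding turns each distinct *internal* gap span (identical
start and end columns) into one binary character: `1` for sequences bearing
exactly that gap, `0` for sequences with residues across the span, `?` when
the sequence's own gap strictly contains or partially overlaps the span, or
when the span touches the sequence's terminal missing region.  Terminal
gaps model sequencing-recovery failure and ragged ends, not indel events,
and are never coded.  The indel block is export-only: it never enters the
distance computation.

## Misidentification flagging

For each marker set (default: rbcL alone, matK alone, and the all-locus
combination) the workflow cross-checks tree placement against similarity
hits.  A specimen violates conspecificity when all three hold:

1. its labelled species fails supported monophyly on that marker set's
   bootstrapped NJ tree;
2. its local neighbourhood — the smallest supported clade containing it and
   at least two other leaves — contains *no* leaf sharing its label;
3. all of its top similarity hits are heterospecific.

Condition 2 is deliberately conservative.  A looser "majority of the local
clade is another species" rule misfires when a specimen's conspecific
sibling has itself been mislabelled: the sibling's sequences still cluster
with the specimen and break monophyly, and a tie-break can then vote for
the sibling's wrong label.  Requiring zero labelled conspecifics in the
neighbourhood leaves such cases to the morphological audit.

A flag is emitted when at least `quorum` marker sets (default 2 of 3) agree.
The proposed species is the majority label among the specimen's neighbours
across agreeing marker sets, recomputed with other flagged specimens'
(suspect) labels excluded — the molecular half of reciprocal illumination;
remaining ties go to the species with the highest-scoring supporting hit.
The confirmation step is by definition herbarium work, so the output is an
audit report (original label, proposed label, per-marker-set evidence),
never an automatic relabelling.  Specimens with data for fewer marker sets
than the quorum are reported as "insufficient data"; sub-quorum violations
are logged.

## Synthetic data generator

The generator emulates the statistical structure such surveys present:

* **Taxonomy scaffold** — configurable genera × species × individuals;
  the `paper_like` preset has 12 genera, 133 species and 409 individuals
  with 22 singleton species and 2–9 (mean ≈ 3.5) individuals otherwise,
  interleaved across genera.  Random per-species counts use a truncated
  geometric on 1–9 with ratio 0.72 (mean ≈ 3).
* **Sequences** — a root sequence evolves down genus → species → individual
  branches under Kimura's two-parameter model with transition/transversion
  ratio 2 and uniform rates across sites.  Branch lengths are chosen so the
  configured divergences are expected *pairwise* distances: individual
  branches intra/2, species stems (inter − intra)/2, genus stems
  inter·(multiplier − 1)/2.  Per-locus rate multipliers reproduce the usual
  plant-barcode ordering (rbcL least variable … ITS most variable).
* **Indels** — Poisson-many deletion events per species clade, spans of 1–5
  columns shared by a random subset of the clade, so indel coding sees
  realistic shared gaps.  Alignment columns are preserved (deletions only).
* **Missingness** — each specimen × locus is dropped independently with the
  locus's missingness probability; `paper_like` uses drop rates of 0.075,
  0.075, 0.216, 0.447 and 0.609 so realized recovery matches the published
  92.5 / 92.5 / 78.4 / 55.3 / 39.1 % individual rates.
* **Label swaps** — each specimen's recorded species is replaced, with
  probability `swap_rate`, by a uniformly drawn other species; the truth
  registry stores every (specimen, true, assigned) triple as the oracle for
  the flagging workflow.

Presets: `strong_gap` (intra 0.002, inter 0.05, 10 genera × 4 species × 3
individuals, rbcL + matK at their published aligned lengths 665 and 746) is
the perfect-barcode-gap limit in which both methods must discriminate
everything; `weak_gap` (intra 0.01, inter 0.015, same shape) makes intra-
and inter-specific distances overlap; `paper_like` is described above, with
inter 0.02 / intra 0.004 / genus multiplier 3 as plausible magnitudes —
no intra/inter divergence statistics are published for the motivating
survey, so these are validated only by the qualitative locus ordering, not
by matching printed discrimination rates.

What the generator does **not** model: intraspecific genealogy (individuals
are a star), site-rate heterogeneity, alignment error, ITS paralogy and
secondary-structure artefacts, or base-composition bias.  Passing the
perfect-gap and swap-recovery checks therefore demonstrates that the
*pipeline logic* is correct in regimes where the answer is knowable, not
that real sequence data will reach any particular discrimination rate.

## Validation script and problem sizes

`scripts/acceptance.py` recomputes, from scratch: the printed recovery-rate
arithmetic (percentage = 100·s/t rounded half-up to one decimal, e.g.
381/412 → 92.5) and the 1474-sequence bookkeeping sum; NJ topology/path
recovery on 200 random additive matrices (n ≤ 8; least-squares oracle for
n ≤ 6); monophyly-criterion agreement with bipartition enumeration on 500
random supported trees (n ≤ 10); the perfect-gap limit (5 seeds); the
planted-swap recovery precision/recall and proposal accuracy (5 seeds, swap
rate 0.05); the weak-below-strong ordering on 10 paired seeds (mean of the
two methods' species rates per run); and the `paper_like` ITS recovery
emulation (50 seeds).  These sizes keep a full run around four minutes on
one core while leaving each stochastic check far from its decision
boundary.
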