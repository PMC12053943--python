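# Methods

`glutenscan` implements the post-identification half of a discovery
proteomics workflow for gluten-containing cereals.  It consumes peptide
identification tables (sequence, score, raw abundance per run) together
with protein/motif/allergen databases, and produces curated
identifications, motif quantitation, homology calls and multivariate
profiles.  This note records the models, the defaults and why, what the
synthetic generator does and does not emulate, and the numerical
choices.

## Digestion model

Chymotrypsin specificity is encoded as: cleave after Y, F, W or L
unless the next residue is P.  Coordinates are 0-based; site *i* means
the bond after `sequence[i]` is cut, and the C-terminus is never a
site.  The digest with `max_missed = k` (default 2) is the set of
concatenations of ≤ *k* + 1 adjacent fully-cleaved fragments; when the
same peptide string arises at several positions the minimum
missed-cleavage count is kept.  There is no default length filter
(`min_len = 1`); the synthetic generator separately applies a
detectability floor of 6 residues, reflecting what search engines
actually report.  Sequence ends are the only valid peptide boundaries
besides sites — no N-terminal methionine clipping or semi-specific
cleavage.  I and L are distinct residues by default (`equate_il`
folds them together for matching, off because search-engine output is
already sequence-level).

## Curation rules

Modified peptide forms are collapsed onto their stripped sequence
before any filter (per-run abundances summed, score = max), because
quantitation is at the sequence level.  Retention is decided per
(sample, peptide):

* **score rule** — best score within the sample ≥ `min_score`
  (default 5; a score of exactly 5 is retained);
* **replicate rule** — within *every* biological replicate where the
  peptide occurs, it must appear in ≥ `min_tech_reps` (default 2)
  technical replicates.  The phrase "only one technical replicate of
  each biological replicate" admits a weaker reading; the alternative
  (`replicate_rule="any_biorep"`: one qualifying biological replicate
  suffices) is provided, with the strict reading as the default.

The protein score is a declared surrogate (commercial engines keep
theirs proprietary): the sum over distinct retained peptides of the
peptide's maximum score across runs.  It preserves the only property
grouping needs — more and better-supported peptides score higher.

## Protein grouping

Parsimony grouping on retained-peptide sets: identical sets merge;
a set that is a strict subset of another is absorbed into that group;
the lead accession maximizes the protein score with lexicographic
tie-break.  When a subset protein fits under several incomparable
maximal sets it is assigned to the group with the highest-scoring
member (then lexicographically smallest member accession), which makes
the partition independent of input order.  Unique peptides are
computed against all other groups' peptide sets.  Groups supported by
a single peptide are flagged `single_peptide_id` in outputs — the
stand-in for manual chromatogram review, which is impossible
downstream of peptide tables.

## Spike-in normalization

For run *r* with spike abundance *s*ᵣ and reference *S*, every
abundance in the run is multiplied by *S*/*s*ᵣ.  The default reference
is the median spike abundance across runs, so normalized values stay on
the raw-abundance scale; a fixed reference can be supplied instead.
Because all abundances in a run share the factor, between-sample ratios
are invariant to the reference choice.  Note that the median itself
depends on the ensemble of runs: global rescaling of one run leaves
within-run ratios exactly invariant, and leaves absolute normalized
values invariant whenever the median spike is unchanged (always true
when, as in the replicate designs used here, at least three runs share
the central spike value).  A missing or zero spike in any run is a
hard error naming the run.  Missing values propagate as missing — no
zero imputation before the multivariate stage.

## Motif quantitation

A peptide contains a celiac-toxic motif iff the motif is a contiguous
substring (total encompassment; equality counts).  Matching is on
unmodified stripped sequences; an optional `equate_eq` mode treats E as
matching Q for pipelines whose search engine reports deamidated
residues as E (off by default).  Overlapping or nested motifs each
receive the peptide's full normalized abundance — no apportioning,
because each motif's abundance is summed independently.  A peptide's
sample-level abundance is its mean normalized abundance over the runs
of the sample in which it was observed.  Heat-map preparation
auto-scales each motif row to a z-score (sample SD, n − 1) and
clusters rows and columns by Ward linkage on Euclidean distance
(average/complete available); constant rows are dropped with a
warning.

## Homology screening

Alignment is optimal pairwise alignment with affine gaps (Gotoh),
BLOSUM62, gap open 10 / extend 1 — FASTA-like defaults; no heuristic
acceleration.  Identity is matches / alignment columns, gap columns
included (a conservative denominator; matches / shorter-sequence-length
is available by config).  Because co-optimal alignments can differ in
identity, the traceback is canonical: endpoint with the best score and
smallest query then subject index; substitution preferred over a gap in
the query, over a gap in the subject; gap closure preferred over
extension.  This makes every reported identity a well-defined,
reproducible quantity.

Two screens per (allergen, candidate) pair:

* **full** — local alignment of the whole allergen; the default pass
  criterion is identity ≥ 50% and query coverage ≥ 50% (no published
  BLAST cutoff exists to adopt, so both are config keys and raw
  identity/coverage are always reported for re-thresholding);
* **window** — each 80-residue window of the allergen, step 1, aligned
  locally against the whole candidate; windows with identity strictly
  greater than 35% count as hits, one hit passes.  The allergen (not
  the candidate) is windowed.  Queries shorter than 80 residues are
  flagged `too_short_for_window`, not errored — they can only be
  screened by the full method.

Fragment-flagged (partial) candidate sequences are discarded before
either screen, so they can never surface as homologue calls.  Fragment
status is detected from FASTA headers (substring `Fragment`, the
UniProt convention; the marker list is configurable).

## Multivariate profiling

Order of operations: imputation (half the row's minimum positive value,
MetaboAnalyst-like; `zero` and `drop` available), then log₁₀(x +
pseudo) with pseudo = 1 when zeros are present (else 0), then Pareto
scaling — centre each feature and divide by the square root of its
standard deviation.  Transformation precedes scaling, following the
MetaboAnalyst convention.  PCA is a full SVD of the column-centred
sample × feature matrix; each component is oriented so its
largest-magnitude loading is positive, making scores and loadings
deterministic.  Explained-variance fractions are reported for every
component (they sum to 1) with the cumulative curve alongside.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of the emulated study: four
cereals, three biological replicates injected three times each;
Q/P-rich repetitive prolamin-like proteins with CD-active motifs
embedded at controlled copy numbers, flanked so chymotryptic sites
never split them (an adversarial `split_motif` mode places a motif
across a site to exercise the no-hit path); homologues generated by
point substitution to a target global identity ± 2 points; log-normal
protein abundances (median 10⁵, ln-σ 1), per-peptide detectability
(ln-σ 0.5), multiplicative biological and technical noise (CV 10%
each), 10% independent dropout, a per-run loading factor (ln-σ 0.3)
applied to everything including the spiked enolase peptide (base
5 × 10⁵), and peptide scores ~ Normal(8, 3) floored at 0.  All draws
are keyed to the seed; datasets are byte-identical across runs.

It does **not** simulate spectra, ion mobility, retention time,
co-elution interference, deamidation chemistry or search-engine FDR
behaviour.  Passing tests therefore demonstrate that the
*post-identification* analysis is correct and well-conditioned under
realistic noise — not that identification itself (outside this
package's scope) would succeed on real spectra.  Absolute
identification counts from the synthetic study are properties of the
generator's composition, not estimates of any real cereal's proteome.

## Problem sizes

The packaged synthetic study uses 6 proteins per cereal (half
prolamin-like, length ≈ 240) plus homologues, one fragment decoy and
two membership decoys — roughly 29 database entries, ~2,000 distinct
peptides and ~25,000 observations across 36 runs.  These sizes keep a
full pipeline run in seconds while exercising every code path
(shared/unique peptides, subset absorption, missing groups, flagged
queries); all statistics scale linearly in database size, and nothing
in the implementation assumes them.

## Known limitations

* The full-sequence screen is optimal alignment, not BLAST/FASTA: no
  E-values, and the pass criterion is a declared convention.
* The protein score is a surrogate; lead accessions can differ from
  engines with proprietary scoring, though group membership cannot.
* Deamidation-aware epitope matching is limited to the `equate_eq`
  toggle; no HLA-binding modelling.
* Absolute gluten content (mg/kg) is out of scope — quantitation is
  relative, anchored to the spike.
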