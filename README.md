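# glutenscan

Post-identification proteomics of gluten-containing cereals (wheat,
barley, rye, oats).  Starting from search-engine peptide identification
tables, `glutenscan` curates and groups identifications, quantifies
celiac-toxic motifs, screens for cross-reactive allergen homologues and
profiles whole proteomes — everything downstream of the mass
spectrometer, reproducibly and fully seeded.

## What it computes

**In-silico chymotryptic digestion.** Chymotrypsin cleaves C-terminally
of Y, F, W or L unless the next residue is P.  With up to *k* missed
cleavages the digest of a protein is every concatenation of at most
*k* + 1 adjacent fully-cleaved fragments.  Peptides are mapped back to
all parent proteins; a peptide is *unique* when it has exactly one
parent.

**Curation and protein grouping.** A peptide is retained only if its
best score in the sample is ≥ 5 and it is seen in ≥ 2 technical
replicates of every biological replicate in which it occurs.  Proteins
with identical retained-peptide sets merge; strict-subset proteins are
absorbed; each group is reported under a *lead accession* (highest
protein score, lexicographic tie-break).  A protein counts as
*identified* when its group has at least one unique peptide.

**Spike-in normalization.** Every run is rescaled to the spiked yeast
enolase peptide `DSRGNPTVEVELTTEKGVF`: for run *r* with spike abundance
*s*ᵣ and reference *S* (median across runs), abundances are multiplied
by *S*/*s*ᵣ.  Between-sample ratios are invariant to the choice of *S*.

**Celiac-toxic motifs (CTMs).** An identified peptide contains a T-cell
epitope when it *totally encompasses* a CD-active motif as a contiguous
substring.  Per motif and cereal, normalized abundances of all
encompassing peptides are summed; the motif × sample matrix is
auto-scaled (per-feature z-score) and clustered (Ward, Euclidean).

**Allergen homology.** Full-sequence optimal alignment
(Smith–Waterman, BLOSUM62, gap open 10 / extend 1) plus the Codex-style
sliding-window screen: every 80-mer of the allergen (step 1) is aligned
locally against the candidate and windows with identity > 35% are
counted.  Queries shorter than 80 residues are flagged; fragment
(partial) sequences are never called as homologues.

**Multivariate profiling.** Group abundances are log₁₀-transformed,
Pareto-scaled (centre, divide by √SD) and decomposed by PCA with a
deterministic sign convention; scores, loadings and explained-variance
fractions are reported.

A seeded synthetic-data generator produces Q/P-rich prolamin-like
proteins with embedded motifs at known copy numbers, homologues at
controlled identity, and replicate-structured observations (log-normal
abundance, 10% CV, 10% dropout, spiked enolase), so the whole pipeline
is testable with known ground truth.

## Worked example

Recovering a configured 4× between-cereal motif abundance difference
from noisy replicate data (`examples/quantify_motifs.py`):

```text
simulated 3483 peptide observations across 18 runs

motif CTM01 (QQPFPQQPQ) summed normalized abundance:
sample_id    cerealA    cerealB
motif_id
CTM01      7079865.0  1706511.0

recovered A:B ratio = 4.15 (configured: 4.0)
```

Two simulated cereals carry the same motif-bearing prolamin at a true
4× abundance ratio; after score/replicate filtering, enolase
normalization and motif-abundance summation the pipeline estimates
4.15 — the configured difference survives 10% technical noise and 10%
dropout.  The other scripts in `examples/` demonstrate digestion,
curation/grouping, homologue screening and the full pipeline run; each
prints a short interpretation of its output.

The command-line interface wraps the same functions:

```sh
glutenscan simulate --seed 1 --out study/
glutenscan run --config study/config.json
```

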