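"""Peptide curation and parsimony protein grouping on a tiny table.

Observations: three peptides across a 3 biological x 3 technical
replicate design.  One peptide fails the score filter (< 5), one is seen
in a single technical replicate only, one passes everything.  The two
proteins sharing the surviving peptide collapse into one group under a
lead accession.
"""

import pandas as pd

from glutenscan.curation import (
    ReplicateDesign,
    filter_observations,
    infer_groups,
    protein_scores_from_observations,
)
from glutenscan.digestion import PeptideProteinMap

design = ReplicateDesign(pd.DataFrame(
    {"sample_id": "wheat", "bio_rep": b, "tech_rep": t, "run_id": f"wheat_b{b}_t{t}"}
    for b in (1, 2, 3) for t in (1, 2, 3)
))

rows = []
for b in (1, 2, 3):
    for t in (1, 2):
        rows.append(("wheat_b%d_t%d" % (b, t), "QQPFPQQPQL", 11.0, 2.0e5))
        rows.append(("wheat_b%d_t%d" % (b, t), "PQQPYPQQL", 4.0, 1.0e5))
rows.append(("wheat_b1_t1", "SQQQPFPQL", 9.0, 5.0e4))
obs = pd.DataFrame(rows, columns=["run_id", "peptide", "score", "raw_abundance"])
obs["modifications"] = ""

retained, log = filter_observations(obs, design)
print("retained peptides:", sorted(retained["peptide"].unique()))
print("removals:")
print(log.to_string(index=False))

pp_map = PeptideProteinMap(parents={"QQPFPQQPQL": frozenset({"GLIA1", "GLIA2"})})
scores = protein_scores_from_observations(retained, pp_map.proteins_to_peptides())
groups = infer_groups(pp_map, scores)
for g in groups:
    print(f"\ngroup lead={g.lead_accession} members={sorted(g.members)} "
          f"unique_peptides={sorted(g.unique_peptides)} score={g.group_score}")
print("\nThe score rule removed the low-scoring peptide, the replicate rule "
      "the one-off observation; homologous gliadins share the surviving "
      "peptide and merge under one lead accession.")
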