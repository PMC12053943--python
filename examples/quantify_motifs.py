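"""Celiac-toxic-motif quantitation with spike-in normalization.

Simulates two cereals whose motif-bearing prolamin differs in abundance
by exactly 4x (3x3 replicates, 10% CV, 10% dropout), renormalizes every
run to the spiked yeast enolase peptide, sums the normalized abundance
of all peptides totally encompassing the motif, and compares the
recovered between-species ratio with the configured truth.
"""

from glutenscan.curation import filter_observations
from glutenscan.motifs import find_encompassing, motif_abundance
from glutenscan.quantify import normalize_to_spike
from glutenscan.synthetic import default_motifs, two_species_ratio_experiment

motif = default_motifs()[0]
obs, design, proteins, truth = two_species_ratio_experiment(seed=1, ratio=4.0)
print(f"simulated {len(obs)} peptide observations across {len(design.run_ids)} runs")

retained, removal_log = filter_observations(obs, design)
normalized = normalize_to_spike(retained)
pairs = find_encompassing(set(normalized["peptide"]), [motif])
matrix = motif_abundance(pairs, normalized, design)

print(f"\nmotif {motif.motif_id} ({motif.sequence}) summed normalized abundance:")
print(matrix.round(0).to_string())
est = matrix.loc[motif.motif_id, "cerealA"] / matrix.loc[motif.motif_id, "cerealB"]
print(f"\nrecovered A:B ratio = {est:.2f} (configured: {truth['configured_ratio']:.1f})")
print("Spike normalization removes per-run loading differences, so the "
      "summed motif signal tracks the true 4x difference despite noise "
      "and dropout.")
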