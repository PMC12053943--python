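"""Packaged synthetic study: a four-cereal dataset writer.

``write_synthetic_dataset`` materialises a complete, seeded input bundle
(per-species proteome FASTAs, an allergen FASTA, a CD-active motif
database, a reference-membership list, peptide observations with a 3x3
replicate design, ground truth, and a ready-to-run pipeline config) so
the full pipeline can be exercised end to end from files, exactly as it
would be on real search-engine output.

The default composition emulates the study design: wheat, barley, rye
and oats; wheat carries the most motif copies at the highest abundance
and oats carries none; barley/rye/oat homologues of a wheat-like
allergen at decreasing identity; one fragment-flagged subject and two
decoy accessions excluded from the reference membership list.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .curation import ReplicateDesign
from .seqio import MotifRecord, ProteinRecord, write_fasta
from .synthetic import (
    HomologueSpec,
    SpeciesSpec,
    SyntheticConfig,
    default_motifs,
    generate_globular,
    generate_prolamin,
    generate_proteomes,
    replace_record,
    simulate_id_table,
)

DEFAULT_SPECIES = ("wheat", "barley", "rye", "oats")


def default_synthetic_config(seed: int) -> SyntheticConfig:
    """Four cereals, 3x3 replicates, motif loads decreasing wheat > rye >
    barley > oats (none), wheat gluten at double abundance."""
    species = [
        SpeciesSpec(
            name="wheat",
            n_proteins=6,
            prolamin_fraction=0.5,
            motif_copies={"CTM01": 2, "CTM02": 2, "CTM03": 1},
            abundance_scale=2.0,
            homologues=(),
        ),
        SpeciesSpec(
            name="barley",
            n_proteins=6,
            prolamin_fraction=0.5,
            motif_copies={"CTM01": 1, "CTM04": 2},
            homologues=(HomologueSpec("ALG_WHEAT1", 75.0),),
        ),
        SpeciesSpec(
            name="rye",
            n_proteins=6,
            prolamin_fraction=0.5,
            motif_copies={"CTM01": 3, "CTM05": 1},
            homologues=(HomologueSpec("ALG_WHEAT1", 60.0),),
        ),
        SpeciesSpec(
            name="oats",
            n_proteins=6,
            prolamin_fraction=0.5,
            motif_copies={},
            homologues=(HomologueSpec("ALG_WHEAT1", 40.0),),
        ),
    ]
    return SyntheticConfig(seed=seed, species=species)


def build_allergens(seed: int) -> list[ProteinRecord]:
    """Two synthetic allergen queries: a windowable 160-mer and a
    79-residue fragment that only the full-sequence method can screen."""
    long_a, _ = generate_prolamin(
        seed + 101, length=160, accession="ALG_WHEAT1", species="allergen"
    )
    long_a = replace_record(long_a, tags={"allergen:ALG_WHEAT1"})
    short = generate_globular(seed + 202, length=79, accession="ALG_SHORT1", species="allergen")
    short = replace_record(
        short,
        description="synthetic short allergen (Fragment)",
        tags={"allergen:ALG_SHORT1"},
    )
    return [long_a, short]


def write_synthetic_dataset(
    seed: int,
    out_dir: str | Path,
    config: SyntheticConfig | None = None,
) -> dict:
    """Write a complete synthetic input bundle; returns the file map.

    The bundle contains ``proteins_<species>.fasta``, ``allergens.fasta``,
    ``motifs.csv``, ``membership.txt``, ``observations.csv``,
    ``design.csv``, ``ground_truth.json`` and ``config.json`` (a
    :class:`~glutenscan.pipeline.PipelineConfig` pointing at the rest).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or default_synthetic_config(seed)
    motifs = default_motifs()
    allergens = build_allergens(seed)

    proteins, truth = generate_proteomes(config, motifs=motifs, allergens=allergens)

    # a fragment-flagged near-copy of a wheat prolamin: high identity but
    # must never surface as a homologue call
    template = next(p for p in proteins if p.accession == "WHEAT_PROL1")
    fragment = replace_record(
        template,
        accession="WHEAT_FRAG1",
        description="synthetic partial sequence (Fragment)",
        sequence=template.sequence[: max(100, len(template.sequence) // 2)],
        is_fragment=True,
    )
    proteins.append(fragment)
    # decoys present in the search space but absent from the reference list
    decoys = [
        generate_globular(seed + 303, length=150, accession="DECOY_X1", species="wheat"),
        generate_globular(seed + 404, length=150, accession="DECOY_X2", species="rye"),
    ]
    proteins.extend(decoys)

    obs, design, sim_truth = simulate_id_table(
        config,
        proteins,
        motifs=motifs,
        motif_positions=truth["motif_positions"],
    )
    truth.update(sim_truth)

    files: dict[str, str] = {}
    species_names = [sp.name for sp in config.species]
    for name in species_names:
        path = out / f"proteins_{name}.fasta"
        write_fasta([p for p in proteins if p.species == name], path)
        files[f"proteome_{name}"] = str(path)
    write_fasta(allergens, out / "allergens.fasta")
    files["allergens"] = str(out / "allergens.fasta")

    with open(out / "motifs.csv", "w") as fh:
        fh.write("motif_id,sequence\n")
        for m in motifs:
            fh.write(f"{m.motif_id},{m.sequence}\n")
    files["motifs"] = str(out / "motifs.csv")

    allowed = sorted(
        p.accession for p in proteins if not p.accession.startswith("DECOY_")
    )
    (out / "membership.txt").write_text("\n".join(allowed) + "\n")
    files["membership"] = str(out / "membership.txt")

    obs.to_csv(out / "observations.csv", index=False)
    design.to_csv(out / "design.csv")
    files["observations"] = str(out / "observations.csv")
    files["design"] = str(out / "design.csv")

    truth_json = {
        "protein_abundance": truth["protein_abundance"],
        "motif_positions": truth["motif_positions"],
        "homologue_identity": truth["homologue_identity"],
        "motif_true_total": truth["motif_true_total"],
        "motif_expected_signal": truth["motif_expected_signal"],
        "run_scale": truth["run_scale"],
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1, sort_keys=True)
    files["ground_truth"] = str(out / "ground_truth.json")

    pipeline_cfg = {
        "proteome_fastas": {
            name: files[f"proteome_{name}"] for name in species_names
        },
        "allergen_fasta": files["allergens"],
        "motif_db": files["motifs"],
        "membership_list": files["membership"],
        "observations": files["observations"],
        "design": files["design"],
        "out_dir": str(out / "report"),
    }
    with open(out / "config.json", "w") as fh:
        json.dump(pipeline_cfg, fh, indent=1, sort_keys=True)
    files["config"] = str(out / "config.json")
    return files
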