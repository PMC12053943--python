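"""Synthetic cereal proteomes and peptide identification tables.

Everything needed to exercise the pipeline without any download: Q/P-rich
repetitive prolamin-like proteins with celiac-toxic motifs embedded at
controlled copy numbers, allergen homologues at controlled percent
identity, and replicate-structured peptide observations with log-normal
abundances, technical/biological noise, dropout, a spiked enolase
peptide and peptide scores.  All outputs are fully determined by the
seed, and every generated dataset carries its ground truth.

Default replicate design: three biological replicates, each injected
three times (nine runs per cereal); biological and technical CV 10%,
dropout 10%.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .curation import ReplicateDesign
from .digestion import DigestParams, digest, fragments
from .quantify import ENOLASE_SPIKE
from .seqio import MotifRecord, ProteinRecord

#: motif placement avoids creating cleavage sites from these residues
_SAFE_SUBSTITUTIONS = "QSTAGNHEVI"
_AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: built-in CD-active-like motifs: Q/P-rich, any cleavable residue
#: followed by proline, so chymotrypsin cannot cut inside them
DEFAULT_MOTIF_SEQUENCES = [
    "QQPFPQQPQ",
    "PQPQLPYPQ",
    "PFPQPQQPF",
    "QPQQPFPQQ",
    "QQPYPQQPQ",
    "PQQLPQPQQ",
]

#: adversarial motif with an internal unblocked Leu site (split by digestion)
SPLIT_MOTIF_SEQUENCE = "QQLQPFPQQ"


def default_motifs() -> list[MotifRecord]:
    return [
        MotifRecord(motif_id=f"CTM{i + 1:02d}", sequence=s)
        for i, s in enumerate(DEFAULT_MOTIF_SEQUENCES)
    ]


def _stable_rng(seed: int, *labels: str) -> np.random.Generator:
    streams = [seed % (2**31)] + [zlib.crc32(lab.encode()) for lab in labels]
    return np.random.default_rng(streams)


def generate_prolamin(
    seed: int,
    length: int = 240,
    repeat_unit: str = "QQPQQPF",
    motifs: Sequence[tuple[MotifRecord, int]] = (),
    accession: str = "SYN_PROL",
    species: str = "other",
    split_motif: bool = False,
    params: DigestParams = DigestParams(),
) -> tuple[ProteinRecord, list[tuple[str, int, int]]]:
    """Generate a prolamin-like repetitive protein with embedded motifs.

    The background is the repeat unit with random point substitutions
    that never create a new cleavage site; each motif is inserted the
    requested number of times at unit boundaries, flanked so no cleavage
    site falls inside it — guaranteeing a fully-cleaved peptide
    encompasses each copy.  ``split_motif=True`` skips that guarantee
    (for motifs that deliberately span a cleavage site).

    Returns the record and ground-truth ``(motif_id, start, end)``
    insertion positions (0-based, end exclusive).

    Raises
    ------
    ValueError
        If the motifs cannot fit in ``length`` residues, or a motif copy
        ends up split by a cleavage site (unless ``split_motif``).
    """
    rng = _stable_rng(seed, "prolamin", accession)
    motif_load = sum(len(m.sequence) * copies for m, copies in motifs)
    if motif_load > length:
        raise ValueError("motifs do not fit: total motif length exceeds protein length")

    n_units = max(1, (length - motif_load) // len(repeat_unit))
    units = []
    for _ in range(n_units):
        unit = list(repeat_unit)
        if rng.random() < 0.6:  # point substitution keeps proteins distinct
            pos = int(rng.integers(0, len(unit) - 1))  # never the cleavable terminus
            unit[pos] = _SAFE_SUBSTITUTIONS[int(rng.integers(0, len(_SAFE_SUBSTITUTIONS)))]
        units.append("".join(unit))

    insertions: list[tuple[str, ...]] = []
    for motif, copies in motifs:
        insertions.extend([(motif.motif_id, motif.sequence)] * copies)
    if len(insertions) > len(units):
        raise ValueError("more motif copies than available insertion slots")

    # spread the insertions over the unit boundaries
    blocks: list[tuple[str | None, str]] = [(None, u) for u in units]
    if insertions:
        slot_step = len(units) // len(insertions)
        for k, (motif_id, mseq) in enumerate(insertions):
            blocks.insert(k * (slot_step + 1) + 1, (motif_id, mseq))

    sequence = ""
    positions: list[tuple[str, int, int]] = []
    for motif_id, text in blocks:
        if motif_id is not None:
            positions.append((motif_id, len(sequence), len(sequence) + len(text)))
        sequence += text

    if not split_motif:
        frag_bounds = []
        start = 0
        for frag in fragments(sequence, params):
            frag_bounds.append((start, start + len(frag)))
            start += len(frag)
        for motif_id, s, e in positions:
            if not any(fs <= s and e <= fe for fs, fe in frag_bounds):
                raise ValueError(
                    f"motif {motif_id} at [{s},{e}) is split by a cleavage site"
                )

    record = ProteinRecord(
        accession=accession,
        description=f"synthetic prolamin seed={seed}",
        sequence=sequence,
        species=species,
        tags={"prolamin", "glupro"},
    )
    return record, positions


def generate_globular(
    seed: int,
    length: int = 200,
    accession: str = "SYN_GLOB",
    species: str = "other",
) -> ProteinRecord:
    """A random non-prolamin protein (uniform 20-residue composition)."""
    rng = _stable_rng(seed, "globular", accession)
    seq = "".join(_AA20[i] for i in rng.integers(0, 20, size=length))
    return ProteinRecord(
        accession=accession,
        description=f"synthetic globular seed={seed}",
        sequence=seq,
        species=species,
    )


def generate_homologue(
    seed: int,
    template: ProteinRecord,
    target_identity: float,
    accession: str | None = None,
    species: str = "other",
) -> tuple[ProteinRecord, float]:
    """Point-substitute a template to a target global percent identity.

    Substitutions hit distinct positions, so the achieved (ungapped)
    identity is ``(L - n_mut) / L``; it must land within +/-2 points of
    the target or a ValueError is raised (short templates make some
    targets unreachable).  Returns the record and achieved identity.
    """
    if not 0 < target_identity <= 100:
        raise ValueError("target identity must be in (0, 100]")
    L = len(template.sequence)
    n_mut = round(L * (1 - target_identity / 100.0))
    achieved = 100.0 * (L - n_mut) / L
    if abs(achieved - target_identity) > 2.0:
        raise ValueError(
            f"target identity {target_identity} unreachable within +/-2 points "
            f"for length {L}"
        )
    accession = accession or f"{template.accession}_hom{target_identity:g}"
    rng = _stable_rng(seed, "homologue", accession)
    seq = list(template.sequence)
    for pos in rng.choice(L, size=n_mut, replace=False):
        current = seq[pos]
        choices = [aa for aa in _AA20 if aa != current]
        seq[pos] = choices[int(rng.integers(0, len(choices)))]
    record = ProteinRecord(
        accession=accession,
        description=f"synthetic homologue of {template.accession} "
        f"at {achieved:.1f}% identity",
        sequence="".join(seq),
        species=species,
        tags={f"homologue:{template.accession}"},
    )
    return record, achieved


# --------------------------------------------------------------- datasets

@dataclass(frozen=True)
class ScoreModel:
    mean: float = 8.0
    sd: float = 3.0
    floor: float = 0.0


@dataclass(frozen=True)
class HomologueSpec:
    allergen_id: str
    target_identity: float


@dataclass
class SpeciesSpec:
    """One cereal's synthetic proteome composition."""

    name: str
    n_proteins: int = 8
    prolamin_fraction: float = 0.5
    motif_copies: Mapping[str, int] = field(default_factory=dict)
    homologues: Sequence[HomologueSpec] = ()
    abundance_scale: float = 1.0
    prolamin_length: int = 240


@dataclass
class SyntheticConfig:
    """Study conditions for the simulated experiment.

    Defaults mirror the replicate design of the emulated study (3
    biological x 3 technical replicates) with 10% biological and
    technical CV and 10% dropout; log-normal protein abundances around
    1e5 (ln-scale sigma 1), per-peptide detectability log-normal
    (sigma 0.5), spike base abundance 5e5 modulated by a per-run scale
    factor (log-normal, sigma 0.3) that multiplies every abundance in
    the run — what the spike normalization must undo.
    """

    seed: int = 0
    species: Sequence[SpeciesSpec] = ()
    n_bio: int = 3
    n_tech: int = 3
    tech_cv: float = 0.10
    bio_cv: float = 0.10
    dropout: float = 0.10
    abundance_median: float = 1e5
    abundance_sigma: float = 1.0
    detectability_sigma: float = 0.5
    spike_base: float = 5e5
    run_scale_sigma: float = 0.3
    score: ScoreModel = ScoreModel()
    min_peptide_len: int = 6
    digest_params: DigestParams = DigestParams()


def build_design(config: SyntheticConfig) -> ReplicateDesign:
    rows = [
        {
            "sample_id": sp.name,
            "bio_rep": b,
            "tech_rep": t,
            "run_id": f"{sp.name}_b{b}_t{t}",
        }
        for sp in config.species
        for b in range(1, config.n_bio + 1)
        for t in range(1, config.n_tech + 1)
    ]
    return ReplicateDesign(pd.DataFrame(rows))


def generate_proteomes(
    config: SyntheticConfig,
    motifs: Sequence[MotifRecord] | None = None,
    allergens: Sequence[ProteinRecord] = (),
) -> tuple[list[ProteinRecord], dict]:
    """Build every species' proteome per its spec.

    Per species: prolamin-like proteins (the first carries the
    configured motif copies), random globular proteins, and any
    configured allergen homologues.  Returns the records and ground
    truth (motif positions per accession, achieved homologue
    identities).
    """
    motifs = list(motifs) if motifs is not None else default_motifs()
    motif_by_id = {m.motif_id: m for m in motifs}
    allergen_by_id = {a.accession: a for a in allergens}
    proteins: list[ProteinRecord] = []
    truth: dict = {"motif_positions": {}, "homologue_identity": {}}
    for sp in config.species:
        n_prolamin = max(1, round(sp.n_proteins * sp.prolamin_fraction))
        n_glob = max(0, sp.n_proteins - n_prolamin)
        for k in range(n_prolamin):
            acc = f"{sp.name.upper()}_PROL{k + 1}"
            load = (
                [(motif_by_id[mid], c) for mid, c in sorted(sp.motif_copies.items())]
                if k == 0
                else []
            )
            rec, positions = generate_prolamin(
                config.seed,
                length=sp.prolamin_length,
                motifs=load,
                accession=acc,
                species=sp.name,
            )
            proteins.append(rec)
            if positions:
                truth["motif_positions"][acc] = positions
        for k in range(n_glob):
            acc = f"{sp.name.upper()}_GLOB{k + 1}"
            proteins.append(
                generate_globular(config.seed, accession=acc, species=sp.name)
            )
        for hs in sp.homologues:
            template = allergen_by_id[hs.allergen_id]
            acc = f"{sp.name.upper()}_HOM_{hs.allergen_id}"
            rec, achieved = generate_homologue(
                config.seed, template, hs.target_identity, accession=acc, species=sp.name
            )
            proteins.append(rec)
            truth["homologue_identity"][acc] = achieved
    return proteins, truth


def simulate_id_table(
    config: SyntheticConfig,
    proteins: Sequence[ProteinRecord],
    abundance_overrides: Mapping[str, float] | None = None,
    motifs: Sequence[MotifRecord] | None = None,
    motif_positions: Mapping[str, Sequence[tuple[str, int, int]]] | None = None,
) -> tuple[pd.DataFrame, ReplicateDesign, dict]:
    """Simulate a replicate-structured peptide identification table.

    Every protein is digested (chymotrypsin, two missed cleavages);
    peptides shorter than ``min_peptide_len`` are considered
    undetectable.  Per-run raw abundance of a peptide is::

        sum_parents(A_p * bio(p, rep)) * det(pep) * tech(pep, run) * run_scale

    with log-normal factors throughout; observations drop out
    independently per (peptide, run); the spike peptide is added to
    every run (never dropped) at ``spike_base * run_scale``; scores are
    normal draws truncated at the floor.

    Returns ``(observations, design, ground_truth)``.  The ground truth
    records true protein abundances, per-peptide expected signals, and
    per-species per-motif true totals (copies x protein abundance) plus
    expected observable signal (sum over encompassing peptides).
    """
    overrides = dict(abundance_overrides or {})
    design = build_design(config)
    rng = _stable_rng(config.seed, "id_table")

    species_of = {p.accession: p.species for p in proteins}
    ordered = sorted(proteins, key=lambda p: p.accession)

    abundance: dict[str, float] = {}
    for p in ordered:
        scale = next(sp.abundance_scale for sp in config.species if sp.name == p.species)
        if p.accession in overrides:
            abundance[p.accession] = overrides[p.accession] * scale
        else:
            abundance[p.accession] = (
                config.abundance_median
                * float(rng.lognormal(0.0, config.abundance_sigma))
                * scale
            )

    digests = {p.accession: digest(p.sequence, config.digest_params) for p in ordered}
    # per-species peptide -> parent accessions (peptides are observed per run,
    # i.e. per species; shared sequences across species stay independent draws)
    species_names = [sp.name for sp in config.species]
    pep_parents: dict[str, dict[str, list[str]]] = {s: {} for s in species_names}
    for p in ordered:
        for pep in digests[p.accession]:
            if len(pep) < config.min_peptide_len:
                continue
            pep_parents[p.species].setdefault(pep, []).append(p.accession)

    detect: dict[str, float] = {}
    all_peps = sorted({pep for d in pep_parents.values() for pep in d})
    for pep in all_peps:
        detect[pep] = float(
            _stable_rng(config.seed, "detect", pep).lognormal(0.0, config.detectability_sigma)
        )

    bio_factor: dict[tuple[str, int], float] = {}
    for p in ordered:
        for b in range(1, config.n_bio + 1):
            bio_factor[(p.accession, b)] = float(rng.lognormal(0.0, config.bio_cv))

    run_scale = {r: float(rng.lognormal(0.0, config.run_scale_sigma)) for r in design.run_ids}

    rows: list[dict] = []
    for sp_name in species_names:
        peps = sorted(pep_parents[sp_name])
        for b in range(1, config.n_bio + 1):
            for t in range(1, config.n_tech + 1):
                run = f"{sp_name}_b{b}_t{t}"
                for pep in peps:
                    base = sum(
                        abundance[acc] * bio_factor[(acc, b)]
                        for acc in pep_parents[sp_name][pep]
                    ) * detect[pep]
                    tech = float(rng.lognormal(0.0, config.tech_cv))
                    dropped = rng.random() < config.dropout
                    score = max(
                        config.score.floor,
                        float(rng.normal(config.score.mean, config.score.sd)),
                    )
                    if dropped:
                        continue
                    rows.append(
                        {
                            "run_id": run,
                            "peptide": pep,
                            "modifications": "",
                            "score": round(score, 4),
                            "raw_abundance": round(base * tech * run_scale[run], 6),
                        }
                    )
                rows.append(
                    {
                        "run_id": run,
                        "peptide": ENOLASE_SPIKE,
                        "modifications": "",
                        "score": 15.0,
                        "raw_abundance": round(config.spike_base * run_scale[run], 6),
                    }
                )

    obs = pd.DataFrame(rows, columns=["run_id", "peptide", "modifications", "score", "raw_abundance"])

    truth: dict = {
        "protein_abundance": abundance,
        "run_scale": run_scale,
        "peptide_detectability": detect,
        "motif_true_total": {},
        "motif_expected_signal": {},
    }
    if motif_positions:
        motifs = list(motifs) if motifs is not None else default_motifs()
        for sp_name in species_names:
            true_tot: dict[str, float] = {}
            for acc, positions in motif_positions.items():
                if species_of.get(acc) != sp_name:
                    continue
                for motif_id, _s, _e in positions:
                    true_tot[motif_id] = true_tot.get(motif_id, 0.0) + abundance[acc]
            truth["motif_true_total"][sp_name] = true_tot
        for sp_name in species_names:
            sig: dict[str, float] = {}
            for m in motifs:
                total = 0.0
                for pep, parents in pep_parents[sp_name].items():
                    if m.sequence in pep:
                        total += sum(abundance[acc] for acc in parents) * detect[pep]
                if total > 0:
                    sig[m.motif_id] = total
            truth["motif_expected_signal"][sp_name] = sig
    return obs, design, truth


def two_species_ratio_experiment(
    seed: int,
    ratio: float = 4.0,
    motif: MotifRecord | None = None,
    copies: int = 3,
    n_background: int = 3,
    **config_kwargs,
) -> tuple[pd.DataFrame, ReplicateDesign, list[ProteinRecord], dict]:
    """Paired two-species dataset with a known motif-abundance ratio.

    Both species carry the *same* motif-bearing prolamin sequence; its
    abundance in species A is exactly ``ratio`` times that in species B
    (background proteins differ).  Used to test that the pipeline
    recovers the configured ratio from noisy replicate data.
    """
    motif = motif or default_motifs()[0]
    spec_a = SpeciesSpec(name="cerealA", n_proteins=n_background + 1, prolamin_fraction=1.0)
    spec_b = replace(spec_a, name="cerealB")
    config = SyntheticConfig(seed=seed, species=[spec_a, spec_b], **config_kwargs)

    prol, positions = generate_prolamin(
        seed, length=240, motifs=[(motif, copies)], accession="SHARED_PROL", species="cerealA"
    )
    proteins: list[ProteinRecord] = []
    motif_positions: dict[str, list] = {}
    for sp_name in ("cerealA", "cerealB"):
        acc = f"{sp_name.upper()}_CTMPROT"
        proteins.append(replace_record(prol, accession=acc, species=sp_name))
        motif_positions[acc] = positions
        for k in range(n_background):
            bg, _ = generate_prolamin(
                seed + 17 * (k + 1) + (0 if sp_name == "cerealA" else 1000),
                length=200,
                accession=f"{sp_name.upper()}_BG{k + 1}",
                species=sp_name,
            )
            proteins.append(bg)

    base = config.abundance_median
    overrides = {"CEREALA_CTMPROT": base * ratio, "CEREALB_CTMPROT": base}
    obs, design, truth = simulate_id_table(
        config,
        proteins,
        abundance_overrides=overrides,
        motifs=[motif],
        motif_positions=motif_positions,
    )
    truth["configured_ratio"] = ratio
    return obs, design, proteins, truth


def replace_record(record: ProteinRecord, **changes) -> ProteinRecord:
    """Copy a ProteinRecord with some fields replaced."""
    return ProteinRecord(
        accession=changes.get("accession", record.accession),
        description=changes.get("description", record.description),
        sequence=changes.get("sequence", record.sequence),
        species=changes.get("species", record.species),
        is_fragment=changes.get("is_fragment", record.is_fragment),
        tags=set(changes.get("tags", record.tags)),
    )


__all__ = [
    "DEFAULT_MOTIF_SEQUENCES",
    "SPLIT_MOTIF_SEQUENCE",
    "default_motifs",
    "generate_prolamin",
    "generate_globular",
    "generate_homologue",
    "ScoreModel",
    "HomologueSpec",
    "SpeciesSpec",
    "SyntheticConfig",
    "build_design",
    "generate_proteomes",
    "simulate_id_table",
    "two_species_ratio_experiment",
    "replace_record",
]
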