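"""End-to-end orchestration: sequence I/O -> digestion -> curation ->
quantification -> motif / homology / multivariate profiling.

``run_pipeline`` consumes a declarative :class:`PipelineConfig` (JSON on
disk) and writes a deterministic report bundle of TSV tables: identical
inputs and configuration yield byte-identical outputs.  Protein
grouping for the per-sample summary follows the per-cereal counting
convention (each sample grouped on its own retained peptides); a single
global grouping feeds quantification and PCA so group abundances are
comparable across samples.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .curation import (
    ReplicateDesign,
    filter_observations,
    identified_proteins,
    infer_groups,
    load_observations,
    protein_scores_from_observations,
)
from .digestion import DigestParams, map_peptides
from .homology import HomologyConfig, common_homologues, find_homologues
from .motifs import autoscale_features, cluster, find_encompassing, motif_abundance
from .multivariate import log_pareto, pca
from .quantify import (
    ENOLASE_SPIKE,
    abundance_rank_curve,
    group_abundance,
    normalize_to_spike,
)
from .seqio import (
    ProteinRecord,
    filter_by_membership,
    read_fasta,
    read_membership_list,
    read_motif_db,
)

SCHEMA_LINE = "# glutenscan table schema 1"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Paths and parameters for a full pipeline run."""

    proteome_fastas: Mapping[str, str]  # species -> FASTA path
    observations: str
    design: str
    out_dir: str
    allergen_fasta: str | None = None
    motif_db: str | None = None
    membership_list: str | None = None
    min_score: float = 5.0
    min_tech_reps: int = 2
    replicate_rule: str = "all_biorep"
    max_missed: int = 2
    min_len: int = 1
    equate_il: bool = False
    spike_peptide: str = ENOLASE_SPIKE
    aggregation: str = "sum_unique"
    top_n: int = 3
    n_components: int = 3
    homology: HomologyConfig = field(default_factory=HomologyConfig)
    highlight_tag: str = "glupro"

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        hom = HomologyConfig(**raw.pop("homology", {}))
        return cls(homology=hom, **raw)

    def digest_params(self) -> DigestParams:
        return DigestParams(
            max_missed=self.max_missed, min_len=self.min_len, equate_il=self.equate_il
        )


def write_table(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    """TSV with a schema-version line and stable float formatting."""
    with open(path, "w") as fh:
        fh.write(SCHEMA_LINE + "\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


@dataclass
class PipelineResult:
    """In-memory handles to the main pipeline outputs."""

    retained: pd.DataFrame
    removal_log: pd.DataFrame
    groups_global: list
    summary: pd.DataFrame
    group_matrix: pd.DataFrame
    motif_matrix: pd.DataFrame
    homology_hits: list
    pca_result: object | None


def _stage(name: str):
    def decorate(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return decorate


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.digest_params()

    @_stage("seqio")
    def _load():
        proteins: list[ProteinRecord] = []
        for species in sorted(config.proteome_fastas):
            proteins.extend(read_fasta(config.proteome_fastas[species], species=species))
        allergens = (
            read_fasta(config.allergen_fasta, species="allergen")
            if config.allergen_fasta
            else []
        )
        motifs, motif_warnings = (
            read_motif_db(config.motif_db) if config.motif_db else ([], [])
        )
        allowed = (
            read_membership_list(config.membership_list)
            if config.membership_list
            else None
        )
        return proteins, allergens, motifs, motif_warnings, allowed

    proteins, allergens, motifs, motif_warnings, allowed = _load()

    @_stage("curation")
    def _curate():
        obs = load_observations(config.observations)
        design = ReplicateDesign.from_csv(config.design)
        retained, removal_log = filter_observations(
            obs,
            design,
            min_score=config.min_score,
            min_tech_reps=config.min_tech_reps,
            replicate_rule=config.replicate_rule,
        )
        return obs, design, retained, removal_log

    obs, design, retained, removal_log = _curate()

    @_stage("digestion")
    def _map():
        peptides = set(retained["peptide"]) - {config.spike_peptide}
        return map_peptides(peptides, proteins, params)

    pp_map = _map()

    @_stage("grouping")
    def _group():
        scores = protein_scores_from_observations(
            retained, pp_map.proteins_to_peptides()
        )
        groups_global = infer_groups(pp_map, scores)

        rows = []
        per_sample_groups = {}
        for sample in design.sample_ids:
            runs = set(design.runs_of_sample(sample))
            sub = retained[retained["run_id"].isin(runs)]
            sub_map = pp_map.restrict(set(sub["peptide"]))
            sub_scores = protein_scores_from_observations(
                sub, sub_map.proteins_to_peptides()
            )
            sgroups = infer_groups(sub_map, sub_scores) if sub_map.parents else []
            per_sample_groups[sample] = sgroups
            leads_all = identified_proteins(sgroups, require_unique=False)
            leads_unique = identified_proteins(sgroups, require_unique=True)
            row = {
                "sample_id": sample,
                "peptides_retained": int(sub["peptide"].nunique()),
                "protein_groups": len(leads_all),
                "proteins_with_unique_peptide": len(leads_unique),
            }
            if allowed is not None:
                row["protein_groups_in_reference"] = sum(
                    1 for a in leads_all if a in allowed
                )
                row["proteins_with_unique_peptide_in_reference"] = sum(
                    1 for a in leads_unique if a in allowed
                )
            rows.append(row)
        summary = pd.DataFrame(rows)
        return groups_global, per_sample_groups, summary

    groups_global, per_sample_groups, summary = _group()

    @_stage("quantify")
    def _quantify():
        normalized = normalize_to_spike(retained, spike_peptide=config.spike_peptide)
        quant_groups = groups_global
        if allowed is not None:
            quant_groups = [g for g in groups_global if g.lead_accession in allowed]
        matrix = group_abundance(
            normalized,
            quant_groups,
            design=design,
            method=config.aggregation,
            n=config.top_n,
            level="sample",
        )
        highlight = {
            p.accession for p in proteins if config.highlight_tag in p.tags
        }
        usable = matrix.dropna(how="all")
        if usable.empty:
            curve = pd.DataFrame(
                columns=["rank", "feature_id", "mean_abundance", "highlighted"]
            )
        else:
            curve = abundance_rank_curve(usable, highlight)
        return normalized, matrix, curve

    normalized, group_matrix, rank_curve = _quantify()

    @_stage("motifs")
    def _motifs():
        if not motifs:
            return [], pd.DataFrame(), pd.DataFrame(), None
        peptides = set(retained["peptide"]) - {config.spike_peptide}
        pairs = find_encompassing(peptides, motifs)
        matrix = motif_abundance(pairs, normalized, design)
        scaled = pd.DataFrame()
        clust = None
        if matrix.shape[0] >= 1 and matrix.shape[1] >= 2:
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                scaled = autoscale_features(matrix)
            if scaled.shape[0] >= 2 and scaled.shape[1] >= 2:
                clust = cluster(scaled)
        return pairs, matrix, scaled, clust

    motif_pairs, motif_matrix, motif_scaled, motif_cluster = _motifs()

    @_stage("homology")
    def _homology():
        if not allergens:
            return []
        return find_homologues(allergens, proteins, config.homology)

    homology_hits = _homology()

    @_stage("multivariate")
    def _multivariate():
        usable = group_matrix.dropna(how="all")
        if usable.shape[0] < 2 or usable.shape[1] < 2:
            return None, pd.DataFrame()
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            transformed = log_pareto(usable)
        k = min(config.n_components, *transformed.shape)
        return pca(transformed, n_components=k), transformed

    pca_result, transformed = _multivariate()

    @_stage("report")
    def _report():
        write_table(retained.sort_values(["run_id", "peptide"]).reset_index(drop=True), out / "retained_observations.tsv")
        write_table(removal_log, out / "removal_log.tsv")
        (out / "orphan_peptides.txt").write_text(
            "\n".join(pp_map.orphans) + ("\n" if pp_map.orphans else "")
        )
        group_rows = [
            {
                "lead_accession": g.lead_accession,
                "members": ";".join(sorted(g.members)),
                "n_peptides": len(g.group_peptides),
                "n_unique_peptides": len(g.unique_peptides),
                "group_score": g.group_score,
                "single_peptide_id": g.single_peptide_id,
                "in_reference": (g.lead_accession in allowed) if allowed is not None else True,
            }
            for g in groups_global
        ]
        write_table(pd.DataFrame(group_rows), out / "protein_groups.tsv")
        write_table(summary, out / "summary.tsv")
        write_table(
            normalized.sort_values(["run_id", "peptide"]).reset_index(drop=True),
            out / "normalized_observations.tsv",
        )
        write_table(group_matrix, out / "group_abundance.tsv", index=True)
        write_table(rank_curve, out / "abundance_rank_curve.tsv")
        if motifs:
            pair_rows = [
                {
                    "motif_id": m,
                    "peptide": p,
                    "accessions": ";".join(sorted(pp_map.parents.get(p, frozenset()))),
                }
                for m, p in sorted(motif_pairs)
            ]
            write_table(pd.DataFrame(pair_rows, columns=["motif_id", "peptide", "accessions"]), out / "motif_hits.tsv")
            write_table(motif_matrix, out / "motif_abundance.tsv", index=True)
            if not motif_scaled.empty:
                write_table(motif_scaled, out / "motif_autoscaled.tsv", index=True)
            if motif_cluster is not None:
                (out / "motif_rows.nwk").write_text(
                    motif_cluster.row_newick(motif_scaled.index) + "\n"
                )
                (out / "motif_cols.nwk").write_text(
                    motif_cluster.col_newick(motif_scaled.columns) + "\n"
                )
        if homology_hits:
            hit_rows = [
                {
                    "query_id": h.query_id,
                    "subject_accession": h.subject_accession,
                    "method": h.method,
                    "percent_identity": h.percent_identity,
                    "coverage": h.coverage,
                    "window_hits": h.window_hits,
                    "passed": h.passed,
                    "flags": ";".join(sorted(h.flags)),
                }
                for h in homology_hits
            ]
            write_table(pd.DataFrame(hit_rows), out / "homology_hits.tsv")
            common = sorted(common_homologues(homology_hits))
            write_table(
                pd.DataFrame(common, columns=["query_id", "subject_accession"]),
                out / "homology_common.tsv",
            )
        if pca_result is not None:
            write_table(pca_result.scores, out / "pca_scores.tsv", index=True)
            loadings = pca_result.loadings.copy()
            gluten = {p.accession for p in proteins if config.highlight_tag in p.tags}
            loadings["gluten_set"] = [a in gluten for a in loadings.index]
            write_table(loadings, out / "pca_loadings.tsv", index=True)
            frac = pca_result.explained_variance_fraction
            var = pd.DataFrame(
                {
                    "component": [f"PC{i + 1}" for i in range(len(frac))],
                    "variance_fraction": frac,
                    "cumulative_fraction": frac.cumsum(),
                }
            )
            write_table(var, out / "pca_variance.tsv")
        log_lines = [
            f"glutenscan {__version__}",
            f"proteins={len(proteins)} allergens={len(allergens)} motifs={len(motifs)}",
            f"observations={len(obs)} retained={len(retained)} removed={len(removal_log)}",
            f"min_score={config.min_score} min_tech_reps={config.min_tech_reps} "
            f"replicate_rule={config.replicate_rule} max_missed={config.max_missed}",
            f"spike_peptide={config.spike_peptide}",
            f"aggregation={config.aggregation} n_components={config.n_components}",
        ] + [f"warning: {w}" for w in motif_warnings]
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")

    _report()
    return PipelineResult(
        retained=retained,
        removal_log=removal_log,
        groups_global=groups_global,
        summary=summary,
        group_matrix=group_matrix,
        motif_matrix=motif_matrix,
        homology_hits=homology_hits,
        pca_result=pca_result,
    )
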