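"""Peptide-level curation filters and parsimony protein grouping.

Observations are pandas DataFrames with columns ``run_id``, ``peptide``
(stripped sequence), ``modifications`` (free text, may be empty),
``score`` and ``raw_abundance``.  Modified forms of the same stripped
sequence are collapsed (abundances summed per run, score = max) before
any filter, because quantitation is at the sequence level.

The two curation rules:

* score rule — a peptide is kept only if its best score within the
  sample reaches ``min_score`` (default 5; a score of exactly 5 passes);
* replicate rule — within every biological replicate in which the
  peptide occurs at all it must be seen in at least ``min_tech_reps``
  technical replicates (strict reading; ``replicate_rule="any_biorep"``
  relaxes this to "at least one biological replicate qualifies").
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

OBSERVATION_COLUMNS = ["run_id", "peptide", "modifications", "score", "raw_abundance"]


@dataclass
class ReplicateDesign:
    """Maps runs to (sample, biological replicate, technical replicate)."""

    table: pd.DataFrame  # columns sample_id, bio_rep, tech_rep, run_id

    def __post_init__(self) -> None:
        required = {"sample_id", "bio_rep", "tech_rep", "run_id"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        if self.table["run_id"].duplicated().any():
            dups = self.table.loc[self.table["run_id"].duplicated(), "run_id"].tolist()
            raise ValueError(f"duplicate run_ids in design: {dups}")
        self._run_info = {
            row.run_id: (row.sample_id, row.bio_rep, row.tech_rep)
            for row in self.table.itertuples()
        }

    @property
    def run_ids(self) -> list[str]:
        return list(self.table["run_id"])

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["sample_id"]))

    def sample_of(self, run_id: str) -> str:
        return self._run_info[run_id][0]

    def bio_rep_of(self, run_id: str) -> object:
        return self._run_info[run_id][1]

    def runs_of_sample(self, sample_id: str) -> list[str]:
        return list(self.table.loc[self.table["sample_id"] == sample_id, "run_id"])

    def check_runs(self, run_ids: Iterable[str]) -> None:
        unknown = sorted(set(run_ids) - set(self._run_info))
        if unknown:
            raise ValueError(f"run_ids not in replicate design: {unknown}")

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "ReplicateDesign":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | os.PathLike) -> None:
        self.table.to_csv(path, index=False)


def load_observations(path: str | os.PathLike) -> pd.DataFrame:
    """Read a peptide identification table (CSV or TSV by extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    obs = pd.read_csv(path, sep=sep)
    missing = set(OBSERVATION_COLUMNS) - set(obs.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")
    obs["modifications"] = obs["modifications"].fillna("")
    return obs


def collapse_modified(obs: pd.DataFrame) -> pd.DataFrame:
    """Collapse modified peptide forms onto their stripped sequence.

    Per (run, peptide): abundances are summed, the score is the maximum
    across forms.
    """
    if obs.empty:
        return obs.copy()
    collapsed = (
        obs.groupby(["run_id", "peptide"], as_index=False, sort=True)
        .agg(score=("score", "max"), raw_abundance=("raw_abundance", "sum"))
    )
    collapsed["modifications"] = ""
    return collapsed[["run_id", "peptide", "modifications", "score", "raw_abundance"]]


def filter_observations(
    obs: pd.DataFrame,
    design: ReplicateDesign,
    min_score: float = 5.0,
    min_tech_reps: int = 2,
    replicate_rule: str = "all_biorep",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the score and technical-replicate filters per sample.

    Returns ``(retained_observations, removal_log)``.  The removal log
    has columns ``sample_id``, ``peptide``, ``reason`` where reason is
    ``"score"``, ``"replicate"`` or ``"score;replicate"``.

    Retention is decided per (sample, stripped peptide); all runs of a
    removed peptide in that sample are dropped together.
    """
    if replicate_rule not in {"all_biorep", "any_biorep"}:
        raise ValueError(f"unknown replicate_rule {replicate_rule!r}")
    obs = collapse_modified(obs)
    design.check_runs(obs["run_id"])
    if obs.empty:
        return obs, pd.DataFrame(columns=["sample_id", "peptide", "reason"])

    obs = obs.assign(
        sample_id=obs["run_id"].map(design.sample_of),
        bio_rep=obs["run_id"].map(design.bio_rep_of),
    )

    removal_rows: list[dict] = []
    keep_keys: set[tuple[str, str]] = set()
    for (sample, pep), grp in obs.groupby(["sample_id", "peptide"], sort=True):
        reasons = []
        if grp["score"].max() < min_score:
            reasons.append("score")
        tech_counts = grp.groupby("bio_rep")["run_id"].nunique()
        if replicate_rule == "all_biorep":
            replicate_ok = (tech_counts >= min_tech_reps).all() and len(tech_counts) >= 1
        else:
            replicate_ok = (tech_counts >= min_tech_reps).any()
        if not replicate_ok:
            reasons.append("replicate")
        if reasons:
            removal_rows.append(
                {"sample_id": sample, "peptide": pep, "reason": ";".join(reasons)}
            )
        else:
            keep_keys.add((sample, pep))

    mask = [
        (row.sample_id, row.peptide) in keep_keys for row in obs.itertuples()
    ]
    retained = obs.loc[mask, ["run_id", "peptide", "modifications", "score", "raw_abundance"]]
    retained = retained.reset_index(drop=True)
    removal_log = pd.DataFrame(removal_rows, columns=["sample_id", "peptide", "reason"])
    return retained, removal_log


def protein_score(obs: pd.DataFrame, peptides: Iterable[str]) -> float:
    """Surrogate protein score: sum over distinct retained peptides of the
    peptide's maximum score across runs.

    (The commercial search engine's protein score is proprietary; this
    declared surrogate preserves "more/better peptides -> higher score".)
    """
    peptides = set(peptides)
    sub = obs[obs["peptide"].isin(peptides)]
    if sub.empty:
        raise ValueError("no retained peptide observations for this protein")
    return float(sub.groupby("peptide")["score"].max().sum())


def protein_scores_from_observations(
    obs: pd.DataFrame, prot2peps: Mapping[str, frozenset[str]]
) -> dict[str, float]:
    """Protein scores for every accession with >= 1 retained peptide."""
    pep_max = obs.groupby("peptide")["score"].max()
    scores: dict[str, float] = {}
    for acc, peps in prot2peps.items():
        present = [p for p in peps if p in pep_max.index]
        if present:
            scores[acc] = float(pep_max.loc[present].sum())
    return scores


@dataclass
class ProteinGroup:
    """Proteins collapsed under a lead accession by peptide-set parsimony."""

    lead_accession: str
    members: frozenset[str]
    group_peptides: frozenset[str]
    unique_peptides: frozenset[str] = frozenset()
    group_score: float = 0.0
    single_peptide_id: bool = False

    def __post_init__(self) -> None:
        if self.lead_accession not in self.members:
            raise ValueError("lead accession must be a group member")
        if not self.unique_peptides <= self.group_peptides:
            raise ValueError("unique peptides must be a subset of group peptides")


def infer_groups(
    pp_map,
    protein_scores: Mapping[str, float],
) -> list[ProteinGroup]:
    """Parsimony protein grouping with lead accessions.

    Rules: (i) proteins with identical retained-peptide sets merge;
    (ii) a protein whose peptide set is a strict subset of another's is
    absorbed into that protein's group; (iii) the lead accession is the
    member with the highest protein score (ties broken by
    lexicographically smallest accession), and the group score is the
    lead's score.  Unique peptides are computed against all other
    groups.  The result is independent of input order.

    ``pp_map`` is a :class:`~glutenscan.digestion.PeptideProteinMap`
    already restricted to retained peptides.
    """
    prot2peps = pp_map.proteins_to_peptides()
    for acc in prot2peps:
        if acc not in protein_scores:
            raise ValueError(f"no protein score for accession {acc!r}")

    # distinct peptide sets, members merged (rule i)
    set_members: dict[frozenset[str], list[str]] = {}
    for acc in sorted(prot2peps):
        set_members.setdefault(prot2peps[acc], []).append(acc)

    distinct = list(set_members)
    maximal = [
        s for s in distinct
        if not any(s < other for other in distinct)
    ]

    def _anchor_key(s: frozenset[str]) -> tuple[float, str]:
        members = set_members[s]
        best = max(protein_scores[a] for a in members)
        return (-best, min(members))

    maximal.sort(key=_anchor_key)

    groups_members: dict[frozenset[str], set[str]] = {s: set(set_members[s]) for s in maximal}
    for s in distinct:
        if s in groups_members:
            continue
        # rule (ii): absorb into the deterministically chosen maximal superset
        candidates = [m for m in maximal if s < m]
        target = min(candidates, key=_anchor_key)
        groups_members[target].update(set_members[s])

    # unique peptides: not present in any other group's peptide set
    groups: list[ProteinGroup] = []
    for s in maximal:
        members = groups_members[s]
        others: set[str] = set()
        for t in maximal:
            if t is not s:
                others |= t
        unique = frozenset(s - others)
        best = max(protein_scores[a] for a in members)
        lead = min(a for a in members if protein_scores[a] == best)
        groups.append(
            ProteinGroup(
                lead_accession=lead,
                members=frozenset(members),
                group_peptides=s,
                unique_peptides=unique,
                group_score=protein_scores[lead],
                single_peptide_id=len(s) == 1,
            )
        )
    groups.sort(key=lambda g: g.lead_accession)
    return groups


def identified_proteins(groups: Sequence[ProteinGroup], require_unique: bool) -> list[str]:
    """Lead accessions of identified groups.

    ``require_unique=True`` keeps only groups with at least one unique
    peptide (unambiguous "Protein" identifications); ``False`` reports
    every group lead ("Protein grouping" semantics).
    """
    if require_unique:
        return [g.lead_accession for g in groups if g.unique_peptides]
    return [g.lead_accession for g in groups]
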