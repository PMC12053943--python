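import numpy as np
import pandas as pd
import pytest

from glutenscan.curation import (
    ReplicateDesign,
    collapse_modified,
    filter_observations,
    identified_proteins,
    infer_groups,
    protein_score,
    protein_scores_from_observations,
)
from glutenscan.digestion import PeptideProteinMap

from conftest import make_design, make_obs


class TestReplicateDesign:
    def test_duplicate_run_rejected(self):
        df = pd.DataFrame(
            {
                "sample_id": ["w", "w"],
                "bio_rep": [1, 1],
                "tech_rep": [1, 2],
                "run_id": ["r1", "r1"],
            }
        )
        with pytest.raises(ValueError, match="r1"):
            ReplicateDesign(df)

    def test_lookups(self, design_3x3):
        assert design_3x3.sample_of("w_b2_t3") == "w"
        assert design_3x3.bio_rep_of("w_b2_t3") == 2
        assert len(design_3x3.runs_of_sample("w")) == 9

    def test_unknown_run_is_error(self, design_3x3):
        obs = make_obs([("mystery_run", "PEPQ", 9, 1.0)])
        with pytest.raises(ValueError, match="mystery_run"):
            filter_observations(obs, design_3x3)


class TestCollapseModified:
    def test_sum_abundance_max_score(self):
        obs = make_obs(
            [
                ("r1", "PEPQ", 6, 10.0, ""),
                ("r1", "PEPQ", 9, 5.0, "Deamidation(2)"),
            ]
        )
        out = collapse_modified(obs)
        assert len(out) == 1
        assert out.loc[0, "score"] == 9
        assert out.loc[0, "raw_abundance"] == 15.0


class TestFilterObservations:
    def test_planned_fixture(self, curation_fixture):
        obs, design = curation_fixture
        retained, log = filter_observations(obs, design)
        assert set(retained["peptide"]) == {"PASSALL", "BOUND5"}
        reasons = dict(zip(log["peptide"], log["reason"]))
        assert reasons == {
            "LOWSCORE": "score",
            "ONETECH": "replicate",
            "MIXEDREP": "replicate",
            "BOTHBAD": "score;replicate",
        }

    def test_score_boundary_is_inclusive(self, curation_fixture):
        obs, design = curation_fixture
        retained, _ = filter_observations(obs, design, min_score=5)
        assert "BOUND5" in set(retained["peptide"])
        retained, _ = filter_observations(obs, design, min_score=5.01)
        assert "BOUND5" not in set(retained["peptide"])

    def test_any_biorep_rule_rescues_mixed_peptide(self, curation_fixture):
        obs, design = curation_fixture
        retained, _ = filter_observations(obs, design, replicate_rule="any_biorep")
        assert "MIXEDREP" in set(retained["peptide"])

    def test_idempotent(self, curation_fixture):
        obs, design = curation_fixture
        once, _ = filter_observations(obs, design)
        twice, log = filter_observations(once, design)
        pd.testing.assert_frame_equal(once, twice)
        assert log.empty

    def test_monotone_in_min_score(self, curation_fixture):
        obs, design = curation_fixture
        sizes = [
            filter_observations(obs, design, min_score=s)[0]["peptide"].nunique()
            for s in (0, 5, 9, 11)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_monotone_in_min_tech_reps(self, curation_fixture):
        obs, design = curation_fixture
        sizes = [
            filter_observations(obs, design, min_tech_reps=k)[0]["peptide"].nunique()
            for k in (1, 2, 3)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestProteinScore:
    def test_single_and_sum(self):
        obs = make_obs([("r1", "A" * 7, 7, 1.0), ("r1", "C" * 6, 5, 1.0)])
        assert protein_score(obs, {"A" * 7}) == 7
        assert protein_score(obs, {"A" * 7, "C" * 6}) == 12

    def test_distinct_peptide_max_not_per_run_sum(self):
        obs = make_obs([(f"r{i}", "PEPQ", s, 1.0) for i, s in enumerate([3, 8, 6, 2, 7, 5])])
        assert protein_score(obs, {"PEPQ"}) == 8

    def test_no_peptides_is_error(self):
        obs = make_obs([("r1", "PEPQ", 3, 1.0)])
        with pytest.raises(ValueError):
            protein_score(obs, {"OTHER"})


def pp_map(mapping):
    return PeptideProteinMap(
        parents={p: frozenset(a) for p, a in mapping.items()}
    )


class TestInferGroups:
    def test_identical_sets_merge_with_high_score_lead(self):
        m = pp_map({"PEPA": ["P1", "P2"], "PEPB": ["P1", "P2"]})
        groups = infer_groups(m, {"P1": 9, "P2": 12})
        assert len(groups) == 1
        g = groups[0]
        assert g.members == frozenset({"P1", "P2"})
        assert g.lead_accession == "P2"
        assert g.group_score == 12

    def test_strict_subset_absorbed(self):
        m = pp_map({"PEPA": ["A"], "PEPB": ["A", "B"]})
        groups = infer_groups(m, {"A": 10, "B": 4})
        assert len(groups) == 1
        assert groups[0].lead_accession == "A"
        assert groups[0].members == frozenset({"A", "B"})
        assert groups[0].group_peptides == frozenset({"PEPA", "PEPB"})

    def test_disjoint_proteins_keep_own_groups(self):
        m = pp_map({"PEPA": ["A"], "PEPB": ["B"]})
        groups = infer_groups(m, {"A": 5, "B": 6})
        assert len(groups) == 2
        assert all(g.unique_peptides == g.group_peptides for g in groups)

    def test_lead_tie_breaks_lexicographically(self):
        m = pp_map({"PEPA": ["ZZ", "AA"]})
        groups = infer_groups(m, {"ZZ": 7, "AA": 7})
        assert groups[0].lead_accession == "AA"

    def test_unique_peptides_computed_across_groups(self):
        m = pp_map({"PEPA": ["A"], "SHARED": ["A", "B"], "PEPB": ["B"]})
        groups = infer_groups(m, {"A": 5, "B": 6})
        by_lead = {g.lead_accession: g for g in groups}
        assert by_lead["A"].unique_peptides == frozenset({"PEPA"})
        assert by_lead["B"].unique_peptides == frozenset({"PEPB"})

    def test_order_invariance(self, rng):
        peptides = [f"PEP{i}" for i in range(12)]
        accs = [f"P{i}" for i in range(8)]
        base = {}
        for pep in peptides:
            k = int(rng.integers(1, 4))
            base[pep] = list(rng.choice(accs, size=k, replace=False))
        scores = {a: float(rng.integers(1, 30)) for a in accs}
        reference = infer_groups(pp_map(base), scores)
        for _ in range(20):
            items = list(base.items())
            rng.shuffle(items)
            shuffled = pp_map(dict(items))
            assert infer_groups(shuffled, scores) == reference

    def test_grouping_is_partition(self, rng):
        m = pp_map({"P1": ["A", "B"], "P2": ["A"], "P3": ["C"], "P4": ["C", "D"]})
        groups = infer_groups(m, {a: 1 for a in "ABCD"})
        seen = [a for g in groups for a in g.members]
        assert sorted(seen) == sorted(set(seen))
        assert set(seen) == {"A", "B", "C", "D"}

    def test_missing_score_is_error(self):
        with pytest.raises(ValueError, match="P1"):
            infer_groups(pp_map({"PEPA": ["P1"]}), {})


class TestIdentifiedProteins:
    def test_unique_requirement(self):
        m = pp_map({"PEPA": ["A"], "SHARED": ["A", "B"], "OTHER": ["B", "C"], "PEPC": ["C"]})
        groups = infer_groups(m, {"A": 3, "B": 2, "C": 1})
        with_unique = identified_proteins(groups, require_unique=True)
        all_leads = identified_proteins(groups, require_unique=False)
        assert set(with_unique) <= set(all_leads)
        assert len(all_leads) == len(groups)
        assert "B" not in with_unique  # only shared peptides

    def test_empty(self):
        assert identified_proteins([], True) == []
        assert identified_proteins([], False) == []


def test_protein_scores_from_observations():
    obs = make_obs([("r1", "PEPA", 7, 1.0), ("r2", "PEPA", 4, 1.0), ("r1", "PEPB", 5, 1.0)])
    scores = protein_scores_from_observations(
        obs, {"P1": frozenset({"PEPA", "PEPB"}), "P2": frozenset({"PEPB"}), "P3": frozenset({"GONE"})}
    )
    assert scores == {"P1": 12.0, "P2": 5.0}
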