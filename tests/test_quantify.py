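import numpy as np
import pandas as pd
import pytest

from glutenscan.curation import ProteinGroup
from glutenscan.quantify import (
    ENOLASE_SPIKE,
    abundance_rank_curve,
    group_abundance,
    normalize_to_spike,
    peptide_sample_abundance,
)

from conftest import make_design, make_obs


def spiked_obs(spikes, extra_rows=()):
    """Observations with a spike row per run plus arbitrary rows."""
    rows = [(run, ENOLASE_SPIKE, 15, s) for run, s in spikes.items()]
    rows.extend(extra_rows)
    return make_obs(rows)


class TestNormalizeToSpike:
    def test_identical_spike_means_identity(self):
        obs = spiked_obs(
            {"r1": 2e5, "r2": 2e5, "r3": 2e5},
            [("r1", "PEPQ", 9, 4.0e5), ("r2", "PEPQ", 9, 1.0e5)],
        )
        out = normalize_to_spike(obs)
        pd.testing.assert_series_equal(
            out["normalized_abundance"], out["raw_abundance"], check_names=False
        )

    def test_double_spike_halves_abundance(self):
        # median spike S = 1e5; run r2 has spike 2S -> factor 1/2
        obs = spiked_obs(
            {"r1": 1e5, "r2": 2e5, "r3": 1e5},
            [("r2", "PEPQ", 9, 4.0e5)],
        )
        out = normalize_to_spike(obs)
        val = out.loc[out["peptide"] == "PEPQ", "normalized_abundance"].iloc[0]
        assert val == pytest.approx(2.0e5, rel=1e-12)

    def test_missing_spike_names_run(self):
        obs = spiked_obs({"w_b1_t1": 1e5}, [("w_b1_t2", "PEPQ", 9, 1.0)])
        with pytest.raises(ValueError, match="w_b1_t2"):
            normalize_to_spike(obs)

    def test_zero_spike_names_run(self):
        obs = spiked_obs({"r1": 1e5, "r2": 0.0})
        with pytest.raises(ValueError, match="r2"):
            normalize_to_spike(obs)

    @pytest.mark.parametrize("c", [0.1, 3.0, 10.0])
    def test_run_scale_invariance(self, c):
        """Rescaling every raw abundance of one run (spike included)
        leaves all normalized abundances unchanged."""
        obs = spiked_obs(
            {"r1": 1e5, "r2": 1e5, "r3": 1e5},
            [
                ("r1", "PEPQ", 9, 4.0e5),
                ("r2", "PEPQ", 9, 3.0e5),
                ("r3", "QQPF", 8, 2.0e5),
            ],
        )
        baseline = normalize_to_spike(obs)
        scaled = obs.copy()
        mask = scaled["run_id"] == "r2"
        scaled.loc[mask, "raw_abundance"] *= c
        out = normalize_to_spike(scaled)
        np.testing.assert_allclose(
            out["normalized_abundance"].to_numpy(),
            baseline["normalized_abundance"].to_numpy(),
            rtol=1e-9,
        )

    def test_spike_constant_across_runs(self):
        obs = spiked_obs({"r1": 1e5, "r2": 7e5, "r3": 3e5})
        out = normalize_to_spike(obs)
        spike_vals = out.loc[out["peptide"] == ENOLASE_SPIKE, "normalized_abundance"]
        assert spike_vals.nunique() == 1
        assert spike_vals.iloc[0] == pytest.approx(3e5)

    def test_fixed_reference(self):
        obs = spiked_obs({"r1": 2e5}, [("r1", "PEPQ", 9, 4.0e5)])
        out = normalize_to_spike(obs, reference=1e5)
        val = out.loc[out["peptide"] == "PEPQ", "normalized_abundance"].iloc[0]
        assert val == pytest.approx(2.0e5)


def norm_obs(rows):
    obs = make_obs(rows)
    obs["normalized_abundance"] = obs["raw_abundance"]
    return obs


def group(lead, peptides, unique=None, members=None):
    peptides = frozenset(peptides)
    return ProteinGroup(
        lead_accession=lead,
        members=frozenset(members or {lead}),
        group_peptides=peptides,
        unique_peptides=frozenset(unique) if unique is not None else peptides,
    )


class TestGroupAbundance:
    def test_sum_unique(self):
        obs = norm_obs([("r1", "PEPA", 9, 2.0), ("r1", "PEPB", 9, 3.0)])
        g = group("P1", {"PEPA", "PEPB"})
        mat = group_abundance(obs, [g])
        assert mat.loc["P1", "r1"] == 5.0

    def test_top_n(self):
        obs = norm_obs([("r1", "PEPA", 9, 2.0), ("r1", "PEPB", 9, 3.0)])
        g = group("P1", {"PEPA", "PEPB"})
        mat = group_abundance(obs, [g], method="topN", n=1)
        assert mat.loc["P1", "r1"] == 3.0

    def test_shared_only_group_is_missing(self):
        obs = norm_obs([("r1", "SHARED", 9, 2.0)])
        g = group("P1", {"SHARED"}, unique=set())
        mat = group_abundance(obs, [g])
        assert mat.loc["P1"].isna().all()

    def test_sample_level_averages_runs(self):
        design = make_design(samples=("w",), n_bio=1, n_tech=2)
        obs = norm_obs([("w_b1_t1", "PEPA", 9, 2.0), ("w_b1_t2", "PEPA", 9, 4.0)])
        g = group("P1", {"PEPA"})
        mat = group_abundance(obs, [g], design=design, level="sample")
        assert mat.loc["P1", "w"] == 3.0

    def test_additive_over_disjoint_unique_subsets(self):
        obs = norm_obs(
            [("r1", "PEPA", 9, 2.0), ("r1", "PEPB", 9, 3.0), ("r1", "PEPC", 9, 5.0)]
        )
        whole = group("P1", {"PEPA", "PEPB", "PEPC"})
        part1 = group("P1", {"PEPA"})
        part2 = group("P2", {"PEPB", "PEPC"})
        total = group_abundance(obs, [whole]).loc["P1", "r1"]
        parts = group_abundance(obs, [part1, part2])
        assert total == parts.loc["P1", "r1"] + parts.loc["P2", "r1"]

    def test_unknown_method_is_error(self):
        obs = norm_obs([("r1", "PEPA", 9, 2.0)])
        with pytest.raises(ValueError):
            group_abundance(obs, [group("P1", {"PEPA"})], method="mean")

    def test_empty_groups_is_error(self):
        obs = norm_obs([("r1", "PEPA", 9, 2.0)])
        with pytest.raises(ValueError):
            group_abundance(obs, [])


class TestRankCurve:
    def test_ranks_and_highlight(self):
        mat = pd.DataFrame({"s1": [10.0, 5.0, 1.0]}, index=["A", "B", "C"])
        curve = abundance_rank_curve(mat, highlight={"B"})
        assert list(curve["rank"]) == [1, 2, 3]
        assert list(curve["feature_id"]) == ["A", "B", "C"]
        assert list(curve["highlighted"]) == [False, True, False]

    def test_ties_break_by_feature_id(self):
        mat = pd.DataFrame({"s1": [5.0, 5.0, 5.0]}, index=["C", "A", "B"])
        curve = abundance_rank_curve(mat)
        assert list(curve["feature_id"]) == ["A", "B", "C"]
        assert not curve["highlighted"].any()

    def test_empty_matrix_is_error(self):
        with pytest.raises(ValueError):
            abundance_rank_curve(pd.DataFrame())


def test_peptide_sample_abundance_means_observed_runs():
    design = make_design(samples=("w",), n_bio=1, n_tech=3)
    obs = norm_obs([("w_b1_t1", "PEPA", 9, 2.0), ("w_b1_t2", "PEPA", 9, 4.0)])
    mat = peptide_sample_abundance(obs, design)
    assert mat.loc["PEPA", "w"] == 3.0  # mean over the two observed runs
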