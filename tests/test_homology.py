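import numpy as np
import pytest

from glutenscan._align import align
from glutenscan.homology import (
    HomologyConfig,
    common_homologues,
    find_homologues,
    pairwise_identity,
    window_scan,
)
from glutenscan.seqio import ProteinRecord

from conftest import (
    AA20,
    oracle_align_global,
    oracle_align_local,
    random_protein,
)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        ident, length, cov = pairwise_identity("ACDEFGHIK", "ACDEFGHIK")
        assert ident == 100.0
        assert length == 9
        assert cov == 1.0

    def test_no_positive_scoring_alignment(self):
        ident, length, cov = pairwise_identity("AAAA", "TTTT", mode="local")
        assert ident == 0.0 and length == 0 and cov == 0.0

    def test_single_mismatch_matches_oracle(self):
        ident, length, _ = pairwise_identity("ACDEFGHIK", "ACDEFGHIR")
        score, matches, cols = oracle_align_local("ACDEFGHIK", "ACDEFGHIR")
        assert length == cols
        assert ident == pytest.approx(100.0 * matches / cols)

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACD")

    @pytest.mark.parametrize("mode", ["local", "global"])
    def test_agreement_with_dp_oracle_random_pairs(self, mode, rng):
        oracle = oracle_align_local if mode == "local" else oracle_align_global
        for _ in range(12):
            a = random_protein(rng, int(rng.integers(10, 121)))
            b = random_protein(rng, int(rng.integers(10, 121)))
            mine = align(a, b, mode)
            score, matches, cols = oracle(a, b)
            if mode == "local" and score <= 0:
                assert mine.score == 0
                continue
            assert (mine.score, mine.matches, mine.columns) == (score, matches, cols)

    def test_global_identity_symmetric_for_substitution_pairs(self, rng):
        # substitution-only pairs have a unique (ungapped) optimal alignment
        for _ in range(8):
            a = random_protein(rng, 60)
            b = list(a)
            for pos in rng.choice(60, size=12, replace=False):
                b[pos] = AA20[(AA20.index(b[pos]) + 1) % 20]
            b = "".join(b)
            fwd, _, _ = pairwise_identity(a, b, mode="global")
            rev, _, _ = pairwise_identity(b, a, mode="global")
            assert fwd == rev == pytest.approx(80.0)

    def test_scores_match_biopython(self, rng):
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10
        aligner.extend_gap_score = -1
        for mode in ("local", "global"):
            aligner.mode = mode
            for _ in range(15):
                a = random_protein(rng, int(rng.integers(15, 90)))
                b = random_protein(rng, int(rng.integers(15, 90)))
                theirs = aligner.score(a, b)
                if mode == "local":
                    theirs = max(theirs, 0)
                assert align(a, b, mode).score == theirs

    def test_shorter_sequence_denominator_option(self):
        config = HomologyConfig(identity_denominator="shorter")
        ident, _, _ = pairwise_identity("ACDEFGHIK", "ACDEFGHIK", config=config)
        assert ident == 100.0


class TestWindowScan:
    def test_query_equal_subject_hits_every_window(self, rng):
        q = random_protein(rng, 100)
        res = window_scan(q, q)
        assert res.n_windows == 21
        assert res.window_hits == 21
        assert res.best_identity == 100.0
        assert not res.too_short_for_window

    def test_query_of_79_flagged_too_short(self, rng):
        res = window_scan(random_protein(rng, 79), random_protein(rng, 200))
        assert res.too_short_for_window
        assert res.window_hits == 0
        assert not res.passed

    def test_query_embedded_in_subject(self, rng):
        q = random_protein(rng, 95)
        subject = random_protein(rng, 40) + q + random_protein(rng, 40)
        res = window_scan(q, subject)
        assert res.window_hits == len(q) - 79

    def test_hits_non_increasing_in_threshold(self, rng):
        q = random_protein(rng, 90)
        s = random_protein(rng, 120)
        hits = [
            window_scan(q, s, HomologyConfig(window_identity_threshold=t)).window_hits
            for t in (0.0, 20.0, 35.0, 60.0, 100.0)
        ]
        assert hits == sorted(hits, reverse=True)

    def test_threshold_100_requires_exact_windows(self, rng):
        q = random_protein(rng, 85)
        exact = window_scan(q, q, HomologyConfig(window_identity_threshold=100.0))
        assert exact.window_hits == 0  # strict '>' can never exceed 100
        almost = window_scan(q, q, HomologyConfig(window_identity_threshold=99.9))
        assert almost.window_hits == 6

    def test_strict_inequality_at_threshold(self, rng):
        # a window whose identity equals the threshold must NOT count
        q = random_protein(rng, 90)
        s = random_protein(rng, 120)
        base = window_scan(q, s, HomologyConfig(window_identity_threshold=0.0))
        t = max(base.window_identities)
        res = window_scan(q, s, HomologyConfig(window_identity_threshold=t))
        assert res.window_hits == sum(1 for x in base.window_identities if x > t)
        assert res.window_hits < base.n_windows

    def test_per_window_identities_match_dp_oracle(self, rng):
        q = random_protein(rng, 84)
        s = random_protein(rng, 110)
        res = window_scan(q, s)
        for start, ident in enumerate(res.window_identities):
            score, matches, cols = oracle_align_local(q[start : start + 80], s)
            expected = 100.0 * matches / cols if cols else 0.0
            assert ident == pytest.approx(expected, abs=1e-12)


class TestFindHomologues:
    def make_proteins(self, rng):
        allergen = ProteinRecord("ALG1", sequence=random_protein(rng, 100), species="allergen")
        selfcopy = ProteinRecord("SELF", sequence=allergen.sequence, species="wheat")
        unrelated = ProteinRecord("UNREL", sequence=random_protein(rng, 150), species="wheat")
        fragment = ProteinRecord(
            "FRAG", sequence=allergen.sequence[:60], species="wheat", is_fragment=True
        )
        return allergen, [selfcopy, unrelated, fragment]

    def test_self_subject_passes_both_methods(self, rng):
        allergen, proteome = self.make_proteins(rng)
        hits = find_homologues([allergen], proteome)
        by = {(h.subject_accession, h.method): h for h in hits}
        assert by[("SELF", "full")].passed
        assert by[("SELF", "window")].passed
        assert ("ALG1", "SELF") in common_homologues(hits)

    def test_fragment_subjects_never_called(self, rng):
        allergen, proteome = self.make_proteins(rng)
        hits = find_homologues([allergen], proteome)
        assert all(h.subject_accession != "FRAG" for h in hits)

    def test_window_only_chimera(self, rng):
        # subject shares one conserved 80-mer but is otherwise unrelated:
        # the window method fires, the full criterion (coverage) does not
        allergen = ProteinRecord("ALG1", sequence=random_protein(rng, 360), species="allergen")
        chimera = ProteinRecord(
            "CHIM",
            sequence=allergen.sequence[:80] + random_protein(rng, 320),
            species="rye",
        )
        hits = find_homologues([allergen], [chimera])
        by = {h.method: h for h in hits}
        assert by["window"].passed and by["window"].window_hits >= 1
        assert not by["full"].passed
        assert by["full"].coverage < 0.5

    def test_short_query_flagged_not_raised(self, rng):
        short = ProteinRecord("SHORT", sequence=random_protein(rng, 79), species="allergen")
        subject = ProteinRecord("S1", sequence=random_protein(rng, 100), species="wheat")
        hits = find_homologues([short], [subject])
        window_hit = next(h for h in hits if h.method == "window")
        assert "too_short_for_window" in window_hit.flags
        assert not window_hit.passed
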