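import itertools

import numpy as np
import pytest

from flowsplice.kmer_enrich import kmer_strings
from flowsplice.rbp_fingerprint import (
    MotifModel,
    fingerprint_region,
    ks_enrichment_score,
    pwm_kmer_set,
    read_motif_db,
    summarize_regions,
    write_motif_db,
)
from flowsplice.splice_events import ValidationError
from flowsplice.synthetic_data import _point_mass


def brute_force_es(n, member_positions):
    """Exhaustive running-sum enumeration (independent oracle)."""
    members = set(member_positions)
    nh = len(members)
    running = 0.0
    profile = []
    for i in range(n):
        running += 1.0 / nh if i in members else -1.0 / (n - nh)
        profile.append(running)
    peak = max(abs(v) for v in profile)
    for v in profile:
        if abs(v) >= peak - 1e-12:
            return v
    return 0.0


class TestMotifDb:
    def _write(self, tmp_path, text):
        path = tmp_path / "motifs.txt"
        path.write_text(text)
        return path

    def test_point_mass_round_trip(self, tmp_path):
        motifs = [MotifModel("M1", ("RbpA", "RbpB"), _point_mass("UGCAUG"))]
        path = tmp_path / "db.txt"
        write_motif_db(motifs, path)
        (back,) = read_motif_db(path)
        assert back.motif_id == "M1" and back.rbp_ids == ("RbpA", "RbpB")
        np.testing.assert_allclose(back.matrix, motifs[0].matrix)
        assert back.matrix[0].argmax() == 3  # U column recognised

    def test_malformed_row_names_motif_and_row(self, tmp_path):
        path = self._write(
            tmp_path,
            "Motif M1 RbpA\nPos A C G U\n1 1.0 0.0 0.0 0.0\n\n"
            "Motif M2 RbpB\nPos A C G U\n1 1.0 0.0 0.0 0.0\n2 0.9 0.0 0.0 0.0\n",
        )
        with pytest.raises(ValidationError, match="M2 row 2"):
            read_motif_db(path)

    def test_duplicate_id_rejected(self, tmp_path):
        path = self._write(
            tmp_path,
            "Motif M1 RbpA\nPos A C G U\n1 1.0 0.0 0.0 0.0\n\n"
            "Motif M1 RbpB\nPos A C G U\n1 1.0 0.0 0.0 0.0\n",
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_motif_db(path)

    def test_empty_file_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            read_motif_db(self._write(tmp_path, "\n"))


class TestPwmKmerSet:
    def test_point_mass_single_member(self):
        motif = MotifModel("M", ("R",), _point_mass("UGCAUG"))
        assert pwm_kmer_set(motif, k=6, score_threshold=0.8) == {"TGCATG"}

    def test_even_split_gives_both_maximal_kmers(self):
        mat = _point_mass("UGCAUG")
        mat[2] = [0.5, 0.5, 0.0, 0.0]  # position 3 split C/A
        motif = MotifModel("M", ("R",), mat)
        assert pwm_kmer_set(motif, k=6, score_threshold=0.99) == {"TGCATG", "TGAATG"}

    def test_short_matrix_padded_uniform(self):
        motif = MotifModel("M", ("R",), _point_mass("GCAUG"))
        members = pwm_kmer_set(motif, k=6, score_threshold=0.8)
        assert members == {b + "GCATG" for b in "ACGT"} | {"GCATG" + b for b in "ACGT"}

    def test_threshold_validated(self):
        motif = MotifModel("M", ("R",), _point_mass("UGCAUG"))
        with pytest.raises(ValidationError):
            pwm_kmer_set(motif, score_threshold=0.0)

    def test_matches_exhaustive_enumeration(self):
        """Member sets equal brute-force scoring of all 4**6 k-mers against
        every window (log-odds vs uniform background)."""
        rng = np.random.default_rng(11)
        kmers = kmer_strings(6)
        col = {"A": 0, "C": 1, "G": 2, "T": 3}
        for trial in range(5):
            mat = rng.dirichlet([0.6] * 4, size=8)
            motif = MotifModel(f"M{trial}", ("R",), mat)
            got = pwm_kmer_set(motif, k=6, score_threshold=0.8)
            expected = set()
            for km in kmers:
                for start in range(3):
                    w = mat[start : start + 6]
                    score = sum(np.log2(w[i, col[b]] / 0.25) for i, b in enumerate(km))
                    wmax = sum(np.log2(w[i].max() / 0.25) for i in range(6))
                    if score >= 0.8 * wmax - 1e-9:
                        expected.add(km)
                        break
            assert got == expected


class TestKsScore:
    @pytest.mark.parametrize(
        "n,members,expected_es",
        [
            (4, {0}, 1.0),  # full separation at the top
            (4, {1, 3}, -0.5),  # running sum (-1/2, 0, -1/2, 0)
            (4, {2, 3}, -1.0),  # complement at the bottom
        ],
    )
    def test_examples_match_enumeration(self, n, members, expected_es):
        ranked = kmer_strings(1)[:n]
        member_kmers = {ranked[i] for i in members}
        ks = ks_enrichment_score(ranked, member_kmers)
        assert ks.es == pytest.approx(expected_es)
        assert ks.es == pytest.approx(brute_force_es(n, members))

    def test_degenerate_sets_rejected(self):
        ranked = ["A", "C", "G", "T"]
        with pytest.raises(ValidationError):
            ks_enrichment_score(ranked, set())
        with pytest.raises(ValidationError):
            ks_enrichment_score(ranked, set(ranked))

    def test_exhaustive_equivalence_small_rankings(self):
        """ES equals brute-force enumeration for every proper member subset of
        rankings up to N = 8 (the N <= 10 sweep runs in the acceptance suite)."""
        for n in range(2, 9):
            ranked = [f"K{i}" for i in range(n)]
            for r in range(1, n):
                for members in itertools.combinations(range(n), r):
                    ks = ks_enrichment_score(ranked, {ranked[i] for i in members})
                    assert ks.es == pytest.approx(brute_force_es(n, members))
                    assert abs(ks.es) <= 1.0 + 1e-12

    def test_leading_edge_positive_es(self):
        ranked = [f"K{i}" for i in range(10)]
        ks = ks_enrichment_score(ranked, {"K0", "K1", "K7"})
        assert ks.es > 0
        assert set(ks.leading_edge) == {"K0", "K1"}


@pytest.fixture()
def planted_ranking(motif_db):
    """A ranking with the Rbfox-core k-mers at the top, decoys shuffled below."""
    rng = np.random.default_rng(0)
    kmers = list(kmer_strings(6))
    top = [km for km in kmers if "GCATG" in km or "TGCAT" in km]
    rest = [km for km in kmers if km not in set(top)]
    rng.shuffle(rest)
    return top + rest


class TestFingerprintRegion:
    def test_planted_ranking_ranks_rbfox_first(self, motif_db, planted_ranking):
        results, _ = fingerprint_region(
            planted_ranking, motif_db, n_permutations=500, seed=0
        )
        best = min(results, key=lambda r: (r.fdr, -abs(r.es)))
        assert best.motif_id.startswith("RBFOX")
        assert best.fdr < 0.05

    def test_determinism(self, motif_db, planted_ranking):
        a, _ = fingerprint_region(planted_ranking, motif_db, n_permutations=200, seed=5)
        b, _ = fingerprint_region(planted_ranking, motif_db, n_permutations=200, seed=5)
        assert [(r.motif_id, r.es, r.p_value, r.fdr) for r in a] == [
            (r.motif_id, r.es, r.p_value, r.fdr) for r in b
        ]

    def test_fdr_monotone_in_p(self, motif_db, planted_ranking):
        results, _ = fingerprint_region(planted_ranking, motif_db, n_permutations=200, seed=1)
        by_p = sorted(results, key=lambda r: r.p_value)
        fdrs = [r.fdr for r in by_p]
        assert all(a <= b + 1e-12 for a, b in zip(fdrs, fdrs[1:]))
        assert all(0 < r.p_value <= 1 and r.fdr >= r.p_value * 0 for r in results)

    def test_motif_without_members_skipped_with_audit(self, motif_db):
        ranking = ["AAAAAA", "AAAAAC", "AAAAAG", "AAAAAT", "TGCATG"]
        results, audit = fingerprint_region(ranking, motif_db, n_permutations=50, seed=2)
        skipped = {a.split(":")[0] for a in audit}
        assert any(m.startswith("DECOY") for m in skipped)
        assert {r.motif_id for r in results} & {"RBFOX_M1", "DECOY_POLYA"}

    def test_allow_list_restricts_motifs(self, motif_db, planted_ranking):
        results, _ = fingerprint_region(
            planted_ranking, motif_db, n_permutations=50, seed=3,
            allow_list=["RBFOX_M1", "DECOY_POLYA"],
        )
        assert {r.motif_id for r in results} == {"RBFOX_M1", "DECOY_POLYA"}

    def test_permutation_p_valid_under_null(self, motif_db):
        """Under a random ranking, P(p <= alpha) <= alpha + 2/sqrt(n_perm)."""
        rng = np.random.default_rng(4)
        hits = {0.01: 0, 0.05: 0}
        trials = 60
        n_perm = 200
        for t in range(trials):
            kmers = list(kmer_strings(6))
            rng.shuffle(kmers)
            results, _ = fingerprint_region(kmers, motif_db[:12], n_permutations=n_perm, seed=t)
            for r in results:
                for a in hits:
                    hits[a] += r.p_value <= a
        n = trials * 12
        for a, h in hits.items():
            assert h / n <= a + 2 / np.sqrt(n_perm)


class TestSummary:
    def test_matrix_shape_and_missing_cells(self, motif_db, planted_ranking):
        results, _ = fingerprint_region(planted_ranking, motif_db, n_permutations=50, seed=0)
        df = summarize_regions(
            {"regionA": results, "regionB": []}, {}, motif_db, k=6
        )
        assert set(df.region) == {"regionA", "regionB"}
        assert len(df) == 2 * len(motif_db)
        b = df[df.region == "regionB"]
        assert b.es.isna().all()
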