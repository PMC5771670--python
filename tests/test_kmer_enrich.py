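import numpy as np
import pytest

from flowsplice.kmer_enrich import (
    KmerTable,
    count_kmers,
    count_vector,
    kmer_enrichment,
    kmer_strings,
    rank_kmers,
)
from flowsplice.splice_events import ValidationError


def naive_count(seqs, k):
    """Brute-force per-position scan oracle."""
    out = {}
    for s in seqs:
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if "N" in w:
                continue
            out[w] = out.get(w, 0) + 1
    return out


def random_seqs(rng, n, length):
    return ["".join(rng.choice(list("ACGT"), size=length)) for _ in range(n)]


class TestCounting:
    def test_overlap_counting(self):
        assert count_kmers(["AAAA"], 2) == {"AA": 3}

    def test_windows_with_n_skipped(self):
        assert count_kmers(["ACGTNA"], 2) == {"AC": 1, "CG": 1, "GT": 1}

    def test_matches_naive_scan_oracle(self):
        rng = np.random.default_rng(0)
        seqs = random_seqs(rng, 100, 60)
        # sprinkle some Ns
        seqs = [s[:10] + "N" + s[11:] if i % 7 == 0 else s for i, s in enumerate(seqs)]
        assert count_kmers(seqs, 6) == naive_count(seqs, 6)

    def test_k_longer_than_regions_warns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            assert count_kmers(["ACG"], 6) == {}
        assert "no countable" in caplog.text

    def test_count_vector_window_total(self):
        counts, windows, bases = count_vector("ACGTACGT", 3)
        assert windows == 6 and counts.sum() == 6
        assert list(bases) == [2, 2, 2, 2]


def naive_enrichment_z(fg, bg_sets, k, gc_edges):
    """Independent oracle for the plain (uncorrected) enrichment z-score:
    dict-based counting, explicit bins, pseudo-frequency and bin weighting."""
    from flowsplice.flank_extract import gc_fraction

    def binof(seq):
        gc = gc_fraction(seq)
        b = 0
        for e in gc_edges:
            if gc > e:
                b += 1
        return b

    n_bins = len(gc_edges) + 1
    kmers = kmer_strings(k)

    def bin_tables(seqs):
        counts = [dict() for _ in range(n_bins)]
        windows = [0] * n_bins
        for s in seqs:
            b = binof(s)
            for w, c in naive_count([s], k).items():
                counts[b][w] = counts[b].get(w, 0) + c
            windows[b] += len(s) - k + 1 - sum(
                1 for i in range(len(s) - k + 1) if "N" in s[i : i + k]
            )
        return counts, windows

    fg_counts, fg_w = bin_tables(fg)
    total = sum(fg_w)
    weights = [w / total for w in fg_w]
    E = np.zeros((len(kmers), len(bg_sets)))
    for si, bset in enumerate(bg_sets):
        bg_counts, bg_w = bin_tables(bset)
        for b in range(n_bins):
            if fg_w[b] == 0:
                continue
            p = 1.0 / min(fg_w[b], bg_w[b]) if bg_w[b] > 0 else 1.0 / fg_w[b]
            for mi, m in enumerate(kmers):
                ffg = fg_counts[b].get(m, 0) / fg_w[b]
                fbg = bg_counts[b].get(m, 0) / bg_w[b] if bg_w[b] else 0.0
                E[mi, si] += weights[b] * np.log2((ffg + p) / (fbg + p))
    mean = E.mean(axis=1)
    sd = E.std(axis=1, ddof=1)
    z = np.where(sd > 0, mean / np.where(sd > 0, sd, 1), np.nan)
    return np.where((sd == 0) & (mean == 0), 0.0, z)


class TestEnrichment:
    def test_identity_case_all_z_zero(self):
        rng = np.random.default_rng(1)
        fg = random_seqs(rng, 10, 50)
        table = kmer_enrichment(fg, [list(fg), list(fg)], k=3, gc_edges=np.array([0.5]))
        assert np.nanmax(np.abs(table.z)) == pytest.approx(0.0)

    def test_micro_fixture_matches_hand_computed_weighted_sum(self):
        """Two GC bins, enrichment only in one: the pooled weighted score and z
        reproduce an independent dict-based computation for every k-mer."""
        rng = np.random.default_rng(2)
        at = lambda: "".join(rng.choice(list("AT"), size=30))
        gcseq = lambda: "".join(rng.choice(list("GC"), size=30))
        fg = [at() + "TGCATG" + at(), at(), gcseq(), gcseq()]
        bg_sets = [[at(), at(), gcseq(), gcseq()] for _ in range(3)]
        edges = np.array([0.5])
        table = kmer_enrichment(fg, bg_sets, k=6, gc_edges=edges, composition_order=None)
        oracle = naive_enrichment_z(fg, bg_sets, 6, edges)
        np.testing.assert_allclose(table.z, oracle, rtol=1e-9, equal_nan=True)

    def test_per_bin_frequencies_normalized(self):
        rng = np.random.default_rng(3)
        fg = random_seqs(rng, 20, 60)
        bg = [random_seqs(rng, 20, 60) for _ in range(2)]
        table = kmer_enrichment(fg, bg, k=4, n_gc_bins=4)
        for b in range(table.fg_freq.shape[0]):
            if table.weights[b] > 0:
                assert table.fg_freq[b].sum() == pytest.approx(1.0)

    def test_planted_kmer_tops_decoys(self):
        """A k-mer planted in 60% of foreground regions scores above the 99th
        percentile of all other k-mers' z, across seeds."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            fg = []
            for i in range(60):
                s = "".join(rng.choice(list("ACGT"), size=150))
                if rng.random() < 0.6:
                    pos = int(rng.integers(0, 144))
                    s = s[:pos] + "TGCATG" + s[pos + 6 :]
                fg.append(s)
            bg = [random_seqs(rng, 100, 150) for _ in range(6)]
            table = kmer_enrichment(fg, bg, k=6, n_gc_bins=2)
            idx = kmer_strings(6).index("TGCATG")
            others = np.delete(table.z, idx)
            assert table.z[idx] > np.nanquantile(others, 0.99)

    def test_determinism_with_sampler(self):
        rng0 = np.random.default_rng(4)
        fg = random_seqs(rng0, 15, 60)
        pool = random_seqs(rng0, 100, 60)

        def sampler(rng):
            return [list(rng.choice(pool, size=20, replace=False)) for _ in range(3)]

        t1 = kmer_enrichment(fg, sampler=sampler, iterations=5, k=4, seed=9, n_gc_bins=3)
        t2 = kmer_enrichment(fg, sampler=sampler, iterations=5, k=4, seed=9, n_gc_bins=3)
        np.testing.assert_array_equal(t1.z, t2.z)

    def test_label_swap_flips_enriched_sign(self):
        """Swapping the foreground with one background set flips the planted
        k-mer's z sign (enriched becomes depleted) in >= 9 of 10 seeds."""
        idx = kmer_strings(6).index("TGCATG")
        flips = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            fg = []
            for i in range(60):
                s = "".join(rng.choice(list("ACGT"), size=150))
                if i % 2 == 0:
                    pos = int(rng.integers(0, 144))
                    s = s[:pos] + "TGCATG" + s[pos + 6 :]
                fg.append(s)
            bg = [random_seqs(rng, 60, 150) for _ in range(4)]
            edges = np.array([0.4, 0.5, 0.6])
            t1 = kmer_enrichment(fg, bg, k=6, gc_edges=edges)
            t2 = kmer_enrichment(bg[0], [fg] + bg[1:], k=6, gc_edges=edges)
            flips += (t1.z[idx] > 0) and (t2.z[idx] < 0)
        assert flips >= 9

    def test_null_sign_symmetry(self):
        """Under the null the z distribution is centred and sign-balanced."""
        rng = np.random.default_rng(6)
        fracs, means = [], []
        for _ in range(5):
            fg = random_seqs(rng, 30, 80)
            bg = [random_seqs(rng, 60, 80) for _ in range(6)]
            table = kmer_enrichment(fg, bg, k=5, n_gc_bins=4)
            z = table.z[~np.isnan(table.z)]
            fracs.append((z > 0).mean())
            means.append(z.mean())
        # the statistic is only approximately symmetric (sparse counts skew
        # individual k-mers), so the bounds are loose
        assert 0.40 < np.mean(fracs) < 0.60
        assert abs(np.mean(means)) < 0.2

    def test_requires_two_background_sets(self):
        with pytest.raises(ValidationError):
            kmer_enrichment(["ACGTACGT"], [["ACGTACGT"]], k=3)


class TestRanking:
    def _table(self, z):
        k = 1
        return KmerTable(
            k=k, z=np.asarray(z, dtype=float),
            fg_freq=np.zeros((1, 4)), bg_freq_mean=np.zeros(4),
            weights=np.ones(1), gc_edges=np.array([]), n_sets=2, n_iterations=1,
        )

    def test_descending_z(self):
        # A, C, G, T with z 2, 5, -1, 0
        assert rank_kmers(self._table([2.0, 5.0, -1.0, 0.0])) == ["C", "A", "T", "G"]

    def test_ties_lexicographic(self):
        assert rank_kmers(self._table([1.0, 1.0, 2.0, 1.0])) == ["G", "A", "C", "T"]

    def test_undefined_z_dropped(self):
        assert rank_kmers(self._table([1.0, np.nan, 2.0, 0.0])) == ["G", "A", "T"]

    def test_all_undefined_rejected(self):
        with pytest.raises(ValidationError):
            rank_kmers(self._table([np.nan] * 4))
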