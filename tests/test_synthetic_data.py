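import numpy as np
import pytest

from flowsplice.filter_cascade import run_cascade
from flowsplice.flank_extract import extract_flanks
from flowsplice.rbp_fingerprint import pwm_kmer_set
from flowsplice.splice_events import GenomeSequence, ValidationError, reverse_complement
from flowsplice.synthetic_data import (
    SyntheticDesign,
    generate_dataset,
    generate_genome_and_events,
    generate_motif_db,
    generate_tables,
    plant_motif,
    write_dataset,
)
from conftest import ROLES


class TestGenomeAndEvents:
    def test_determinism_byte_identical(self, tmp_path):
        design = SyntheticDesign(n_foreground=20, n_pool=100)
        for sub in ("a", "b"):
            ds = generate_dataset(design, seed=3)
            write_dataset(ds, tmp_path / sub)
        for name in ("genome.fa", "events.tsv", "comparisons.tsv", "expression.tsv",
                     "motifs.txt", "manifest.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_strand_assignment_balanced(self):
        design = SyntheticDesign(n_foreground=100, n_pool=1900)
        _, events, _ = generate_genome_and_events(design, np.random.default_rng(1))
        frac = np.mean([ev.strand == "-" for ev in events])
        assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(2000)

    def test_events_valid_and_manifest_complete(self):
        design = SyntheticDesign(n_foreground=15, n_pool=60)
        contigs, events, manifest = generate_genome_and_events(design, np.random.default_rng(2))
        assert len(events) == 75 and len(manifest) == 75
        assert manifest.regulated.sum() == 15
        assert set(manifest[manifest.regulated].direction) <= {"increased", "decreased"}
        # nested truth structure
        assert not (manifest.platelet & ~manifest.endothelial).any()
        assert not (manifest.in_vitro & ~manifest.platelet).any()

    def test_infeasible_intron_vs_flank_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticDesign(intron_len=(100, 150), flank_len=200, allow_truncated=False)


class TestPlanting:
    def _dataset(self, rate, seed=0, n=12):
        design = SyntheticDesign(n_foreground=n, n_pool=10, frac_decreased=1.0,
                                 plant_rate=rate)
        return generate_dataset(design, seed=seed)

    def test_rate_one_plants_every_downstream_flank(self):
        ds = self._dataset(rate=1.0)
        targets = ds.manifest[ds.manifest.direction == "decreased"]
        assert targets.planted.all()
        for ev in ds.events[: len(targets)]:
            _, down = extract_flanks(ev, ds.genome, 200)
            assert "TGCATG" in down.sequence

    def test_rate_zero_leaves_genome_unchanged(self):
        design = SyntheticDesign(n_foreground=12, n_pool=10, plant_rate=0.0)
        ds0 = generate_dataset(design, seed=5)
        design2 = SyntheticDesign(n_foreground=12, n_pool=10, plant_rate=1e-12)
        ds1 = generate_dataset(design2, seed=5)
        assert ds0.genome.fetch("chrS", 0, ds0.genome.length("chrS")) == \
            ds1.genome.fetch("chrS", 0, ds1.genome.length("chrS"))
        assert not ds0.manifest.planted.any()

    def test_minus_strand_plant_reverse_complemented_in_genome(self):
        """Planting on a minus-strand event writes the reverse complement at
        the mapped genomic coordinates (coordinate-mapping oracle)."""
        ds = self._dataset(rate=1.0, seed=2)
        minus = [ev for ev in ds.events
                 if ev.strand == "-" and
                 ds.manifest.set_index("event_id").loc[ev.event_id, "planted"]]
        assert minus
        for ev in minus:
            ds_, de = ev.downstream_intron
            eff = min(200, de - ds_)
            genomic = ds.genome.fetch(ev.chrom, de - eff, de, "+")
            assert reverse_complement("TGCATG") in genomic

    def test_plant_rate_matches_binomial(self):
        design = SyntheticDesign(n_foreground=400, n_pool=10, frac_decreased=1.0,
                                 plant_rate=0.6)
        ds = generate_dataset(design, seed=9)
        n_planted = int(ds.manifest.planted.sum())
        assert abs(n_planted - 240) < 3 * np.sqrt(400 * 0.6 * 0.4)

    def test_invalid_side_rejected(self):
        design = SyntheticDesign(n_foreground=4, n_pool=4)
        contigs, events, manifest = generate_genome_and_events(design, np.random.default_rng(0))
        with pytest.raises(ValidationError):
            plant_motif(contigs, events, "TGCATG", "sideways", 1.0, np.random.default_rng(0))


class TestTables:
    def test_psi_within_unit_interval(self, small_dataset):
        for rec in small_dataset.comparisons:
            assert 0.0 <= rec.psi_a <= 1.0 and 0.0 <= rec.psi_b <= 1.0
            assert rec.bayes_factor >= 0

    def test_every_arm_generated(self, small_dataset):
        comps = {r.comparison_id for r in small_dataset.comparisons}
        assert comps == set(ROLES)

    def test_zero_noise_zero_effect_passes_nothing(self):
        design = SyntheticDesign(n_foreground=20, n_pool=60, effect_size=0.0,
                                 noise_sd=0.0, plant_rate=0.0)
        _, _, manifest = generate_genome_and_events(design, np.random.default_rng(3))
        records, _ = generate_tables(design, manifest, np.random.default_rng(4))
        report = run_cascade(records, ROLES)
        assert report.flow.retained == set()
        for rule in ("endothelial", "platelet", "in_vitro", "rbfox2"):
            assert getattr(report, rule).retained == set()

    def test_foreground_expression_stochastically_higher(self, small_dataset):
        m = small_dataset.manifest
        fg = m[m.regulated].expression
        pool = m[~m.regulated].expression
        assert fg.median() > pool.median()


class TestMotifCatalogue:
    def test_catalogue_valid_and_stable(self, motif_db, tmp_path):
        from flowsplice.rbp_fingerprint import read_motif_db, write_motif_db

        assert len(motif_db) == 85
        path = tmp_path / "db.txt"
        write_motif_db(motif_db, path)
        back = read_motif_db(path)
        assert [m.motif_id for m in back] == [m.motif_id for m in motif_db]

    def test_rbfox_member_set_contains_planted_kmer(self, motif_db):
        rbfox = [m for m in motif_db if m.motif_id.startswith("RBFOX")]
        assert len(rbfox) == 5
        for m in rbfox:
            assert "TGCATG" in pwm_kmer_set(m, k=6, score_threshold=0.8)

    def test_polya_decoy_disjoint_from_rbfox(self, motif_db):
        polya = next(m for m in motif_db if m.motif_id == "DECOY_POLYA")
        assert pwm_kmer_set(polya, k=6, score_threshold=0.8) == {"AAAAAA"}

    def test_decoys_disjoint_from_core(self, motif_db):
        for m in motif_db:
            if not m.motif_id.startswith("DECOY"):
                continue
            members = pwm_kmer_set(m, k=6, score_threshold=0.8)
            assert members, m.motif_id
            assert not any("GCATG" in x or "TGCAT" in x for x in members), m.motif_id


def test_dataset_roundtrips_through_readers(tmp_path, small_dataset):
    """Written synthetic inputs load back through the standard readers."""
    from flowsplice.splice_events import read_comparisons, read_events, read_expression
    from flowsplice.rbp_fingerprint import read_motif_db

    write_dataset(small_dataset, tmp_path)
    events = read_events(tmp_path / "events.tsv")
    assert events == small_dataset.events
    records = read_comparisons(tmp_path / "comparisons.tsv")
    assert records == small_dataset.comparisons
    assert read_expression(tmp_path / "expression.tsv") == small_dataset.expression
    assert len(read_motif_db(tmp_path / "motifs.txt")) == len(small_dataset.motifs)
    genome = GenomeSequence.from_fasta(tmp_path / "genome.fa")
    n = small_dataset.genome.length("chrS")
    assert genome.fetch("chrS", 0, n) == small_dataset.genome.fetch("chrS", 0, n)
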