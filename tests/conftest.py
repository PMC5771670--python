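"""Shared fixtures: toy genomes, a small synthetic study, a hand-built
comparison table exercising every selection clause, and the motif catalogue."""

from __future__ import annotations

import numpy as np
import pytest

from flowsplice.filter_cascade import ROLE_NAMES
from flowsplice.splice_events import ComparisonRecord, GenomeSequence, SplicingEvent
from flowsplice.synthetic_data import SyntheticDesign, generate_dataset, generate_motif_db

ROLES = {r: r for r in ROLE_NAMES}


@pytest.fixture(scope="session")
def motif_db():
    return generate_motif_db(2024)


@pytest.fixture(scope="session")
def small_dataset():
    """A scaled-down synthetic study shared by read-only tests."""
    design = SyntheticDesign(n_foreground=60, n_pool=600)
    return generate_dataset(design, seed=7)


@pytest.fixture()
def toy_genome():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    return GenomeSequence({"chr1": seq})


def make_plus_event(event_id="EVP", chrom="chr1", up=(100, 300), cas=(300, 400), down=(400, 650)):
    return SplicingEvent(
        event_id=event_id, gene_id="G1", chrom=chrom, strand="+",
        cassette=cas, upstream_intron=up, downstream_intron=down,
    )


def make_minus_event(event_id="EVM", chrom="chr1", down=(100, 300), cas=(300, 400), up=(400, 650)):
    # transcript-upstream intron is genomically right of the cassette
    return SplicingEvent(
        event_id=event_id, gene_id="G2", chrom=chrom, strand="-",
        cassette=cas, upstream_intron=up, downstream_intron=down,
    )


def _rec(ev, comp, dpsi, bf, psi_b=0.25):
    # psi_b and all delta values are exact binary fractions so that boundary
    # clauses (recapitulation == 0.5, ratio == 2x) are hit exactly
    psi_a = psi_b + dpsi
    return ComparisonRecord(event_id=ev, comparison_id=comp, psi_a=psi_a, psi_b=psi_b,
                            bayes_factor=bf)


def cascade_toy_table():
    """Twelve hand-built events exercising every cascade clause.

    Returns (records, roles, expected) where expected maps each rule to the
    hand-computed retained set (and rbfox2 labels).
    """
    rows: list[ComparisonRecord] = []

    def add(ev, **kw):
        defaults = dict(
            flow_1=(0.25, 10), flow_2=(0.25, 10), replicate_control=(0.0625, 1),
            endothelial=(0.1875, 5), platelet_igg_1=(0.25, 8), platelet_igg_2=(0.25, 8),
            platelet_depl_1=(0.03125, 2), platelet_depl_2=(0.03125, 2), in_vitro=(0.1875, 5),
            rbfox2_invivo_low_1=(-0.125, 2), rbfox2_invivo_low_2=(-0.15625, 1),
            rbfox2_invivo_high=(0.015625, 1), rbfox2_invitro=(0.03125, 2),
        )
        defaults.update(kw)
        for comp, (dpsi, bf) in defaults.items():
            if bf is None:
                continue
            rows.append(_rec(ev, comp, dpsi, bf))

    # E01 passes everything; rbfox2 "reverted" (BF>5 in low_1, KO dPsi opposes flow)
    add("E01", rbfox2_invivo_low_1=(-0.125, 8))
    # E02 BF boundary: BF == 5 in flow_1 -> excluded (strict >5)
    add("E02", flow_1=(0.25, 5.0))
    # E03 ratio boundary: min|dPsi| = 0.125 == 2 * 0.0625 -> excluded (strict >)
    add("E03", flow_1=(0.125, 9), flow_2=(0.1875, 9))
    # E04 sign inconsistency between the two flow comparisons
    add("E04", flow_1=(0.25, 9), flow_2=(-0.25, 9))
    # E05 missing flow_2 record -> excluded as incomplete
    add("E05", flow_2=(0.0, None))
    # E06 endothelial boundary: recapitulation exactly 0.5 (inclusive -> retained);
    # platelet reversion exactly 0.5 in pair 1 (strict -> excluded)
    add("E06", endothelial=(0.125, 5), platelet_depl_1=(0.125, 2))
    # E07 endothelial recapitulation 0.375 -> excluded at endothelial
    add("E07", endothelial=(0.09375, 5))
    # E08 platelet pair 2 reversion 0.4375 <= 0.5 -> excluded at platelet
    add("E08", platelet_depl_2=(0.140625, 2))
    # E09 in vitro recapitulation exactly 0.5 -> excluded (strict)
    add("E09", in_vitro=(0.125, 5))
    # E10 in vitro 0.75; rbfox2 "same": BF>5 only in rbfox2_invitro, KO dPsi same sign
    add("E10", in_vitro=(0.1875, 5),
        rbfox2_invivo_low_1=(0.0625, 2), rbfox2_invivo_low_2=(0.078125, 3),
        rbfox2_invitro=(0.0625, 6))
    # E11 fails endothelial; rbfox2 BF (3, 1, 2) all <= 5 -> excluded from rbfox2
    add("E11", endothelial=(0.046875, 5),
        rbfox2_invivo_low_1=(-0.125, 3), rbfox2_invivo_high=(0.015625, 1),
        rbfox2_invitro=(0.03125, 2))
    # E12 passes the nested cascade; rbfox2 BF ok but inconsistent in vivo direction
    add("E12", in_vitro=(0.1875, 5),
        rbfox2_invivo_low_1=(0.125, 9), rbfox2_invivo_low_2=(-0.125, 9))

    expected = {
        "flow": {"E01", "E06", "E07", "E08", "E09", "E10", "E11", "E12"},
        "endothelial": {"E01", "E06", "E08", "E09", "E10", "E12"},
        "platelet": {"E01", "E09", "E10", "E12"},
        "in_vitro": {"E01", "E10", "E12"},
        "rbfox2": {"E01", "E10"},
        "rbfox2_labels": {"E01": "reverted", "E10": "same"},
    }
    return rows, dict(ROLES), expected
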