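"""Synthetic data emulating a flow-regulated splicing study.

Generates every input the pipeline consumes — a toy genome, cassette-exon
annotations, multi-arm Psi/Bayes-factor comparison tables, a per-gene
expression table, and a PWM motif catalogue — together with a ground-truth
manifest, so that the whole analysis can be exercised and its recovery of
planted signal asserted without any external download.

The generative model mirrors the statistical structure the analysis assumes:

* a pool of unregulated skipped exons with U-shaped Psi (events near
  complete inclusion/exclusion) and moderate expression, plus a foreground
  of truly regulated events poised at intermediate Psi and stochastically
  higher expression (this is what makes matched backgrounds necessary);
* flow regulation as a fixed-magnitude delta-Psi (default 0.3, split
  between increased and decreased inclusion) observed through Gaussian
  measurement noise (default sd 0.02), with the Bayes factor produced by a
  stated monotone map of the observed signal-to-noise ratio,
  BF = exp(c * |dPsi| / noise_sd); the cascade only thresholds BF, so any
  strictly monotone map exercises it;
* nested dependence structure: most regulated events recapitulate in
  cultured endothelial cells, a subset depends on platelets, half of those
  on the in vitro platelet/macrophage/plasma cocktail, and an independent
  subset on Rbfox2 (knockout moves splicing back toward high flow);
* an Rbfox-binding-site analogue: the 6-mer TGCATG planted, at a stated
  rate, into the downstream flanks of decreased-inclusion foreground exons
  (transcript orientation, reverse-complemented onto minus-strand genomic
  sequence).  Planting overwrites bases rather than inserting, preserving
  coordinates, and keeps the motif wholly inside the flank.

Per-event base composition follows a Beta-distributed GC mean (bases i.i.d.
given it); an optional foreground GC shift lets GC-normalization be
stress-tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .filter_cascade import ROLE_NAMES
from .flank_extract import _flank_interval
from .rbp_fingerprint import MotifModel, pwm_kmer_set, write_motif_db
from .splice_events import (
    ComparisonRecord,
    GenomeSequence,
    SplicingEvent,
    ValidationError,
    reverse_complement,
    write_comparisons,
    write_events,
    write_expression,
)

log = logging.getLogger(__name__)

_LETTERS = np.frombuffer(b"GCAT", dtype=np.uint8)  # order used by the GC sampler


@dataclass
class SyntheticDesign:
    """Parameters of the synthetic study (defaults are the study conditions)."""

    n_foreground: int = 300
    n_pool: int = 3000
    frac_decreased: float = 0.5
    flank_len: int = 200
    intron_len: tuple[int, int] = (400, 800)
    exon_len: tuple[int, int] = (80, 160)
    spacer: int = 80
    gc_beta: tuple[float, float] = (9.0, 11.0)  # mean GC ~ 0.45
    foreground_gc_shift: float = 0.0
    fg_psi_beta: tuple[float, float] = (5.0, 5.0)  # intermediate Psi
    pool_psi_beta: tuple[float, float] = (0.45, 0.45)  # U-shaped Psi
    effect_size: float = 0.3
    noise_sd: float = 0.02
    bf_scale: float = 0.5
    endothelial_frac: float = 0.9
    platelet_frac: float = 1.0 / 3.0
    invitro_frac: float = 0.5
    rbfox2_frac: float = 0.25
    recap_strong: float = 0.9
    recap_weak: float = 0.1
    reversion: float = 0.8
    rbfox2_reversion: float = 0.8
    plant_motif: str = "TGCATG"
    plant_side: str = "downstream"
    plant_direction: str = "decreased"
    plant_rate: float = 0.6
    expr_fg_lognorm: tuple[float, float] = (1.8, 1.0)
    expr_pool_lognorm: tuple[float, float] = (1.0, 1.2)
    allow_truncated: bool = True

    def __post_init__(self) -> None:
        for name in ("frac_decreased", "plant_rate", "endothelial_frac", "platelet_frac",
                     "invitro_frac", "rbfox2_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"SyntheticDesign.{name}={v} must be in [0, 1]")
        if self.plant_side not in ("upstream", "downstream"):
            raise ValidationError("plant_side must be 'upstream' or 'downstream'")
        if self.plant_direction not in ("increased", "decreased"):
            raise ValidationError("plant_direction must be 'increased' or 'decreased'")
        if self.intron_len[0] < self.flank_len and not self.allow_truncated:
            raise ValidationError(
                f"minimum intron length {self.intron_len[0]} below flank_len "
                f"{self.flank_len} with truncation disabled"
            )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass
class SyntheticDataset:
    design: SyntheticDesign
    genome: GenomeSequence
    events: list[SplicingEvent]
    comparisons: list[ComparisonRecord]
    expression: dict[str, float]
    motifs: list[MotifModel]
    manifest: pd.DataFrame
    roles: dict[str, str] = field(default_factory=lambda: {r: r for r in ROLE_NAMES})


def _sample_bases(gc: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. bases with per-position P(G) = P(C) = gc/2."""
    r = rng.random(gc.size)
    half = (1.0 - gc) / 2.0
    code = (r >= gc / 2).astype(np.int8) + (r >= gc) + (r >= gc + half)
    return _LETTERS[code]


def generate_genome_and_events(
    design: SyntheticDesign, rng: np.random.Generator | int | None = None
) -> tuple[dict[str, np.ndarray], list[SplicingEvent], pd.DataFrame]:
    """Build the toy contig, the SE annotations, and the truth manifest.

    The genome is returned as mutable uint8 arrays (one per contig) so that
    motifs can be planted before freezing it into a :class:`GenomeSequence`.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = design.n_foreground + design.n_pool
    lo_i, hi_i = design.intron_len
    lo_e, hi_e = design.exon_len
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    lu = rng.integers(lo_i, hi_i + 1, size=n)
    ld = rng.integers(lo_i, hi_i + 1, size=n)
    le = rng.integers(lo_e, hi_e + 1, size=n)
    gc_mean = rng.beta(*design.gc_beta, size=n)
    regulated = np.arange(n) < design.n_foreground
    if design.foreground_gc_shift:
        gc_mean = np.where(
            regulated, np.clip(gc_mean + design.foreground_gc_shift, 0.02, 0.98), gc_mean
        )

    n_dec = int(round(design.frac_decreased * design.n_foreground))
    dec_idx = rng.permutation(design.n_foreground)[:n_dec]
    decreased = np.zeros(n, dtype=bool)
    decreased[dec_idx] = True
    direction = np.where(regulated, np.where(decreased, "decreased", "increased"), "")

    u = rng.random((4, n))
    endothelial = regulated & (u[0] < design.endothelial_frac)
    platelet = endothelial & (u[1] < design.platelet_frac)
    in_vitro = platelet & (u[2] < design.invitro_frac)
    rbfox2 = regulated & (u[3] < design.rbfox2_frac)

    total_len = int(design.spacer * (n + 1) + (lu + le + ld).sum())
    gc_track = np.full(total_len, 0.42)
    events: list[SplicingEvent] = []
    cursor = design.spacer
    rows = []
    for i in range(n):
        block = int(lu[i] + le[i] + ld[i])
        gc_track[cursor : cursor + block] = gc_mean[i]
        if strands[i] == "+":
            up = (cursor, cursor + int(lu[i]))
            cas = (up[1], up[1] + int(le[i]))
            down = (cas[1], cas[1] + int(ld[i]))
        else:
            down = (cursor, cursor + int(ld[i]))
            cas = (down[1], down[1] + int(le[i]))
            up = (cas[1], cas[1] + int(lu[i]))
        ev_id = f"EV{i:06d}"
        events.append(
            SplicingEvent(
                event_id=ev_id,
                gene_id=f"G{i:06d}",
                chrom="chrS",
                strand=str(strands[i]),
                cassette=cas,
                upstream_intron=up,
                downstream_intron=down,
            )
        )
        rows.append(
            {
                "event_id": ev_id,
                "gene_id": f"G{i:06d}",
                "strand": str(strands[i]),
                "regulated": bool(regulated[i]),
                "direction": direction[i],
                "endothelial": bool(endothelial[i]),
                "platelet": bool(platelet[i]),
                "in_vitro": bool(in_vitro[i]),
                "rbfox2": bool(rbfox2[i]),
                "gc_mean": float(gc_mean[i]),
                "planted": False,
            }
        )
        cursor += block + design.spacer
    contig = _sample_bases(gc_track, rng)
    manifest = pd.DataFrame(rows)
    return {"chrS": contig}, events, manifest


def plant_motif(
    contigs: dict[str, np.ndarray],
    events: Sequence[SplicingEvent],
    motif: str,
    side: str,
    rate: float,
    rng: np.random.Generator | int | None = None,
    flank_len: int = 200,
    manifest: pd.DataFrame | None = None,
) -> int:
    """Overwrite ``motif`` into the designated flank of each event w.p. ``rate``.

    The motif is written in transcript orientation at a uniformly chosen
    offset wholly inside the flank (reverse-complemented onto the genomic
    strand for minus-strand events).  Returns the number of planted events
    and flags them in ``manifest`` if given.
    """
    if side not in ("upstream", "downstream"):
        raise ValidationError(f"side must be 'upstream' or 'downstream', got {side!r}")
    if len(motif) > flank_len:
        raise ValidationError("motif longer than flank")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    fwd = np.frombuffer(motif.encode("ascii"), dtype=np.uint8)
    rev = np.frombuffer(reverse_complement(motif).encode("ascii"), dtype=np.uint8)
    planted_ids = []
    for ev in events:
        if rng.random() >= rate:
            continue
        fs, fe, _ = _flank_interval(ev, side, flank_len)
        eff = fe - fs
        if eff < len(motif):
            continue
        off = int(rng.integers(0, eff - len(motif) + 1))
        arr = contigs[ev.chrom]
        if ev.strand == "+":
            arr[fs + off : fs + off + len(motif)] = fwd
        else:
            arr[fe - off - len(motif) : fe - off] = rev
        planted_ids.append(ev.event_id)
    if manifest is not None and planted_ids:
        manifest.loc[manifest["event_id"].isin(planted_ids), "planted"] = True
    return len(planted_ids)


def _bf(delta: np.ndarray, design: SyntheticDesign) -> np.ndarray:
    denom = design.noise_sd if design.noise_sd > 0 else 1.0
    return np.exp(design.bf_scale * np.abs(delta) / denom)


def generate_tables(
    design: SyntheticDesign,
    manifest: pd.DataFrame,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[ComparisonRecord], dict[str, float]]:
    """Comparison records for every cascade arm, plus the expression table.

    Arm construction (delta-Psi targets before noise; d is the signed flow
    effect, zero for unregulated events):

    ==================== =========================================================
    flow_1, flow_2        d
    replicate_control     0
    endothelial           recap_strong*d if endothelial else recap_weak*d
    platelet_igg_1/2      d
    platelet_depl_1/2     (1-reversion)*d if platelet-dependent else d
    in_vitro              recap_strong*d if in-vitro-dependent else recap_weak*d
    rbfox2_invivo_low_1/2 -rbfox2_reversion*d if Rbfox2-dependent else 0
    rbfox2_invivo_high    0
    rbfox2_invitro        -rbfox2_reversion*d if Rbfox2-dependent else 0
    ==================== =========================================================
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = len(manifest)
    regulated = manifest["regulated"].to_numpy()
    sign = np.where(manifest["direction"].to_numpy() == "decreased", -1.0, 1.0)
    d = np.where(regulated, sign * design.effect_size, 0.0)
    endo = manifest["endothelial"].to_numpy()
    plat = manifest["platelet"].to_numpy()
    invi = manifest["in_vitro"].to_numpy()
    rbf = manifest["rbfox2"].to_numpy()

    psi_base = np.where(
        regulated,
        rng.beta(*design.fg_psi_beta, size=n),
        rng.beta(*design.pool_psi_beta, size=n),
    )

    targets = {
        "flow_1": d,
        "flow_2": d,
        "replicate_control": np.zeros(n),
        "endothelial": np.where(endo, design.recap_strong, design.recap_weak) * d,
        "platelet_igg_1": d,
        "platelet_igg_2": d,
        "platelet_depl_1": np.where(plat, 1.0 - design.reversion, 1.0) * d,
        "platelet_depl_2": np.where(plat, 1.0 - design.reversion, 1.0) * d,
        "in_vitro": np.where(invi, design.recap_strong, design.recap_weak) * d,
        "rbfox2_invivo_low_1": np.where(rbf, -design.rbfox2_reversion, 0.0) * d,
        "rbfox2_invivo_low_2": np.where(rbf, -design.rbfox2_reversion, 0.0) * d,
        "rbfox2_invivo_high": np.zeros(n),
        "rbfox2_invitro": np.where(rbf, -design.rbfox2_reversion, 0.0) * d,
    }
    assert set(targets) == set(ROLE_NAMES)

    event_ids = manifest["event_id"].tolist()
    records: list[ComparisonRecord] = []
    n_clipped = 0
    for role in ROLE_NAMES:
        tgt = targets[role]
        psi_b = np.clip(psi_base + rng.normal(0.0, design.noise_sd, size=n), 0.0, 1.0)
        psi_a_raw = psi_b + tgt + rng.normal(0.0, design.noise_sd, size=n)
        psi_a = np.clip(psi_a_raw, 0.0, 1.0)
        n_clipped += int((psi_a != psi_a_raw).sum())
        delta = psi_a - psi_b
        bf = _bf(delta, design)
        for i in range(n):
            records.append(
                ComparisonRecord(
                    event_id=event_ids[i],
                    comparison_id=role,
                    psi_a=float(psi_a[i]),
                    psi_b=float(psi_b[i]),
                    bayes_factor=float(bf[i]),
                )
            )
    if n_clipped:
        log.info("generate_tables: clipped Psi in %d records", n_clipped)

    mu_fg, sd_fg = design.expr_fg_lognorm
    mu_pool, sd_pool = design.expr_pool_lognorm
    expr = np.where(
        regulated,
        rng.lognormal(mu_fg, sd_fg, size=n),
        rng.lognormal(mu_pool, sd_pool, size=n),
    )
    expression = {g: float(v) for g, v in zip(manifest["gene_id"], expr)}
    manifest["psi_base"] = psi_base
    manifest["expression"] = expr
    return records, expression


def _point_mass(consensus: str, conc: float = 0.97) -> np.ndarray:
    """PWM concentrated on a consensus RNA string (columns A, C, G, U)."""
    col = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
    mat = np.full((len(consensus), 4), (1.0 - conc) / 3.0)
    for i, b in enumerate(consensus):
        mat[i, col[b]] = conc
    return mat


def _rbfox_family() -> list[MotifModel]:
    """Five Rbfox-family motif variants around the (U)GCAUG element.

    The variants differ in how far they extend the core to either side (an
    unconstrained flanking position is a uniform column), mirroring how one
    binding element yields several in-vitro-defined motif versions whose
    member k-mer sets are the element plus its flanking extensions.
    """
    family = ("Rbfox1", "Rbfox2", "Rbfox3")
    uniform = np.full((1, 4), 0.25)
    m1 = _point_mass("UGCAUG")
    # core + free right flank: members TGCATG, GCATGN
    m2 = np.vstack([_point_mass("UGCAUG"), uniform])
    m3 = _point_mass("UGCAUGU")
    # free left flank + core: members NTGCAT, TGCATG
    m4 = np.vstack([uniform, _point_mass("UGCAUG")])
    m5 = _point_mass("UGCAUG")
    m5[5] = [0.01, 0.01, 0.58, 0.40]  # G/U split at position 6
    return [
        MotifModel("RBFOX_M1", family, m1),
        MotifModel("RBFOX_M2", family, m2),
        MotifModel("RBFOX_M3", family, m3),
        MotifModel("RBFOX_M4", family, m4),
        MotifModel("RBFOX_M5", family, m5),
    ]


def generate_motif_db(
    seed: int | None = None,
    n_decoys: int = 80,
    k: int = 6,
    score_threshold: float = 0.8,
) -> list[MotifModel]:
    """Fixture PWM catalogue: an Rbfox family (five UGCAUG-core variants)
    plus decoy motifs of varied length and sharpness.

    The catalogue size (85 motifs) matches the scale of a curated
    RNA-binding-protein signature collection.  Decoy member sets are kept
    disjoint from the GCAUG core so planted-motif recovery is attributable.
    """
    rng = np.random.default_rng(seed)
    motifs = _rbfox_family()
    motifs.append(MotifModel("DECOY_POLYA", ("RbpPolyA",), _point_mass("AAAAAA")))
    bases = "ACGU"
    made = 1
    while made < n_decoys:
        L = int(rng.integers(5, 9))
        consensus = "".join(bases[c] for c in rng.integers(0, 4, size=L))
        conc = rng.choice([0.97, 0.9, 0.8, 0.7], size=L, p=[0.4, 0.3, 0.2, 0.1])
        mat = np.full((L, 4), 0.0)
        for i, b in enumerate(consensus):
            c = float(conc[i])
            mat[i] = (1.0 - c) / 3.0
            mat[i, bases.index(b)] = c
        motif = MotifModel(f"DECOY_{made:03d}", (f"Rbp{made:03d}",), mat)
        members = pwm_kmer_set(motif, k=k, score_threshold=score_threshold)
        if not members or len(members) > 400:
            continue
        if any("GCATG" in m or "TGCAT" in m for m in members):
            continue
        motifs.append(motif)
        made += 1
    return motifs


def generate_dataset(
    design: SyntheticDesign | None = None,
    seed: int | None = None,
    motif_db_seed: int = 2024,
) -> SyntheticDataset:
    """One-call generation of a complete synthetic study.

    Everything except the motif catalogue derives from ``seed``; the
    catalogue is a fixture shared across runs (``motif_db_seed``) so that
    motif identities are stable between seeds.
    """
    design = design or SyntheticDesign()
    ss = np.random.SeedSequence(seed)
    rng_genome, rng_plant, rng_tables = (np.random.default_rng(c) for c in ss.spawn(3))
    contigs, events, manifest = generate_genome_and_events(design, rng_genome)
    if design.plant_rate > 0:
        targets = [
            ev
            for ev, direction in zip(events, manifest["direction"])
            if direction == design.plant_direction
        ]
        plant_motif(
            contigs,
            targets,
            design.plant_motif,
            design.plant_side,
            design.plant_rate,
            rng_plant,
            design.flank_len,
            manifest,
        )
    records, expression = generate_tables(design, manifest, rng_tables)
    genome = GenomeSequence(
        {name: arr.tobytes().decode("ascii") for name, arr in contigs.items()}
    )
    motifs = generate_motif_db(motif_db_seed)
    return SyntheticDataset(
        design=design,
        genome=genome,
        events=events,
        comparisons=records,
        expression=expression,
        motifs=motifs,
        manifest=manifest,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path, seed: int = 0) -> Path:
    """Write every pipeline input plus the ground-truth manifest and a ready
    pipeline config; returns the config path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.genome.write_fasta(outdir / "genome.fa")
    write_events(ds.events, outdir / "events.tsv")
    write_comparisons(ds.comparisons, outdir / "comparisons.tsv")
    write_expression(ds.expression, outdir / "expression.tsv")
    write_motif_db(ds.motifs, outdir / "motifs.txt")
    ds.manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    with open(outdir / "design.yaml", "w") as fh:
        yaml.safe_dump(asdict(ds.design), fh, sort_keys=True)
    config = {
        "events": "events.tsv",
        "comparisons": "comparisons.tsv",
        "genome": "genome.fa",
        "expression": "expression.tsv",
        "motif_db": "motifs.txt",
        "roles": dict(ds.roles),
        "flank_len": ds.design.flank_len,
        "seed": seed,
    }
    config_path = outdir / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return config_path
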