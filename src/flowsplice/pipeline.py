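"""End-to-end analysis: selection cascade -> flanks -> matched backgrounds ->
k-mer z-scores -> motif fingerprints -> summaries.

The library core is :func:`analyze`, a pure function of in-memory inputs and
a seed; :func:`run_pipeline` wraps it with file I/O driven by a declarative
YAML config and writes plain-text reports plus a run manifest (config hash,
seed, stage counts).  One top-level seed deterministically derives every
per-stage stream, so identical (inputs, config, seed) give byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .background_match import (
    BackgroundSpec,
    MatchedBackground,
    eligible_pool,
    gc_bin_edges,
    sample_matched_backgrounds,
)
from .filter_cascade import ROLE_NAMES, SelectionConfig, SelectionReport, index_records, run_cascade
from .flank_extract import (
    REGION_CLASSES,
    FlankRegion,
    build_region_sets,
    extract_flanks,
    region_name,
    write_flank_bed,
    write_flank_fasta,
)
from .kmer_enrich import KmerTable, kmer_enrichment, rank_kmers
from .rbp_fingerprint import (
    FingerprintResult,
    MotifModel,
    fingerprint_region,
    read_motif_db,
    summarize_regions,
)
from .splice_events import (
    ComparisonRecord,
    GenomeSequence,
    SplicingEvent,
    ValidationError,
    read_comparisons,
    read_events,
    read_expression,
)

log = logging.getLogger(__name__)

TIERS = ("flow", "endothelial", "platelet", "in_vitro")

_CONFIG_KEYS = {
    "events", "comparisons", "genome", "expression", "motif_db", "roles",
    "selection", "background", "k_list", "iterations", "n_permutations",
    "flank_len", "fpkm_floor", "score_threshold", "analysis_tier",
    "allow_list", "seed",
}


@dataclass
class PipelineConfig:
    events: Path
    comparisons: Path
    genome: Path
    expression: Path
    motif_db: Path
    roles: dict[str, str]
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    k_list: tuple[int, ...] = (6,)
    iterations: int = 100
    n_permutations: int = 1000
    flank_len: int = 200
    fpkm_floor: float = 1.0
    score_threshold: float = 0.8
    analysis_tier: str = "flow"
    allow_list: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        missing = [r for r in ROLE_NAMES if r not in self.roles]
        if missing:
            raise ValidationError(f"config missing comparison roles: {missing}")
        if self.analysis_tier not in TIERS:
            raise ValidationError(f"analysis_tier must be one of {TIERS}")
        for name in ("iterations", "n_permutations", "flank_len"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.seed is None:
            raise ValidationError("seed is mandatory")

    def canonical_dict(self) -> dict:
        d = asdict(self)
        for key in ("events", "comparisons", "genome", "expression", "motif_db"):
            d[key] = str(d[key])
        d["k_list"] = list(self.k_list)
        d["allow_list"] = list(self.allow_list) if self.allow_list else None
        return d


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a pipeline config; unknown keys are rejected and all
    referenced paths must exist (resolved relative to the config file)."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    base = path.parent
    kwargs: dict = {}
    for key in ("events", "comparisons", "genome", "expression", "motif_db"):
        if key not in raw:
            raise ValidationError(f"config missing required path {key!r}")
        p = (base / raw[key]).resolve()
        if not p.exists():
            raise ValidationError(f"config path {key}={raw[key]!r} does not exist")
        kwargs[key] = p
    kwargs["roles"] = dict(raw.get("roles") or {})
    if "selection" in raw:
        kwargs["selection"] = SelectionConfig(**raw["selection"])
    if "background" in raw:
        kwargs["background"] = BackgroundSpec(**raw["background"])
    for key in ("iterations", "n_permutations", "flank_len", "fpkm_floor",
                "score_threshold", "analysis_tier", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    if raw.get("k_list"):
        kwargs["k_list"] = tuple(int(k) for k in raw["k_list"])
    if raw.get("allow_list"):
        kwargs["allow_list"] = tuple(raw["allow_list"])
    return PipelineConfig(**kwargs)


@dataclass
class AnalysisResult:
    report: SelectionReport
    foreground_regions: dict[tuple[str, str], list[FlankRegion]]
    backgrounds: list[MatchedBackground]
    pool_ids: list[str]
    tables: dict[tuple[int, str], KmerTable]
    rankings: dict[tuple[int, str], list[str]]
    fingerprints: dict[tuple[int, str], list[FingerprintResult]]
    summaries: dict[int, pd.DataFrame]
    funnel: dict[str, int]
    audits: dict[str, list] = field(default_factory=dict)


def _flank_map(
    event_by_id: Mapping[str, SplicingEvent],
    ids: Sequence[str],
    genome: GenomeSequence,
    flank_len: int,
) -> tuple[dict[str, tuple[FlankRegion, FlankRegion]], list[dict]]:
    flanks: dict[str, tuple[FlankRegion, FlankRegion]] = {}
    audit = []
    for ev_id in ids:
        try:
            flanks[ev_id] = extract_flanks(event_by_id[ev_id], genome, flank_len)
        except ValidationError as exc:
            audit.append({"event_id": ev_id, "error": str(exc)})
    return flanks, audit


def analyze(
    events: Sequence[SplicingEvent],
    comparisons: Sequence[ComparisonRecord],
    expression: Mapping[str, float],
    genome: GenomeSequence,
    motifs: Sequence[MotifModel],
    roles: Mapping[str, str],
    *,
    selection: SelectionConfig | None = None,
    background: BackgroundSpec | None = None,
    k_list: Sequence[int] = (6,),
    iterations: int = 100,
    n_permutations: int = 1000,
    flank_len: int = 200,
    fpkm_floor: float = 1.0,
    score_threshold: float = 0.8,
    analysis_tier: str = "flow",
    allow_list: Sequence[str] | None = None,
    seed: int = 0,
) -> AnalysisResult:
    """Run the full analysis in memory (see module docstring)."""
    selection = selection or SelectionConfig()
    background = background or BackgroundSpec()
    event_by_id = {ev.event_id: ev for ev in events}
    idx = index_records(comparisons)

    # 1. selection cascade
    report = run_cascade(idx, roles, selection)
    tier_set = getattr(report, analysis_tier).retained
    if not tier_set:
        raise ValidationError(f"no events retained at tier {analysis_tier!r}")

    # 2. foreground flank regions (four region classes)
    fg_events = [event_by_id[e] for e in sorted(tier_set) if e in event_by_id]
    fg_regions, fg_audit = build_region_sets(fg_events, report.directions, genome, flank_len)

    # 3. covariates for matching: baseline inclusion = mean reference-sample
    # Psi over the two flow comparisons; expression mapped via the gene
    def baseline_psi(ev_id: str) -> float | None:
        recs = [idx.get((ev_id, roles["flow_1"])), idx.get((ev_id, roles["flow_2"]))]
        recs = [r for r in recs if r is not None]
        return float(np.mean([r.psi_b for r in recs])) if recs else None

    psi_by_event: dict[str, float] = {}
    expr_by_event: dict[str, float] = {}
    for ev in events:
        p = baseline_psi(ev.event_id)
        if p is not None:
            psi_by_event[ev.event_id] = p
            expr_by_event[ev.event_id] = float(expression.get(ev.gene_id, 0.0))

    pool_ids = eligible_pool(events, expression, report.flow.retained, fpkm_floor)
    pool_ids = [e for e in pool_ids if e in psi_by_event]
    fg_ids = [e for e in sorted(tier_set) if e in psi_by_event]

    # 4. matched background rounds (first round also used for reports/GC bins)
    ss = np.random.SeedSequence(seed)
    bg_stream, fp_stream = ss.spawn(2)
    bg_rng = np.random.default_rng(bg_stream)
    rounds_events = [
        sample_matched_backgrounds(
            pool_ids, fg_ids, expr_by_event, psi_by_event, background, bg_rng, warn=(i == 0)
        )
        for i in range(iterations)
    ]
    backgrounds = rounds_events[0]

    # 5. pool flanks (extracted once, k-mer counts cached on the regions)
    pool_flanks, pool_audit = _flank_map(event_by_id, pool_ids, genome, flank_len)
    side_index = {"upstream": 0, "downstream": 1}

    def side_flanks(ids: Sequence[str], side: str) -> list[FlankRegion]:
        si = side_index[side]
        return [pool_flanks[e][si] for e in ids if e in pool_flanks]

    gc_edges = {
        side: gc_bin_edges(
            [fl for bg in backgrounds for fl in side_flanks(bg.event_ids, side)],
            background.n_gc_bins,
        )
        for side in side_index
    }

    # 6. enrichment + fingerprints per (k, region class)
    tables: dict[tuple[int, str], KmerTable] = {}
    rankings: dict[tuple[int, str], list[str]] = {}
    fingerprints: dict[tuple[int, str], list[FingerprintResult]] = {}
    fp_audit: dict[str, list[str]] = {}
    fp_children = iter(fp_stream.spawn(len(k_list) * len(REGION_CLASSES)))
    for k in k_list:
        for side, direction in REGION_CLASSES:
            child = next(fp_children)
            name = region_name(side, direction)
            fg = fg_regions[(side, direction)]
            if not fg:
                log.warning("skipping empty region %s", name)
                continue
            rounds = [
                [side_flanks(bg.event_ids, side) for bg in rnd] for rnd in rounds_events
            ]
            table = kmer_enrichment(
                fg, background_rounds=rounds, k=k, gc_edges=gc_edges[side]
            )
            ranking = rank_kmers(table)
            results, audit = fingerprint_region(
                ranking,
                motifs,
                k=k,
                score_threshold=score_threshold,
                n_permutations=n_permutations,
                seed=int(np.random.default_rng(child).integers(2**31)),
                allow_list=allow_list,
                region_class=name,
            )
            tables[(k, name)] = table
            rankings[(k, name)] = ranking
            fingerprints[(k, name)] = results
            fp_audit[f"{k}:{name}"] = audit

    summaries = {
        k: summarize_regions(
            {name: res for (kk, name), res in fingerprints.items() if kk == k},
            {name: tab for (kk, name), tab in tables.items() if kk == k},
            motifs,
            k=k,
            score_threshold=score_threshold,
        )
        for k in k_list
    }

    funnel = {
        "events_total": len(events),
        "events_with_comparisons": len({e for e, _ in idx}),
        **{f"retained_{rule}": c for rule, c in report.counts().items()},
        "analysis_tier_size": len(tier_set),
        "background_pool": len(pool_ids),
        **{
            f"region_{region_name(s, d)}": len(fg_regions[(s, d)])
            for s, d in REGION_CLASSES
        },
    }
    return AnalysisResult(
        report=report,
        foreground_regions=fg_regions,
        backgrounds=backgrounds,
        pool_ids=pool_ids,
        tables=tables,
        rankings=rankings,
        fingerprints=fingerprints,
        summaries=summaries,
        funnel=funnel,
        audits={"foreground_flanks": fg_audit, "pool_flanks": pool_audit, "fingerprint": fp_audit},
    )


def _write_fingerprints(results: Sequence[FingerprintResult], path: Path) -> None:
    rows = [
        {
            "motif_id": r.motif_id,
            "rbp_ids": ";".join(r.rbp_ids),
            "es": r.es,
            "p_value": r.p_value,
            "fdr": r.fdr,
            "n_members": r.n_members,
            "leading_edge": ",".join(r.leading_edge),
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> AnalysisResult:
    """Load inputs, run :func:`analyze`, and write all reports under ``outdir``.

    On a stage failure a ``FAILED.partial`` marker naming the stage is left
    in ``outdir`` and the error re-raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load_inputs"
    try:
        events = read_events(config.events)
        comparisons = read_comparisons(config.comparisons)
        expression = read_expression(config.expression)
        genome = GenomeSequence.from_fasta(config.genome)
        motifs = read_motif_db(config.motif_db)
        log.info("loaded %d events, %d comparison records, %d motifs",
                 len(events), len(comparisons), len(motifs))

        stage = "analyze"
        result = analyze(
            events, comparisons, expression, genome, motifs, config.roles,
            selection=config.selection,
            background=config.background,
            k_list=config.k_list,
            iterations=config.iterations,
            n_permutations=config.n_permutations,
            flank_len=config.flank_len,
            fpkm_floor=config.fpkm_floor,
            score_threshold=config.score_threshold,
            analysis_tier=config.analysis_tier,
            allow_list=config.allow_list,
            seed=config.seed,
        )

        stage = "write_outputs"
        sel_dir = outdir / "selection"
        sel_dir.mkdir(exist_ok=True)
        for rule in ("flow", "endothelial", "platelet", "in_vitro", "rbfox2"):
            getattr(result.report, rule).audit.to_csv(
                sel_dir / f"{rule}.tsv", sep="\t", index=False
            )
        flank_dir = outdir / "flanks"
        flank_dir.mkdir(exist_ok=True)
        all_fg = [fl for lst in result.foreground_regions.values() for fl in lst]
        write_flank_fasta(all_fg, flank_dir / "foreground.fa")
        write_flank_bed(all_fg, flank_dir / "foreground.bed")
        bg_dir = outdir / "backgrounds"
        bg_dir.mkdir(exist_ok=True)
        for bg in result.backgrounds:
            pd.DataFrame(
                {
                    "event_id": bg.event_ids,
                    "stratum": [str(bg.strata.get(e)) for e in bg.event_ids],
                    "set_id": bg.set_id,
                }
            ).to_csv(bg_dir / f"set_{bg.set_id}.tsv", sep="\t", index=False)
        kmer_dir = outdir / "kmer"
        kmer_dir.mkdir(exist_ok=True)
        for (k, name), table in result.tables.items():
            table.to_frame().to_csv(kmer_dir / f"k{k}_{name}.tsv", sep="\t", index=False)
        fp_dir = outdir / "fingerprint"
        fp_dir.mkdir(exist_ok=True)
        for (k, name), res in result.fingerprints.items():
            _write_fingerprints(res, fp_dir / f"k{k}_{name}.tsv")
        for k, df in result.summaries.items():
            df.to_csv(outdir / f"summary_k{k}.tsv", sep="\t", index=False)

        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(
                json.dumps(config.canonical_dict(), sort_keys=True).encode()
            ).hexdigest(),
            "funnel": result.funnel,
        }
        with open(outdir / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:
        (outdir / "FAILED.partial").write_text(f"stage={stage}\nerror={exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    marker = outdir / "FAILED.partial"
    if marker.exists():
        marker.unlink()
    return result
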