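"""Matched background construction and GC binning.

Regulated cassette exons differ systematically from the bulk of annotated
skipped exons: they sit more often at intermediate inclusion (Psi near 0.5)
and come from more highly expressed genes.  Naive backgrounds would therefore
confound motif enrichment with expression and Psi composition.  This module
draws several (default six) background sets from the expressed-but-unregulated
pool such that each set reproduces the foreground's joint histogram over
expression deciles and |Psi - 0.5| strata.

k-mer frequencies are additionally compared within GC bins (default ten),
whose edges are quantiles of the pooled background flank GC content, so that
GC composition differences cannot masquerade as motif enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .flank_extract import FlankRegion
from .splice_events import SplicingEvent, ValidationError

log = logging.getLogger(__name__)


@dataclass
class BackgroundSpec:
    """How background sets are matched and GC bins built."""

    n_sets: int = 6
    expression_strata: int = 10
    psi_strata: int = 5
    n_gc_bins: int = 10
    match_mode: str = "joint"  # "joint" (default, stricter) or "marginal"

    def __post_init__(self) -> None:
        for name in ("n_sets", "expression_strata", "psi_strata", "n_gc_bins"):
            if getattr(self, name) < 1:
                raise ValidationError(f"BackgroundSpec.{name} must be >= 1")
        if self.match_mode not in ("joint", "marginal"):
            raise ValidationError("match_mode must be 'joint' or 'marginal'")


@dataclass
class MatchedBackground:
    set_id: int
    event_ids: list[str]
    # per sampled event, the foreground stratum (expr_stratum, psi_stratum) it matches
    strata: dict[str, tuple[int, int]]


def eligible_pool(
    events: Sequence[SplicingEvent],
    expression: Mapping[str, float],
    foreground_ids: set[str],
    fpkm_floor: float = 1.0,
) -> list[str]:
    """Annotated SE events from expressed genes that are not flow-regulated.

    Event order is preserved.  Events without an expression value for their
    gene are excluded (treated as not expressed).
    """
    pool = [
        ev.event_id
        for ev in events
        if ev.event_class == "SE"
        and ev.event_id not in foreground_ids
        and expression.get(ev.gene_id, 0.0) >= fpkm_floor
    ]
    if not pool:
        raise ValidationError("eligible background pool is empty")
    return pool


def quantile_edges(values: Sequence[float], n_bins: int) -> np.ndarray:
    """Interior quantile edges for ``n_bins`` bins; duplicate edges collapse."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("cannot compute quantile edges of no values")
    qs = np.arange(1, n_bins) / n_bins
    edges = np.quantile(values, qs)
    uniq = np.unique(edges)
    if uniq.size < edges.size:
        log.warning(
            "fewer distinct values than bins: collapsing %d edges to %d", edges.size, uniq.size
        )
    return uniq


def assign_bins(values: Sequence[float], edges: np.ndarray) -> np.ndarray:
    """Bin index per value; a value equal to an edge goes to the lower bin."""
    return np.searchsorted(np.asarray(edges, dtype=float), np.asarray(values, dtype=float), side="left")


def gc_bin_edges(background_flanks: Iterable[FlankRegion], n_bins: int) -> np.ndarray:
    """GC-bin edges from the pooled background flanks (quantile bins)."""
    gcs = [fl.gc for fl in background_flanks]
    if not gcs:
        raise ValidationError("no background flanks to derive GC bins from")
    return quantile_edges(gcs, n_bins)


def _strata_of(
    ids: Sequence[str],
    expression_by_event: Mapping[str, float],
    psi_by_event: Mapping[str, float],
    expr_edges: np.ndarray,
    psi_edges: np.ndarray,
) -> dict[str, tuple[int, int]]:
    expr = assign_bins([expression_by_event[e] for e in ids], expr_edges)
    psi = assign_bins([abs(psi_by_event[e] - 0.5) for e in ids], psi_edges)
    return {e: (int(a), int(b)) for e, a, b in zip(ids, expr, psi)}


def sample_matched_backgrounds(
    pool_ids: Sequence[str],
    foreground_ids: Sequence[str],
    expression_by_event: Mapping[str, float],
    psi_by_event: Mapping[str, float],
    spec: BackgroundSpec | None = None,
    rng: np.random.Generator | int | None = None,
    warn: bool = True,
) -> list[MatchedBackground]:
    """Draw ``spec.n_sets`` background sets matching the foreground's joint
    (expression-decile x |Psi-0.5|-stratum) histogram.

    Stratum edges are quantiles of the pool.  Sampling is without replacement
    within a set; when a foreground stratum has too few pool events the
    deficit is drawn with replacement from the nearest nonempty stratum
    (Manhattan distance on stratum indices), with a logged warning.  Sets are
    sampled independently and may overlap each other but never the
    foreground.
    """
    spec = spec or BackgroundSpec()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if not pool_ids:
        raise ValidationError("background pool is empty")
    if not foreground_ids:
        raise ValidationError("foreground is empty")
    overlap = set(pool_ids) & set(foreground_ids)
    if overlap:
        raise ValidationError(f"pool overlaps foreground: {sorted(overlap)[:3]}...")

    expr_edges = quantile_edges([expression_by_event[e] for e in pool_ids], spec.expression_strata)
    psi_edges = quantile_edges([abs(psi_by_event[e] - 0.5) for e in pool_ids], spec.psi_strata)
    fg_strata = _strata_of(foreground_ids, expression_by_event, psi_by_event, expr_edges, psi_edges)
    pool_strata = _strata_of(pool_ids, expression_by_event, psi_by_event, expr_edges, psi_edges)

    if spec.match_mode == "marginal":
        # match each marginal independently: alternate which axis defines the
        # stratum by collapsing the other one
        fg_cells = {e: (a, 0) for e, (a, b) in fg_strata.items()}
        pool_cells_map = {e: (a, 0) for e, (a, b) in pool_strata.items()}
    else:
        fg_cells = fg_strata
        pool_cells_map = pool_strata

    pool_by_cell: dict[tuple[int, int], np.ndarray] = {}
    for e, cell in pool_cells_map.items():
        pool_by_cell.setdefault(cell, []).append(e)  # type: ignore[arg-type]
    pool_by_cell = {c: np.asarray(v, dtype=object) for c, v in pool_by_cell.items()}

    fg_counts: dict[tuple[int, int], int] = {}
    for cell in fg_cells.values():
        fg_counts[cell] = fg_counts.get(cell, 0) + 1

    nonempty = sorted(pool_by_cell)
    warned = False
    backgrounds: list[MatchedBackground] = []
    for set_id in range(1, spec.n_sets + 1):
        chosen: list[str] = []
        strata: dict[str, tuple[int, int]] = {}
        for cell in sorted(fg_counts):
            need = fg_counts[cell]
            avail = pool_by_cell.get(cell, np.asarray([], dtype=object))
            if len(avail) >= need:
                picks = rng.choice(avail, size=need, replace=False)
            else:
                picks = list(avail)
                deficit = need - len(avail)
                # fall back to the nearest nonempty stratum, with replacement
                others = [c for c in nonempty if c != cell] or nonempty
                nearest = min(others, key=lambda c: (abs(c[0] - cell[0]) + abs(c[1] - cell[1]), c))
                if not warned:
                    (log.warning if warn else log.debug)(
                        "stratum %s has %d pool events for %d foreground events; "
                        "sampling deficit with replacement from %s",
                        cell, len(avail), need, nearest,
                    )
                    warned = True
                picks = np.concatenate(
                    [picks, rng.choice(pool_by_cell[nearest], size=deficit, replace=True)]
                )
            for e in picks:
                chosen.append(str(e))
                strata[str(e)] = cell
        backgrounds.append(MatchedBackground(set_id=set_id, event_ids=chosen, strata=strata))
    return backgrounds
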