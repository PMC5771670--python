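"""GC-bin-normalized k-mer enrichment of foreground versus matched backgrounds.

For each k-mer m, GC bin b and background set s the per-bin enrichment is

    e(m, b, s) = log2( (f_fg(m, b) + p) / (f_bg(m, b, s) + p) )
                 - log2( E_fg(m, b) / E_bg(m, b, s) )        [default]

where f are within-bin k-mer *frequencies* (counts over total counted
windows, so foreground/background size imbalance cancels) and p is a
pseudo-frequency, 1 over the smaller of the two window totals in that bin.
The second term is a composition correction: E(m, .) is the k-mer's
expected frequency under a low-order background model fitted to the region
set's own within-bin sequence (``composition_order=1``, a first-order
Markov chain, by default; 0 for mononucleotide; None disables the
correction).  Flank-level composition fluctuations (residual GC inside a
bin, A/T skew, dinucleotide content) move all compositionally similar
k-mers coherently; because motif member sets are compositionally
clustered, that coherence would otherwise inflate fingerprint enrichment
against a random-k-mer null.  Estimating the expectation from the very
same windows cancels the realized fluctuation while leaving genuine
site-level k-mer enrichment intact.
Per-set scores are pooled across bins with weights w_b equal to the
foreground k-mer mass in bin b,

    E(m, s) = sum_b w_b * e(m, b, s),

and the enrichment z-score is mean_s E(m, s) / sd_s E(m, s) (sample sd).  A
k-mer with zero spread across sets has an undefined z (reported missing and
excluded from ranking) unless its mean is also exactly zero, in which case
z = 0 (the foreground-identical-to-background identity case).

Because the matched background sets are themselves a random draw, the whole
computation can be iterated over freshly resampled background sets
(``background_rounds`` / ``sampler``) with z averaged across rounds.

Counting rules: occurrences may overlap; any window containing an N is
skipped entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .background_match import assign_bins, quantile_edges
from .flank_extract import FlankRegion
from .splice_events import ValidationError

log = logging.getLogger(__name__)

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _BASE_CODE[ord(b)] = i
    _BASE_CODE[ord(b.lower())] = i


def encode_sequence(seq: str) -> np.ndarray:
    """DNA string -> int8 codes (A=0, C=1, G=2, T=3, anything else -1)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@lru_cache(maxsize=8)
def kmer_strings(k: int) -> tuple[str, ...]:
    """All 4**k k-mers in code (= lexicographic) order."""
    bases = "ACGT"
    out = [""]
    for _ in range(k):
        out = [s + b for s in out for b in bases]
    return tuple(out)


def _sequence_of(region) -> str:
    return region.sequence if isinstance(region, FlankRegion) else str(region)


def count_vector(region, k: int) -> tuple[np.ndarray, int, np.ndarray]:
    """(k-mer counts over all 4**k k-mers, number of valid windows, base
    counts over ACGT) for one sequence.

    Results are cached on :class:`FlankRegion` instances.
    """
    if isinstance(region, FlankRegion):
        hit = region._kmer_cache.get(k)
        if hit is not None:
            return hit
    seq = _sequence_of(region)
    codes = encode_sequence(seq)
    bases = np.bincount(codes[codes >= 0], minlength=4).astype(np.int64)
    n = codes.size - k + 1
    if n <= 0:
        result = (np.zeros(4**k, dtype=np.int32), 0, bases)
    else:
        win = np.lib.stride_tricks.sliding_window_view(codes, k)
        valid = ~(win < 0).any(axis=1)
        pow4 = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        idx = win[valid].astype(np.int64) @ pow4
        result = (np.bincount(idx, minlength=4**k).astype(np.int32), int(valid.sum()), bases)
    if isinstance(region, FlankRegion):
        region._kmer_cache[k] = result
    return result


def count_kmers(regions: Iterable, k: int) -> dict[str, int]:
    """Total k-mer occurrence counts over a collection of sequences.

    Overlapping occurrences are counted; windows containing N are skipped.
    Returns only k-mers with nonzero counts.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    total = np.zeros(4**k, dtype=np.int64)
    windows = 0
    for r in regions:
        c, w, _ = count_vector(r, k)
        total += c
        windows += w
    if windows == 0:
        log.warning("no countable %d-mer windows in any region", k)
    names = kmer_strings(k)
    nz = np.nonzero(total)[0]
    return {names[i]: int(total[i]) for i in nz}


def _binned_counts(
    regions: Sequence, k: int, bins: np.ndarray, n_bins: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin k-mer count matrix (n_bins x 4**k), per-bin window totals,
    per-bin base counts (n_bins x 4) and dinucleotide counts (n_bins x 16)."""
    counts = np.zeros((n_bins, 4**k), dtype=np.float64)
    windows = np.zeros(n_bins, dtype=np.float64)
    base_counts = np.zeros((n_bins, 4), dtype=np.float64)
    dinuc_counts = np.zeros((n_bins, 16), dtype=np.float64)
    for r, b in zip(regions, bins):
        c, w, bc = count_vector(r, k)
        counts[b] += c
        windows[b] += w
        base_counts[b] += bc
        dinuc_counts[b] += count_vector(r, 2)[0]
    return counts, windows, base_counts, dinuc_counts


@lru_cache(maxsize=8)
def _kmer_comp_matrices(k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-k-mer composition designs: base counts (4**k x 4), first-base
    one-hot (4**k x 4), prefix base counts over positions 0..k-2 (4**k x 4),
    and dinucleotide counts (4**k x 16)."""
    idx = np.arange(4**k)
    digits = (idx[:, None] // (4 ** np.arange(k - 1, -1, -1))) % 4
    base = np.stack([(digits == b).sum(axis=1) for b in range(4)], axis=1).astype(np.float64)
    first = np.zeros((4**k, 4))
    first[idx, digits[:, 0]] = 1.0
    prefix = np.stack(
        [(digits[:, :-1] == b).sum(axis=1) for b in range(4)], axis=1
    ).astype(np.float64)
    pairs = digits[:, :-1] * 4 + digits[:, 1:]
    dinuc = np.stack([(pairs == d).sum(axis=1) for d in range(16)], axis=1).astype(np.float64)
    return base, first, prefix, dinuc


def _log_expected(
    base_counts_row: np.ndarray, dinuc_counts_row: np.ndarray, k: int, order: int
) -> np.ndarray:
    """log2 expected frequency of every k-mer under an order-0 (i.i.d. base)
    or order-1 (Markov chain) model fitted, with add-one smoothing, to one
    bin's base and dinucleotide counts."""
    base_m, first_m, prefix_m, dinuc_m = _kmer_comp_matrices(k)
    f1 = np.log2((base_counts_row + 1.0) / (base_counts_row.sum() + 4.0))
    if order == 0:
        return base_m @ f1
    f2 = np.log2((dinuc_counts_row + 1.0) / (dinuc_counts_row.sum() + 16.0))
    # log E = log f1(b1) + sum_i log f2(b_{i-1} b_i) / f1(b_{i-1})
    return first_m @ f1 + dinuc_m @ f2 - prefix_m @ f1


@dataclass
class KmerTable:
    """Per-k-mer enrichment results for one analysis region."""

    k: int
    z: np.ndarray  # 4**k, NaN where undefined
    fg_freq: np.ndarray  # n_bins x 4**k foreground frequency per GC bin
    bg_freq_mean: np.ndarray  # 4**k, bin-weight-pooled mean background frequency
    weights: np.ndarray  # n_bins, foreground k-mer mass per bin
    gc_edges: np.ndarray
    n_sets: int
    n_iterations: int

    @property
    def kmers(self) -> tuple[str, ...]:
        return kmer_strings(self.k)

    def z_of(self, kmer: str) -> float:
        return float(self.z[self.kmers.index(kmer)])

    def to_frame(self) -> pd.DataFrame:
        pooled_fg = self.weights @ self.fg_freq if self.fg_freq.size else np.zeros(4**self.k)
        return pd.DataFrame(
            {
                "kmer": self.kmers,
                "z": self.z,
                "fg_freq": pooled_fg,
                "bg_freq_mean": self.bg_freq_mean,
                "n_iterations": self.n_iterations,
            }
        )


def _region_gc(regions: Sequence) -> np.ndarray:
    out = []
    for r in regions:
        if isinstance(r, FlankRegion):
            out.append(r.gc)
        else:
            from .flank_extract import gc_fraction

            out.append(gc_fraction(str(r)))
    return np.asarray(out)


def kmer_enrichment(
    foreground: Sequence,
    background_sets: Sequence[Sequence] | None = None,
    *,
    background_rounds: Sequence[Sequence[Sequence]] | None = None,
    sampler: Callable[[np.random.Generator], Sequence[Sequence]] | None = None,
    iterations: int = 1,
    k: int = 6,
    gc_edges: np.ndarray | None = None,
    n_gc_bins: int = 10,
    seed: int | None = None,
    centered: bool = False,
    composition_order: int | None = 1,
) -> KmerTable:
    """Compute GC-normalized enrichment z-scores (see module docstring).

    Exactly one background source must be given: ``background_sets`` (a single
    round of >= 2 sets), ``background_rounds`` (pre-drawn rounds, each a list
    of sets), or ``sampler`` (called ``iterations`` times with a seeded
    generator).  ``gc_edges`` defaults to quantile edges of the first round's
    pooled background GC.  ``composition_order`` selects the within-bin
    composition correction (1 = Markov-1 default, 0 = mononucleotide,
    None = plain frequency ratio; see module docstring).
    """
    if sum(x is not None for x in (background_sets, background_rounds, sampler)) != 1:
        raise ValidationError("give exactly one of background_sets, background_rounds, sampler")
    if sampler is not None:
        rng = np.random.default_rng(seed)
        rounds = [sampler(rng) for _ in range(iterations)]
    elif background_rounds is not None:
        rounds = list(background_rounds)
    else:
        rounds = [background_sets]
    if not rounds or any(len(rnd) < 2 for rnd in rounds):
        raise ValidationError("each background round needs >= 2 background sets")
    if len(foreground) == 0:
        raise ValidationError("foreground region set is empty")

    if gc_edges is None:
        pooled_gc = np.concatenate([_region_gc(s) for s in rounds[0]])
        gc_edges = quantile_edges(pooled_gc, n_gc_bins)
    gc_edges = np.asarray(gc_edges, dtype=float)
    n_bins = gc_edges.size + 1
    m = 4**k

    if composition_order not in (None, 0, 1):
        raise ValidationError("composition_order must be None, 0 or 1")
    adjust = composition_order is not None
    fg_bins = assign_bins(_region_gc(foreground), gc_edges)
    fg_counts, fg_w, fg_bases, fg_dinucs = _binned_counts(foreground, k, fg_bins, n_bins)
    if fg_w.sum() == 0:
        raise ValidationError("foreground has no countable k-mer windows")
    weights = fg_w / fg_w.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        fg_freq = np.where(fg_w[:, None] > 0, fg_counts / np.maximum(fg_w, 1)[:, None], 0.0)

    active = np.nonzero(fg_w > 0)[0]
    fg_log_exp = (
        {b: _log_expected(fg_bases[b], fg_dinucs[b], k, composition_order) for b in active}
        if adjust
        else {}
    )

    z_sum = np.zeros(m)
    z_n = np.zeros(m, dtype=np.int64)
    bg_pooled_sum = np.zeros(m)
    bg_pooled_n = 0
    for rnd in rounds:
        n_sets = len(rnd)
        E = np.zeros((m, n_sets))
        bg_freqs = np.zeros((n_sets, n_bins, m))
        bg_ws = np.zeros((n_sets, n_bins))
        bg_bases_all = np.zeros((n_sets, n_bins, 4))
        bg_dinucs_all = np.zeros((n_sets, n_bins, 16))
        for si, bset in enumerate(rnd):
            if len(bset) == 0:
                raise ValidationError("empty background set")
            bg_bins = assign_bins(_region_gc(bset), gc_edges)
            bg_counts, bg_w, bg_bases, bg_dinucs = _binned_counts(bset, k, bg_bins, n_bins)
            bg_ws[si] = bg_w
            bg_bases_all[si] = bg_bases
            bg_dinucs_all[si] = bg_dinucs
            for b in active:
                if bg_w[b] > 0:
                    p = 1.0 / min(fg_w[b], bg_w[b])
                    f_bg = bg_counts[b] / bg_w[b]
                else:
                    p = 1.0 / fg_w[b]
                    f_bg = np.zeros(m)
                bg_freqs[si, b] = f_bg
                e = np.log2((fg_freq[b] + p) / (f_bg + p))
                if adjust:
                    e = e - (
                        fg_log_exp[b]
                        - _log_expected(bg_bases[b], bg_dinucs[b], k, composition_order)
                    )
                E[:, si] += weights[b] * e
                bg_pooled_sum += weights[b] * f_bg
            bg_pooled_n += 1
        sd = E.std(axis=1, ddof=1)
        if centered:
            # score the foreground against the across-set mean background
            score = np.zeros(m)
            f_bg_mean = bg_freqs.mean(axis=0)
            w_bg_mean = bg_ws.mean(axis=0)
            for b in active:
                denom = min(fg_w[b], w_bg_mean[b]) if w_bg_mean[b] > 0 else fg_w[b]
                p = 1.0 / denom
                e = np.log2((fg_freq[b] + p) / (f_bg_mean[b] + p))
                if adjust:
                    e = e - (
                        fg_log_exp[b]
                        - _log_expected(
                            bg_bases_all[:, b].mean(axis=0),
                            bg_dinucs_all[:, b].mean(axis=0),
                            k,
                            composition_order,
                        )
                    )
                score += weights[b] * e
            mean = score
        else:
            mean = E.mean(axis=1)
        z_round = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.nan)
        # identity case: no spread and no signal -> define z = 0
        z_round = np.where((sd == 0) & (mean == 0), 0.0, z_round)
        ok = ~np.isnan(z_round)
        z_sum[ok] += z_round[ok]
        z_n += ok
    with np.errstate(invalid="ignore"):
        z = np.where(z_n > 0, z_sum / np.maximum(z_n, 1), np.nan)
    n_missing = int(np.isnan(z).sum())
    if n_missing:
        log.info("%d of %d %d-mers have undefined z (no spread across sets)", n_missing, m, k)
    return KmerTable(
        k=k,
        z=z,
        fg_freq=fg_freq,
        bg_freq_mean=bg_pooled_sum / max(bg_pooled_n, 1),
        weights=weights,
        gc_edges=gc_edges,
        n_sets=len(rounds[0]),
        n_iterations=len(rounds),
    )


def rank_kmers(table: KmerTable) -> list[str]:
    """K-mers ordered by descending z; ties broken lexicographically.

    K-mers with undefined z are dropped (logged).  Raises if no k-mer has a
    defined z.
    """
    defined = np.nonzero(~np.isnan(table.z))[0]
    if defined.size == 0:
        raise ValidationError("no k-mer has a defined z-score; cannot rank")
    names = table.kmers
    # lexicographic order == index order, so a stable sort on -z suffices
    order = defined[np.argsort(-table.z[defined], kind="stable")]
    dropped = 4**table.k - defined.size
    if dropped:
        log.info("rank_kmers: dropped %d k-mers with undefined z", dropped)
    return [names[i] for i in order]
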