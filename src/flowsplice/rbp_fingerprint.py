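"""RNA-binding-protein motif fingerprints against a ranked k-mer list.

A motif catalogue (CisBP-RNA-like plain text, one position weight matrix per
motif, possibly shared by several proteins) is bridged to the k-mer ranking
by deriving each motif's *member k-mer set*: a k-mer belongs to a motif iff
its best log-odds score (base-2, versus a uniform background) over all
k-wide windows of the matrix reaches ``score_threshold`` times that window's
maximum attainable score.  Matrices shorter than k are padded with uniform
columns on both sides, so any alignment of the motif inside the k-mer
counts; U and T are interconverted at the RNA/DNA boundary.

Each motif's fingerprint is then tested with the unweighted GSEA-style
Kolmogorov-Smirnov statistic: walking down the ranked k-mer list, member
hits add 1/Nh and misses subtract 1/(N-Nh); the enrichment score ES is the
running sum's deviation of maximum magnitude (signed).  Significance comes
from a permutation null of size-matched random member sets drawn from the
ranked universe; null sets additionally preserve the member set's internal
count-covariance (overlapping k-mers share occurrence windows, see
:func:`_shift_correlation`), without which clustered member sets would be
anticonservative.  The test is one-sided for leading-edge abundance: with
the add-one estimator, p = (1 + #{ES_null >= ES_obs}) / (1 +
n_permutations) on the signed ES, so depleted fingerprints score p near 1.
Benjamini-Hochberg FDR is applied across motifs within each analysis
region.

Catalogue grammar (blocks separated by blank lines)::

    Motif <motif_id> <rbp1;rbp2;...>
    Pos A C G U
    1 0.97 0.01 0.01 0.01
    ...
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .kmer_enrich import KmerTable, kmer_strings
from .splice_events import ValidationError

log = logging.getLogger(__name__)

_ROW_SUM_TOL = 1e-3
_RNA_COLS = ("A", "C", "G", "U")


@dataclass
class MotifModel:
    """One RBP motif: a position weight matrix over (A, C, G, U)."""

    motif_id: str
    rbp_ids: tuple[str, ...]
    matrix: np.ndarray  # L x 4 probabilities
    member_kmers: frozenset[str] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 1:
            raise ValidationError(f"motif {self.motif_id}: matrix must be L x 4 with L >= 1")
        if (self.matrix < 0).any():
            raise ValidationError(f"motif {self.motif_id}: negative probabilities")
        bad = np.nonzero(np.abs(self.matrix.sum(axis=1) - 1.0) > _ROW_SUM_TOL)[0]
        if bad.size:
            raise ValidationError(
                f"motif {self.motif_id}: row {bad[0] + 1} does not sum to 1"
            )

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


def read_motif_db(path: str | Path) -> list[MotifModel]:
    """Parse a plain-text PWM catalogue (grammar in the module docstring)."""
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    motifs: list[MotifModel] = []
    seen: set[str] = set()
    i = 0
    n = len(lines)
    while i < n:
        if not lines[i].strip():
            i += 1
            continue
        head = lines[i].split()
        if len(head) != 3 or head[0] != "Motif":
            raise ValidationError(f"{path}:{i + 1}: expected 'Motif <id> <rbps>' header")
        motif_id = head[1]
        if motif_id in seen:
            raise ValidationError(f"{path}:{i + 1}: duplicate motif id {motif_id!r}")
        seen.add(motif_id)
        rbp_ids = tuple(head[2].split(";"))
        i += 1
        if i >= n or lines[i].split() != ["Pos", "A", "C", "G", "U"]:
            raise ValidationError(f"{path}:{i + 1}: motif {motif_id}: expected 'Pos A C G U' line")
        i += 1
        rows = []
        while i < n and lines[i].strip():
            fields = lines[i].split()
            if len(fields) != 5:
                raise ValidationError(
                    f"{path}:{i + 1}: motif {motif_id} row {len(rows) + 1}: expected 5 fields"
                )
            try:
                row = [float(x) for x in fields[1:]]
            except ValueError as exc:
                raise ValidationError(
                    f"{path}:{i + 1}: motif {motif_id} row {len(rows) + 1}: non-numeric value"
                ) from exc
            if abs(sum(row) - 1.0) > _ROW_SUM_TOL:
                raise ValidationError(
                    f"motif {motif_id} row {len(rows) + 1} does not sum to 1 (got {sum(row):.4f})"
                )
            rows.append(row)
            i += 1
        try:
            motifs.append(MotifModel(motif_id=motif_id, rbp_ids=rbp_ids, matrix=np.asarray(rows)))
        except ValidationError:
            raise
    if not motifs:
        raise ValidationError(f"{path}: no motifs found")
    return motifs


def write_motif_db(motifs: Iterable[MotifModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f"Motif {m.motif_id} {';'.join(m.rbp_ids)}\n")
            fh.write("Pos A C G U\n")
            for i, row in enumerate(m.matrix, start=1):
                fh.write(f"{i} " + " ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


@lru_cache(maxsize=8)
def _kmer_digits(k: int) -> np.ndarray:
    """(4**k, k) matrix of base codes for every k-mer, in lexicographic order."""
    idx = np.arange(4**k)
    return (idx[:, None] // (4 ** np.arange(k - 1, -1, -1))) % 4


def pwm_kmer_set(motif: MotifModel, k: int = 6, score_threshold: float = 0.8) -> frozenset[str]:
    """Member k-mers of a motif (see module docstring for the rule).

    May be empty, in which case the motif is unusable for fingerprinting.
    """
    if not (0 < score_threshold <= 1):
        raise ValidationError("score_threshold must be in (0, 1]")
    mat = motif.matrix
    if mat.shape[0] < k:
        pad = np.full((k - mat.shape[0], 4), 0.25)
        mat = np.vstack([pad, mat, pad])
    with np.errstate(divide="ignore"):
        lo = np.log2(mat / 0.25)  # -inf where p == 0
    digits = _kmer_digits(k)
    names = kmer_strings(k)
    member = np.zeros(4**k, dtype=bool)
    for start in range(mat.shape[0] - k + 1):
        w = lo[start : start + k]  # k x 4
        scores = w[np.arange(k)[None, :], digits].sum(axis=1)
        best = w.max(axis=1).sum()
        member |= scores >= score_threshold * best - 1e-9
    return frozenset(names[i] for i in np.nonzero(member)[0])


@dataclass
class KSResult:
    es: float
    es_index: int  # 0-based position of the running-sum extremum
    profile: np.ndarray
    leading_edge: tuple[str, ...]


def ks_enrichment_score(ranked_kmers: Sequence[str], member_set: Iterable[str]) -> KSResult:
    """Unweighted GSEA running-sum statistic of a member set in a ranking.

    ES is the signed deviation of maximum magnitude (first such position on
    ties).  The leading edge is the members at or before the extremum for
    positive ES, and at or after it for negative ES.
    """
    members = set(member_set)
    n = len(ranked_kmers)
    hits = np.fromiter((km in members for km in ranked_kmers), dtype=bool, count=n)
    nh = int(hits.sum())
    if nh == 0 or nh == n:
        raise ValidationError(
            f"degenerate member set: {nh} of {n} ranked k-mers are members"
        )
    steps = np.where(hits, 1.0 / nh, -1.0 / (n - nh))
    profile = np.cumsum(steps)
    # first position attaining the maximum magnitude (tolerance guards exact
    # ties such as -1/3 then +1/3 against cumsum rounding)
    absprof = np.abs(profile)
    i = int(np.argmax(absprof >= absprof.max() - 1e-12))
    es = float(profile[i])
    if es >= 0:
        edge = tuple(km for j, km in enumerate(ranked_kmers[: i + 1]) if hits[j])
    else:
        edge = tuple(km for j, km in enumerate(ranked_kmers) if j >= i and hits[j])
    return KSResult(es=es, es_index=i, profile=profile, leading_edge=edge)


def _es_from_positions(pos: np.ndarray, n: int) -> np.ndarray:
    """Signed ES per row of sorted 0-based hit positions in a length-n ranking."""
    m = pos.shape[1]
    j = np.arange(m, dtype=float)
    # running-sum value just after and just before each hit
    after = (j + 1.0) / m - (pos + 1.0 - (j + 1.0)) / (n - m)
    before = j / m - (pos - j) / (n - m)
    cand = np.concatenate([after, before], axis=1)
    idx = np.argmax(np.abs(cand), axis=1)
    return np.take_along_axis(cand, idx[:, None], axis=1)[:, 0]


def _shift_correlation(members: Sequence[str]) -> np.ndarray:
    """Pairwise rank-score correlation implied by k-mer overlap counting.

    Two k-mers that are offset copies of one another (the last k-d bases of
    one equal the first k-d bases of the other) share every occurrence of
    the merged (k+d)-mer, so their counts carry covariance ~ 4**-d of the
    count variance.  Member sets derived from one PWM are full of such
    pairs (windows of a common consensus), which makes them score-correlated
    even when the ranking is pure noise; an independence null would
    understate their ES spread.
    """
    m = len(members)
    k = len(members[0]) if m else 0
    corr = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            rho = 0.0
            for d in range(1, k):
                if members[i][d:] == members[j][: k - d]:
                    rho += 4.0 ** (-d)
                if members[j][d:] == members[i][: k - d]:
                    rho += 4.0 ** (-d)
            corr[i, j] = corr[j, i] = min(rho, 0.99)
    return corr


def _null_es(
    n: int,
    members: Sequence[str] | int,
    n_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Signed ES of ``n_draws`` random size-matched member sets.

    Given the member k-mers themselves (rather than just a size), null rank
    vectors are drawn through a Gaussian copula with the overlap-implied
    correlation of :func:`_shift_correlation`, so the null preserves the
    set's internal count-covariance structure; marginally each null rank is
    uniform on the ranking.
    """
    from scipy.stats import norm

    if isinstance(members, int):
        m = members
        corr = None
    else:
        m = len(members)
        corr = _shift_correlation(members)
        if np.allclose(corr, np.eye(m)):
            corr = None
    if corr is None:
        pos = rng.integers(0, n, size=(n_draws, m))
        if m > 1:
            while True:
                pos.sort(axis=1)
                dup = (np.diff(pos, axis=1) == 0).any(axis=1)
                if not dup.any():
                    break
                pos[dup] = rng.integers(0, n, size=(int(dup.sum()), m))
    else:
        try:
            chol = np.linalg.cholesky(corr)
        except np.linalg.LinAlgError:
            w, v = np.linalg.eigh(corr)
            chol = v @ np.diag(np.sqrt(np.clip(w, 1e-9, None)))
        g = rng.standard_normal((n_draws, m)) @ chol.T
        u = norm.cdf(g)
        pos = np.minimum((u * n).astype(np.int64), n - 1)
        pos.sort(axis=1)
        if m > 1:
            # separate collided ranks while keeping order
            for col in range(1, m):
                pos[:, col] = np.maximum(pos[:, col], pos[:, col - 1] + 1)
            pos = np.minimum(pos, n - m + np.arange(m))
    return _es_from_positions(pos.astype(float), n)


@dataclass
class FingerprintResult:
    motif_id: str
    rbp_ids: tuple[str, ...]
    region_class: str
    es: float
    p_value: float
    fdr: float
    n_members: int
    leading_edge: tuple[str, ...]


def fingerprint_region(
    ranked_kmers: Sequence[str],
    motifs: Sequence[MotifModel],
    *,
    k: int = 6,
    score_threshold: float = 0.8,
    n_permutations: int = 1000,
    seed: int | None = None,
    allow_list: Iterable[str] | None = None,
    region_class: str = "",
) -> tuple[list[FingerprintResult], list[str]]:
    """Fingerprint every usable motif against one region's ranked k-mer list.

    Each motif gets its own size-matched permutation null (independent
    draws; sharing nulls between same-size motifs would correlate their
    p-values in the extreme tail).  Returns the results (sorted by motif_id,
    FDR already applied) and an audit list of skipped motifs.
    """
    if len(ranked_kmers) == 0:
        raise ValidationError("empty ranking")
    allow = set(allow_list) if allow_list is not None else None
    ranked_set = set(ranked_kmers)
    audit: list[str] = []
    prepared: list[tuple[MotifModel, set[str]]] = []
    for motif in sorted(motifs, key=lambda m: m.motif_id):
        if allow is not None and motif.motif_id not in allow:
            continue
        members = motif.member_kmers
        if members is None:
            members = pwm_kmer_set(motif, k=k, score_threshold=score_threshold)
        inter = set(members) & ranked_set
        if not inter or len(inter) == len(ranked_set):
            audit.append(f"{motif.motif_id}: skipped ({len(inter)} members in ranking)")
            continue
        prepared.append((motif, inter))
    if not prepared:
        raise ValidationError("no usable motif has members in the ranking")

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(prepared))
    n = len(ranked_kmers)

    results: list[FingerprintResult] = []
    for (motif, inter), child in zip(prepared, children):
        ks = ks_enrichment_score(ranked_kmers, inter)
        null = _null_es(n, sorted(inter), n_permutations, np.random.default_rng(child))
        # one-sided: how often does a random size-matched set lead the ranking
        # at least as strongly (signed ES)?  Depleted sets get p near 1.
        p = (1.0 + int((null >= ks.es - 1e-12).sum())) / (1.0 + n_permutations)
        results.append(
            FingerprintResult(
                motif_id=motif.motif_id,
                rbp_ids=motif.rbp_ids,
                region_class=region_class,
                es=ks.es,
                p_value=p,
                fdr=np.nan,
                n_members=len(inter),
                leading_edge=ks.leading_edge,
            )
        )
    _, fdrs, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
    for r, q in zip(results, fdrs):
        r.fdr = float(q)
    return results, audit


def summarize_regions(
    results_by_region: Mapping[str, Sequence[FingerprintResult]],
    tables_by_region: Mapping[str, KmerTable],
    motifs: Sequence[MotifModel],
    *,
    k: int = 6,
    score_threshold: float = 0.8,
    top_n: int = 5,
) -> pd.DataFrame:
    """Tidy motif x region summary: ES, p, FDR, and the mean z-score of each
    motif's ``top_n`` member k-mers in that region (missing cells are NaN)."""
    member_cache: dict[str, frozenset[str]] = {}
    by_id = {m.motif_id: m for m in motifs}
    rows = []
    all_ids = sorted(by_id)
    for region in sorted(results_by_region):
        res_by_id = {r.motif_id: r for r in results_by_region[region]}
        table = tables_by_region.get(region)
        kmers = kmer_strings(k)
        kmer_index = {km: i for i, km in enumerate(kmers)}
        for motif_id in all_ids:
            r = res_by_id.get(motif_id)
            top_mean_z = np.nan
            if table is not None:
                members = member_cache.get(motif_id)
                if members is None:
                    members = pwm_kmer_set(by_id[motif_id], k=k, score_threshold=score_threshold)
                    member_cache[motif_id] = members
                zs = np.asarray(
                    [table.z[kmer_index[m]] for m in members if m in kmer_index], dtype=float
                )
                zs = zs[~np.isnan(zs)]
                if zs.size:
                    top_mean_z = float(np.sort(zs)[::-1][:top_n].mean())
            rows.append(
                {
                    "region": region,
                    "motif_id": motif_id,
                    "rbp_ids": ";".join(by_id[motif_id].rbp_ids),
                    "es": r.es if r else np.nan,
                    "p_value": r.p_value if r else np.nan,
                    "fdr": r.fdr if r else np.nan,
                    "n_members": r.n_members if r else 0,
                    "top_mean_z": top_mean_z,
                }
            )
    return pd.DataFrame(rows)
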