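"""Domain types and I/O for cassette-exon splicing analysis.

The pipeline consumes four kinds of input, all plain text:

* an event annotation table describing skipped (cassette) exons and their
  flanking introns (TSV, BED-style 0-based half-open coordinates);
* comparison tables carrying, per event and per pairwise comparison, the
  inclusion level Psi in each sample and a Bayes factor for differential
  inclusion (the flattened summary dialect of a MISO-style analysis);
* a per-gene expression table (FPKM-like values);
* a genome in FASTA.

Conventions fixed here and used pipeline-wide:

* coordinates are 0-based half-open (BED convention);
* Psi is stored as a fraction in [0, 1]; percent-scale input (0-100) is
  auto-detected and rescaled with a logged notice;
* ``delta_psi = psi_a - psi_b``, condition of interest minus reference
  (e.g. low flow minus high flow);
* ``upstream``/``downstream`` introns are named in transcript orientation:
  the upstream intron ends at the cassette acceptor (3'SS), the downstream
  intron begins at the cassette donor (5'SS).  On the minus strand the
  upstream intron is therefore the genomically *rightmost* interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

log = logging.getLogger(__name__)

EVENT_CLASSES = ("SE", "A3SS", "A5SS", "RI", "MXE", "ALE", "TandemUTR")

EVENT_COLUMNS = (
    "event_id",
    "gene_id",
    "chrom",
    "strand",
    "cassette_start",
    "cassette_end",
    "up_intron_start",
    "up_intron_end",
    "down_intron_start",
    "down_intron_end",
)

COMPARISON_COLUMNS = ("event_id", "comparison_id", "psi_a", "psi_b", "bayes_factor")


class SpliceFileError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SplicingEvent:
    """One cassette-exon event with its flanking introns.

    Intervals are (start, end) tuples, 0-based half-open, in genomic
    coordinates; ``upstream_intron``/``downstream_intron`` follow transcript
    orientation (see module docstring).
    """

    event_id: str
    gene_id: str
    chrom: str
    strand: str
    cassette: tuple[int, int]
    upstream_intron: tuple[int, int]
    downstream_intron: tuple[int, int]
    event_class: str = "SE"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.event_id}: strand must be '+' or '-'")
        if self.event_class not in EVENT_CLASSES:
            raise ValidationError(f"{self.event_id}: unknown event class {self.event_class!r}")
        for name, (s, e) in (
            ("cassette", self.cassette),
            ("upstream_intron", self.upstream_intron),
            ("downstream_intron", self.downstream_intron),
        ):
            if not (0 <= s < e):
                raise ValidationError(f"{self.event_id}: {name} interval {s, e} is empty or negative")
        cs, ce = self.cassette
        us, ue = self.upstream_intron
        ds, de = self.downstream_intron
        if self.strand == "+":
            # genomic order: upstream intron | cassette | downstream intron
            ok = ue == cs and ds == ce
        else:
            # genomic order: downstream intron | cassette | upstream intron
            ok = de == cs and us == ce
        if not ok:
            raise ValidationError(
                f"{self.event_id}: introns must flank the cassette exactly "
                f"(cassette={self.cassette}, up={self.upstream_intron}, "
                f"down={self.downstream_intron}, strand={self.strand})"
            )


@dataclass(frozen=True)
class ComparisonRecord:
    """Psi in two samples, their difference, and a Bayes factor for one event.

    ``psi_a`` is the condition of interest, ``psi_b`` the reference;
    ``delta_psi`` is always ``psi_a - psi_b``.
    """

    event_id: str
    comparison_id: str
    psi_a: float
    psi_b: float
    bayes_factor: float
    delta_psi: float = field(default=None)  # type: ignore[assignment]
    sample_a: str = ""
    sample_b: str = ""

    def __post_init__(self) -> None:
        for name, v in (("psi_a", self.psi_a), ("psi_b", self.psi_b)):
            if not (0.0 <= v <= 1.0):
                raise ValidationError(
                    f"{self.event_id}/{self.comparison_id}: {name}={v} outside [0, 1]"
                )
        if self.bayes_factor < 0:
            raise ValidationError(
                f"{self.event_id}/{self.comparison_id}: negative Bayes factor {self.bayes_factor}"
            )
        expected = self.psi_a - self.psi_b
        if self.delta_psi is None:
            object.__setattr__(self, "delta_psi", expected)
        elif abs(self.delta_psi - expected) > 1e-9:
            raise ValidationError(
                f"{self.event_id}/{self.comparison_id}: delta_psi={self.delta_psi} "
                f"!= psi_a - psi_b = {expected}"
            )


class GenomeSequence:
    """Genome as an in-memory mapping of contig name -> DNA string over ACGTN.

    ``fetch`` is strand-aware (reverse complement on '-') and rejects
    out-of-bounds requests.
    """

    def __init__(self, contigs: Mapping[str, str]):
        self._contigs: dict[str, str] = {}
        for name, seq in contigs.items():
            seq = seq.upper()
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValidationError(f"contig {name!r}: non-ACGTN characters {sorted(bad)}")
            self._contigs[name] = seq

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, read_ahead=10_000_000)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def contigs(self) -> list[str]:
        return list(self._contigs)

    def __contains__(self, name: str) -> bool:
        return name in self._contigs

    def length(self, name: str) -> int:
        return len(self._contigs[name])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        if chrom not in self._contigs:
            raise ValidationError(f"unknown contig {chrom!r}")
        n = len(self._contigs[chrom])
        if not (0 <= start < end <= n):
            raise ValidationError(
                f"interval [{start}, {end}) out of bounds for contig {chrom!r} (length {n})"
            )
        seq = self._contigs[chrom][start:end]
        if strand == "-":
            seq = reverse_complement(seq)
        elif strand != "+":
            raise ValidationError(f"strand must be '+' or '-', got {strand!r}")
        return seq

    def write_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name in sorted(self._contigs):
                fh.write(f">{name}\n")
                seq = self._contigs[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv_rows(path: str | Path, required: tuple[str, ...]) -> list[tuple[int, dict[str, str]]]:
    """Read a headered TSV into (line_number, row-dict) pairs, validating the header."""
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        return []
    header = lines[0].split("\t")
    missing = [c for c in required if c not in header]
    if missing:
        raise SpliceFileError(f"{path}: header missing required columns {missing}")
    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise SpliceFileError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        rows.append((lineno, dict(zip(header, fields))))
    return rows


def read_events(path: str | Path) -> list[SplicingEvent]:
    """Read an event annotation TSV into validated :class:`SplicingEvent` records.

    Input order is preserved.  An empty file yields an empty list with a
    logged warning.
    """
    rows = _read_tsv_rows(path, EVENT_COLUMNS)
    if not rows:
        log.warning("event file %s is empty", path)
        return []
    events = []
    for lineno, row in rows:
        try:
            ev = SplicingEvent(
                event_id=row["event_id"],
                gene_id=row["gene_id"],
                chrom=row["chrom"],
                strand=row["strand"],
                cassette=(int(row["cassette_start"]), int(row["cassette_end"])),
                upstream_intron=(int(row["up_intron_start"]), int(row["up_intron_end"])),
                downstream_intron=(int(row["down_intron_start"]), int(row["down_intron_end"])),
                event_class=row.get("event_class", "SE"),
            )
        except ValidationError:
            raise
        except (KeyError, ValueError) as exc:
            raise SpliceFileError(f"{path}:{lineno}: malformed event line ({exc})") from exc
        events.append(ev)
    return events


def write_events(events: Iterable[SplicingEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(EVENT_COLUMNS + ("event_class",)) + "\n")
        for ev in events:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        ev.event_id,
                        ev.gene_id,
                        ev.chrom,
                        ev.strand,
                        ev.cassette[0],
                        ev.cassette[1],
                        ev.upstream_intron[0],
                        ev.upstream_intron[1],
                        ev.downstream_intron[0],
                        ev.downstream_intron[1],
                        ev.event_class,
                    )
                )
                + "\n"
            )


def read_comparisons(path: str | Path) -> list[ComparisonRecord]:
    """Read a comparison TSV into validated :class:`ComparisonRecord` records.

    Psi columns are auto-detected as fraction (0-1) or percent (0-100); the
    percent dialect is rescaled with a logged notice.  Duplicate
    (event_id, comparison_id) pairs are rejected.
    """
    rows = _read_tsv_rows(path, COMPARISON_COLUMNS)
    if not rows:
        log.warning("comparison file %s is empty", path)
        return []
    parsed = []
    for lineno, row in rows:
        try:
            parsed.append(
                (
                    lineno,
                    row["event_id"],
                    row["comparison_id"],
                    float(row["psi_a"]),
                    float(row["psi_b"]),
                    float(row["bayes_factor"]),
                )
            )
        except ValueError as exc:
            raise SpliceFileError(f"{path}:{lineno}: malformed comparison line ({exc})") from exc
    percent = any(abs(pa) > 1.5 or abs(pb) > 1.5 for _, _, _, pa, pb, _ in parsed)
    if percent:
        log.info("comparison file %s uses the percent Psi dialect; rescaling to fractions", path)
    scale = 0.01 if percent else 1.0
    records: list[ComparisonRecord] = []
    seen: set[tuple[str, str]] = set()
    for lineno, event_id, comparison_id, pa, pb, bf in parsed:
        key = (event_id, comparison_id)
        if key in seen:
            raise SpliceFileError(
                f"{path}:{lineno}: duplicate record for event {event_id!r} "
                f"in comparison {comparison_id!r}"
            )
        seen.add(key)
        try:
            records.append(
                ComparisonRecord(
                    event_id=event_id,
                    comparison_id=comparison_id,
                    psi_a=pa * scale,
                    psi_b=pb * scale,
                    bayes_factor=bf,
                )
            )
        except ValidationError as exc:
            raise SpliceFileError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_comparisons(records: Iterable[ComparisonRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(COMPARISON_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.event_id}\t{r.comparison_id}\t{r.psi_a!r}\t{r.psi_b!r}\t{r.bayes_factor!r}\n"
            )


def read_expression(path: str | Path) -> dict[str, float]:
    """Read a two-column (gene_id, fpkm) TSV; values must be non-negative."""
    rows = _read_tsv_rows(path, ("gene_id", "fpkm"))
    table: dict[str, float] = {}
    for lineno, row in rows:
        try:
            v = float(row["fpkm"])
        except ValueError as exc:
            raise SpliceFileError(f"{path}:{lineno}: malformed fpkm value") from exc
        if v < 0:
            raise ValidationError(f"{path}:{lineno}: negative expression for {row['gene_id']!r}")
        table[row["gene_id"]] = v
    return table


def write_expression(table: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tfpkm\n")
        for gene in table:
            fh.write(f"{gene}\t{table[gene]!r}\n")


def compute_purity(egfp_reads: float, tdtomato_reads: float) -> float:
    """Contamination percentage of a lineage-labelled endothelial RNA pool.

    With eGFP marking endothelial transcripts and tdTomato all other cells,
    contamination is ``100 * tdTomato / (tdTomato + eGFP)``.
    """
    if egfp_reads < 0 or tdtomato_reads < 0:
        raise ValidationError("read counts must be non-negative")
    total = egfp_reads + tdtomato_reads
    if total == 0:
        raise ValidationError("cannot compute purity from zero total reads")
    return 100.0 * tdtomato_reads / total
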