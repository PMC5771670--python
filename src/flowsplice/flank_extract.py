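"""Strand-aware extraction of intronic flanking sequences.

For every cassette exon the analysis isolates up to ``flank_len`` (default
200) intronic nucleotides adjacent to each splice site: the *upstream* flank
ends at the cassette acceptor (3'SS) and the *downstream* flank begins at the
cassette donor (5'SS), both reported in transcript orientation (minus-strand
events are reverse-complemented).  Combined with the direction of the
inclusion change this yields four analysis regions per event set:
(upstream|downstream) x (increased|decreased).

Flanks never cross out of their intron: introns shorter than ``flank_len``
give a truncated flank carrying a flag (or an error, if truncation is
disabled).  The flank starts at the first intronic base; no splice-site
consensus or polypyrimidine-tract masking is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .splice_events import GenomeSequence, SplicingEvent, ValidationError

log = logging.getLogger(__name__)

SIDES = ("upstream", "downstream")
DIRECTIONS = ("increased", "decreased")
#: the four analysis regions, as (side, direction) pairs
REGION_CLASSES = tuple((s, d) for d in DIRECTIONS for s in SIDES)


def region_name(side: str, direction: str) -> str:
    return f"{side}_{direction}"


@dataclass
class FlankRegion:
    """One intronic flank in transcript orientation, with its genomic interval."""

    event_id: str
    side: str
    sequence: str
    gc: float
    truncated: bool
    chrom: str
    start: int
    end: int
    strand: str
    direction_class: str | None = None
    # per-k cache of k-mer count vectors, filled lazily by kmer_enrich
    _kmer_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.sequence)


def gc_fraction(sequence: str) -> float:
    """G+C fraction over unambiguous bases; N bases are excluded entirely."""
    if not sequence:
        raise ValidationError("gc_fraction of empty sequence is undefined")
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValidationError("gc_fraction undefined for all-N sequence")
    return gc / (gc + at)


def _flank_interval(event: SplicingEvent, side: str, flank_len: int) -> tuple[int, int, bool]:
    """Genomic (start, end) of a flank and whether the intron truncated it."""
    if side == "upstream":
        s, e = event.upstream_intron
        # flank ends at the acceptor: genomically right edge on '+', left on '-'
        at_right_edge = event.strand == "+"
    elif side == "downstream":
        s, e = event.downstream_intron
        # flank begins at the donor: genomically left edge on '+', right on '-'
        at_right_edge = event.strand == "-"
    else:
        raise ValidationError(f"side must be 'upstream' or 'downstream', got {side!r}")
    length = e - s
    eff = min(flank_len, length)
    if at_right_edge:
        return e - eff, e, length < flank_len
    return s, s + eff, length < flank_len


def extract_flanks(
    event: SplicingEvent,
    genome: GenomeSequence,
    flank_len: int = 200,
    on_short: str = "truncate",
) -> tuple[FlankRegion, FlankRegion]:
    """Extract the (upstream, downstream) intronic flanks of one event.

    Sequences are returned in transcript orientation.  ``on_short`` is
    ``"truncate"`` (flagged short flank) or ``"error"``.
    """
    if on_short not in ("truncate", "error"):
        raise ValidationError(f"on_short must be 'truncate' or 'error', got {on_short!r}")
    out = []
    for side in SIDES:
        start, end, truncated = _flank_interval(event, side, flank_len)
        if truncated and on_short == "error":
            raise ValidationError(
                f"{event.event_id}: {side} intron shorter than flank_len={flank_len}"
            )
        seq = genome.fetch(event.chrom, start, end, event.strand)
        out.append(
            FlankRegion(
                event_id=event.event_id,
                side=side,
                sequence=seq,
                gc=gc_fraction(seq),
                truncated=truncated,
                chrom=event.chrom,
                start=start,
                end=end,
                strand=event.strand,
            )
        )
    return out[0], out[1]


def build_region_sets(
    events: Iterable[SplicingEvent],
    directions: Mapping[str, str],
    genome: GenomeSequence,
    flank_len: int = 200,
) -> tuple[dict[tuple[str, str], list[FlankRegion]], list[dict]]:
    """Assign each event's two flanks to the four analysis regions.

    Returns ``{(side, direction): [FlankRegion, ...]}`` plus an audit list of
    per-event failures (extraction errors are recorded and skipped, not
    raised).
    """
    regions: dict[tuple[str, str], list[FlankRegion]] = {rc: [] for rc in REGION_CLASSES}
    audit: list[dict] = []
    for ev in events:
        direction = directions.get(ev.event_id)
        if direction not in DIRECTIONS:
            audit.append({"event_id": ev.event_id, "error": f"missing direction ({direction!r})"})
            continue
        try:
            up, down = extract_flanks(ev, genome, flank_len)
        except ValidationError as exc:
            audit.append({"event_id": ev.event_id, "error": str(exc)})
            continue
        for fl in (up, down):
            fl.direction_class = direction
            regions[(fl.side, direction)].append(fl)
    for rc, lst in regions.items():
        if not lst:
            log.warning("region class %s is empty", region_name(*rc))
    return regions, audit


def write_flank_fasta(regions: Iterable[FlankRegion], path: str | Path) -> None:
    """FASTA with structured headers: event_id|side|direction|truncated."""
    with open(path, "w") as fh:
        for fl in regions:
            fh.write(f">{fl.event_id}|{fl.side}|{fl.direction_class}|{int(fl.truncated)}\n")
            fh.write(fl.sequence + "\n")


def write_flank_bed(regions: Iterable[FlankRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for fl in regions:
            name = f"{fl.event_id}|{fl.side}|{fl.direction_class}"
            fh.write(f"{fl.chrom}\t{fl.start}\t{fl.end}\t{name}\t0\t{fl.strand}\n")
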