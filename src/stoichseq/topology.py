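"""Membrane-protein topology: Phobius short-format parsing, membrane
classification, and dissection into cytoplasmic / transmembrane /
periplasmic-extracellular domains.

Coordinates are 1-based inclusive throughout (the Phobius convention).
A prediction string such as ``i12-31o40-62i`` reads: cytoplasmic flank,
transmembrane helix 12-31, outside loop, helix 40-62, cytoplasmic tail.
An optional signal-peptide prefix ``n<a>-<b>c<c>/<c+1>`` marks a signal
segment ending at position ``c`` (the residue before the cleavage
site); signal residues are excluded from all domain analyses.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "SegmentKind",
    "TopologySegment",
    "TopologyAnnotation",
    "TmMultiplicity",
    "PhobiusParseError",
    "NotMembraneProteinError",
    "parse_phobius_short",
    "write_phobius_short",
    "prediction_string",
    "classify_membrane",
    "tm_multiplicity",
    "dissect_domains",
    "filter_domain_sizes",
]


class SegmentKind(str, enum.Enum):
    CYTOPLASMIC = "cytoplasmic"
    TRANSMEMBRANE = "transmembrane"
    PERIPLASMIC_EXTRACELLULAR = "periplasmic_extracellular"
    SIGNAL = "signal"


class TmMultiplicity(str, enum.Enum):
    SINGLE_TM = "single_tm"
    MULTI_TM = "multi_tm"


class PhobiusParseError(ValueError):
    pass


class NotMembraneProteinError(ValueError):
    pass


@dataclass(frozen=True)
class TopologySegment:
    kind: SegmentKind
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid segment bounds {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1


_FLANKS = (SegmentKind.CYTOPLASMIC, SegmentKind.PERIPLASMIC_EXTRACELLULAR)


@dataclass(frozen=True)
class TopologyAnnotation:
    """Ordered, contiguous segments tiling a protein from 1 to its length."""

    protein_id: str
    segments: tuple[TopologySegment, ...]

    def __post_init__(self) -> None:
        segs = self.segments
        if not segs:
            raise ValueError("annotation needs at least one segment")
        if segs[0].start != 1:
            raise ValueError("segments must start at position 1")
        for a, b in zip(segs, segs[1:]):
            if b.start != a.end + 1:
                raise ValueError(
                    f"segments not contiguous at {a.end}/{b.start} in {self.protein_id}"
                )
        for i, s in enumerate(segs):
            if s.kind is SegmentKind.SIGNAL and i != 0:
                raise ValueError("signal segment allowed only at the start")
        # flanks on both sides of a TM helix must be on opposite membrane faces
        flanks = [s.kind for s in segs if s.kind in _FLANKS]
        for a, b in zip(flanks, flanks[1:]):
            if a is b:
                raise ValueError(
                    f"inconsistent membrane topology in {self.protein_id}: "
                    "consecutive flanks on the same side"
                )

    @property
    def length(self) -> int:
        return self.segments[-1].end

    @property
    def tm_count(self) -> int:
        return sum(1 for s in self.segments if s.kind is SegmentKind.TRANSMEMBRANE)

    @property
    def signal(self) -> TopologySegment | None:
        first = self.segments[0]
        return first if first.kind is SegmentKind.SIGNAL else None


def classify_membrane(annotation: TopologyAnnotation) -> bool:
    """True iff the protein has at least one transmembrane segment."""
    return annotation.tm_count >= 1


def tm_multiplicity(annotation: TopologyAnnotation) -> TmMultiplicity:
    if annotation.tm_count == 0:
        raise NotMembraneProteinError(f"{annotation.protein_id} is not a membrane protein")
    return TmMultiplicity.SINGLE_TM if annotation.tm_count == 1 else TmMultiplicity.MULTI_TM


def dissect_domains(sequence: str, annotation: TopologyAnnotation) -> dict[SegmentKind, str]:
    """Concatenate residues of each kind in sequence order.

    Returns the three domain strings (cytoplasmic, transmembrane,
    periplasmic/extracellular); signal-peptide residues appear in none
    of them.
    """
    if annotation.length != len(sequence):
        raise ValueError(
            f"annotation covers {annotation.length} residues but sequence "
            f"{annotation.protein_id} has {len(sequence)}"
        )
    if annotation.tm_count == 0:
        raise NotMembraneProteinError(
            f"{annotation.protein_id} has no transmembrane segment"
        )
    parts: dict[SegmentKind, list[str]] = {
        SegmentKind.CYTOPLASMIC: [],
        SegmentKind.TRANSMEMBRANE: [],
        SegmentKind.PERIPLASMIC_EXTRACELLULAR: [],
    }
    for seg in annotation.segments:
        if seg.kind is SegmentKind.SIGNAL:
            continue
        parts[seg.kind].append(sequence[seg.start - 1 : seg.end])
    return {kind: "".join(chunks) for kind, chunks in parts.items()}


def filter_domain_sizes(domains: Mapping[SegmentKind, str], min_per_domain: int = 20) -> bool:
    """Keep a membrane protein only if every one of the three domains
    has at least ``min_per_domain`` residues."""
    return all(
        len(domains.get(kind, "")) >= min_per_domain
        for kind in (
            SegmentKind.CYTOPLASMIC,
            SegmentKind.TRANSMEMBRANE,
            SegmentKind.PERIPLASMIC_EXTRACELLULAR,
        )
    )


# ---------------------------------------------------------------------------
# Phobius short format

_SIGNAL_RE = re.compile(r"^n(\d+)-(\d+)c(\d+)/(\d+)")
_TOKEN_RE = re.compile(r"([io])|(\d+)-(\d+)")


def _parse_prediction(pred: str, length: int, where: str) -> tuple[TopologySegment, ...]:
    segs: list[TopologySegment] = []
    cursor = 1
    rest = pred
    m = _SIGNAL_RE.match(rest)
    if m:
        c, c1 = int(m.group(3)), int(m.group(4))
        if c1 != c + 1:
            raise PhobiusParseError(f"{where}: cleavage site {c}/{c1} not adjacent")
        segs.append(TopologySegment(SegmentKind.SIGNAL, 1, c))
        cursor = c + 1
        rest = rest[m.end():]
    tokens: list = []
    pos = 0
    for m in _TOKEN_RE.finditer(rest):
        if m.start() != pos:
            raise PhobiusParseError(f"{where}: malformed prediction string {pred!r}")
        pos = m.end()
        if m.group(1):
            tokens.append(m.group(1))
        else:
            tokens.append((int(m.group(2)), int(m.group(3))))
    if pos != len(rest) or not tokens or not isinstance(tokens[0], str):
        raise PhobiusParseError(f"{where}: malformed prediction string {pred!r}")

    def flank_kind(letter: str) -> SegmentKind:
        return SegmentKind.CYTOPLASMIC if letter == "i" else SegmentKind.PERIPLASMIC_EXTRACELLULAR

    for i, tok in enumerate(tokens):
        if isinstance(tok, str):
            if i + 1 < len(tokens):
                nxt = tokens[i + 1]
                if isinstance(nxt, str):
                    raise PhobiusParseError(f"{where}: consecutive region letters in {pred!r}")
                flank_end = nxt[0] - 1
            else:
                flank_end = length
            if flank_end >= cursor:
                segs.append(TopologySegment(flank_kind(tok), cursor, flank_end))
                cursor = flank_end + 1
        else:
            s, e = tok
            if s != cursor or e < s or e > length:
                raise PhobiusParseError(
                    f"{where}: transmembrane range {s}-{e} inconsistent with "
                    f"cursor {cursor} / length {length} in {pred!r}"
                )
            segs.append(TopologySegment(SegmentKind.TRANSMEMBRANE, s, e))
            cursor = e + 1
    if cursor != length + 1:
        raise PhobiusParseError(
            f"{where}: prediction {pred!r} covers {cursor - 1} of {length} residues"
        )
    return tuple(segs)


def parse_phobius_short(
    text: str, lengths: Mapping[str, int]
) -> list[TopologyAnnotation]:
    """Parse Phobius short-format output (4 whitespace-delimited columns:
    id, TM count, signal-peptide flag, prediction string).

    ``lengths`` maps protein id to sequence length; the final flank of a
    prediction string is open-ended, so lengths are required to tile the
    whole protein.  A header line starting with ``SEQ`` (or ``#``) is
    tolerated.
    """
    annotations: list[TopologyAnnotation] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if fields[0].upper() in ("SEQENCE", "SEQUENCE", "SEQ", "ID") and lineno == 1:
            continue
        if len(fields) != 4:
            raise PhobiusParseError(f"line {lineno}: expected 4 columns, got {len(fields)}")
        pid, tm_str, sp_str, pred = fields
        where = f"line {lineno} ({pid})"
        try:
            tm_declared = int(tm_str)
        except ValueError:
            raise PhobiusParseError(f"{where}: bad TM count {tm_str!r}") from None
        if pid not in lengths:
            raise PhobiusParseError(f"{where}: unknown protein id {pid!r}")
        segs = _parse_prediction(pred, lengths[pid], where)
        ann = TopologyAnnotation(protein_id=pid, segments=segs)
        if ann.tm_count != tm_declared:
            raise PhobiusParseError(
                f"{where}: declared TM count {tm_declared} but prediction has {ann.tm_count}"
            )
        sp_declared = sp_str.upper() in ("Y", "1")
        if sp_declared != (ann.signal is not None):
            raise PhobiusParseError(
                f"{where}: signal-peptide flag {sp_str!r} disagrees with prediction"
            )
        annotations.append(ann)
    return annotations


def prediction_string(annotation: TopologyAnnotation) -> str:
    """Emit the short-format prediction string for an annotation."""
    out: list[str] = []
    segs = annotation.segments
    if annotation.signal is not None:
        c = annotation.signal.end
        # n- and h-region bounds inside the signal are not modelled;
        # emit a nominal n-region, only the cleavage position matters.
        out.append(f"n1-{max(1, c - 2)}c{c}/{c + 1}")
        segs = segs[1:]
    for seg in segs:
        if seg.kind is SegmentKind.TRANSMEMBRANE:
            out.append(f"{seg.start}-{seg.end}")
        else:
            out.append("i" if seg.kind is SegmentKind.CYTOPLASMIC else "o")
    return "".join(out)


def write_phobius_short(annotations: Iterable[TopologyAnnotation]) -> str:
    """Render annotations as a Phobius short-format table with header."""
    lines = ["SEQENCE ID\tTM\tSP\tPREDICTION"]
    for ann in annotations:
        sp = "Y" if ann.signal is not None else "0"
        lines.append(f"{ann.protein_id}\t{ann.tm_count}\t{sp}\t{prediction_string(ann)}")
    return "\n".join(lines) + "\n"
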