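"""Residue-level nitrogen scoring and sequence-level nitrogen content.

The nitrogen content of a protein is the mean number of side-chain
nitrogen atoms per residue,

    Nc = (sum_i n_i) / L,

where ``n_i`` counts the nitrogen atoms in the side chain of the i-th
residue and ``L`` is the number of residues scored.  Side-chain counts
for the 20 standard amino acids: asparagine, glutamine, lysine and
tryptophan carry one nitrogen; histidine two; arginine three; all other
residues none.  Nc therefore lies in [0, 3], reaching 3 only for pure
polyarginine.

Ambiguity codes (X, B, Z, U, O and the stop symbol '*') are excluded
from both the numerator and the denominator, so Nc stays a mean over
scorable residues.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

__all__ = [
    "SIDE_CHAIN_NITROGEN",
    "AMBIGUOUS_CODES",
    "Habitat",
    "ProteinRecord",
    "NitrogenScore",
    "AmbiguousResidueError",
    "UnscorableSequenceError",
    "side_chain_nitrogen",
    "nitrogen_content",
    "nitrogen_content_masked",
    "filter_min_length",
    "read_fasta",
    "write_fasta",
    "read_sample_metadata",
    "attach_habitats",
]

#: Side-chain nitrogen atoms per standard residue (one-letter codes).
SIDE_CHAIN_NITROGEN: Mapping[str, int] = {
    "A": 0, "R": 3, "N": 1, "D": 0, "C": 0,
    "Q": 1, "E": 0, "G": 0, "H": 2, "I": 0,
    "L": 0, "K": 1, "M": 0, "F": 0, "P": 0,
    "S": 0, "T": 0, "W": 1, "Y": 0, "V": 0,
}

#: Codes tolerated in input but excluded from scoring.
AMBIGUOUS_CODES = frozenset("XBZUO*")


class AmbiguousResidueError(ValueError):
    """Raised when a single residue query is not a standard code."""


class UnscorableSequenceError(ValueError):
    """Raised when a sequence (or selection) has no scorable residues."""


class Habitat(str, enum.Enum):
    OPEN_OCEAN = "open_ocean"
    COASTAL = "coastal"
    ESTUARY = "estuary"

    @property
    def analysis_label(self) -> "Habitat":
        """Habitat used in contrasts: estuary samples are merged into
        coastal (estuaries are a coastal subtype and too few to stand
        alone), while the original label is kept for provenance."""
        return Habitat.COASTAL if self is Habitat.ESTUARY else self


@dataclass(frozen=True)
class ProteinRecord:
    """One peptide with its sample and habitat labels."""

    id: str
    sequence: str
    sample_id: str = ""
    habitat: Habitat | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def analysis_habitat(self) -> Habitat | None:
        return None if self.habitat is None else self.habitat.analysis_label


@dataclass(frozen=True)
class NitrogenScore:
    """Nitrogen atoms per scorable residue, with the residue count used."""

    value: float
    n_residues_counted: int


def side_chain_nitrogen(residue: str) -> int:
    """Number of side-chain nitrogen atoms of a standard residue.

    Raises :class:`AmbiguousResidueError` for any non-standard code so
    the caller decides how to handle it.
    """
    try:
        return SIDE_CHAIN_NITROGEN[residue.upper()]
    except KeyError:
        raise AmbiguousResidueError(f"not a standard residue code: {residue!r}") from None


def _score(residues: Iterable[str], context: str) -> NitrogenScore:
    total = 0
    counted = 0
    for ch in residues:
        ch = ch.upper()
        n = SIDE_CHAIN_NITROGEN.get(ch)
        if n is None:
            if ch in AMBIGUOUS_CODES or ch == "-":
                continue
            raise AmbiguousResidueError(f"unexpected residue code {ch!r} in {context}")
        total += n
        counted += 1
    if counted == 0:
        raise UnscorableSequenceError(f"no scorable residues in {context}")
    return NitrogenScore(value=total / counted, n_residues_counted=counted)


def nitrogen_content(sequence: str) -> NitrogenScore:
    """Nc of a sequence: mean side-chain nitrogen over scorable residues."""
    return _score(sequence, "unscorable sequence")


def nitrogen_content_masked(sequence: str, positions: Iterable[int]) -> NitrogenScore:
    """Nc restricted to a set of 1-based positions.

    Used for rate-class- or domain-restricted scoring.  Positions whose
    residue is an ambiguity code are dropped; an empty effective
    selection raises :class:`UnscorableSequenceError`.
    """
    pos = sorted(set(positions))
    if pos and (pos[0] < 1 or pos[-1] > len(sequence)):
        raise IndexError(
            f"positions out of range 1..{len(sequence)}: {pos[0]}..{pos[-1]}"
        )
    return _score((sequence[p - 1] for p in pos), "unscorable selection")


def filter_min_length(
    records: Iterable[ProteinRecord], threshold: int = 100
) -> list[ProteinRecord]:
    """Keep records strictly longer than ``threshold`` residues."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return [r for r in records if len(r) > threshold]


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> Iterator[ProteinRecord]:
    """Read protein records from FASTA; id = first whitespace token."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield ProteinRecord(id=rec.id, sequence=str(rec.seq))


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            seq = r.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_sample_metadata(path: str | Path) -> dict[str, Habitat]:
    """Read sample metadata TSV with columns ``sample_id`` and
    ``habitat`` (open_ocean / coastal / estuary)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "habitat"):
        if col not in df.columns:
            raise ValueError(f"metadata file {path} lacks required column {col!r}")
    return {row.sample_id: Habitat(row.habitat) for row in df.itertuples()}


def attach_habitats(
    records: Iterable[ProteinRecord],
    metadata: Mapping[str, Habitat],
    strict: bool = True,
) -> list[ProteinRecord]:
    """Join habitat labels onto records via the sample-id prefix of each
    sequence id (``<sample_id>_<n>``) or an exact sample_id match."""
    out: list[ProteinRecord] = []
    orphans: list[str] = []
    for r in records:
        sample = r.sample_id or r.id.rsplit("_", 1)[0]
        hab = metadata.get(sample)
        if hab is None:
            orphans.append(r.id)
            continue
        out.append(ProteinRecord(id=r.id, sequence=r.sequence, sample_id=sample, habitat=hab))
    if orphans and strict:
        preview = ", ".join(orphans[:5])
        raise KeyError(
            f"{len(orphans)} records have no habitat metadata (e.g. {preview})"
        )
    return out
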