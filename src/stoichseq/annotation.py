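"""Functional annotation from HMM search hit tables.

Parses HMMER3 per-sequence tabular output (``--tblout``), filters hits
by model-specific noise cutoffs (the TIGRFAM per-model bitscore below
which hits are unreliable; comparison is inclusive, matching HMMER's
gathering/noise-cutoff semantics), and assigns each query protein to a
gene of either the NtcA-induced nitrogen-starvation cascade or the
arginine biosynthetic pathway via its best surviving hit.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Pathway",
    "HmmHit",
    "PathwayGene",
    "HmmTableParseError",
    "NTCA_INDUCED_GENES",
    "ARG_BIOSYNTHESIS_GENES",
    "default_gene_table",
    "parse_hmm_table",
    "write_hmm_table",
    "apply_noise_cutoff",
    "assign_pathway",
    "read_cutoff_table",
    "read_gene_table",
]


class Pathway(str, enum.Enum):
    NTCA_INDUCED = "ntca_induced"
    ARG_BIOSYNTHESIS = "arg_biosynthesis"


class HmmTableParseError(ValueError):
    pass


@dataclass(frozen=True)
class HmmHit:
    query_id: str
    model_accession: str
    model_name: str
    full_sequence_bitscore: float
    full_sequence_evalue: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.full_sequence_bitscore):
            raise ValueError("bitscore must be finite")
        if self.full_sequence_evalue < 0:
            raise ValueError("E-value must be >= 0")


@dataclass(frozen=True)
class PathwayGene:
    gene_symbol: str
    pathway: Pathway
    model_accessions: tuple[str, ...]


# Gene membership of the two contrasted pathways.  recD appears in the
# NtcA-induced set of the source gene list and is carried verbatim.
NTCA_INDUCED_GENES = ("NtcA", "glnA", "pII", "urtB", "urtC", "urtD", "urtE", "recD", "amt1")
ARG_BIOSYNTHESIS_GENES = ("argC", "argJ", "argH", "argE", "argG", "argF")


def default_gene_table() -> list[PathwayGene]:
    """One placeholder TIGRFAM-style accession per gene.

    Synthetic accessions (``SYN_<gene>``): the real gene-to-model map is
    deployment-specific and ships as an editable TSV; these defaults
    make the synthetic pipeline self-contained.
    """
    genes = [
        PathwayGene(g, Pathway.NTCA_INDUCED, (f"SYN_{g}",)) for g in NTCA_INDUCED_GENES
    ]
    genes += [
        PathwayGene(g, Pathway.ARG_BIOSYNTHESIS, (f"SYN_{g}",)) for g in ARG_BIOSYNTHESIS_GENES
    ]
    return genes


def parse_hmm_table(text: str) -> list[HmmHit]:
    """Parse HMMER3 per-sequence tabular output.

    Lines starting with ``#`` are comments.  Data lines carry at least
    19 whitespace-separated fields: target name, target accession,
    query name, query accession, full-sequence E-value, score, bias,
    best-domain triple, and the remaining counters; here the *query* is
    the protein searched with ``hmmscan`` against profile models, so
    fields 0-1 are the model and field 2 the protein.
    """
    hits: list[HmmHit] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        fields = raw.split()
        if len(fields) < 19:
            raise HmmTableParseError(
                f"line {lineno}: expected >= 19 fields, got {len(fields)}"
            )
        model_name, model_acc, query_id = fields[0], fields[1], fields[2]
        try:
            evalue = float(fields[4])
            score = float(fields[5])
        except ValueError as exc:
            raise HmmTableParseError(f"line {lineno}: {exc}") from None
        hits.append(
            HmmHit(
                query_id=query_id,
                model_accession=model_acc,
                model_name=model_name,
                full_sequence_bitscore=score,
                full_sequence_evalue=evalue,
            )
        )
    return hits


def write_hmm_table(hits: Iterable[HmmHit]) -> str:
    """Render hits in HMMER3 ``--tblout`` per-sequence layout."""
    lines = [
        "# target name        accession   query name           accession "
        "  E-value  score  bias   E-value  score  bias   exp reg clu  ov env dom rep inc description of target"
    ]
    for h in hits:
        lines.append(
            f"{h.model_name:<20} {h.model_accession:<11} {h.query_id:<20} -"
            f" {h.full_sequence_evalue:9.2g} {h.full_sequence_bitscore:6.1f}   0.0"
            f" {h.full_sequence_evalue:9.2g} {h.full_sequence_bitscore:6.1f}   0.0"
            f"   1.0   1   0   0   1   1   1   1 -"
        )
    return "\n".join(lines) + "\n"


def apply_noise_cutoff(
    hits: Iterable[HmmHit], cutoffs: Mapping[str, float]
) -> list[HmmHit]:
    """Keep hits whose full-sequence bitscore meets the model's noise
    cutoff (inclusive)."""
    kept: list[HmmHit] = []
    for h in hits:
        if h.model_accession not in cutoffs:
            raise KeyError(f"no noise cutoff for model {h.model_accession!r}")
        if h.full_sequence_bitscore >= cutoffs[h.model_accession]:
            kept.append(h)
    return kept


def assign_pathway(
    hits: Iterable[HmmHit], gene_table: Iterable[PathwayGene]
) -> dict[str, tuple[str, Pathway]]:
    """Assign each query to the gene of its highest-bitscore surviving
    hit; ties broken by lexicographically smallest model accession.
    Queries whose best hit is outside both gene sets are unassigned."""
    model_to_gene: dict[str, PathwayGene] = {}
    for gene in gene_table:
        for acc in gene.model_accessions:
            model_to_gene[acc] = gene
    best: dict[str, HmmHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if (
            cur is None
            or h.full_sequence_bitscore > cur.full_sequence_bitscore
            or (
                h.full_sequence_bitscore == cur.full_sequence_bitscore
                and h.model_accession < cur.model_accession
            )
        ):
            best[h.query_id] = h
    out: dict[str, tuple[str, Pathway]] = {}
    for query_id, h in best.items():
        gene = model_to_gene.get(h.model_accession)
        if gene is not None:
            out[query_id] = (gene.gene_symbol, gene.pathway)
    return out


def read_cutoff_table(path: str | Path) -> dict[str, float]:
    """TSV with columns model_accession, noise_cutoff_bits."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["model_accession"], df["noise_cutoff_bits"].astype(float)))


def read_gene_table(path: str | Path) -> list[PathwayGene]:
    """TSV with columns gene_symbol, pathway, model_accession (one row
    per accession; accessions of a gene are aggregated)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    genes: dict[str, tuple[Pathway, list[str]]] = {}
    for row in df.itertuples():
        pathway = Pathway(row.pathway)
        entry = genes.setdefault(row.gene_symbol, (pathway, []))
        if entry[0] is not pathway:
            raise ValueError(f"gene {row.gene_symbol!r} listed under two pathways")
        entry[1].append(row.model_accession)
    return [
        PathwayGene(sym, pw, tuple(accs)) for sym, (pw, accs) in genes.items()
    ]
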