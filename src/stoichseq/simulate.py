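"""Synthetic study generator.

Emulates the statistical structure of a two-habitat (open ocean vs
coastal) marine metagenome study so every pipeline stage can be tested
without external data:

* habitat-specific amino-acid composition profiles with a controlled
  relative difference in expected nitrogen content (a common tilt on
  the six nitrogen-bearing residues, solved by root finding);
* i.i.d. proteomes sampled from those profiles;
* membrane proteins assembled segment-wise (hydrophobic transmembrane
  stretches, inside/outside loops, optional signal peptide) together
  with their true topology and a Phobius-short line;
* HMM-style hit tables with known gene labels;
* gene-family alignments evolved along a Yule tree under JTT with
  gamma site rates, with a habitat-dependent nitrogen deficit injected
  only at designated fast-evolving sites (nitrogen-bearing residues of
  open-habitat leaves swapped to nitrogen-free residues with a small
  probability — a swap probability q produces an expected relative
  nitrogen-content drop of exactly -100*q percent at those sites).

All randomness flows from one master seed through named substreams, so
regeneration is bit-identical.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.optimize import brentq

from .annotation import HmmHit, default_gene_table, write_hmm_table
from .jtt import AA_INDEX, AMINO_ACIDS, SubstitutionModel, jtt_model
from .nitrogen import SIDE_CHAIN_NITROGEN, Habitat, ProteinRecord, write_fasta
from .site_rates import Alignment
from .topology import (
    SegmentKind,
    TopologyAnnotation,
    TopologySegment,
    write_phobius_short,
)
from .trees import Tree, TreeNode

__all__ = [
    "EnvironmentProfile",
    "StudyConfig",
    "SyntheticStudy",
    "make_environment_profiles",
    "sample_proteome",
    "simulate_membrane_protein",
    "simulate_yule_tree",
    "simulate_alignment",
    "generate_study",
    "nitrogen_swap_map",
]

_N_BEARING = "NQKWHR"
_NITROGEN_VEC = np.array([SIDE_CHAIN_NITROGEN[a] for a in AMINO_ACIDS], dtype=float)

#: Chemically conservative nitrogen-to-nitrogen-free residue swaps used
#: to inject habitat effects (every target carries zero side-chain N).
NITROGEN_SWAP = {"N": "D", "Q": "E", "K": "T", "W": "F", "H": "Y", "R": "S"}


def nitrogen_swap_map() -> dict[str, str]:
    return dict(NITROGEN_SWAP)


@dataclass(frozen=True)
class EnvironmentProfile:
    """Amino-acid frequency profile of one habitat."""

    frequencies: np.ndarray  # over AMINO_ACIDS order, sums to 1
    habitat: Habitat

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.shape != (20,) or np.any(f < 0) or abs(f.sum() - 1) > 1e-9:
            raise ValueError("frequencies must be a length-20 simplex vector")
        object.__setattr__(self, "frequencies", f)

    @property
    def expected_nc(self) -> float:
        return float(self.frequencies @ _NITROGEN_VEC)


def _tilted(baseline: np.ndarray, factor: float) -> np.ndarray:
    f = baseline.copy()
    for aa in _N_BEARING:
        f[AA_INDEX[aa]] *= factor
    return f / f.sum()


def make_environment_profiles(
    baseline: Sequence[float] | None = None,
    target_rel_diff_percent: float = -5.0,
) -> tuple[EnvironmentProfile, EnvironmentProfile]:
    """Coastal profile = baseline; open-ocean profile = baseline with
    the nitrogen-bearing residues tilted by a common factor chosen so
    the relative difference in expected nitrogen content hits the
    target (within 1e-6 percentage points).

    Default baseline: JTT equilibrium frequencies (consistency with the
    evolution model).
    """
    if abs(target_rel_diff_percent) >= 50:
        raise ValueError("target relative difference must be within (-50, 50) percent")
    base = (
        jtt_model().frequencies
        if baseline is None
        else np.asarray(baseline, dtype=float)
    )
    base = base / base.sum()
    coastal = EnvironmentProfile(base, Habitat.COASTAL)

    def rel_diff(factor: float) -> float:
        open_nc = float(_tilted(base, factor) @ _NITROGEN_VEC)
        return 100.0 * (open_nc - coastal.expected_nc) / coastal.expected_nc

    if target_rel_diff_percent == 0:
        return coastal, EnvironmentProfile(base, Habitat.OPEN_OCEAN)
    lo, hi = 1e-9, 1e9
    if not (rel_diff(lo) - 1e-6 < target_rel_diff_percent < rel_diff(hi) + 1e-6):
        raise ValueError(
            f"target {target_rel_diff_percent}% outside attainable range "
            f"({rel_diff(lo):.2f}%, {rel_diff(hi):.2f}%)"
        )
    factor = brentq(
        lambda f: rel_diff(f) - target_rel_diff_percent, lo, hi, xtol=1e-12
    )
    return coastal, EnvironmentProfile(_tilted(base, factor), Habitat.OPEN_OCEAN)


def sample_proteome(
    profile: EnvironmentProfile,
    n_sequences: int,
    length_range: tuple[int, int] = (101, 300),
    seed: int | np.random.Generator = 0,
    sample_id: str = "S0",
    id_prefix: str | None = None,
) -> list[ProteinRecord]:
    """I.i.d. residues from the profile; lengths uniform over the range
    (default minimum 101 so every record passes the >100 aa filter)."""
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    aa = np.array(list(AMINO_ACIDS))
    prefix = id_prefix or sample_id
    records = []
    for i in range(n_sequences):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(aa[rng.choice(20, size=length, p=profile.frequencies)])
        records.append(
            ProteinRecord(
                id=f"{prefix}_{i:05d}",
                sequence=seq,
                sample_id=sample_id,
                habitat=profile.habitat,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Membrane proteins

#: Hydrophobic-enriched composition for transmembrane stretches.
_TM_WEIGHTS = {
    "A": 8, "C": 1, "F": 9, "G": 5, "I": 12, "L": 16, "M": 3,
    "V": 12, "W": 2, "Y": 3, "S": 3, "T": 3, "P": 1,
    "N": 0.5, "Q": 0.5, "K": 0.3, "R": 0.3, "H": 0.3, "D": 0.3, "E": 0.3,
}


def _tm_profile() -> np.ndarray:
    w = np.array([_TM_WEIGHTS[a] for a in AMINO_ACIDS], dtype=float)
    return w / w.sum()


def simulate_membrane_protein(
    rng: np.random.Generator,
    protein_id: str,
    n_tm: int = 2,
    tm_length_range: tuple[int, int] = (15, 30),
    loop_length_range: tuple[int, int] = (5, 80),
    loop_profile: EnvironmentProfile | None = None,
    tm_frequencies: np.ndarray | None = None,
    with_signal: bool = False,
    signal_length_range: tuple[int, int] = (15, 30),
    sample_id: str = "S0",
    habitat: Habitat | None = None,
) -> tuple[ProteinRecord, TopologyAnnotation]:
    """Assemble a membrane protein segment-wise with its true topology.

    Loops alternate between the cytoplasmic and periplasmic sides
    (starting side random); transmembrane stretches draw from a
    hydrophobic-enriched profile.
    """
    if n_tm < 1:
        raise ValueError("need at least one transmembrane segment")
    if loop_profile is None:
        loop_profile = EnvironmentProfile(jtt_model().frequencies, habitat or Habitat.COASTAL)
    tm_freq = _tm_profile() if tm_frequencies is None else tm_frequencies
    aa = np.array(list(AMINO_ACIDS))

    def draw(n: int, freqs: np.ndarray) -> str:
        return "".join(aa[rng.choice(20, size=n, p=freqs)])

    segments: list[TopologySegment] = []
    chunks: list[str] = []
    pos = 1
    if with_signal:
        n = int(rng.integers(*signal_length_range))
        segments.append(TopologySegment(SegmentKind.SIGNAL, pos, pos + n - 1))
        chunks.append(draw(n, tm_freq))  # signal peptides are hydrophobic too
        pos += n
    inside_first = bool(rng.integers(2)) if not with_signal else True
    side = SegmentKind.CYTOPLASMIC if inside_first else SegmentKind.PERIPLASMIC_EXTRACELLULAR
    for k in range(n_tm + 1):
        n = int(rng.integers(*loop_length_range))
        segments.append(TopologySegment(side, pos, pos + n - 1))
        chunks.append(draw(n, loop_profile.frequencies))
        pos += n
        if k < n_tm:
            n = int(rng.integers(*tm_length_range))
            segments.append(TopologySegment(SegmentKind.TRANSMEMBRANE, pos, pos + n - 1))
            chunks.append(draw(n, tm_freq))
            pos += n
        side = (
            SegmentKind.PERIPLASMIC_EXTRACELLULAR
            if side is SegmentKind.CYTOPLASMIC
            else SegmentKind.CYTOPLASMIC
        )
    record = ProteinRecord(
        id=protein_id, sequence="".join(chunks), sample_id=sample_id, habitat=habitat
    )
    annotation = TopologyAnnotation(protein_id=protein_id, segments=tuple(segments))
    return record, annotation


# ---------------------------------------------------------------------------
# Trees and alignments


def simulate_yule_tree(
    n_taxa: int,
    seed: int | np.random.Generator = 0,
    mean_root_to_tip: float = 1.0,
    taxon_prefix: str = "t",
) -> Tree:
    """Pure-birth (Yule) topology with branch lengths rescaled so the
    mean root-to-tip path equals ``mean_root_to_tip`` substitutions per
    site."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    import random as _random

    import dendropy
    from dendropy.simulate import treesim

    rng = np.random.default_rng(seed)
    pyrng = _random.Random(int(rng.integers(0, 2**31 - 1)))
    taxa = dendropy.TaxonNamespace([f"{taxon_prefix}{i+1}" for i in range(n_taxa)])
    dtree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        taxon_namespace=taxa,
        rng=pyrng,
    )

    def convert(dnode) -> TreeNode:
        node = TreeNode(
            name=dnode.taxon.label if dnode.taxon else None,
            length=float(dnode.edge.length or 0.0),
        )
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    root = convert(dtree.seed_node)
    root.length = 0.0
    tree = Tree(root=root)

    depths: list[float] = []

    def depth(node: TreeNode, acc: float) -> None:
        if node.is_leaf:
            depths.append(acc)
        for c in node.children:
            depth(c, acc + c.length)

    depth(tree.root, 0.0)
    mean_depth = float(np.mean(depths))
    if mean_depth <= 0:  # degenerate 2-taxon draw: both tips at the root
        for node in tree.postorder():
            if node.is_leaf:
                node.length = mean_root_to_tip
    else:
        scale = mean_root_to_tip / mean_depth
        for node in tree.postorder():
            node.length *= scale
    tree.root.length = 0.0
    return tree


@dataclass(frozen=True)
class SimulatedAlignment:
    alignment: Alignment
    true_rates: np.ndarray          # per-column gamma rates
    designated_fast: np.ndarray     # bool mask of effect-carrying columns
    habitat_of_leaf: dict[str, Habitat]


def simulate_alignment(
    tree: Tree,
    n_columns: int,
    alpha: float = 0.7,
    seed: int | np.random.Generator = 0,
    model: SubstitutionModel | None = None,
    habitat_of_leaf: Mapping[str, Habitat] | None = None,
    fast_site_fraction: float = 0.0,
    swap_probability: float = 0.0,
) -> SimulatedAlignment:
    """Evolve a gap-free alignment along the tree under JTT with
    mean-one gamma(alpha) site rates, then inject a habitat-dependent
    nitrogen deficit at designated fast sites.

    Designated sites are the top ``fast_site_fraction`` of the drawn
    rate distribution.  At those sites, each nitrogen-bearing residue
    of an open-ocean leaf is swapped to its nitrogen-free counterpart
    (:data:`NITROGEN_SWAP`) with probability ``swap_probability`` —
    giving an expected relative nitrogen-content drop at designated
    sites of -100 * swap_probability percent.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    model = model or jtt_model()
    rng = np.random.default_rng(seed)
    rates = rng.gamma(shape=alpha, scale=1.0 / alpha, size=n_columns)

    eig, right, left = model._eigvals, model._right, model._left
    pi = model.frequencies

    leaf_states: dict[str, np.ndarray] = {}

    def evolve(node: TreeNode, states: np.ndarray) -> None:
        for child in node.children:
            t = child.length
            if t == 0:
                child_states = states.copy()
            else:
                # per-site transition rows: P_s[a_s, :] via spectral form
                decay = np.exp(np.outer(rates * t, eig))        # (S, 20)
                rows = np.einsum("sk,sk,kj->sj", right[states], decay, left)
                np.clip(rows, 0.0, None, out=rows)
                rows /= rows.sum(axis=1, keepdims=True)
                u = rng.random(n_columns)
                child_states = (rows.cumsum(axis=1) < u[:, None]).sum(axis=1)
                np.clip(child_states, 0, 19, out=child_states)
            if child.is_leaf:
                leaf_states[child.name] = child_states
            else:
                evolve(child, child_states)

    root_states = rng.choice(20, size=n_columns, p=pi)
    evolve(tree.root, root_states)
    if tree.root.is_leaf:  # degenerate single-node case
        leaf_states[tree.root.name] = root_states

    designated = np.zeros(n_columns, dtype=bool)
    if fast_site_fraction > 0:
        n_fast = int(round(fast_site_fraction * n_columns))
        designated[np.argsort(rates)[::-1][:n_fast]] = True

    habitat_of_leaf = dict(habitat_of_leaf or {})
    swap_codes = {
        AA_INDEX[src]: AA_INDEX[dst] for src, dst in NITROGEN_SWAP.items()
    }
    if swap_probability > 0 and fast_site_fraction > 0:
        fast_cols = np.nonzero(designated)[0]
        for name in sorted(leaf_states):
            if habitat_of_leaf.get(name) is not Habitat.OPEN_OCEAN:
                continue
            states = leaf_states[name]
            for col in fast_cols:
                code = int(states[col])
                if code in swap_codes and rng.random() < swap_probability:
                    states[col] = swap_codes[code]

    ids = tuple(sorted(leaf_states))
    rows = tuple(
        "".join(AMINO_ACIDS[c] for c in leaf_states[name]) for name in ids
    )
    return SimulatedAlignment(
        alignment=Alignment(ids=ids, rows=rows),
        true_rates=rates,
        designated_fast=designated,
        habitat_of_leaf={k: v for k, v in habitat_of_leaf.items()},
    )


# ---------------------------------------------------------------------------
# Whole-study generation


@dataclass
class StudyConfig:
    """Conditions of the generated study.

    Defaults emulate the analysis setting: a -5% open-vs-coastal
    difference in expected nitrogen content, proteome groups of 2,000
    sequences (>100 aa by construction), 300 membrane proteins per
    habitat, and two gene families — one from the nitrogen-starvation
    regulon with the deficit confined to designated fast sites, one
    arginine-pathway control with no habitat effect.
    """

    target_rel_diff_percent: float = -5.0
    n_sequences_per_group: int = 2000
    length_range: tuple[int, int] = (101, 300)
    n_membrane_per_group: int = 300
    tm_count_range: tuple[int, int] = (1, 4)
    effect_genes: tuple[str, ...] = ("NtcA",)
    null_genes: tuple[str, ...] = ("argF",)
    n_taxa_per_group: int = 250
    n_alignment_columns: int = 2000
    gamma_alpha: float = 0.7
    fast_site_fraction: float = 0.25
    fast_site_rel_diff_percent: float = -5.0
    mean_root_to_tip: float = 1.0


@dataclass(frozen=True)
class SyntheticStudy:
    """Handles to every generated file plus the underlying truth."""

    root: Path
    config: StudyConfig
    seed: int
    records: list[ProteinRecord]
    membrane_records: list[ProteinRecord]
    annotations: list[TopologyAnnotation]
    hits: list[HmmHit]
    alignments: dict[str, SimulatedAlignment]
    trees: dict[str, Tree]
    paths: dict[str, Path]


def _substream(master_seed: int, label: str) -> np.random.Generator:
    import zlib

    return np.random.default_rng([master_seed, zlib.crc32(label.encode())])


def generate_study(
    out_dir: str | Path,
    config: StudyConfig | None = None,
    master_seed: int = 0,
) -> SyntheticStudy:
    """Generate and write a complete labeled study.

    Writes FASTA, metadata TSV, Phobius-short text, HMMER-style hit
    tables with cutoff and gene-map TSVs, per-gene aligned FASTA and
    newick trees, truth TSVs and a YAML manifest.  On failure the
    partially written directory is removed.
    """
    config = config or StudyConfig()
    out = Path(out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _generate_study(out, config, master_seed)
    except Exception:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        raise


def _generate_study(out: Path, config: StudyConfig, master_seed: int) -> SyntheticStudy:
    paths: dict[str, Path] = {}
    coastal, open_ocean = make_environment_profiles(
        target_rel_diff_percent=config.target_rel_diff_percent
    )

    # --- proteomes: two open samples, one coastal, one estuary --------------
    sample_plan = [
        ("OO1", open_ocean, Habitat.OPEN_OCEAN),
        ("OO2", open_ocean, Habitat.OPEN_OCEAN),
        ("CO1", coastal, Habitat.COASTAL),
        ("ES1", coastal, Habitat.ESTUARY),
    ]
    per_sample = {
        "OO1": config.n_sequences_per_group // 2,
        "OO2": config.n_sequences_per_group - config.n_sequences_per_group // 2,
        "CO1": config.n_sequences_per_group // 2,
        "ES1": config.n_sequences_per_group - config.n_sequences_per_group // 2,
    }
    records: list[ProteinRecord] = []
    for sample_id, profile, habitat in sample_plan:
        recs = sample_proteome(
            EnvironmentProfile(profile.frequencies, habitat),
            per_sample[sample_id],
            config.length_range,
            seed=_substream(master_seed, f"proteome:{sample_id}"),
            sample_id=sample_id,
        )
        records.extend(recs)

    # --- membrane proteins --------------------------------------------------
    membrane_records: list[ProteinRecord] = []
    annotations: list[TopologyAnnotation] = []
    for sample_id, profile, habitat in sample_plan:
        rng = _substream(master_seed, f"membrane:{sample_id}")
        n = config.n_membrane_per_group // 2
        for i in range(n):
            n_tm = int(rng.integers(config.tm_count_range[0], config.tm_count_range[1] + 1))
            rec, ann = simulate_membrane_protein(
                rng,
                protein_id=f"{sample_id}_TM{i:04d}",
                n_tm=n_tm,
                loop_length_range=(20, 80),
                loop_profile=EnvironmentProfile(profile.frequencies, habitat),
                with_signal=bool(rng.random() < 0.2),
                sample_id=sample_id,
                habitat=habitat,
            )
            membrane_records.append(rec)
            annotations.append(ann)

    # --- gene families ------------------------------------------------------
    genes = list(config.effect_genes) + list(config.null_genes)
    alignments: dict[str, SimulatedAlignment] = {}
    trees: dict[str, Tree] = {}
    swap_prob = -config.fast_site_rel_diff_percent / 100.0
    for gene in genes:
        n_taxa = 2 * config.n_taxa_per_group
        tree = simulate_yule_tree(
            n_taxa,
            seed=_substream(master_seed, f"tree:{gene}"),
            mean_root_to_tip=config.mean_root_to_tip,
            taxon_prefix=f"{gene}_t",
        )
        leaves = tree.leaf_names
        rng = _substream(master_seed, f"habitats:{gene}")
        order = rng.permutation(len(leaves))
        habitat_of_leaf = {}
        for rank, leaf_idx in enumerate(order):
            habitat_of_leaf[leaves[leaf_idx]] = (
                Habitat.OPEN_OCEAN if rank < len(leaves) // 2 else Habitat.COASTAL
            )
        is_effect = gene in config.effect_genes
        sim = simulate_alignment(
            tree,
            n_columns=config.n_alignment_columns,
            alpha=config.gamma_alpha,
            seed=_substream(master_seed, f"alignment:{gene}"),
            habitat_of_leaf=habitat_of_leaf,
            fast_site_fraction=config.fast_site_fraction if is_effect else 0.0,
            swap_probability=swap_prob if is_effect else 0.0,
        )
        alignments[gene] = sim
        trees[gene] = tree

    # --- HMM hit tables -----------------------------------------------------
    gene_table = default_gene_table()
    acc_of = {g.gene_symbol: g.model_accessions[0] for g in gene_table}
    cutoffs = {acc: 25.0 for acc in acc_of.values()}
    rng = _substream(master_seed, "hits")
    hits: list[HmmHit] = []
    for gene, sim in alignments.items():
        for leaf in sim.alignment.ids:
            hits.append(
                HmmHit(
                    query_id=leaf,
                    model_accession=acc_of[gene],
                    model_name=gene,
                    full_sequence_bitscore=float(np.round(rng.uniform(60, 300), 1)),
                    full_sequence_evalue=float(10 ** rng.uniform(-60, -10)),
                )
            )
    # sub-cutoff decoys that the noise filter must remove
    for i in range(25):
        gene = genes[i % len(genes)]
        hits.append(
            HmmHit(
                query_id=f"decoy_{i:03d}",
                model_accession=acc_of[gene],
                model_name=gene,
                full_sequence_bitscore=float(np.round(rng.uniform(2, 24.9), 1)),
                full_sequence_evalue=float(10 ** rng.uniform(-3, 1)),
            )
        )

    # --- write everything ---------------------------------------------------
    import pandas as pd

    paths["proteins"] = out / "proteins.fasta"
    write_fasta(records, paths["proteins"])
    paths["membrane_proteins"] = out / "membrane_proteins.fasta"
    write_fasta(membrane_records, paths["membrane_proteins"])
    paths["metadata"] = out / "samples.tsv"
    pd.DataFrame(
        [
            {"sample_id": s, "habitat": h.value}
            for s, _, h in sample_plan
        ]
    ).to_csv(paths["metadata"], sep="\t", index=False)
    paths["phobius"] = out / "topology.phobius.txt"
    paths["phobius"].write_text(write_phobius_short(annotations))
    paths["hits"] = out / "hits.tblout.txt"
    paths["hits"].write_text(write_hmm_table(hits))
    paths["cutoffs"] = out / "noise_cutoffs.tsv"
    pd.DataFrame(
        [{"model_accession": a, "noise_cutoff_bits": c} for a, c in sorted(cutoffs.items())]
    ).to_csv(paths["cutoffs"], sep="\t", index=False)
    paths["gene_map"] = out / "gene_map.tsv"
    pd.DataFrame(
        [
            {"gene_symbol": g.gene_symbol, "pathway": g.pathway.value, "model_accession": acc}
            for g in gene_table
            for acc in g.model_accessions
        ]
    ).to_csv(paths["gene_map"], sep="\t", index=False)

    for gene, sim in alignments.items():
        afa = out / f"{gene}.aligned.fasta"
        with open(afa, "w") as fh:
            for sid, row in zip(sim.alignment.ids, sim.alignment.rows):
                fh.write(f">{sid}\n{row}\n")
        paths[f"alignment:{gene}"] = afa
        nwk = out / f"{gene}.nwk"
        nwk.write_text(trees[gene].to_newick() + "\n")
        paths[f"tree:{gene}"] = nwk
        truth = out / f"{gene}.true_rates.tsv"
        pd.DataFrame(
            {
                "column_index": np.arange(len(sim.true_rates)),
                "true_rate": sim.true_rates,
                "designated_fast": sim.designated_fast.astype(int),
            }
        ).to_csv(truth, sep="\t", index=False, float_format="%.6g")
        paths[f"true_rates:{gene}"] = truth
        hab = out / f"{gene}.leaf_habitats.tsv"
        pd.DataFrame(
            [
                {"leaf": k, "habitat": v.value}
                for k, v in sorted(sim.habitat_of_leaf.items())
            ]
        ).to_csv(hab, sep="\t", index=False)
        paths[f"leaf_habitats:{gene}"] = hab

    paths["manifest"] = out / "manifest.yaml"
    manifest = {
        "master_seed": master_seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "files": {k: str(v.name) for k, v in paths.items()},
        "true_effect": {
            "proteome_rel_diff_percent": config.target_rel_diff_percent,
            "fast_site_rel_diff_percent": config.fast_site_rel_diff_percent,
            "coastal_expected_nc": coastal.expected_nc,
            "open_expected_nc": open_ocean.expected_nc,
        },
    }
    paths["manifest"].write_text(yaml.safe_dump(manifest, sort_keys=True))

    return SyntheticStudy(
        root=out,
        config=config,
        seed=master_seed,
        records=records,
        membrane_records=membrane_records,
        annotations=annotations,
        hits=hits,
        alignments=alignments,
        trees=trees,
        paths=paths,
    )
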