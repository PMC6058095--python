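"""End-to-end analyses mirroring the study's three contrasts:

* overall: membrane vs non-membrane proteins, open ocean vs coastal;
* domain: cytoplasmic / transmembrane / periplasmic-extracellular
  domains of membrane proteins, split by single- vs multi-TM;
* rate-stratified: per gene family, nitrogen content over fast- and
  slow-evolving sites.

Each function returns a report DataFrame (one GroupComparison row per
stratum) plus a counter dict making the filter cascade auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .nitrogen import (
    Habitat,
    ProteinRecord,
    UnscorableSequenceError,
    filter_min_length,
    nitrogen_content,
)
from .site_rates import FAST, SLOW, Alignment, SiteRateModel, SiteRateResults
from .stats import Alternative, GroupComparison, Method, compare_groups
from .topology import (
    SegmentKind,
    TopologyAnnotation,
    classify_membrane,
    dissect_domains,
    filter_domain_sizes,
    tm_multiplicity,
)

logger = logging.getLogger("stoichseq")

__all__ = [
    "RunConfig",
    "run_overall_comparison",
    "run_domain_comparison",
    "run_rate_stratified_comparison",
    "rate_stratified_gene",
    "comparisons_to_frame",
]


@dataclass
class RunConfig:
    """Every analysis constant as a named, defaulted key."""

    min_length: int = 100
    min_domain: int = 20
    min_ungapped_fraction: float = 0.10
    n_rate_categories: int = 16
    alpha: float | None = None           # None = grid maximum likelihood
    slow_cutoff: float = -0.75
    fast_cutoff: float = 0.75
    alternative: str = "less"
    method: str = "monte_carlo"
    n_permutations: int = 10_000
    seed: int = 0
    max_inference_rows: int = 30         # tree/rate estimation subsample

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


def comparisons_to_frame(comparisons: Iterable[GroupComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        rows.append(
            {
                "stratum": c.stratum,
                "N_open": c.n_open,
                "N_coastal": c.n_coastal,
                "mean_open": c.mean_open,
                "mean_coastal": c.mean_coastal,
                "sem_open": c.sem_open,
                "sem_coastal": c.sem_coastal,
                "rel_diff_percent": c.relative_difference_percent,
                "p_value": c.p_value,
                "test": c.method.value,
                "alternative": c.alternative.value,
                "n_sites": c.n_sites if c.n_sites is not None else "",
            }
        )
    return pd.DataFrame(rows)


def _split_by_habitat(
    values: Sequence[float], habitats: Sequence[Habitat]
) -> tuple[list[float], list[float]]:
    open_vals, coastal_vals = [], []
    for v, h in zip(values, habitats):
        if h.analysis_label is Habitat.OPEN_OCEAN:
            open_vals.append(v)
        else:
            coastal_vals.append(v)
    return open_vals, coastal_vals


def _scored(records: Iterable[ProteinRecord]) -> tuple[list[float], list[Habitat], int]:
    values, habitats, dropped = [], [], 0
    for r in records:
        if r.habitat is None:
            raise ValueError(f"record {r.id} has no habitat label")
        try:
            values.append(nitrogen_content(r.sequence).value)
        except UnscorableSequenceError:
            logger.warning("dropped %s: unscorable", r.id)
            dropped += 1
            continue
        habitats.append(r.habitat)
    return values, habitats, dropped


def run_overall_comparison(
    records: Sequence[ProteinRecord],
    annotations: Mapping[str, TopologyAnnotation],
    config: RunConfig | None = None,
) -> tuple[list[GroupComparison], dict[str, int]]:
    """Open-vs-coastal nitrogen content for membrane and non-membrane
    proteins (four strata, two contrasts)."""
    config = config or RunConfig()
    counters = {"read": len(records)}
    unlabeled = [r.id for r in records if r.habitat is None]
    if unlabeled:
        raise ValueError(
            f"{len(unlabeled)} records lack habitat labels (e.g. {unlabeled[:5]})"
        )
    kept = filter_min_length(records, config.min_length)
    counters["length_filtered"] = len(records) - len(kept)
    membrane, non_membrane = [], []
    for r in kept:
        ann = annotations.get(r.id)
        if ann is not None and classify_membrane(ann):
            membrane.append(r)
        else:
            non_membrane.append(r)
    counters["membrane"] = len(membrane)
    counters["non_membrane"] = len(non_membrane)
    out: list[GroupComparison] = []
    for stratum, group in (("membrane", membrane), ("non_membrane", non_membrane)):
        values, habitats, dropped = _scored(group)
        counters[f"unscorable_{stratum}"] = dropped
        open_vals, coastal_vals = _split_by_habitat(values, habitats)
        out.append(
            compare_groups(
                open_vals, coastal_vals, stratum=stratum,
                alternative=config.alternative, method=config.method,
                n_permutations=config.n_permutations, seed=config.seed,
            )
        )
    counters["tested"] = len(out)
    return out, counters


def run_domain_comparison(
    records: Sequence[ProteinRecord],
    annotations: Mapping[str, TopologyAnnotation],
    config: RunConfig | None = None,
) -> tuple[list[GroupComparison], dict[str, int]]:
    """Per-domain contrasts for membrane proteins: 3 topological
    domains x single/multi TM (six strata)."""
    config = config or RunConfig()
    counters = {"read": len(records), "not_membrane": 0, "domain_size_filtered": 0}
    kept = filter_min_length(records, config.min_length)
    counters["length_filtered"] = len(records) - len(kept)
    per_stratum: dict[tuple[str, str], tuple[list[float], list[Habitat]]] = {}
    for r in kept:
        ann = annotations.get(r.id)
        if ann is None or not classify_membrane(ann):
            counters["not_membrane"] += 1
            continue
        domains = dissect_domains(r.sequence, ann)
        if not filter_domain_sizes(domains, config.min_domain):
            counters["domain_size_filtered"] += 1
            continue
        mult = tm_multiplicity(ann).value
        for kind in (
            SegmentKind.CYTOPLASMIC,
            SegmentKind.TRANSMEMBRANE,
            SegmentKind.PERIPLASMIC_EXTRACELLULAR,
        ):
            try:
                value = nitrogen_content(domains[kind]).value
            except UnscorableSequenceError:
                continue
            key = (kind.value, mult)
            per_stratum.setdefault(key, ([], []))[0].append(value)
            per_stratum[key][1].append(r.habitat)
    out: list[GroupComparison] = []
    for (kind, mult), (values, habitats) in sorted(per_stratum.items()):
        open_vals, coastal_vals = _split_by_habitat(values, habitats)
        if len(open_vals) < 2 or len(coastal_vals) < 2:
            logger.warning("stratum %s/%s skipped: too few sequences", kind, mult)
            continue
        if np.mean(coastal_vals) == 0:
            logger.warning("stratum %s/%s: zero coastal mean, not applicable", kind, mult)
            continue
        out.append(
            compare_groups(
                open_vals, coastal_vals, stratum=f"{kind}/{mult}",
                alternative=config.alternative, method=config.method,
                n_permutations=config.n_permutations, seed=config.seed,
            )
        )
    counters["tested"] = len(out)
    return out, counters


# ---------------------------------------------------------------------------
# Rate-stratified contrasts

from .jtt import AA_INDEX  # noqa: E402
from .nitrogen import SIDE_CHAIN_NITROGEN  # noqa: E402

_N_VALUES = np.array(
    [SIDE_CHAIN_NITROGEN[a] for a in sorted(AA_INDEX, key=AA_INDEX.get)], dtype=float
)


def _masked_nc_per_row(alignment: Alignment, column_mask: np.ndarray) -> np.ndarray:
    """Per-row Nc over the selected columns (NaN when a row has no
    scorable residue there); vectorized over the encoded alignment."""
    enc = alignment.encoded()
    sel = enc[:, column_mask]
    scorable = sel >= 0
    counts = scorable.sum(axis=1)
    totals = np.where(scorable, _N_VALUES[np.clip(sel, 0, 19)], 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, totals / np.maximum(counts, 1), np.nan)


def _stratified_subsample(
    ids: Sequence[str],
    habitat_of_leaf: Mapping[str, Habitat],
    max_rows: int,
    seed: int,
) -> list[str]:
    if len(ids) <= max_rows:
        return list(ids)
    rng = np.random.default_rng(seed)
    open_ids = [i for i in ids if habitat_of_leaf[i].analysis_label is Habitat.OPEN_OCEAN]
    coastal_ids = [i for i in ids if habitat_of_leaf[i].analysis_label is Habitat.COASTAL]
    half = max_rows // 2
    chosen = list(rng.choice(open_ids, size=min(half, len(open_ids)), replace=False))
    chosen += list(
        rng.choice(coastal_ids, size=min(max_rows - len(chosen), len(coastal_ids)), replace=False)
    )
    return sorted(chosen)


def rate_stratified_gene(
    gene: str,
    alignment: Alignment,
    habitat_of_leaf: Mapping[str, Habitat],
    config: RunConfig | None = None,
) -> tuple[list[GroupComparison], SiteRateResults]:
    """Fast- and slow-site nitrogen contrasts for one gene family.

    Site rates are estimated on a stratified subsample of at most
    ``config.max_inference_rows`` sequences (rates are column
    properties, so classes transfer to every row); masked per-sequence
    Nc over each rate class is then compared between habitats across
    all sequences.
    """
    config = config or RunConfig()
    sub_ids = _stratified_subsample(
        alignment.ids, habitat_of_leaf, config.max_inference_rows, config.seed
    )
    sub = Alignment(
        ids=tuple(sub_ids), rows=tuple(alignment.row(i) for i in sub_ids)
    )
    results = SiteRateModel(
        sub,
        n_categories=config.n_rate_categories,
        alpha=config.alpha,
        min_ungapped_fraction=config.min_ungapped_fraction,
        slow_cutoff=config.slow_cutoff,
        fast_cutoff=config.fast_cutoff,
    ).fit()

    comparisons: list[GroupComparison] = []
    habitats = [habitat_of_leaf[i] for i in alignment.ids]
    for klass in (FAST, SLOW):
        col_mask = results.included & (results.classes == klass)
        n_sites = int(col_mask.sum())
        if n_sites == 0:
            logger.warning("%s: no %s sites, contrast skipped", gene, klass)
            continue
        values = _masked_nc_per_row(alignment, col_mask)
        keep = ~np.isnan(values)
        open_vals, coastal_vals = _split_by_habitat(
            values[keep], [h for h, k in zip(habitats, keep) if k]
        )
        if len(open_vals) < 2 or len(coastal_vals) < 2:
            logger.warning("%s/%s skipped: fewer than 2 sequences per group", gene, klass)
            continue
        comparisons.append(
            compare_groups(
                open_vals, coastal_vals, stratum=f"{gene}/{klass}",
                alternative=config.alternative, method=config.method,
                n_permutations=config.n_permutations, seed=config.seed,
                n_sites=n_sites,
            )
        )
    return comparisons, results


def localization_replicate(
    seed: int,
    n_taxa_per_group: int = 250,
    n_columns: int = 2000,
    alpha: float = 0.7,
    fast_site_fraction: float = 0.25,
    fast_site_rel_diff_percent: float = -5.0,
    config: RunConfig | None = None,
) -> dict[str, GroupComparison]:
    """One synthetic gene family with a nitrogen deficit confined to
    designated fast sites, pushed through the rate-stratified contrast.

    Returns the fast- and slow-class comparisons keyed by class — the
    unit of the localization power study (can the pipeline see an
    effect at fast sites and no effect at slow sites?).
    """
    from .simulate import simulate_alignment, simulate_yule_tree

    config = config or RunConfig(alpha=alpha, method="normal_approx", seed=seed)
    rng = np.random.default_rng([seed, 0xA11C])
    tree = simulate_yule_tree(2 * n_taxa_per_group, seed=rng)
    leaves = tree.leaf_names
    order = np.random.default_rng([seed, 0xA11D]).permutation(len(leaves))
    habitat_of_leaf = {
        leaves[i]: (Habitat.OPEN_OCEAN if rank < n_taxa_per_group else Habitat.COASTAL)
        for rank, i in enumerate(order)
    }
    sim = simulate_alignment(
        tree,
        n_columns=n_columns,
        alpha=alpha,
        seed=np.random.default_rng([seed, 0xA11E]),
        habitat_of_leaf=habitat_of_leaf,
        fast_site_fraction=fast_site_fraction,
        swap_probability=-fast_site_rel_diff_percent / 100.0,
    )
    comps, _ = rate_stratified_gene("gene", sim.alignment, habitat_of_leaf, config)
    return {c.stratum.split("/")[1]: c for c in comps}


def run_rate_stratified_comparison(
    gene_alignments: Mapping[str, Alignment],
    habitats_per_gene: Mapping[str, Mapping[str, Habitat]],
    config: RunConfig | None = None,
) -> tuple[list[GroupComparison], dict[str, SiteRateResults]]:
    """Fast/slow-site contrasts across gene families (scatter-ready)."""
    config = config or RunConfig()
    comparisons: list[GroupComparison] = []
    fits: dict[str, SiteRateResults] = {}
    for gene in sorted(gene_alignments):
        comps, results = rate_stratified_gene(
            gene, gene_alignments[gene], habitats_per_gene[gene], config
        )
        comparisons.extend(comps)
        fits[gene] = results
    return comparisons, fits
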