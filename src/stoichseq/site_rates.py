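"""Per-site evolutionary rate estimation by empirical Bayes.

Given a protein multiple sequence alignment, the procedure is:

1. exclude columns with fewer than 10% ungapped residues;
2. compute Poisson-corrected pairwise distances and a neighbor-joining
   tree (branch lengths taken as-is, no optimization);
3. under the JTT substitution model with a mean-one discrete-gamma rate
   prior (K equal-probability categories), compute each column's
   likelihood at every category rate with Felsenstein's pruning
   algorithm, estimating the gamma shape alpha by grid maximum
   likelihood;
4. report the posterior mean rate per column,
       r_hat_s = sum_k r_k p_k L_s(r_k) / sum_k p_k L_s(r_k),
   z-score-normalize over included columns (mean 0, sd 1), and classify
   sites as slow (z <= -0.75), fast (z >= +0.75) or intermediate.

Slow sites are interpreted as functionally constrained (purifying
selection), fast sites as weakly constrained — the strata over which
nitrogen content is then compared between habitats.

The public surface is :class:`SiteRateModel` / :class:`SiteRateResults`;
the stage functions below them are usable on their own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import gamma as gamma_dist

from .jtt import AA_INDEX, SubstitutionModel, jtt_model
from .trees import Tree, TreeNode, nj_tree, pairwise_distance_matrix

__all__ = [
    "Alignment",
    "RateModel",
    "SiteRateModel",
    "SiteRateResults",
    "read_alignment_fasta",
    "mask_columns",
    "discretize_gamma",
    "site_log_likelihoods",
    "site_likelihood",
    "posterior_mean_rates",
    "estimate_alpha",
    "normalize_scores",
    "classify_sites",
    "map_rates_to_sequence",
    "SLOW", "INTERMEDIATE", "FAST",
]

SLOW, INTERMEDIATE, FAST = "slow", "intermediate", "fast"


@dataclass(frozen=True)
class Alignment:
    """Equal-length aligned rows over residues and the gap symbol '-'."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        object.__setattr__(self, "rows", tuple(r.upper() for r in self.rows))

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"sequence id {seq_id!r} not in alignment") from None

    def encoded(self) -> np.ndarray:
        """(n_rows, n_cols) int8 matrix; 0..19 residues, -1 for gap or
        any ambiguity code (treated as missing data)."""
        mat = np.full((self.n_rows, self.n_cols), -1, dtype=np.int8)
        for i, row in enumerate(self.rows):
            for j, ch in enumerate(row):
                mat[i, j] = AA_INDEX.get(ch, -1)
        return mat


def read_alignment_fasta(path: str | Path) -> Alignment:
    from Bio import SeqIO

    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq))
    return Alignment(ids=tuple(ids), rows=tuple(rows))


def mask_columns(alignment: Alignment, min_ungapped_fraction: float = 0.10) -> np.ndarray:
    """Column inclusion flags: a column is excluded iff fewer than
    ``min_ungapped_fraction`` of its rows carry a residue (strict <)."""
    enc = alignment.encoded()
    frac = (enc >= 0).mean(axis=0)
    return frac >= min_ungapped_fraction


@dataclass(frozen=True)
class RateModel:
    """Mean-one discrete rate prior with equal category probabilities."""

    alpha: float
    rates: np.ndarray  # increasing, mean 1

    @property
    def n_categories(self) -> int:
        return len(self.rates)

    @property
    def probabilities(self) -> np.ndarray:
        k = self.n_categories
        return np.full(k, 1.0 / k)


def discretize_gamma(alpha: float, n_categories: int) -> RateModel:
    """Discretize a mean-one gamma(alpha) into K equal-probability
    categories, each represented by its conditional mean (computed from
    the incomplete-gamma identity), renormalized so the category mean
    is exactly 1."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    k = int(n_categories)
    if k < 1:
        raise ValueError("need at least one category")
    if k == 1:
        return RateModel(alpha=alpha, rates=np.array([1.0]))
    edges = gamma_dist.ppf(np.linspace(0.0, 1.0, k + 1), a=alpha, scale=1.0 / alpha)
    # E[X | a < X < b] * P(a < X < b) = F_{alpha+1}(b) - F_{alpha+1}(a)
    cdf_up = gamma_dist.cdf(edges, a=alpha + 1.0, scale=1.0 / alpha)
    rates = k * np.diff(cdf_up)
    rates = rates / (rates.mean())
    return RateModel(alpha=alpha, rates=rates)


# ---------------------------------------------------------------------------
# Pruning likelihoods


def _edge_list(tree: Tree) -> list[tuple[TreeNode, list[TreeNode]]]:
    """Internal nodes in postorder with their children."""
    return [(n, n.children) for n in tree.postorder() if not n.is_leaf]


def site_log_likelihoods(
    encoded: np.ndarray,
    leaf_order: Sequence[str],
    tree: Tree,
    model: SubstitutionModel,
    rates: Sequence[float],
) -> np.ndarray:
    """log L_s(r_k) for every column s and rate r_k.

    Felsenstein pruning with per-column rescaling: gap/ambiguity cells
    contribute an all-ones partial vector (missing data); the root is
    weighted by the equilibrium frequencies (reversibility makes the
    root placement immaterial).  Returns an array of shape
    (len(rates), n_cols).
    """
    idx = {name: i for i, name in enumerate(leaf_order)}
    n_cols = encoded.shape[1]
    pi = model.frequencies
    out = np.empty((len(rates), n_cols))

    # leaf partials are rate-independent: indicator vectors / all-ones
    leaf_partials: dict[int, np.ndarray] = {}

    def leaf_partial(row: int) -> np.ndarray:
        part = leaf_partials.get(row)
        if part is None:
            codes = encoded[row]
            part = np.zeros((n_cols, 20))
            missing = codes < 0
            part[missing, :] = 1.0
            cols = np.nonzero(~missing)[0]
            part[cols, codes[cols]] = 1.0
            leaf_partials[row] = part
        return part

    for k, rate in enumerate(rates):
        stack: dict[int, tuple[np.ndarray, np.ndarray]] = {}

        def partial(node: TreeNode) -> tuple[np.ndarray, np.ndarray]:
            if node.is_leaf:
                return leaf_partial(idx[node.name]), np.zeros(n_cols)
            prod = np.ones((n_cols, 20))
            logscale = np.zeros(n_cols)
            for child in node.children:
                cpart, cscale = partial(child)
                p = model.transition(child.length, rate)
                prod *= cpart @ p.T
                logscale += cscale
            m = prod.max(axis=1)
            m[m == 0] = 1.0
            prod /= m[:, None]
            return prod, logscale + np.log(m)

        part, logscale = partial(tree.root)
        with np.errstate(divide="ignore"):
            out[k] = np.log(part @ pi) + logscale
    return out


def site_likelihood(
    column: Sequence[str],
    tree: Tree,
    model: SubstitutionModel,
    rate: float = 1.0,
) -> float:
    """Likelihood of a single alignment column (residues/gaps in the
    order of the tree's leaf names)."""
    leaves = tree.leaf_names
    if len(column) != len(leaves):
        raise ValueError("column length must equal leaf count")
    enc = np.array(
        [[AA_INDEX.get(ch.upper(), -1)] for ch in column], dtype=np.int8
    )
    ll = site_log_likelihoods(enc, leaves, tree, model, [rate])
    return float(np.exp(ll[0, 0]))


def posterior_mean_rates(loglik: np.ndarray, rate_model: RateModel) -> np.ndarray:
    """Posterior mean rate per column from the (K, n_cols) category
    log-likelihood matrix; equal prior category weights.  Computed in
    log space, so category-likelihood underflow cannot corrupt the
    posterior weights."""
    logw = loglik - logsumexp(loglik, axis=0, keepdims=True)
    return np.exp(logw).T @ rate_model.rates


def estimate_alpha(
    encoded: np.ndarray,
    leaf_order: Sequence[str],
    tree: Tree,
    model: SubstitutionModel,
    n_categories: int = 16,
    grid: Sequence[float] | None = None,
) -> tuple[float, np.ndarray]:
    """Grid maximum likelihood for the gamma shape.

    Maximizes sum_s log mean_k L_s(r_k) over a log-spaced alpha grid
    (default 0.1-5.0, 25 points).  Returns the best alpha and its
    (K, n_cols) log-likelihood matrix; a boundary maximum triggers a
    warning.
    """
    if grid is None:
        grid = np.geomspace(0.1, 5.0, 25)
    grid = np.asarray(list(grid), dtype=float)
    best_ll, best_alpha, best_mat = -np.inf, grid[0], None
    for alpha in grid:
        rm = discretize_gamma(alpha, n_categories)
        mat = site_log_likelihoods(encoded, leaf_order, tree, model, rm.rates)
        total = float(np.sum(logsumexp(mat, axis=0) - np.log(rm.n_categories)))
        if total > best_ll:
            best_ll, best_alpha, best_mat = total, float(alpha), mat
    if best_alpha in (grid[0], grid[-1]) and len(grid) > 1:
        warnings.warn(
            f"alpha maximum at grid boundary ({best_alpha}); consider widening the grid",
            stacklevel=2,
        )
    return best_alpha, best_mat


def normalize_scores(rates: np.ndarray) -> np.ndarray:
    """Z-scores over included columns: mean 0, sd 1 (population sd);
    all zero when the rates are constant."""
    rates = np.asarray(rates, dtype=float)
    if len(rates) < 2:
        raise ValueError("need at least 2 included columns to normalize")
    sd = rates.std()
    if sd == 0:
        return np.zeros_like(rates)
    return (rates - rates.mean()) / sd


def classify_sites(
    zscores: np.ndarray, slow_cutoff: float = -0.75, fast_cutoff: float = 0.75
) -> np.ndarray:
    """Slow iff z <= slow_cutoff, fast iff z >= fast_cutoff (cutoffs
    inclusive), else intermediate."""
    z = np.asarray(zscores, dtype=float)
    out = np.full(z.shape, INTERMEDIATE, dtype=object)
    out[z <= slow_cutoff] = SLOW
    out[z >= fast_cutoff] = FAST
    return out


def map_rates_to_sequence(
    alignment: Alignment,
    seq_id: str,
    included: np.ndarray,
    classes: np.ndarray,
) -> dict[int, str]:
    """Map column classes onto the ungapped residues of one sequence.

    Returns {1-based ungapped position: class} for positions whose
    column is included; positions in excluded columns are absent (and
    therefore dropped from any masked nitrogen score).
    """
    row = alignment.row(seq_id)
    out: dict[int, str] = {}
    pos = 0
    for col, ch in enumerate(row):
        if ch == "-":
            continue
        pos += 1
        if included[col]:
            out[pos] = classes[col]
    return out


# ---------------------------------------------------------------------------
# Model / Results


class SiteRateModel:
    """Empirical-Bayes site-rate model for one protein alignment.

    Parameters
    ----------
    alignment
        The protein MSA (rows over residues and ``-``).
    n_categories
        Discrete-gamma category count (default 16).
    alpha
        Fix the gamma shape; ``None`` estimates it by grid ML.
    min_ungapped_fraction
        Columns below this ungapped fraction are excluded (default 0.10).
    slow_cutoff, fast_cutoff
        Z-score class boundaries (default -0.75 / +0.75, inclusive).
    tree
        Optional fixed tree; by default a neighbor-joining tree is
        built from Poisson-corrected distances.
    """

    def __init__(
        self,
        alignment: Alignment,
        *,
        n_categories: int = 16,
        alpha: float | None = None,
        alpha_grid: Sequence[float] | None = None,
        min_ungapped_fraction: float = 0.10,
        slow_cutoff: float = -0.75,
        fast_cutoff: float = 0.75,
        substitution_model: SubstitutionModel | None = None,
        tree: Tree | None = None,
    ) -> None:
        self.alignment = alignment
        self.n_categories = n_categories
        self.alpha = alpha
        self.alpha_grid = alpha_grid
        self.min_ungapped_fraction = min_ungapped_fraction
        self.slow_cutoff = slow_cutoff
        self.fast_cutoff = fast_cutoff
        self.substitution_model = substitution_model or jtt_model()
        self.tree = tree

    @classmethod
    def from_fasta(cls, path: str | Path, **kwargs) -> "SiteRateModel":
        return cls(read_alignment_fasta(path), **kwargs)

    def fit(self) -> "SiteRateResults":
        aln = self.alignment
        included = mask_columns(aln, self.min_ungapped_fraction)
        if included.sum() < 2:
            raise ValueError("fewer than 2 included columns")
        tree = self.tree
        if tree is None:
            dist = pairwise_distance_matrix(list(aln.rows))
            tree = nj_tree(list(aln.ids), dist)
        enc = aln.encoded()[:, included]
        if self.alpha is None and self.n_categories > 1:
            alpha, loglik = estimate_alpha(
                enc, aln.ids, tree, self.substitution_model,
                self.n_categories, self.alpha_grid,
            )
        else:
            alpha = self.alpha if self.alpha is not None else 1.0
            rm = discretize_gamma(alpha, self.n_categories)
            loglik = site_log_likelihoods(
                enc, aln.ids, tree, self.substitution_model, rm.rates
            )
        rate_model = discretize_gamma(alpha, self.n_categories)
        r_inc = posterior_mean_rates(loglik, rate_model)
        z_inc = normalize_scores(r_inc)
        cls_inc = classify_sites(z_inc, self.slow_cutoff, self.fast_cutoff)

        n_cols = aln.n_cols
        rates = np.full(n_cols, np.nan)
        zscores = np.full(n_cols, np.nan)
        classes = np.full(n_cols, None, dtype=object)
        rates[included] = r_inc
        zscores[included] = z_inc
        classes[included] = cls_inc
        total_ll = float(
            np.sum(logsumexp(loglik, axis=0) - np.log(rate_model.n_categories))
        )
        return SiteRateResults(
            model=self, tree=tree, alpha=alpha, rate_model=rate_model,
            included=included, rates=rates, zscores=zscores, classes=classes,
            log_likelihood=total_ll,
        )


@dataclass(frozen=True)
class SiteRateResults:
    """Fitted per-site rates, their normalized scores and classes."""

    model: SiteRateModel
    tree: Tree
    alpha: float
    rate_model: RateModel
    included: np.ndarray       # (n_cols,) bool
    rates: np.ndarray          # posterior means; NaN at excluded columns
    zscores: np.ndarray
    classes: np.ndarray        # 'slow'/'intermediate'/'fast'; None excluded
    log_likelihood: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "column_index": np.arange(len(self.rates)),
                "included": self.included.astype(int),
                "rate": self.rates,
                "z": self.zscores,
                "class": [c if c is not None else "" for c in self.classes],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def map_to_sequence(self, seq_id: str) -> dict[int, str]:
        return map_rates_to_sequence(
            self.model.alignment, seq_id, self.included, self.classes
        )

    def summary(self) -> str:
        n_inc = int(self.included.sum())
        counts = {
            k: int(np.sum(self.classes[self.included] == k))
            for k in (SLOW, INTERMEDIATE, FAST)
        }
        lines = [
            "Empirical-Bayes site rates (JTT + discrete gamma)",
            "=" * 50,
            f"sequences:            {self.model.alignment.n_rows}",
            f"columns:              {len(self.rates)} ({n_inc} included)",
            f"gamma shape alpha:    {self.alpha:.4g}"
            + ("  (fixed)" if self.model.alpha is not None else "  (grid ML)"),
            f"rate categories:      {self.rate_model.n_categories}",
            f"log-likelihood:       {self.log_likelihood:.4f}",
            f"site classes:         slow {counts[SLOW]}, "
            f"intermediate {counts[INTERMEDIATE]}, fast {counts[FAST]}",
            f"class cutoffs (z):    <= {self.model.slow_cutoff} slow, "
            f">= {self.model.fast_cutoff} fast",
        ]
        return "\n".join(lines)
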