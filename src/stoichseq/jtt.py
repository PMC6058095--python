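"""The Jones-Taylor-Thornton (JTT) amino-acid substitution model.

A general time-reversible rate matrix Q is assembled from the published
JTT exchangeability table and equilibrium frequencies:

    Q_ij = s_ij * pi_j   (i != j),   Q_ii = -sum_{j != i} Q_ij,

scaled so the expected substitution rate at equilibrium,
``-sum_i pi_i Q_ii``, equals 1 — branch lengths are then expected
substitutions per site.  Transition matrices P(t) = expm(Q t r) are
computed through the symmetric eigendecomposition of
``diag(sqrt(pi)) Q diag(1/sqrt(pi))``, which time reversibility makes
exact and cheap to re-evaluate for many branch-length/rate products.

The exchangeability constants below are the standard published integer
table (lower triangle, residue order ARNDCQEGHILKMFPSTWYV).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AMINO_ACIDS", "AA_INDEX", "SubstitutionModel", "jtt_model", "jtt_transition"]

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Published JTT exchangeabilities, lower triangle row by row:
# row R: (A); row N: (A, R); ... row V: (A, ..., Y).
_JTT_LOWER = [
    58,
    54, 45,
    81, 16, 528,
    56, 113, 34, 10,
    57, 310, 86, 49, 9,
    105, 29, 58, 767, 5, 323,
    179, 137, 81, 130, 59, 26, 119,
    27, 328, 391, 112, 69, 597, 26, 23,
    36, 22, 47, 11, 17, 9, 12, 6, 16,
    30, 38, 12, 7, 23, 72, 9, 6, 56, 229,
    35, 646, 263, 26, 7, 292, 181, 27, 45, 21, 14,
    54, 44, 30, 15, 31, 43, 18, 14, 33, 479, 388, 65,
    15, 5, 10, 4, 78, 4, 5, 5, 40, 89, 248, 4, 43,
    194, 74, 15, 15, 14, 164, 18, 24, 115, 10, 102, 21, 16, 17,
    378, 101, 503, 59, 223, 53, 30, 201, 73, 40, 59, 47, 29, 92, 285,
    475, 64, 232, 38, 42, 51, 32, 33, 46, 245, 25, 103, 226, 12, 118, 477,
    9, 126, 8, 4, 115, 18, 10, 55, 8, 9, 52, 10, 24, 53, 6, 35, 12,
    11, 20, 70, 46, 209, 24, 7, 8, 573, 32, 24, 8, 18, 536, 10, 63, 21, 71,
    298, 17, 16, 31, 62, 20, 45, 47, 11, 961, 180, 14, 323, 62, 23, 38, 112, 25, 16,
]

_JTT_FREQS = [
    0.076747923252076758, 0.051690948309051694, 0.042644957355042652,
    0.051543948456051550, 0.019802980197019805, 0.040751959248040752,
    0.061829938170061841, 0.073151926848073159, 0.022943977056022944,
    0.053760946239053767, 0.091903908096091905, 0.058675941324058678,
    0.023825976174023829, 0.040125959874040135, 0.050900949099050907,
    0.068764931235068771, 0.058564941435058568, 0.014260985739014262,
    0.032101967898032102, 0.066004933995066004,
]


def _exchangeability_matrix() -> np.ndarray:
    s = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            s[i, j] = s[j, i] = _JTT_LOWER[k]
            k += 1
    assert k == 190
    return s


@dataclass(frozen=True)
class SubstitutionModel:
    """Time-reversible 20-state model with precomputed spectral form."""

    rate_matrix: np.ndarray          # Q, rows sum to 0, mean rate 1
    frequencies: np.ndarray          # pi, sums to 1
    _eigvals: np.ndarray = field(repr=False, default=None)
    _right: np.ndarray = field(repr=False, default=None)   # diag(1/sqrt(pi)) V
    _left: np.ndarray = field(repr=False, default=None)    # V.T diag(sqrt(pi))

    @classmethod
    def from_exchangeabilities(
        cls, s: np.ndarray, frequencies: np.ndarray
    ) -> "SubstitutionModel":
        pi = np.asarray(frequencies, dtype=float)
        pi = pi / pi.sum()
        q = np.asarray(s, dtype=float) * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mean_rate = -float(np.dot(pi, np.diag(q)))
        q = q / mean_rate
        sqrt_pi = np.sqrt(pi)
        sym = (q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        sym = 0.5 * (sym + sym.T)  # enforce exact symmetry pre-decomposition
        eigvals, v = np.linalg.eigh(sym)
        right = v / sqrt_pi[:, None]
        left = v.T * sqrt_pi[None, :]
        return cls(rate_matrix=q, frequencies=pi,
                   _eigvals=eigvals, _right=right, _left=left)

    def transition(self, branch_length: float, rate: float = 1.0) -> np.ndarray:
        """P(t) for t = branch_length * rate; rows sum to 1."""
        t = branch_length * rate
        if t < 0:
            raise ValueError("branch length and rate must be non-negative")
        p = (self._right * np.exp(self._eigvals * t)) @ self._left
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p


def jtt_model() -> SubstitutionModel:
    """The JTT model, scaled to one expected substitution per unit time."""
    return SubstitutionModel.from_exchangeabilities(
        _exchangeability_matrix(), np.array(_JTT_FREQS)
    )


def jtt_transition(
    branch_length: float, rate: float, model: SubstitutionModel | None = None
) -> np.ndarray:
    """Transition probability matrix under JTT for one branch."""
    if model is None:
        model = jtt_model()
    return model.transition(branch_length, rate)
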