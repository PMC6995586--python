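"""Coevolutionary coupling scores from a multiple sequence alignment.

Implements the classical mean-field direct coupling analysis (mfDCA)
workflow over a q = 21 state alphabet (20 amino acids + gap):

1. *Sequence reweighting.*  Each row ``a`` receives weight ``1 / m_a``
   where ``m_a`` is the number of rows (including itself) whose fractional
   identity to ``a`` is at least the identity threshold (default 0.8).
   The sum of weights is the effective sequence count ``M_eff``.

2. *Pseudocounted frequencies.*  Single-site frequencies
   ``P_i(A) = (lambda/q + sum_a w_a [A_i^a = A]) / (lambda + M_eff)`` and
   pair frequencies with ``lambda/q**2`` in the numerator.  The diagonal
   pair block is defined as ``P_ii(A,B) = delta_AB P_i(A)`` so that
   marginal consistency holds exactly for every pair.

3. *Mutual information* (natural log) between columns, computed from the
   same frequency model — captures direct plus transitively induced
   covariation.

4. *Mean-field couplings.*  The connected-correlation matrix
   ``C_ij(A,B) = P_ij(A,B) - P_i(A) P_j(B)`` is built over q - 1 states
   per site (the gap state is the reference/gauge state) and the pair
   couplings are ``e = -C^{-1}``.

5. *Direct information.*  For each pair a two-site distribution
   ``P^dir_ij(A,B) ~ exp(e_ij(A,B) + h_i(A) + h_j(B))`` is fitted by a
   fixed-point iteration so that its marginals match ``P_i`` and ``P_j``;
   ``DI_ij`` is the mutual information of that two-site distribution.
   DI isolates the *direct* statistical coupling of a pair from
   correlations mediated by third sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .msa_io import Alignment, GAP_STATE, Q

logger = logging.getLogger(__name__)

DEFAULT_IDENTITY_THRESHOLD = 0.8


@dataclass
class WeightSet:
    """Per-sequence reweighting factors and the effective sequence count."""

    weights: np.ndarray
    identity_threshold: float

    @property
    def m_eff(self) -> float:
        return float(self.weights.sum())


@dataclass
class FrequencyModel:
    """Pseudocounted single-site and pair frequencies of an alignment."""

    f1: np.ndarray  # (L, q)
    f2: np.ndarray  # (L, L, q, q)
    lam: float
    q: int = Q

    @property
    def length(self) -> int:
        return self.f1.shape[0]


@dataclass
class CouplingScores:
    """Symmetric per-pair MI and DI matrices plus the parameters used."""

    mi: np.ndarray
    di: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.mi.shape[0]


def compute_weights(
    aln: Alignment,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    chunk: int = 256,
) -> WeightSet:
    """Down-weight redundant rows: weight of row a is 1/m_a.

    ``m_a`` counts the rows (including ``a`` itself) whose fraction of
    identical positions with ``a`` is >= ``identity_threshold``.  With all
    rows mutually dissimilar every weight is 1 and ``M_eff = M``; M copies
    of one sequence jointly weigh 1.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0, 1]")
    X = aln.matrix
    M, L = X.shape
    counts = np.zeros(M, dtype=np.int64)
    # chunked O(M^2 L) comparison; exact, no approximation
    for start in range(0, M, chunk):
        block = X[start : start + chunk]  # (b, L)
        ident = (block[:, None, :] == X[None, :, :]).sum(axis=2)  # (b, M)
        counts[start : start + chunk] = (ident >= identity_threshold * L).sum(axis=1)
    weights = 1.0 / counts
    return WeightSet(weights=weights, identity_threshold=identity_threshold)


def frequencies(aln: Alignment, w: WeightSet, lam: float) -> FrequencyModel:
    """Pseudocounted weighted frequency model of the alignment.

    ``lam`` spreads a pseudocount uniformly over the q (q^2) outcomes of
    each site (pair); ``lam = M_eff`` is the mfDCA convention used as the
    pipeline default.
    """
    if lam < 0:
        raise ValueError("pseudocount lambda must be nonnegative")
    X = aln.matrix
    M, L = X.shape
    m_eff = w.m_eff
    norm = lam + m_eff

    onehot = np.zeros((M, L, Q), dtype=np.float64)
    onehot[np.arange(M)[:, None], np.arange(L)[None, :], X] = 1.0

    f1 = (lam / Q + np.einsum("a,alA->lA", w.weights, onehot)) / norm

    flat = onehot.reshape(M, L * Q)
    pair_counts = (flat * w.weights[:, None]).T @ flat  # (L*Q, L*Q)
    f2 = (lam / Q**2 + pair_counts.reshape(L, Q, L, Q).transpose(0, 2, 1, 3)) / norm

    # diagonal pair block is the single-site distribution on the diagonal,
    # which keeps marginal consistency exact for i = j as well
    eye = np.eye(Q)
    for i in range(L):
        f2[i, i] = eye * f1[i]
    return FrequencyModel(f1=f1, f2=f2, lam=lam)


def mutual_information(fm: FrequencyModel) -> np.ndarray:
    """Plug-in mutual information (nats) for every column pair.

    ``MI_ij = sum_AB P_ij(A,B) ln(P_ij(A,B) / (P_i(A) P_j(B)))`` with the
    convention ``0 * ln(0/x) = 0``; the diagonal is zeroed.
    """
    L = fm.length
    prod = fm.f1[:, None, :, None] * fm.f1[None, :, None, :]  # (L, L, q, q)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(fm.f2 > 0, fm.f2 / prod, 1.0)
        mi = np.sum(fm.f2 * np.log(ratio), axis=(2, 3))
    np.fill_diagonal(mi, 0.0)
    return 0.5 * (mi + mi.T)


def mean_field_couplings(fm: FrequencyModel) -> np.ndarray:
    """Mean-field pair couplings ``e = -C^{-1}``.

    The connected-correlation matrix C is built over q - 1 states per site
    (the gap state is removed as the gauge/reference state, which makes C
    invertible given a pseudocount).  Returns an ``(L, L, q, q)`` tensor
    with zeros in the reference-state rows/columns and on the site
    diagonal; symmetric under ``(i, A) <-> (j, B)`` exchange.
    """
    if fm.lam <= 0:
        raise ValueError("mean-field inversion requires a pseudocount lambda > 0")
    L, q = fm.length, fm.q
    keep = [s for s in range(q) if s != GAP_STATE]  # q-1 non-gap states
    r = len(keep)
    f1r = fm.f1[:, keep]  # (L, r)
    f2r = fm.f2[np.ix_(range(L), range(L), keep, keep)]  # (L, L, r, r)
    C = f2r - f1r[:, None, :, None] * f1r[None, :, None, :]
    Cmat = C.transpose(0, 2, 1, 3).reshape(L * r, L * r)
    try:
        e_mat = -np.linalg.inv(Cmat)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "connected-correlation matrix is singular; increase the pseudocount lambda"
        ) from err
    e_r = e_mat.reshape(L, r, L, r).transpose(0, 2, 1, 3)  # (L, L, r, r)
    e = np.zeros((L, L, q, q))
    e[np.ix_(range(L), range(L), keep, keep)] = e_r
    for i in range(L):
        e[i, i] = 0.0
    return e


def _two_site_direct(
    e_ij: np.ndarray,
    p_i: np.ndarray,
    p_j: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[np.ndarray, float, int]:
    """Fit the two-site direct distribution for one pair.

    Alternating marginal-matching updates on the auxiliary single-site
    factors mu1, mu2 such that ``P ~ mu1(A) W(A,B) mu2(B)`` has marginals
    ``p_i`` and ``p_j``, where ``W = exp(e_ij)``.  Returns the normalized
    distribution, the final max marginal error, and iterations used.
    """
    W = np.exp(e_ij)
    q = W.shape[0]
    mu1 = np.full(q, 1.0 / q)
    mu2 = np.full(q, 1.0 / q)
    err = np.inf
    for it in range(1, max_iter + 1):
        s2 = W @ mu2
        mu1 = np.where(s2 > 0, p_i / np.where(s2 > 0, s2, 1.0), 0.0)
        mu1 /= mu1.sum()
        s1 = W.T @ mu1
        mu2 = np.where(s1 > 0, p_j / np.where(s1 > 0, s1, 1.0), 0.0)
        mu2 /= mu2.sum()
        P = mu1[:, None] * W * mu2[None, :]
        P /= P.sum()
        err = max(
            np.abs(P.sum(axis=1) - p_i).max(), np.abs(P.sum(axis=0) - p_j).max()
        )
        if err < tol:
            return P, err, it
    return P, err, max_iter


def direct_information(
    fm: FrequencyModel,
    e: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> np.ndarray:
    """Direct information matrix from the mean-field coupling tensor.

    ``DI_ij`` is the mutual information of the fitted two-site direct
    distribution against the product of the single-site marginals; it is
    nonnegative and symmetric, zero when ``e_ij = 0``.  Raises if the
    marginal-matching fixed point fails to converge for a pair.
    """
    L = fm.length
    di = np.zeros((L, L))
    for i in range(L):
        p_i = fm.f1[i]
        for j in range(i + 1, L):
            p_j = fm.f1[j]
            P, err, _ = _two_site_direct(e[i, j], p_i, p_j, tol=tol, max_iter=max_iter)
            if err >= tol:
                raise RuntimeError(
                    f"direct-distribution fixed point did not converge for pair "
                    f"({i}, {j}); max marginal residual {err:.3e}"
                )
            prod = p_i[:, None] * p_j[None, :]
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(P > 0, P / prod, 1.0)
                val = float(np.sum(P * np.log(ratio)))
            di[i, j] = di[j, i] = max(val, 0.0)
    return di


def compute_couplings(
    aln: Alignment,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    lam: float | None = None,
) -> CouplingScores:
    """Full chain: weights -> frequencies -> MI + DI.

    ``lam=None`` uses the convention lambda = M_eff.  The alignment needs
    at least 2 effective sequences for covariation to be defined.
    """
    w = compute_weights(aln, identity_threshold)
    if aln.n_sequences < 2:
        raise ValueError("coupling analysis needs >= 2 effective sequences")
    if lam is None:
        lam = w.m_eff
    fm = frequencies(aln, w, lam)
    mi = mutual_information(fm)
    e = mean_field_couplings(fm)
    di = direct_information(fm, e)
    logger.info(
        "couplings computed: M=%d, M_eff=%.1f, L=%d, lambda=%.2f",
        aln.n_sequences, w.m_eff, aln.length, lam,
    )
    return CouplingScores(
        mi=mi,
        di=di,
        params={
            "identity_threshold": identity_threshold,
            "lambda": lam,
            "m_eff": w.m_eff,
            "gap_policy": "gap is the 21st state; gauge state for inversion",
        },
    )


def write_pair_scores(scores: CouplingScores, aln: Alignment, path) -> None:
    """TSV of all upper-triangle pairs: i, j (reference numbering), mi, di."""
    cmap = aln.column_map or {c: c + 1 for c in range(aln.length)}
    with open(path, "w") as fh:
        fh.write("i\tj\tmi\tdi\n")
        for ci in range(scores.length):
            if ci not in cmap:
                continue
            for cj in range(ci + 1, scores.length):
                if cj not in cmap:
                    continue
                fh.write(
                    f"{cmap[ci]}\t{cmap[cj]}\t{scores.mi[ci, cj]:.6g}\t{scores.di[ci, cj]:.6g}\n"
                )
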