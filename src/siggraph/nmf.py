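"""Multi-rank non-negative matrix factorization (mrNMF).

Classical NMF approximates a nonnegative genes x samples matrix X by W @ H
with W (genes x k) and H (k x samples) nonnegative, minimizing the squared
Frobenius loss ||X - WH||_F^2. The rank k fixes the number of "signatures"
(columns of W: weighted gene vectors whose entries are called exposures) and
is notoriously hard to choose. The multi-rank strategy sidesteps the choice:
X is decomposed independently at every rank k in [kmin, kmax] and all
resulting signatures are pooled into a single set, capturing transcriptional
programs at every granularity. With the defaults kmin=2, kmax=20 each cohort
contributes sum(k, k=2..20) = 209 signatures before filtering.

The solver is the classical multiplicative-update algorithm for the Frobenius
objective, which guarantees a non-increasing per-iteration loss, started from
a deterministic NNDSVDa initialization so identical inputs give identical
factorizations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortDataset

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class Signature:
    """One NMF signature: a W column with its matching H row.

    ``gene_exposures`` holds the nonnegative weight of every gene in the
    signature; ``sample_exposures`` the signature's activity in every sample.
    ``diagnosis_p`` is filled by the diagnosis-association filter.
    """

    cohort_id: str
    rank_k: int
    index_in_rank: int
    gene_exposures: pd.Series
    sample_exposures: pd.Series
    diagnosis_p: float | None = None

    @property
    def node_id(self) -> str:
        return f"{self.cohort_id}|k{self.rank_k}|{self.index_in_rank}"

    @property
    def is_degenerate(self) -> bool:
        """True for an exactly-zero signature (empty factor)."""
        return float(self.gene_exposures.sum()) == 0.0


@dataclass
class SignatureSet:
    """All signatures of one cohort pooled over the factorization ranks."""

    cohort_id: str
    disease: str
    disease_class: str
    tissue: str
    signatures: list[Signature]
    losses: dict[int, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.signatures)

    def __iter__(self):
        return iter(self.signatures)


@dataclass
class NMFResult:
    W: np.ndarray
    H: np.ndarray
    loss: float
    loss_history: np.ndarray
    n_iter: int
    converged: bool


def _nndsvda_init(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic NNDSVDa initialization (zeros filled with the mean of X)."""
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    W = np.zeros((X.shape[0], k))
    H = np.zeros((k, X.shape[1]))

    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])

    for j in range(1, min(k, len(S))):
        u, v = U[:, j], Vt[j, :]
        up, un = np.clip(u, 0, None), np.clip(-u, 0, None)
        vp, vn = np.clip(v, 0, None), np.clip(-v, 0, None)
        nup, nun = np.linalg.norm(up), np.linalg.norm(un)
        nvp, nvn = np.linalg.norm(vp), np.linalg.norm(vn)
        if nup * nvp >= nun * nvn:
            norm_prod = nup * nvp
            w = up / nup if nup > 0 else up
            h = vp / nvp if nvp > 0 else vp
        else:
            norm_prod = nun * nvn
            w = un / nun if nun > 0 else un
            h = vn / nvn if nvn > 0 else vn
        scale = np.sqrt(S[j] * norm_prod)
        W[:, j] = scale * w
        H[j, :] = scale * h

    mean = X.mean()
    if mean > 0:
        W[W <= 0] = mean
        H[H <= 0] = mean
    return W, H


def decompose_single_rank(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
    init: str = "nndsvda",
) -> NMFResult:
    """Factor a nonnegative matrix at a single rank k.

    Minimizes ||X - WH||_F^2 subject to W, H >= 0 with multiplicative updates;
    the loss after every full update is recorded in ``loss_history`` and is
    non-increasing up to floating-point slack. Convergence is declared when
    the relative loss decrease drops below ``tol``.

    ``seed`` only matters for ``init='random'``; the default NNDSVDa start is
    deterministic, so repeated calls are bit-identical.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    if not np.isfinite(X).all() or (X < 0).any():
        raise ValueError("X must be nonnegative and finite")
    if k < 1 or k > min(X.shape):
        raise ValueError(
            f"rank k={k} must satisfy 1 <= k <= min(genes, samples) = {min(X.shape)}"
        )

    if init == "nndsvda":
        W, H = _nndsvda_init(X, k)
    elif init == "random":
        rng = np.random.default_rng(seed)
        scale = np.sqrt(max(X.mean(), _EPS) / k)
        W = rng.uniform(0, 2 * scale, size=(X.shape[0], k))
        H = rng.uniform(0, 2 * scale, size=(k, X.shape[1]))
    else:
        raise ValueError(f"unknown init {init!r}")

    losses = []
    prev = np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # multiplicative updates for the Frobenius objective
        H *= (W.T @ X) / (W.T @ W @ H + _EPS)
        W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
        resid = X - W @ H
        loss = float(np.einsum("ij,ij->", resid, resid))
        losses.append(loss)
        if prev - loss <= tol * max(prev, _EPS) and np.isfinite(prev):
            converged = True
            break
        prev = loss

    if not converged:
        logger.warning(
            "NMF did not converge at k=%d within %d iterations (rel. change > %g); "
            "returning best iterate", k, max_iter, tol,
        )
    return NMFResult(
        W=W, H=H, loss=losses[-1], loss_history=np.array(losses),
        n_iter=n_iter, converged=converged,
    )


def mrnmf(
    cohort: CohortDataset,
    kmin: int = 2,
    kmax: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
    init: str = "nndsvda",
) -> SignatureSet:
    """Decompose one cohort at every rank in [kmin, kmax] and pool signatures.

    The cohort's expression is expected to be row-mean normalized (every gene
    mean 1); a warning is emitted otherwise. Returns a :class:`SignatureSet`
    with sum(k, k=kmin..kmax) signatures, each tagged with its source rank and
    its column index within that rank, plus the per-rank Frobenius loss.
    """
    if kmin < 1 or kmax < kmin:
        raise ValueError(f"need 1 <= kmin <= kmax, got kmin={kmin}, kmax={kmax}")
    limit = min(cohort.n_genes, cohort.n_samples)
    if kmax > limit:
        raise ValueError(
            f"cohort {cohort.cohort_id}: kmax={kmax} exceeds min(genes, samples)="
            f"{limit}; use kmax <= {limit}"
        )

    means = cohort.expression.mean(axis=1).to_numpy()
    if means.size and np.abs(means - 1.0).max() > 1e-6:
        logger.warning(
            "cohort %s: expression does not look row-mean normalized "
            "(max |row mean - 1| = %.3g)", cohort.cohort_id, np.abs(means - 1.0).max(),
        )

    X = cohort.expression.to_numpy(dtype=float)
    genes = cohort.expression.index
    samples = cohort.expression.columns

    signatures: list[Signature] = []
    losses: dict[int, float] = {}
    for k in range(kmin, kmax + 1):
        res = decompose_single_rank(
            X, k, seed=int(seed) + k, max_iter=max_iter, tol=tol, init=init
        )
        losses[k] = res.loss
        for j in range(k):
            sig = Signature(
                cohort_id=cohort.cohort_id,
                rank_k=k,
                index_in_rank=j,
                gene_exposures=pd.Series(res.W[:, j], index=genes),
                sample_exposures=pd.Series(res.H[j, :], index=samples),
            )
            if sig.is_degenerate:
                logger.warning(
                    "cohort %s: degenerate (all-zero) signature at k=%d index %d",
                    cohort.cohort_id, k, j,
                )
            signatures.append(sig)

    return SignatureSet(
        cohort_id=cohort.cohort_id,
        disease=cohort.disease,
        disease_class=cohort.disease_class,
        tissue=cohort.tissue,
        signatures=signatures,
        losses=losses,
    )
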