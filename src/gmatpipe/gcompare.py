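"""Comparison of G-matrices across contexts.

Three complementary views of how additive genetic (co)variance differs
between environments and species:

* eigenanalysis of each G (size, shape and orientation of genetic
  variation; the leading eigenvector is g_max);
* angles between eigenvectors of different G's, computed as
  theta = arccos(|r|) * 180 / pi with r the vector correlation, so theta
  is in [0, 90] degrees and insensitive to arbitrary sign flips;
* the genetic covariance tensor: the S-matrix of (co)variances of the
  individual elements of G across the m input matrices is eigendecomposed,
  and its eigenvectors are rearranged into symmetric "eigentensors" —
  independent axes of change of G itself.  Matrix coordinates (Frobenius
  inner products of each G with each eigentensor) say which contexts drive
  each axis of change.

Vectorization uses the standard sqrt(2) off-diagonal weighting so the
Euclidean inner product of vectorized matrices equals the Frobenius inner
product of the matrices; eigentensors are then orthonormal under the
Frobenius product and the variance of coordinates across the inputs equals
the corresponding S eigenvalue exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .halfsib import GPosterior, MCMCSettings, MixedModelSpec, fit_halfsib
from .core_io import PhenotypeTable


# ---------------------------------------------------------------------------
# eigenanalysis
# ---------------------------------------------------------------------------

@dataclass
class EigenSummary:
    """Sorted eigenvalues/eigenvectors of a covariance matrix."""

    eigenvalues: np.ndarray          # descending
    eigenvectors: np.ndarray         # columns, unit length, sign convention applied
    proportions: np.ndarray          # eigenvalue / trace

    @property
    def g_max(self) -> np.ndarray:
        return self.eigenvectors[:, 0]


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make the largest-|loading| entry of every column positive."""
    out = vectors.copy()
    for k in range(out.shape[1]):
        j = int(np.argmax(np.abs(out[:, k])))
        if out[j, k] < 0:
            out[:, k] = -out[:, k]
    return out


def eigen_G(G: np.ndarray, atol: float = 1e-8) -> EigenSummary:
    """Eigendecompose a symmetric (co)variance matrix.

    Eigenvalues are returned in descending order with unit-length
    eigenvectors whose largest-magnitude loading is made positive (a
    deterministic sign convention; eigenvector signs are otherwise
    arbitrary).
    """
    G = np.asarray(G, dtype=float)
    if not np.allclose(G, G.T, atol=atol):
        raise ValueError("eigen_G requires a symmetric matrix")
    w, V = np.linalg.eigh(0.5 * (G + G.T))
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    total = w.sum()
    props = w / total if total != 0 else np.zeros_like(w)
    return EigenSummary(eigenvalues=w, eigenvectors=_fix_signs(V), proportions=props)


def angle_between(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle in degrees between two directions, ignoring sign.

    theta = arccos(|r|) * 180/pi with r the correlation (normalized inner
    product); always in [0, 90].
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("cannot compute an angle with a zero vector")
    r = float(np.dot(v1, v2) / (n1 * n2))
    r = min(1.0, abs(r))
    return float(np.degrees(np.arccos(r)))


def angle_posterior(g_draws_a: np.ndarray, g_draws_b: np.ndarray, axis: int = 0,
                    hpd_prob: float = 0.95) -> dict:
    """Posterior of the angle between the ``axis``-th eigenvectors of two G's.

    Draws are paired by index (chains are independent, so the pairing is
    arbitrary but harmless); unequal draw counts are truncated to the
    shorter with a warning.  Returns draws, posterior mean and HPD interval.
    """
    import arviz as az

    na, nb = len(g_draws_a), len(g_draws_b)
    if na != nb:
        warnings.warn(f"pairing {min(na, nb)} of {na} vs {nb} draws", stacklevel=2)
    n = min(na, nb)
    angles = np.empty(n)
    for i in range(n):
        ea = eigen_G(g_draws_a[i]).eigenvectors[:, axis]
        eb = eigen_G(g_draws_b[i]).eigenvectors[:, axis]
        angles[i] = angle_between(ea, eb)
    hpd = az.hdi(angles, hdi_prob=hpd_prob)
    return {"draws": angles, "mean": float(angles.mean()),
            "hpd": (float(hpd[0]), float(hpd[1])), "hpd_prob": hpd_prob}


# ---------------------------------------------------------------------------
# covariance tensor
# ---------------------------------------------------------------------------

def vectorize_G(G: np.ndarray) -> np.ndarray:
    """Stack the unique elements of a symmetric matrix, off-diagonals x sqrt(2).

    Row-major upper triangle: for p=2, (g11, sqrt(2) g12, g22).  The
    weighting makes vectorization an isometry: u . v equals the Frobenius
    inner product of the corresponding matrices.
    """
    G = np.asarray(G, dtype=float)
    p = G.shape[0]
    iu = np.triu_indices(p)
    w = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
    return G[iu] * w


def unvectorize_G(v: np.ndarray, p: int) -> np.ndarray:
    """Inverse of :func:`vectorize_G`: rebuild the symmetric matrix."""
    iu = np.triu_indices(p)
    w = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
    M = np.zeros((p, p))
    M[iu] = np.asarray(v, dtype=float) / w
    return M + np.triu(M, 1).T


def matrix_coordinates(G: np.ndarray, eigentensor: np.ndarray) -> float:
    """Frobenius inner product <G, E> = sum_ij G_ij E_ij."""
    return float(np.sum(np.asarray(G) * np.asarray(eigentensor)))


@dataclass
class TensorResult:
    """Genetic covariance tensor of m G-matrices.

    ``S`` is the q x q covariance matrix (q = p(p+1)/2, denominator m - 1)
    of the vectorized inputs; ``eigentensors`` has shape (k, p, p) with
    k = min(q, m - 1) retained axes; ``coordinates`` is (m, k).  When built
    from posteriors, ``S`` is the average of per-draw S-matrices,
    ``eigenvalue_draws``/``coordinate_draws`` carry per-draw posteriors, and
    the point coordinates are posterior means.
    """

    S: np.ndarray
    eigenvalues: np.ndarray
    eigentensors: np.ndarray
    coordinates: np.ndarray
    matrix_labels: list = field(default_factory=list)
    eigenvalue_draws: np.ndarray | None = None
    coordinate_draws: np.ndarray | None = None
    null_eigenvalues: np.ndarray | None = None
    significant: np.ndarray | None = None

    @property
    def n_axes(self) -> int:
        return self.eigentensors.shape[0]

    def proportions(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        return self.eigenvalues / tot if tot > 0 else np.zeros_like(self.eigenvalues)


def _tensor_from_matrices(mats: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """S, eigenvalues and eigentensor stack for one set of m matrices."""
    m, p, _ = mats.shape
    V = np.stack([vectorize_G(Gi) for Gi in mats])      # (m, q)
    S = np.cov(V, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    w, E = np.linalg.eigh(S)
    order = np.argsort(w)[::-1]
    w, E = w[order], E[:, order]
    k = min(S.shape[0], m - 1)
    tensors = np.stack([unvectorize_G(_fix_signs(E[:, [j]])[:, 0], p) for j in range(k)])
    return S, w[:k], tensors


def covariance_tensor(G_sets: Sequence[np.ndarray], labels: Sequence | None = None) -> TensorResult:
    """Build the covariance tensor from m matrices or m posterior draw stacks.

    Plain matrices (each p x p): single deterministic tensor.  Posterior
    stacks (each n_draws x p x p): the S-matrix is computed for every paired
    draw (draw t of each context) and averaged; eigentensors come from the
    averaged S; eigenvalue and coordinate posteriors are recorded per draw.
    """
    arrs = [np.asarray(G, dtype=float) for G in G_sets]
    m = len(arrs)
    if m < 2:
        raise ValueError("need at least 2 matrices to build a covariance tensor")
    dims = {a.shape[-1] for a in arrs}
    if len(dims) != 1 or any(a.shape[-1] != a.shape[-2] for a in arrs):
        raise ValueError("all matrices must be square with a common dimension")
    labels = list(labels) if labels is not None else list(range(m))

    if arrs[0].ndim == 2:
        mats = np.stack(arrs)
        S, w, tensors = _tensor_from_matrices(mats)
        coords = np.array([[matrix_coordinates(Gi, E) for E in tensors] for Gi in mats])
        return TensorResult(S=S, eigenvalues=w, eigentensors=tensors,
                            coordinates=coords, matrix_labels=labels)

    n_draws = min(a.shape[0] for a in arrs)
    p = arrs[0].shape[-1]
    q = p * (p + 1) // 2
    S_sum = np.zeros((q, q))
    V_draws = np.empty((n_draws, m, q))
    for t in range(n_draws):
        mats_t = np.stack([a[t] for a in arrs])
        V_draws[t] = np.stack([vectorize_G(Gi) for Gi in mats_t])
        S_sum += np.atleast_2d(np.cov(V_draws[t], rowvar=False, ddof=1))
    S = S_sum / n_draws
    w_all, E = np.linalg.eigh(S)
    order = np.argsort(w_all)[::-1]
    w_all, E = w_all[order], E[:, order]
    k = min(q, m - 1)
    tensors = np.stack([unvectorize_G(_fix_signs(E[:, [j]])[:, 0], p) for j in range(k)])
    Evec = np.stack([vectorize_G(E_k) for E_k in tensors])   # (k, q)
    coord_draws = V_draws @ Evec.T                            # (n_draws, m, k)
    lam_draws = coord_draws.var(axis=1, ddof=1)               # (n_draws, k)
    return TensorResult(S=S, eigenvalues=w_all[:k], eigentensors=tensors,
                        coordinates=coord_draws.mean(axis=0), matrix_labels=labels,
                        eigenvalue_draws=lam_draws, coordinate_draws=coord_draws)


# ---------------------------------------------------------------------------
# breeding-value-randomization null for the tensor
# ---------------------------------------------------------------------------

def _reconstruct_with_effects(table: PhenotypeTable, posterior: GPosterior,
                              new_effects: np.ndarray) -> PhenotypeTable:
    """Replace each sire's posterior-mean effect with a supplied one.

    y* = y - s_hat[own sire] + s_new[own sire]: the dam, block and residual
    layers ride along untouched inside y.
    """
    df = table.data.copy().reset_index(drop=True)
    eff = posterior.effects["sire"]
    new = pd.DataFrame(new_effects, index=eff.index, columns=eff.columns)
    measured = df["measured"] == 1
    delta = (new.loc[df.loc[measured, "sire_id"]].to_numpy()
             - eff.loc[df.loc[measured, "sire_id"]].to_numpy())
    df.loc[measured, table.traits] = df.loc[measured, table.traits].to_numpy() + delta
    return PhenotypeTable(df, table.traits)


def null_tensor(contexts: Sequence[tuple[PhenotypeTable, GPosterior]],
                spec: MixedModelSpec, n_sim: int = 100,
                mcmc_reduced: MCMCSettings | None = None,
                alpha: float = 0.05, seed: int = 0,
                observed: TensorResult | None = None) -> TensorResult:
    """Null eigenvalue distributions for the covariance tensor.

    Sire-level breeding values are randomized under a shared-G null: for
    every replicate, each context's sire effects are replaced by fresh
    draws from N(0, G_common), where G_common is the across-context mean
    of the fitted sire matrices, while the dam, block and residual layers
    of the observed phenotypes are retained untouched
    (y* = y - s_hat + s_simulated).  Refitting the half-sib model (at
    reduced MCMC settings) and recomputing the tensor then yields
    eigenvalues that reflect sampling variation around one common G.
    Observed eigenvalues are flagged significant when they exceed the
    (1 - alpha) null quantile.

    Fresh draws, rather than a permutation of the predicted effects, are
    used because predicted (posterior-mean) effects are shrunk: redealing
    them between contexts underdisperses the null and flags sampling-only
    differences as significant.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if n_sim < 20:
        warnings.warn(f"n_sim={n_sim} gives unstable null quantiles; use >= 20", stacklevel=2)
    if mcmc_reduced is None:
        mcmc_reduced = MCMCSettings(n_burnin=500, thin=2, n_samples=200)
    rng = np.random.default_rng(seed)
    if observed is None:
        observed = covariance_tensor([post.G() for _, post in contexts],
                                     labels=[post.context for _, post in contexts])
    k = observed.n_axes
    G_common = np.mean([post.posterior_mean("sire") for _, post in contexts], axis=0)
    w, V = np.linalg.eigh(0.5 * (G_common + G_common.T))
    L_common = V * np.sqrt(np.clip(w, 0.0, None))
    null_eigs = np.empty((n_sim, k))
    for r in range(n_sim):
        null_posts = []
        for tab, post in contexts:
            n_sires = len(post.effects["sire"])
            s_sim = rng.standard_normal((n_sires, L_common.shape[0])) @ L_common.T
            tab_r = _reconstruct_with_effects(tab, post, s_sim)
            m = MCMCSettings(n_burnin=mcmc_reduced.n_burnin, thin=mcmc_reduced.thin,
                             n_samples=mcmc_reduced.n_samples,
                             seed=int(rng.integers(2**31 - 1)))
            null_posts.append(fit_halfsib(tab_r, spec, m))
        t_null = covariance_tensor([np2.G() for np2 in null_posts])
        null_eigs[r] = t_null.eigenvalues[:k]
    crit = np.quantile(null_eigs, 1.0 - alpha, axis=0)
    observed.null_eigenvalues = null_eigs
    observed.significant = observed.eigenvalues > crit
    return observed
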