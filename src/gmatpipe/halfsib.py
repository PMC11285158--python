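"""Bayesian multivariate nested half-sib mixed model, fit by Gibbs sampling.

For one species in one environment the model for the p-dimensional trait
vector of offspring l from dam j nested in sire i, grown in block k, is

    y_ijkl = mu + s_i + d_j(i) + b_k + e_ijkl

with independent multivariate-normal random effects

    s ~ N(0, Sigma_sire),  d ~ N(0, Sigma_dam),
    b ~ N(0, Sigma_block), e ~ N(0, Sigma_resid).

All four covariance components are full p x p matrices sampled jointly
(the response is multivariate, not trait-by-trait).  Under a paternal
half-sib interpretation the sire component estimates one quarter of the
additive genetic (co)variance; following common practice the sire matrix
itself is reported as G by default, with the x4 additive scale available.

Here ``block`` is the experimental planting block of the field layout,
crossed with families (each family's offspring are spread over every
block), not the mating group of the breeding design.

Sampling uses conditionally conjugate Gibbs updates — multivariate-normal
draws for effect vectors and the grand mean (flat prior), inverse-Wishart
draws for covariance components — with scalar parameter expansion on every
random term (see :class:`MixedModelSpec`), which both speeds mixing and
makes the induced priors on the variance components close to flat.

Sampling-error significance of G elements uses a design-respecting
randomization null: sire assignments are destroyed (by default intact
families are reassigned among sires; optionally offspring are shuffled
within planting blocks), the model is refit, and observed posterior means
are compared with the null distribution of posterior means over many
randomizations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .core_io import PhenotypeTable

TERMS = ("sire", "dam", "block", "resid")


@dataclass
class MCMCSettings:
    """Chain length controls: desk-scale defaults, journal-scale by config."""

    n_burnin: int = 5000
    thin: int = 10
    n_samples: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thin < 1 or self.n_samples < 1 or self.n_burnin < 0:
            raise ValueError("MCMC settings must be positive (burn-in may be 0)")


@dataclass
class MixedModelSpec:
    """Model structure and prior hyperparameters.

    Random terms are sampled with scalar parameter expansion: each term t is
    written ``effect = alpha_t * u`` with ``u ~ N(0, W_t)``, a near-flat
    normal working prior on ``alpha_t`` (sd ``px_sd``) and an
    inverse-Wishart(``prior_df``, ``prior_scale[t]``) prior on the working
    covariance ``W_t``; the reported component is ``alpha_t^2 W_t``.  The
    induced prior on each component is heavy-tailed and nearly flat on the
    effect-scale, so small variance components are neither pinned to the
    prior scale nor shrunk hard toward zero.  The residual covariance gets
    a conventional inverse-Wishart prior scaled to the observed trait
    variance.

    ``prior_df`` must exceed p - 1 for a proper inverse-Wishart; default
    p + 1.  Working prior scales default to the identity (their overall
    magnitude is absorbed by alpha); the residual scale defaults to
    ``0.5 * vbar * I`` with ``vbar`` the mean observed trait variance.
    """

    traits: list[str]
    prior_df: float | None = None
    prior_scale: dict[str, np.ndarray | float] | None = None
    block_random: bool = True
    px_sd: float = 100.0

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def resolved_priors(self, y: np.ndarray) -> tuple[float, dict[str, np.ndarray]]:
        p = self.n_traits
        nu = float(self.prior_df) if self.prior_df is not None else p + 1.0
        if nu <= p - 1:
            raise ValueError(f"prior_df must exceed p - 1 = {p - 1} for a proper inverse-Wishart")
        vbar = float(np.mean(np.var(y, axis=0, ddof=1))) if len(y) > 1 else 1.0
        if vbar <= 0:
            vbar = 1.0
        defaults = {"sire": 1.0, "dam": 1.0, "block": 1.0, "resid": 0.5 * vbar}
        scales = {}
        user = self.prior_scale or {}
        for term in TERMS:
            S = user.get(term, defaults[term])
            S = float(S) * np.eye(p) if np.isscalar(S) else np.asarray(S, dtype=float)
            if S.shape != (p, p) or not np.allclose(S, S.T, atol=1e-10):
                raise ValueError(f"prior scale for {term!r} must be a symmetric {p}x{p} matrix")
            if np.linalg.eigvalsh(S).min() <= 0:
                raise ValueError(f"prior scale for {term!r} must be positive definite")
            scales[term] = S
        return nu, scales


@dataclass
class GPosterior:
    """Posterior draws of all covariance components for one context.

    ``Sigma[term]`` has shape (n_samples, p, p).  ``effects`` holds posterior
    means of the random-effect vectors (used by breeding-value
    randomization); ``mu`` the grand-mean draws.
    """

    context: tuple[str, str]
    traits: list[str]
    Sigma: dict[str, np.ndarray]
    mu: np.ndarray
    effects: dict[str, pd.DataFrame]
    settings: MCMCSettings

    @property
    def n_samples(self) -> int:
        return self.Sigma["sire"].shape[0]

    def G(self, scale: float = 1.0) -> np.ndarray:
        """G draws from the sire component; ``scale=4`` for the additive scale."""
        return extract_G(self, scale)

    def posterior_mean(self, term: str = "sire") -> np.ndarray:
        return self.Sigma[term].mean(axis=0)


def extract_G(posterior: GPosterior, scale: float = 1.0) -> np.ndarray:
    """Sire-component draws times ``scale`` (1 = sire matrix, 4 = additive)."""
    if scale not in (1, 4, 1.0, 4.0):
        raise ValueError("scale must be 1 (sire matrix) or 4 (additive scale)")
    return float(scale) * posterior.Sigma["sire"]


# ---------------------------------------------------------------------------
# inverse-Wishart sampling (Bartlett decomposition)
# ---------------------------------------------------------------------------

_IW_CACHE: dict = {}


def _rinvwishart(nu: float, Psi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One draw from InverseWishart(nu, Psi) via the Bartlett construction.

    If W ~ Wishart(nu, Psi^-1) then W^-1 ~ IW(nu, Psi).  Hand-rolled because
    the generic scipy interface is too slow for the millions of draws the
    permutation tests make; agreement with scipy is unit-tested.
    """
    p = Psi.shape[0]
    try:
        eye, tril, diag, ar = _IW_CACHE[p]
    except KeyError:
        eye, tril, diag, ar = _IW_CACHE.setdefault(
            p, (np.eye(p), np.tril_indices(p, -1), np.diag_indices(p), np.arange(p)))
    Psi_inv = np.linalg.inv(Psi)
    L = np.linalg.cholesky(0.5 * (Psi_inv + Psi_inv.T))
    A = np.zeros((p, p))
    A[tril] = rng.standard_normal(len(tril[0]))
    A[diag] = np.sqrt(rng.chisquare(nu - ar))
    M = L @ A  # chol factor of W
    Minv = np.linalg.solve(M, eye)
    Sigma = Minv.T @ Minv
    return 0.5 * (Sigma + Sigma.T)


# ---------------------------------------------------------------------------
# Gibbs sampler internals
# ---------------------------------------------------------------------------

class _Grouping:
    """Pre-sorted index structure for fast per-level residual sums."""

    def __init__(self, codes: np.ndarray, n_levels: int):
        self.n_levels = n_levels
        self.order = np.argsort(codes, kind="stable")
        sorted_codes = codes[self.order]
        self.starts = np.searchsorted(sorted_codes, np.arange(n_levels))
        self.counts = np.bincount(codes, minlength=n_levels).astype(float)
        self.unique_counts = np.unique(self.counts)
        self.count_masks = [self.counts == n for n in self.unique_counts]
        self.codes = codes

    def sums(self, r: np.ndarray) -> np.ndarray:
        return np.add.reduceat(r[self.order], self.starts, axis=0)


def _sample_level(data_sums_Ainv: np.ndarray, prior_mean_Binv: np.ndarray,
                  grp: "_Grouping", A_inv: np.ndarray, B_inv: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Draw all latent means of one hierarchy level from their full conditional.

    Level g with n_g children and child precision A_inv, prior precision
    B_inv around its parent mean:
      precision P_g = B_inv + n_g A_inv
      mean      P_g^-1 (A_inv child_sum_g + B_inv parent_mean_g)
    ``data_sums_Ainv`` and ``prior_mean_Binv`` are the two right-hand-side
    pieces already multiplied by their precisions.  Levels sharing a count
    share P_g, so draws are batched by count.
    """
    p = A_inv.shape[0]
    rhs = data_sums_Ainv + prior_mean_Binv
    if len(grp.unique_counts) == 1:
        n_g = grp.unique_counts[0]
        P = B_inv + n_g * A_inv
        C = np.linalg.cholesky(0.5 * (P + P.T))
        z = rng.standard_normal(rhs.shape)
        return np.linalg.solve(P, rhs.T).T + np.linalg.solve(C.T, z.T).T
    out = np.empty_like(rhs)
    for n_g, sel in zip(grp.unique_counts, grp.count_masks):
        P = B_inv + n_g * A_inv
        C = np.linalg.cholesky(0.5 * (P + P.T))
        mean = np.linalg.solve(P, rhs[sel].T).T
        z = rng.standard_normal((int(sel.sum()), p))
        out[sel] = mean + np.linalg.solve(C.T, z.T).T
    return out


def _prepare(table: PhenotypeTable, spec: MixedModelSpec):
    df = table.measured()
    contexts = df[["species", "environment"]].drop_duplicates()
    if len(contexts) != 1:
        raise ValueError(
            f"fit_halfsib expects one species x environment context, got {len(contexts)}; "
            "subset the table first"
        )
    y = df[spec.traits].to_numpy(dtype=float)
    sire_codes, sires = pd.factorize(df["sire_id"], sort=True)
    dam_codes, dams = pd.factorize(df["sire_id"].astype(str) + "/" + df["dam_id"].astype(str), sort=True)
    block_codes, blocks = pd.factorize(df["block_id"], sort=True)
    if len(sires) < 2:
        raise ValueError("need at least 2 sires to estimate the sire covariance")
    ctx = (str(contexts.iloc[0, 0]), str(contexts.iloc[0, 1]))
    return y, (sire_codes, list(sires)), (dam_codes, list(dams)), (block_codes, list(blocks)), ctx


def fit_halfsib(table: PhenotypeTable, spec: MixedModelSpec,
                mcmc: MCMCSettings | None = None) -> GPosterior:
    """Fit the nested half-sib model to one context by Gibbs sampling.

    Uses measured individuals only.  Returns posterior draws of all four
    covariance components (every draw symmetric positive semidefinite),
    grand-mean draws, and posterior-mean random effects.
    """
    if mcmc is None:
        mcmc = MCMCSettings()
    y, (sire_c, sires), (fam_c, fams), (block_c, blocks), ctx = _prepare(table, spec)
    return _gibbs(y, (sire_c, sires), (fam_c, fams), (block_c, blocks), ctx, spec, mcmc)


def _gibbs(y, sire_pack, fam_pack, block_pack, ctx, spec: MixedModelSpec,
           mcmc: MCMCSettings) -> GPosterior:
    (sire_c, sires), (fam_c, fams), (block_c, blocks) = sire_pack, fam_pack, block_pack
    p = spec.n_traits
    N = len(y)
    nu0, S0 = spec.resolved_priors(y)
    rng = np.random.default_rng(mcmc.seed)
    n_fam, n_sires, n_blocks = len(fams), len(sires), len(blocks)
    terms = ["sire", "dam", "block"] if spec.block_random else ["sire", "dam"]
    groups = {"sire": _Grouping(sire_c, n_sires), "dam": _Grouping(fam_c, n_fam),
              "block": _Grouping(block_c, n_blocks)}
    codes = {"sire": sire_c, "dam": fam_c, "block": block_c}

    # parameter-expanded non-centered state: effect_t = alpha_t * u_t
    vbar = float(np.mean(np.var(y, axis=0, ddof=1))) if N > 1 else 1.0
    mu = y.mean(axis=0)
    u = {t: np.zeros((groups[t].n_levels, p)) for t in terms}
    alpha = {t: 0.1 * np.sqrt(max(vbar, 1e-8)) for t in terms}
    W = {t: np.eye(p) for t in terms}            # working covariances
    Sigma_e = max(vbar, 1e-8) * np.eye(p)
    px_prec = 1.0 / spec.px_sd**2

    n_iter = mcmc.n_burnin + mcmc.thin * mcmc.n_samples
    draws = {t: np.empty((mcmc.n_samples, p, p)) for t in (*terms, "resid")}
    mu_draws = np.empty((mcmc.n_samples, p))
    eff_sums = {t: np.zeros((groups[t].n_levels, p)) for t in terms}
    kept = 0
    eye = np.eye(p)
    contrib = {t: np.zeros((N, p)) for t in terms}

    total = sum(contrib[t] for t in terms)
    for it in range(n_iter):
        Se_inv = np.linalg.inv(Sigma_e + 1e-12 * eye)

        # grand mean (flat prior)
        r_all = y - total
        Lmu = np.linalg.cholesky(Sigma_e / N + 1e-14 * eye)
        mu = r_all.mean(axis=0) + Lmu @ rng.standard_normal(p)
        y_mu = y - mu

        for t in terms:
            # partial residual excluding this term
            r = y_mu - (total - contrib[t])
            W_inv = np.linalg.inv(W[t] + 1e-12 * eye)
            sums_Se = groups[t].sums(r) @ Se_inv.T          # (n_levels, p)
            a = alpha[t]
            u[t] = _sample_level(a * sums_Se, 0.0,
                                 groups[t], a * a * Se_inv, W_inv, rng)
            # working scalar: regression of the partial residual on u
            num = float(np.sum(u[t] * sums_Se))
            den = float(np.sum(groups[t].counts *
                               np.einsum("ij,jk,ik->i", u[t], Se_inv, u[t])))
            var_a = 1.0 / (den + px_prec)
            alpha[t] = var_a * num + np.sqrt(var_a) * rng.standard_normal()
            # working covariance
            W[t] = _rinvwishart(nu0 + groups[t].n_levels,
                                S0[t] + u[t].T @ u[t], rng)
            total -= contrib[t]
            contrib[t] = alpha[t] * u[t][codes[t]]
            total += contrib[t]

        resid = y_mu - total
        Sigma_e = _rinvwishart(nu0 + N, S0["resid"] + resid.T @ resid, rng)

        if it >= mcmc.n_burnin and (it - mcmc.n_burnin) % mcmc.thin == mcmc.thin - 1:
            for t in terms:
                draws[t][kept] = alpha[t] ** 2 * W[t]
            draws["resid"][kept] = Sigma_e
            mu_draws[kept] = mu
            for t in terms:
                eff_sums[t] += alpha[t] * u[t]
            kept += 1
            if kept == mcmc.n_samples:
                break

    if not spec.block_random:
        draws["block"] = np.zeros((mcmc.n_samples, p, p))

    labels = {"sire": sires, "dam": fams, "block": blocks}
    effects = {t: pd.DataFrame(eff_sums[t] / max(kept, 1), index=labels[t], columns=spec.traits)
               for t in eff_sums}
    return GPosterior(context=ctx, traits=list(spec.traits), Sigma=draws,
                      mu=mu_draws, effects=effects, settings=mcmc)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def diagnose_chain(posterior: GPosterior, threshold: float = 0.05) -> pd.DataFrame:
    """Lag-1 autocorrelation and effective sample size per covariance element.

    One row per (term, i, j) with the lag-1 autocorrelation of the thinned
    chain, arviz effective sample size, and a pass flag at ``threshold``.
    Deterministic given the draws.
    """
    import arviz as az

    if posterior.n_samples < 100:
        raise ValueError("need at least 100 saved draws for stable diagnostics")
    p = len(posterior.traits)
    iu = np.triu_indices(p)
    rows = []
    for term, arr in posterior.Sigma.items():
        for i, j in zip(*iu):
            x = arr[:, i, j]
            if np.var(x) < 1e-300:
                lag1, ess = 0.0, float(len(x))
            else:
                xc = x - x.mean()
                lag1 = float(np.dot(xc[:-1], xc[1:]) / np.dot(xc, xc))
                ess = float(az.ess(np.asarray(x)))
            rows.append((term, posterior.traits[i], posterior.traits[j], lag1, ess,
                         abs(lag1) < threshold))
    out = pd.DataFrame(rows, columns=["term", "trait_i", "trait_j", "lag1_autocorr", "ess", "pass"])
    return out


# ---------------------------------------------------------------------------
# offspring randomization null
# ---------------------------------------------------------------------------

def randomize_offspring(table: PhenotypeTable, seed: int | np.random.Generator = 0) -> PhenotypeTable:
    """Permute offspring among families within each block.

    Shuffles the (sire_id, dam_id) assignment across rows separately inside
    every block, preserving block sizes and the multiset of family sizes in
    each block while destroying any true sire signal.  Differences among
    blocks are retained by never moving a row between blocks.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = table.data.copy().reset_index(drop=True)
    for _, idx in df.groupby("block_id", sort=False).indices.items():
        perm = rng.permutation(idx)
        df.loc[idx, ["sire_id", "dam_id"]] = df.loc[perm, ["sire_id", "dam_id"]].to_numpy()
    return PhenotypeTable(df, table.traits)


def null_G_test(table: PhenotypeTable, spec: MixedModelSpec, mcmc: MCMCSettings,
                n_perm: int = 100, alpha: float = 0.05, seed: int = 0,
                observed: GPosterior | None = None, unit: str = "family") -> dict:
    """Element-wise significance of G against a randomization null.

    Because the sampler constrains variances to be positive, an element is
    called significant only when its observed posterior mean exceeds the
    (1 - alpha) quantile of posterior means over ``n_perm`` randomized
    refits (one-sided exceedance; off-diagonals compared on absolute value
    so covariances of either sign can be detected).

    ``unit`` chooses what is randomized among sires:

    * ``"family"`` (default): intact full-sib families are reassigned to
      sires at random, destroying only the sire-level grouping.  The null
      then reproduces exactly the sampling variation of sire means given
      the observed family structure, which keeps the test calibrated.
    * ``"offspring"``: individual offspring are shuffled among families
      within each planting block.  This also dissolves family structure,
      so null refits see less upper-level noise than the observed data and
      the test becomes anticonservative when dam variance is present.

    Neither scheme moves any row between planting blocks, so block
    differences are preserved.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 20:
        warnings.warn(f"n_perm={n_perm} gives unstable null quantiles; use >= 20", stacklevel=2)
    if unit not in ("family", "offspring"):
        raise ValueError(f"unknown randomization unit {unit!r}")
    rng = np.random.default_rng(seed)
    if observed is None:
        observed = fit_halfsib(table, spec, mcmc)
    obs_mean = observed.posterior_mean("sire")
    p = spec.n_traits
    null_means = np.empty((n_perm, p, p))
    # permute assignments as integer codes directly (equivalent to
    # randomize_offspring + refit, without rebuilding tables)
    y, (sire_c, sires), (fam_c, fams), (block_c, blocks), ctx = _prepare(table, spec)
    block_rows = [np.where(block_c == k)[0] for k in range(len(blocks))]
    fam_sire = np.full(len(fams), -1)
    fam_sire[fam_c] = sire_c
    for b in range(n_perm):
        if unit == "family":
            new_map = fam_sire[rng.permutation(len(fam_sire))]
            sire_p, fam_p = new_map[fam_c], fam_c
        else:
            sire_p, fam_p = sire_c.copy(), fam_c.copy()
            for idx in block_rows:
                perm = rng.permutation(idx)
                sire_p[idx], fam_p[idx] = sire_c[perm], fam_c[perm]
        null_mcmc = MCMCSettings(n_burnin=mcmc.n_burnin, thin=mcmc.thin,
                                 n_samples=mcmc.n_samples, seed=int(rng.integers(2**31 - 1)))
        post = _gibbs(y, (sire_p, sires), (fam_p, fams), (block_c, blocks), ctx,
                      spec, null_mcmc)
        null_means[b] = post.posterior_mean("sire")

    diag_mask = np.eye(p, dtype=bool)
    stat_obs = np.where(diag_mask, obs_mean, np.abs(obs_mean))
    stat_null = np.where(diag_mask, null_means, np.abs(null_means))
    crit = np.quantile(stat_null, 1.0 - alpha, axis=0)
    exceed = (stat_null >= stat_obs).mean(axis=0)
    return {
        "observed_mean": obs_mean,
        "null_means": null_means,
        "critical": crit,
        "significant": stat_obs > crit,
        "exceedance_p": exceed,
        "alpha": alpha,
        "n_perm": n_perm,
    }
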