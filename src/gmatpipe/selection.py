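"""Directional vectors and their projection through G.

The questions this module answers: how much of the additive genetic
variance available in a context lies in the direction of (a) phenotypic
plasticity between environments, (b) viability selection, or (c) the
difference between species' native phenotypes?

Direction vectors
-----------------
* plasticity: difference of trait-mean vectors, native minus other
  environment (mean-standardized traits);
* selection: beta from a multiple logistic regression of survival on all
  traits jointly (the joint fit supplies the P^-1 adjustment of the
  classical beta = P^-1 s), moved from the logit scale to the probability
  scale by the average-gradient transform (x mean of p_hat (1 - p_hat)) and
  then to the relative-fitness scale (/ mean survival);
* native-phenotype: between-species difference of trait means at one
  environment.

Projection
----------
For a unit vector v and a G-matrix draw, the proportion of the maximum
genetic variance available in direction v is (v' G v) / lambda_max, where
lambda_max is the leading eigenvalue of that same draw — between 0 and 1,
equal to 1 when v is g_max.  Vectors are normalized to unit length before
projecting so the ratio is a true proportion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_io import PhenotypeTable
from .gcompare import eigen_G


# ---------------------------------------------------------------------------
# direction vectors
# ---------------------------------------------------------------------------

@dataclass
class DirectionVector:
    """A direction in trait space with its provenance."""

    vector: np.ndarray
    kind: str                      # "plasticity" | "selection" | "native_difference"
    labels: dict = field(default_factory=dict)
    degenerate: bool = False       # zero vector; cannot be normalized

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("direction vector has non-finite entries")
        self.degenerate = bool(np.allclose(self.vector, 0.0))

    def unit(self) -> np.ndarray:
        if self.degenerate:
            raise ValueError(f"degenerate (zero) {self.kind} vector cannot be normalized")
        return self.vector / np.linalg.norm(self.vector)


def plasticity_vector(means_native: np.ndarray, means_other: np.ndarray,
                      labels: dict | None = None) -> DirectionVector:
    """Plasticity as the trait-mean difference, native minus other environment."""
    a = np.asarray(means_native, dtype=float)
    b = np.asarray(means_other, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"trait dimensions differ: {a.shape} vs {b.shape}")
    return DirectionVector(a - b, kind="plasticity", labels=labels or {})


def native_direction(means_species_a: np.ndarray, means_species_b: np.ndarray,
                     at_env: str = "", toward: str = "") -> DirectionVector:
    """Between-species trait-mean difference at one environment.

    Points from species B's mean toward species A's mean; ``toward`` records
    which species' native phenotype the direction represents.
    """
    a = np.asarray(means_species_a, dtype=float)
    b = np.asarray(means_species_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"trait dimensions differ: {a.shape} vs {b.shape}")
    return DirectionVector(a - b, kind="native_difference",
                           labels={"environment": at_env, "toward": toward})


# ---------------------------------------------------------------------------
# projection through G
# ---------------------------------------------------------------------------

def project_through_G(v: DirectionVector | np.ndarray, G: np.ndarray,
                      lambda_max: float | None = None) -> float:
    """Proportion of the maximum genetic variance lying along v.

    (v' G v) / lambda_max with v normalized internally; lambda_max defaults
    to the leading eigenvalue of G.  Always in [0, 1].
    """
    u = v.unit() if isinstance(v, DirectionVector) else np.asarray(v, dtype=float)
    n = np.linalg.norm(u)
    if n == 0:
        raise ValueError("cannot project a zero vector")
    u = u / n
    G = np.asarray(G, dtype=float)
    if lambda_max is None:
        lambda_max = float(np.linalg.eigvalsh(G).max())
    if lambda_max <= 0:
        raise ValueError("lambda_max must be positive (G has no genetic variance)")
    val = float(u @ G @ u) / lambda_max
    return min(max(val, 0.0), 1.0)


@dataclass
class ProjectionResult:
    """Distribution of the projected proportion over vector x G draws."""

    draws: np.ndarray
    mean: float
    hpd: tuple[float, float]
    hpd_prob: float = 0.95
    labels: dict = field(default_factory=dict)


def project_posterior(v_draws: np.ndarray, G_draws: np.ndarray,
                      pairing: str = "random", max_pairs: int = 20000,
                      hpd_prob: float = 0.95, seed: int = 0,
                      labels: dict | None = None) -> ProjectionResult:
    """Propagate vector and G uncertainty through the projection.

    ``v_draws`` is (n_v, p) (bootstrap draws of a direction, or a single
    vector) and ``G_draws`` is (n_G, p, p).  Pairing policies:

    * ``"random"`` (default): each vector draw is paired with one randomly
      chosen G draw — cheap and unbiased for marginal summaries;
    * ``"paired"``: draw i with draw i (cycling the shorter);
    * ``"cross"``: the full n_v x n_G grid, subsampled to ``max_pairs``.
    """
    import arviz as az

    v_draws = np.atleast_2d(np.asarray(v_draws, dtype=float))
    G_draws = np.asarray(G_draws, dtype=float)
    if G_draws.ndim == 2:
        G_draws = G_draws[None]
    if len(v_draws) == 0 or len(G_draws) == 0:
        raise ValueError("need at least one vector draw and one G draw")
    rng = np.random.default_rng(seed)
    n_v, n_G = len(v_draws), len(G_draws)

    if pairing == "random":
        # each vector draw gets one randomly chosen G draw; a single fixed
        # vector is propagated through the full G posterior
        pairs = [(i % n_v, int(rng.integers(n_G))) for i in range(max(n_v, n_G))]
    elif pairing == "paired":
        n = max(n_v, n_G)
        pairs = [(i % n_v, i % n_G) for i in range(n)]
    elif pairing == "cross":
        pairs = [(i, j) for i in range(n_v) for j in range(n_G)]
        if len(pairs) > max_pairs:
            keep = rng.choice(len(pairs), size=max_pairs, replace=False)
            pairs = [pairs[k] for k in keep]
    else:
        raise ValueError(f"unknown pairing policy {pairing!r}")

    lam = np.linalg.eigvalsh(G_draws)[:, -1]
    draws = np.array([project_through_G(v_draws[i], G_draws[j], lam[j]) for i, j in pairs])
    if len(draws) > 1 and np.ptp(draws) > 0:
        h = az.hdi(draws, hdi_prob=hpd_prob)
        hpd = (float(h[0]), float(h[1]))
    else:
        hpd = (float(draws.min()), float(draws.max()))
    return ProjectionResult(draws=draws, mean=float(draws.mean()), hpd=hpd,
                            hpd_prob=hpd_prob, labels=labels or {})


def hpd_overlap(a: ProjectionResult | np.ndarray, b: ProjectionResult | np.ndarray,
                hpd_prob: float = 0.90) -> bool:
    """Do the two distributions' HPD intervals at ``hpd_prob`` overlap?

    Non-overlap at a high level (the conventional >90% screen) is read as a
    credible difference between the two projected proportions.
    """
    import arviz as az

    da = a.draws if isinstance(a, ProjectionResult) else np.asarray(a)
    db = b.draws if isinstance(b, ProjectionResult) else np.asarray(b)
    ia = az.hdi(da, hdi_prob=hpd_prob) if np.ptp(da) > 0 else (da.min(), da.max())
    ib = az.hdi(db, hdi_prob=hpd_prob) if np.ptp(db) > 0 else (db.min(), db.max())
    return not (ia[1] < ib[0] or ib[1] < ia[0])


# ---------------------------------------------------------------------------
# selection gradients
# ---------------------------------------------------------------------------

@dataclass
class SelectionGradientResult:
    """Viability selection gradient on several scales.

    ``logit`` are the raw multiple-logistic-regression coefficients;
    ``probability`` applies the average-gradient transform (x mean
    p_hat(1 - p_hat)); ``relative`` divides by mean survival (selection on
    relative fitness); ``direction`` is the unit-length relative-scale
    vector.  All three scales are positive multiples of each other, so the
    direction is shared.
    """

    logit: np.ndarray
    probability: np.ndarray
    relative: np.ndarray
    direction: np.ndarray
    mean_survival: float
    wald_chi2: np.ndarray
    wald_p: np.ndarray
    traits: list[str]
    n: int
    bootstrap_draws: np.ndarray | None = None

    def as_direction(self) -> DirectionVector:
        return DirectionVector(self.direction, kind="selection")


def _fit_logistic(X: np.ndarray, y: np.ndarray, var_weights: np.ndarray | None = None):
    Xc = sm.add_constant(X, has_constant="add")
    model = sm.GLM(y, Xc, family=sm.families.Binomial(), var_weights=var_weights)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=200)
    if not np.all(np.isfinite(res.bse)) or np.any(np.abs(res.params) > 50):
        raise RuntimeError(
            "logistic fit unstable (likely complete separation); consider pooling "
            "contexts, dropping collinear traits, or penalized estimation"
        )
    return res, Xc


def _scale_chain(res, Xc: np.ndarray, y_mean: float, traits: Sequence[str], n: int,
                 transform: str = "average_gradient") -> SelectionGradientResult:
    logit = np.asarray(res.params[1:], dtype=float)
    p_hat = np.asarray(res.fittedvalues, dtype=float)
    if transform == "average_gradient":
        deriv = float(np.mean(p_hat * (1.0 - p_hat)))
    elif transform == "at_mean":
        deriv = float(y_mean * (1.0 - y_mean))
    else:
        raise ValueError(f"unknown transform {transform!r}")
    prob = logit * deriv
    if not 0.0 < y_mean < 1.0:
        raise ValueError("mean survival must lie strictly between 0 and 1")
    rel = prob / y_mean
    norm = np.linalg.norm(rel)
    if norm == 0:
        raise ValueError("zero selection gradient; direction undefined")
    z = res.params[1:] / res.bse[1:]
    chi2 = np.asarray(z, dtype=float) ** 2
    from scipy.stats import chi2 as chi2_dist
    pvals = chi2_dist.sf(chi2, df=1)
    return SelectionGradientResult(logit=logit, probability=prob, relative=rel,
                                   direction=rel / norm, mean_survival=float(y_mean),
                                   wald_chi2=chi2, wald_p=pvals, traits=list(traits), n=n)


def check_selection_estimable(table: PhenotypeTable, min_mortality: float = 0.05) -> None:
    """Refuse contexts without enough post-measurement mortality.

    Viability selection is only estimable where individuals died *after*
    their traits were measured; with (nearly) everyone surviving there is
    no fitness variation to regress on.
    """
    df = table.measured()
    if df.empty:
        raise ValueError("no measured individuals")
    dead = 1.0 - df["survived"].mean()
    if dead < min_mortality:
        raise ValueError(
            f"post-measurement mortality {dead:.1%} < {min_mortality:.0%}; "
            "selection gradient not estimable in this context"
        )


def selection_gradient(table: PhenotypeTable, transform: str = "average_gradient",
                       check_mortality: bool = False) -> SelectionGradientResult:
    """Multiple logistic regression of survival on all traits jointly.

    Traits should be mean standardized.  The joint fit conditions each
    coefficient on the other traits, supplying the phenotypic-covariance
    adjustment of the classical gradient beta = P^-1 s.
    """
    if check_mortality:
        check_selection_estimable(table)
    df = table.measured()
    y = df["survived"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("survival must include both outcomes (all survived or all died)")
    X = df[table.traits].to_numpy(dtype=float)
    res, Xc = _fit_logistic(X, y)
    return _scale_chain(res, Xc, float(y.mean()), table.traits, len(y), transform)


def genotypic_selection_gradient(table: PhenotypeTable, min_families: int = 10,
                                 transform: str = "average_gradient") -> SelectionGradientResult:
    """Gradient on family means: trait means vs family mean survival.

    Fitted as a binomial GLM on family survival fractions with variance
    weights equal to family size (the quasi-binomial weighting), so large
    families carry proportionally more information.
    """
    df = table.measured()
    fam = df.groupby(["sire_id", "dam_id"], sort=False)
    means = fam[table.traits].mean()
    surv = fam["survived"].mean()
    sizes = fam.size().to_numpy(dtype=float)
    if len(means) < min_families:
        raise ValueError(f"need >= {min_families} families with measured offspring, got {len(means)}")
    y = surv.to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("no variation in family mean survival")
    X = means.to_numpy(dtype=float)
    res, Xc = _fit_logistic(X, y, var_weights=sizes)
    mean_surv = float(np.average(y, weights=sizes))
    return _scale_chain(res, Xc, mean_surv, table.traits, int(sizes.sum()), transform)


def bootstrap_beta(table: PhenotypeTable, n_boot: int = 1000, seed: int = 0,
                   transform: str = "average_gradient") -> tuple[np.ndarray, int]:
    """Case-resampling bootstrap of the relative-scale selection gradient.

    Individuals (measured rows) are resampled with replacement within the
    context and the gradient refit; replicates that fail (separation,
    one-class survival) are dropped.  Returns (draws, n_failed) with draws
    of shape (n_boot - n_failed, p).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    df = table.measured().reset_index(drop=True)
    rng = np.random.default_rng(seed)
    out = []
    failed = 0
    n = len(df)
    for _ in range(n_boot):
        idx = rng.integers(n, size=n)
        boot = PhenotypeTable(
            df.iloc[idx].assign(individual_id=np.arange(n).astype(str)).reset_index(drop=True),
            table.traits)
        try:
            out.append(selection_gradient(boot, transform=transform).relative)
        except (ValueError, RuntimeError):
            failed += 1
    if not out:
        raise RuntimeError(f"all {n_boot} bootstrap refits failed")
    return np.stack(out), failed


# ---------------------------------------------------------------------------
# D-matrix of group means
# ---------------------------------------------------------------------------

@dataclass
class DMatrixResult:
    """Among-group-mean (co)variance matrix and its leading axes."""

    D: np.ndarray
    eigenvalues: np.ndarray
    axes: np.ndarray               # columns d_max, d_2, ...
    proportions: np.ndarray
    scores: pd.DataFrame           # per-group scores on the axes


def compute_D(group_mean_vectors: Sequence[np.ndarray] | pd.DataFrame,
              labels: Sequence | None = None) -> DMatrixResult:
    """Covariance of group trait-mean vectors (denominator n_groups - 1).

    Eigenanalysis of D gives the axes of mean-phenotype divergence (d_max,
    d_2, ...); group scores are the centered means projected on those axes.
    rank(D) <= n_groups - 1 by construction.
    """
    if isinstance(group_mean_vectors, pd.DataFrame):
        labels = list(group_mean_vectors.index) if labels is None else list(labels)
        M = group_mean_vectors.to_numpy(dtype=float)
    else:
        M = np.stack([np.asarray(v, dtype=float) for v in group_mean_vectors])
        labels = list(labels) if labels is not None else list(range(len(M)))
    if len(M) < 2:
        raise ValueError("need at least 2 groups to estimate D")
    D = np.cov(M, rowvar=False, ddof=1)
    D = np.atleast_2d(D)
    summ = eigen_G(D)
    centered = M - M.mean(axis=0)
    scores = pd.DataFrame(centered @ summ.eigenvectors, index=labels,
                          columns=[f"d_{k + 1}" for k in range(D.shape[0])])
    return DMatrixResult(D=D, eigenvalues=summ.eigenvalues, axes=summ.eigenvectors,
                         proportions=summ.proportions, scores=scores)
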