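"""Synthetic data for a reciprocally transplanted nested half-sib breeding design.

The generator emulates the data-producing process the downstream analysis
assumes: sires each mated to several dams in small full-factorial blocks,
offspring of every family planted at several environments (elevations), and
traits generated as

    y = mu(env) + sire effect + dam effect + block effect + residual,

with the sire-level covariance allowed to differ between environments
(genotype-by-environment interaction, G x E).  Sire effects at different
environments are correlated through a user-set cross-environment genetic
correlation ``rho_GE``: with ``rho_GE = 1`` every sire expresses the same
(rescaled) effect everywhere, with ``rho_GE = 0`` environment-specific
effects are independent.

Survival is Bernoulli with a logistic dependence on (centered) traits, so a
known selection gradient can be planted and recovered.  Pre-measurement
mortality removes individuals before their traits are recorded — by default
at random with respect to phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core_io import PhenotypeTable

DEFAULT_TRAITS = ["leaf_complexity", "indent_width", "indent_number", "sla", "flavonol"]
DEFAULT_ENVIRONMENTS = ["elev_500", "elev_1000", "elev_1500", "elev_2000"]


class ConfigurationError(ValueError):
    pass


def make_cov(variances: Sequence[float], corr: float | np.ndarray = 0.0) -> np.ndarray:
    """Build a covariance matrix from per-trait variances and a correlation.

    ``corr`` may be a scalar (constant correlation between every pair) or a
    full correlation matrix.
    """
    v = np.asarray(variances, dtype=float)
    p = len(v)
    if np.isscalar(corr):
        R = np.full((p, p), float(corr))
        np.fill_diagonal(R, 1.0)
    else:
        R = np.asarray(corr, dtype=float)
    sd = np.sqrt(v)
    return R * np.outer(sd, sd)


def _check_psd(name: str, M: np.ndarray, p: int) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.shape != (p, p):
        raise ConfigurationError(f"{name} must be {p}x{p}, got {M.shape}")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ConfigurationError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(M)
    if w.min() < -1e-10:
        raise ConfigurationError(f"{name} must be positive semidefinite (min eigenvalue {w.min():.3g})")
    return M


@dataclass
class SimConfig:
    """Parameters of one species' breeding design and generative model.

    Per-environment parameters (``mu``, ``Sigma_sire``, ``Sigma_resid``,
    ``beta_survival``, ``survival_intercept``) may be given either as a
    single value applied to every environment or as a mapping keyed by
    environment label.
    """

    n_blocks: int = 12
    sires_per_block: int = 3
    dams_per_block: int = 3
    last_block_sires: int | None = None   # e.g. a final 2x2 block
    last_block_dams: int | None = None
    environments: list[str] = field(default_factory=lambda: list(DEFAULT_ENVIRONMENTS))
    offspring_per_family_per_env: int = 25
    n_exp_blocks: int = 5                 # planting blocks per environment (crossed with family)
    trait_names: list[str] = field(default_factory=lambda: list(DEFAULT_TRAITS))
    species: str = "sp"
    mu: Mapping[str, np.ndarray] | np.ndarray | None = None
    Sigma_sire: Mapping[str, np.ndarray] | np.ndarray | None = None
    Sigma_dam: np.ndarray | None = None
    sigma2_block: float = 0.005
    Sigma_resid: Mapping[str, np.ndarray] | np.ndarray | None = None
    rho_GE: float = 0.5
    beta_survival: Mapping[str, np.ndarray] | np.ndarray | None = None
    survival_intercept: Mapping[str, float] | float = 0.0
    premeasurement_mortality: float = 0.0
    mortality_beta: np.ndarray | None = None  # optional trait-dependent early mortality
    family_dropout: float = 0.0
    seed: int = 0

    # -- resolution helpers ----------------------------------------------
    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def _per_env(self, value, default, as_matrix=False, name=""):
        p = self.n_traits
        if value is None:
            value = default
        if isinstance(value, Mapping):
            out = {}
            for env in self.environments:
                if env not in value:
                    raise ConfigurationError(f"{name} missing environment {env!r}")
                out[env] = np.asarray(value[env], dtype=float)
        else:
            arr = np.asarray(value, dtype=float) if not np.isscalar(value) else value
            out = {env: (np.array(arr, dtype=float, copy=True) if not np.isscalar(arr) else arr)
                   for env in self.environments}
        if as_matrix:
            out = {env: _check_psd(f"{name}[{env}]", M, p) for env, M in out.items()}
        return out

    def resolved(self) -> dict:
        """Validate and expand all per-environment parameters."""
        p = self.n_traits
        if not self.environments:
            raise ConfigurationError("environments must be non-empty")
        for fld in ("n_blocks", "sires_per_block", "dams_per_block",
                    "offspring_per_family_per_env", "n_exp_blocks"):
            if getattr(self, fld) <= 0:
                raise ConfigurationError(f"{fld} must be positive")
        for fld in ("premeasurement_mortality", "family_dropout"):
            v = getattr(self, fld)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{fld} must lie in [0, 1]")
        if self.sigma2_block < 0:
            raise ConfigurationError("sigma2_block must be >= 0")
        if not 0.0 <= self.rho_GE <= 1.0:
            raise ConfigurationError("rho_GE must lie in [0, 1]")

        mu = self._per_env(self.mu, np.ones(p), name="mu")
        for env, m in mu.items():
            if m.shape != (p,):
                raise ConfigurationError(f"mu[{env}] must have length {p}")
        Sigma_sire = self._per_env(self.Sigma_sire, 0.02 * np.eye(p), as_matrix=True, name="Sigma_sire")
        Sigma_resid = self._per_env(self.Sigma_resid, 0.25 * np.eye(p), as_matrix=True, name="Sigma_resid")
        Sigma_dam = _check_psd("Sigma_dam", self.Sigma_dam if self.Sigma_dam is not None else 0.015 * np.eye(p), p)
        beta = self._per_env(self.beta_survival, np.zeros(p), name="beta_survival")
        for env, b in beta.items():
            if b.shape != (p,):
                raise ConfigurationError(f"beta_survival[{env}] must have length {p}")
        icpt = self.survival_intercept
        if not isinstance(icpt, Mapping):
            icpt = {env: float(icpt) for env in self.environments}
        return dict(mu=mu, Sigma_sire=Sigma_sire, Sigma_dam=Sigma_dam,
                    Sigma_resid=Sigma_resid, beta_survival=beta, survival_intercept=icpt)

    def to_yaml(self, path) -> None:
        def _plain(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, Mapping):
                return {k: _plain(x) for k, x in v.items()}
            return v
        doc = {k: _plain(v) for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def build_pedigree(config: SimConfig) -> pd.DataFrame:
    """Cross sires and dams in full-factorial blocks.

    Each block holds ``sires_per_block`` x ``dams_per_block`` families (the
    final block may be smaller via ``last_block_*``); parents are never
    reused across breeding blocks.  Returns one row per family with columns
    ``species, breeding_block, sire_id, dam_id, family_id``.  Breeding
    blocks structure the matings only; the experimental planting blocks of
    the field design are assigned in :func:`simulate_traits`.
    """
    config.resolved()  # validation only
    rows = []
    for b in range(config.n_blocks):
        ns, nd = config.sires_per_block, config.dams_per_block
        if b == config.n_blocks - 1:
            ns = config.last_block_sires or ns
            nd = config.last_block_dams or nd
        bb = f"{config.species}_b{b + 1:02d}"
        sires = [f"{bb}_s{i + 1}" for i in range(ns)]
        dams = [f"{bb}_d{j + 1}" for j in range(nd)]
        for s in sires:
            for d in dams:
                rows.append((config.species, bb, s, d, f"{s}x{d}"))
    return pd.DataFrame(rows, columns=["species", "breeding_block", "sire_id", "dam_id", "family_id"])


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------


def _psd_factor(M: np.ndarray) -> np.ndarray:
    """Factor L with L L' = M for any symmetric PSD M (exact for M = 0)."""
    w, V = np.linalg.eigh(np.asarray(M, dtype=float))
    return V * np.sqrt(np.clip(w, 0.0, None))


def _sire_effects(sire_ids: Sequence[str], Sigma_sire: Mapping[str, np.ndarray],
                  environments: Sequence[str], rho: float, rng: np.random.Generator) -> dict:
    """Draw per-environment sire effects with cross-environment correlation.

    Effect at environment a:  u_a = L_a (sqrt(rho) z0 + sqrt(1-rho) z_a)
    with L_a the Cholesky factor of that environment's sire covariance and
    z0, z_a independent standard normal vectors.  Marginally Cov(u_a) is
    exactly Sigma_sire[a]; across environments Cov(u_a, u_b) = rho L_a L_b'.
    """
    p = next(iter(Sigma_sire.values())).shape[0]
    n = len(sire_ids)
    L = {env: _psd_factor(Sigma_sire[env]) for env in environments}
    z0 = rng.standard_normal((n, p))
    out: dict = {}
    for env in environments:
        z = rng.standard_normal((n, p))
        mixed = np.sqrt(rho) * z0 + np.sqrt(1.0 - rho) * z
        out[env] = {sid: mixed[i] @ L[env].T for i, sid in enumerate(sire_ids)}
    return out


def simulate_traits(pedigree: pd.DataFrame, config: SimConfig,
                    rng: np.random.Generator | None = None) -> PhenotypeTable:
    """Generate offspring trait records for every family at every environment.

    Sire effects are drawn per environment with cross-environment
    correlation ``rho_GE``; dam effects once per dam; each offspring is
    randomized into one of ``n_exp_blocks`` planting blocks per environment
    (crossed with family, as in a reciprocal-transplant field layout) whose
    effects are iid N(0, sigma2_block) per trait; residuals are independent
    per offspring.  Families drop out entirely (produce no offspring
    anywhere) with probability ``family_dropout``, mimicking failed
    crosses.  All individuals start with ``emerged = measured = 1``;
    mortality is applied by :func:`simulate_survival`.
    """
    params = config.resolved()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    p = config.n_traits
    envs = config.environments

    keep = rng.random(len(pedigree)) >= config.family_dropout
    ped = pedigree[keep].reset_index(drop=True)
    if ped.empty:
        raise ConfigurationError("all families dropped out; lower family_dropout")

    sire_ids = ped["sire_id"].unique()
    dam_ids = ped["dam_id"].unique()

    sire_eff = _sire_effects(sire_ids, params["Sigma_sire"], envs, config.rho_GE, rng)
    Ld = _psd_factor(params["Sigma_dam"])
    dam_eff = {d: rng.standard_normal(p) @ Ld.T for d in dam_ids}
    sd_b = np.sqrt(config.sigma2_block)
    nxb = config.n_exp_blocks
    block_eff = {(env, j): sd_b * rng.standard_normal(p) for env in envs for j in range(nxb)}

    n_off = config.offspring_per_family_per_env
    frames = []
    counter = 0
    for env in envs:
        mu = params["mu"][env]
        Lr = _psd_factor(params["Sigma_resid"][env])
        for fam in ped.itertuples(index=False):
            xb = rng.integers(nxb, size=n_off)
            base = mu + sire_eff[env][fam.sire_id] + dam_eff[fam.dam_id]
            resid = rng.standard_normal((n_off, p)) @ Lr.T
            traits = base + np.stack([block_eff[(env, j)] for j in xb]) + resid
            ids = [f"{fam.family_id}_{env}_o{counter + i + 1}" for i in range(n_off)]
            counter += n_off
            frame = pd.DataFrame({
                "individual_id": ids,
                "sire_id": fam.sire_id,
                "dam_id": fam.dam_id,
                "block_id": [f"{env}_xb{j + 1}" for j in xb],
                "species": fam.species,
                "environment": env,
            })
            for j, t in enumerate(config.trait_names):
                frame[t] = traits[:, j]
            frames.append(frame)
    df = pd.concat(frames, ignore_index=True)
    df["emerged"] = 1
    df["measured"] = 1
    df["survived"] = np.nan
    return PhenotypeTable(df, list(config.trait_names))


# ---------------------------------------------------------------------------
# survival and pre-measurement mortality
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_survival(table: PhenotypeTable, config: SimConfig,
                      rng: np.random.Generator | None = None) -> PhenotypeTable:
    """Draw survival and apply pre-measurement mortality.

    Survival is Bernoulli with logit equal to the environment's intercept
    plus ``beta_survival . (traits - context mean)``; centering makes the
    intercept the logit of mean survival regardless of trait means.

    Pre-measurement mortality sets ``measured = 0`` (and blanks traits and
    survival) — uniformly at random by default, or with a logistic trait
    dependence when ``mortality_beta`` is set, to study the bias early
    selection would cause.
    """
    params = config.resolved()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    df = table.data.copy()
    X = df[table.traits].to_numpy(dtype=float)

    survived = np.zeros(len(df), dtype=float)
    for env in config.environments:
        mask = (df["environment"] == env).to_numpy()
        if not mask.any():
            continue
        Xc = X[mask] - X[mask].mean(axis=0)
        logit = params["survival_intercept"][env] + Xc @ params["beta_survival"][env]
        survived[mask] = (rng.random(mask.sum()) < _sigmoid(logit)).astype(float)

    if config.mortality_beta is not None:
        mb = np.asarray(config.mortality_beta, dtype=float)
        q = config.premeasurement_mortality
        icpt = np.log(q / (1 - q)) if 0 < q < 1 else (-np.inf if q == 0 else np.inf)
        dead_early = rng.random(len(df)) < _sigmoid(icpt + (X - X.mean(axis=0)) @ mb)
    else:
        dead_early = rng.random(len(df)) < config.premeasurement_mortality

    df["survived"] = survived
    df["measured"] = (~dead_early).astype(int)
    df.loc[dead_early, table.traits] = np.nan
    df.loc[dead_early, "survived"] = 0.0  # died before traits could be taken
    return PhenotypeTable(df, table.traits)


def simulate_dataset(config: SimConfig) -> PhenotypeTable:
    """Pedigree -> traits -> survival, all sub-streams derived from one seed."""
    ss = np.random.SeedSequence(config.seed)
    s_traits, s_surv = ss.spawn(2)
    ped = build_pedigree(config)
    table = simulate_traits(ped, config, np.random.default_rng(s_traits))
    return simulate_survival(table, config, np.random.default_rng(s_surv))


# ---------------------------------------------------------------------------
# study-like default configurations
# ---------------------------------------------------------------------------

def study_config(species: str = "sp_high", seed: int = 0, **overrides) -> SimConfig:
    """A realistic two-species, four-environment parameterization.

    ``sp_high`` mimics a high-elevation native: 12 complete 3x3 blocks, its
    G-matrix loses size and rotates at low elevations (strong G x E).
    ``sp_low`` mimics a low-elevation native: 13 blocks with a final 2x2
    block, milder G x E.  Trait scale is the mean-standardized scale (means
    near 1, sire variances of a few percent).
    """
    p = len(DEFAULT_TRAITS)
    envs = list(DEFAULT_ENVIRONMENTS)

    def g(total, lead_corr):
        v = np.full(p, total)
        return make_cov(v, lead_corr)

    if species == "sp_high":
        # native 2000 m: nearly spherical, smaller; novel low: larger, strongly correlated
        Sigma_sire = {
            "elev_500": g(0.020, 0.6),
            "elev_1000": g(0.018, 0.6),
            "elev_1500": g(0.018, 0.5),
            "elev_2000": g(0.008, 0.1),
        }
        mu = {
            "elev_500": np.array([0.90, 1.10, 1.05, 1.00, 0.95]),
            "elev_1000": np.array([0.95, 1.05, 1.02, 1.00, 0.97]),
            "elev_1500": np.array([1.00, 1.00, 1.00, 1.00, 1.00]),
            "elev_2000": np.array([1.05, 0.92, 0.96, 1.02, 1.05]),
        }
        cfg = SimConfig(species=species, n_blocks=12, mu=mu, Sigma_sire=Sigma_sire,
                        family_dropout=0.13, seed=seed)
    elif species == "sp_low":
        Sigma_sire = {
            "elev_500": g(0.020, 0.55),
            "elev_1000": g(0.018, 0.55),
            "elev_1500": g(0.008, 0.3),
            "elev_2000": g(0.012, 0.5),
        }
        mu = {
            "elev_500": np.array([1.10, 0.90, 0.95, 1.00, 1.05]),
            "elev_1000": np.array([1.05, 0.94, 0.97, 1.00, 1.02]),
            "elev_1500": np.array([1.00, 0.98, 0.99, 1.00, 1.00]),
            "elev_2000": np.array([0.95, 1.05, 1.02, 1.00, 0.97]),
        }
        cfg = SimConfig(species=species, n_blocks=13, last_block_sires=2, last_block_dams=2,
                        mu=mu, Sigma_sire=Sigma_sire, family_dropout=0.04, seed=seed)
    else:
        raise ConfigurationError(f"unknown study species {species!r}")

    cfg.Sigma_dam = 0.015 * np.eye(p)
    cfg.Sigma_resid = make_cov(np.full(p, 0.25), 0.1)
    cfg.rho_GE = 0.5
    cfg.beta_survival = np.array([1.0, 0.0, 0.0, 0.6, 0.4])
    cfg.survival_intercept = 0.4
    cfg.premeasurement_mortality = 0.35
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg
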