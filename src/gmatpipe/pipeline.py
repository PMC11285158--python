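"""End-to-end orchestration: simulate/load -> standardize -> fit -> compare -> project.

One master seed drives every stage through deterministically spawned
sub-streams, so rerunning a configuration reproduces the report
byte-for-byte.  The report is a single JSON document; posterior draws can
additionally be written as plain-text matrix directories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core_io, gcompare, halfsib, selection, simdata
from .core_io import PhenotypeTable, log


@dataclass
class PipelineConfig:
    """Everything one run needs.

    Either ``input_csv`` (a phenotype table on disk) or ``simulate``
    (species label -> :class:`simdata.SimConfig`) must be provided.
    ``native_env`` maps each species to its native environment (used for
    angles, plasticity and the native-vs-novel projections).
    """

    input_csv: str | None = None
    simulate: dict[str, simdata.SimConfig] = field(default_factory=dict)
    native_env: dict[str, str] = field(default_factory=dict)
    per_context_standardization: bool = False
    mcmc: halfsib.MCMCSettings = field(default_factory=halfsib.MCMCSettings)
    n_perm: int = 0            # offspring-randomization refits per context (0 = skip)
    n_sim: int = 0             # breeding-value-randomization tensor nulls (0 = skip)
    n_boot: int = 200          # bootstrap replicates for selection gradients
    alpha: float = 0.05
    hpd_prob: float = 0.95
    g_scale: float = 1.0       # 1 = sire matrix reported as G, 4 = additive scale
    min_post_measurement_mortality: float = 0.05
    native_projections: list[dict] = field(default_factory=list)
    outdir: str = "pipeline_out"
    seed: int = 0
    save_posteriors: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "simulate" in doc:
            doc["simulate"] = {sp: simdata.SimConfig(**c) for sp, c in doc["simulate"].items()}
        if "mcmc" in doc:
            doc["mcmc"] = halfsib.MCMCSettings(**doc["mcmc"])
        return cls(**doc)


def study_pipeline_config(seed: int = 0, mcmc: halfsib.MCMCSettings | None = None,
                          **overrides) -> PipelineConfig:
    """The bundled two-species, four-environment demonstration configuration."""
    ss = np.random.SeedSequence(seed)
    s_high, s_low = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2))
    cfg = PipelineConfig(
        simulate={
            "sp_high": simdata.study_config("sp_high", seed=s_high),
            "sp_low": simdata.study_config("sp_low", seed=s_low),
        },
        native_env={"sp_high": "elev_2000", "sp_low": "elev_500"},
        native_projections=[
            {"species": "sp_high", "environment": "elev_500", "toward": "sp_low"},
            {"species": "sp_low", "environment": "elev_2000", "toward": "sp_high"},
        ],
        mcmc=mcmc or halfsib.MCMCSettings(n_burnin=2000, thin=5, n_samples=400),
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


# ---------------------------------------------------------------------------
# posterior persistence (plain text)
# ---------------------------------------------------------------------------

def save_posterior(post: halfsib.GPosterior, outdir) -> None:
    """Write draws as plain-text matrix files (one per draw) plus a JSON summary."""
    out = Path(outdir)
    for term, arr in post.Sigma.items():
        d = out / term
        d.mkdir(parents=True, exist_ok=True)
        for i in range(arr.shape[0]):
            np.savetxt(d / f"draw_{i:05d}.txt", arr[i])
    np.savetxt(out / "mu.txt", post.mu)
    for term, eff in post.effects.items():
        eff.to_csv(out / f"effects_{term}.csv")
    import arviz as az
    hpds = {}
    p = len(post.traits)
    for t, arr in post.Sigma.items():
        hpds[t] = [[list(map(float, az.hdi(np.ascontiguousarray(arr[:, i, j]), hdi_prob=0.95)))
                    for j in range(p)] for i in range(p)]
    diagnostics = None
    if post.n_samples >= 100:
        from . import halfsib as _hs
        d = _hs.diagnose_chain(post)
        diagnostics = {"max_abs_lag1_autocorr": float(d["lag1_autocorr"].abs().max()),
                       "min_ess": float(d["ess"].min()),
                       "all_pass": bool(d["pass"].all())}
    summary = {
        "context": list(post.context),
        "traits": post.traits,
        "n_samples": post.n_samples,
        "posterior_mean": {t: post.Sigma[t].mean(axis=0).tolist() for t in post.Sigma},
        "hpd_95": hpds,
        "diagnostics": diagnostics,
        "settings": vars(post.settings),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))


def load_posterior(indir) -> halfsib.GPosterior:
    d = Path(indir)
    summary = json.loads((d / "summary.json").read_text())
    Sigma = {}
    for term_dir in sorted(x for x in d.iterdir() if x.is_dir()):
        files = sorted(term_dir.glob("draw_*.txt"))
        Sigma[term_dir.name] = np.stack([np.loadtxt(f) for f in files])
    effects = {}
    for f in d.glob("effects_*.csv"):
        effects[f.stem.removeprefix("effects_")] = pd.read_csv(f, index_col=0)
    return halfsib.GPosterior(
        context=tuple(summary["context"]), traits=summary["traits"], Sigma=Sigma,
        mu=np.loadtxt(d / "mu.txt"), effects=effects,
        settings=halfsib.MCMCSettings(**summary["settings"]))


# ---------------------------------------------------------------------------
# JSON plumbing
# ---------------------------------------------------------------------------

def _plain(obj):
    """Recursively convert numpy containers for deterministic JSON output."""
    if isinstance(obj, np.ndarray):
        return [_plain(x) for x in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(x) for x in obj]
    return obj


def _ctx_key(species: str, env: str) -> str:
    return f"{species}@{env}"


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write ``report.json`` to ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: int(s.generate_state(1)[0] % (2**31 - 1))
             for name, s in zip(["mcmc", "perm", "tensor_null", "boot", "project"], ss.spawn(5))}
    report: dict = {"seed": config.seed, "g_scale": config.g_scale}

    # ---- data ----------------------------------------------------------
    if config.input_csv:
        log("data", f"reading {config.input_csv}")
        table = core_io.read_phenotypes(config.input_csv)
    elif config.simulate:
        log("data", f"simulating {sorted(config.simulate)} species")
        parts = [simdata.simulate_dataset(c) for c in config.simulate.values()]
        traits = parts[0].traits
        table = PhenotypeTable(pd.concat([p.data for p in parts], ignore_index=True), traits)
    else:
        raise ValueError("config must provide input_csv or simulate")
    core_io.write_phenotypes(table, out / "phenotypes.csv")

    std = core_io.mean_standardize(
        table, core_io.grand_mean_reference(table, per_context=config.per_context_standardization))
    contexts = std.contexts()
    report["contexts"] = [_ctx_key(*c) for c in contexts]
    missing = [sp for sp in {c[0] for c in contexts} if sp not in config.native_env]
    if missing:
        raise ValueError(f"native_env missing for species: {missing}")

    # ---- per-context fits ---------------------------------------------
    spec = halfsib.MixedModelSpec(traits=std.traits)
    posts: dict[tuple[str, str], halfsib.GPosterior] = {}
    tabs: dict[tuple[str, str], PhenotypeTable] = {}
    fit_seed = np.random.SeedSequence(seeds["mcmc"])
    report["fits"] = {}
    for (sp, env), child in zip(contexts, fit_seed.spawn(len(contexts))):
        sub = std.subset(species=sp, environment=env)
        m = halfsib.MCMCSettings(n_burnin=config.mcmc.n_burnin, thin=config.mcmc.thin,
                                 n_samples=config.mcmc.n_samples,
                                 seed=int(child.generate_state(1)[0] % (2**31 - 1)))
        log("fit", f"{_ctx_key(sp, env)}: {len(sub.measured())} measured individuals")
        post = halfsib.fit_halfsib(sub, spec, m)
        posts[(sp, env)], tabs[(sp, env)] = post, sub
        if config.save_posteriors:
            save_posterior(post, out / "posteriors" / _ctx_key(sp, env))
        G = post.G(config.g_scale)
        summ = gcompare.eigen_G(G.mean(axis=0))
        diag = halfsib.diagnose_chain(post) if post.n_samples >= 100 else None
        report["fits"][_ctx_key(sp, env)] = {
            "n_measured": len(sub.measured()),
            "G_posterior_mean": G.mean(axis=0),
            "eigenvalues": summ.eigenvalues,
            "proportions": summ.proportions,
            "g_max": summ.g_max,
            "max_abs_lag1_autocorr": float(diag["lag1_autocorr"].abs().max()) if diag is not None else None,
        }

    # ---- null-G significance ------------------------------------------
    if config.n_perm > 0:
        perm_seed = np.random.SeedSequence(seeds["perm"])
        report["null_G"] = {}
        for (sp, env), child in zip(contexts, perm_seed.spawn(len(contexts))):
            log("null-G", _ctx_key(sp, env))
            res = halfsib.null_G_test(
                tabs[(sp, env)], spec, config.mcmc, n_perm=config.n_perm,
                alpha=config.alpha, seed=int(child.generate_state(1)[0] % (2**31 - 1)),
                observed=posts[(sp, env)])
            report["null_G"][_ctx_key(sp, env)] = {
                "significant": res["significant"], "exceedance_p": res["exceedance_p"]}

    # ---- angles vs native ---------------------------------------------
    report["angles_vs_native"] = {}
    for sp in sorted({c[0] for c in contexts}):
        native = config.native_env[sp]
        for env in [e for s, e in contexts if s == sp and e != native]:
            ang = gcompare.angle_posterior(posts[(sp, native)].G(config.g_scale),
                                           posts[(sp, env)].G(config.g_scale),
                                           hpd_prob=config.hpd_prob)
            report["angles_vs_native"][f"{sp}:{native}->{env}"] = {
                "mean_deg": ang["mean"], "hpd": ang["hpd"]}

    # ---- covariance tensor --------------------------------------------
    log("tensor", f"{len(contexts)} G matrices")
    tensor = gcompare.covariance_tensor([posts[c].G(config.g_scale) for c in contexts],
                                        labels=[_ctx_key(*c) for c in contexts])
    if config.n_sim > 0:
        tensor = gcompare.null_tensor([(tabs[c], posts[c]) for c in contexts], spec,
                                      n_sim=config.n_sim, alpha=config.alpha,
                                      seed=seeds["tensor_null"], observed=tensor)
    report["tensor"] = {
        "eigenvalues": tensor.eigenvalues,
        "proportions": tensor.proportions(),
        "eigentensors": tensor.eigentensors,
        "coordinates": tensor.coordinates,
        "matrix_labels": tensor.matrix_labels,
        "significant": tensor.significant,
    }

    # ---- D matrix and plasticity projections ---------------------------
    means = core_io.group_means(std)
    dres = selection.compute_D(means)
    report["D"] = {"eigenvalues": dres.eigenvalues, "proportions": dres.proportions,
                   "axes": dres.axes, "scores": {str(k): v for k, v in
                                                 zip(dres.scores.index, dres.scores.to_numpy())}}

    proj_seed = np.random.SeedSequence(seeds["project"])
    proj_streams = iter(proj_seed.spawn(200))

    def _project(vec_draws, post, labels):
        s = int(next(proj_streams).generate_state(1)[0] % (2**31 - 1))
        return selection.project_posterior(vec_draws, post.G(config.g_scale),
                                           hpd_prob=config.hpd_prob, seed=s, labels=labels)

    report["plasticity"] = {}
    for sp in sorted({c[0] for c in contexts}):
        native = config.native_env[sp]
        mu_native = means.loc[(sp, native)].to_numpy()
        for env in [e for s, e in contexts if s == sp and e != native]:
            dv = selection.plasticity_vector(mu_native, means.loc[(sp, env)].to_numpy(),
                                             labels={"species": sp, "from": native, "to": env})
            if dv.degenerate:
                report["plasticity"][f"{sp}:{native}->{env}"] = {"degenerate": True}
                continue
            at_env = _project(dv.unit(), posts[(sp, env)], {"where": env})
            at_native = _project(dv.unit(), posts[(sp, native)], {"where": native})
            report["plasticity"][f"{sp}:{native}->{env}"] = {
                "vector": dv.vector,
                "proportion_at_env": {"mean": at_env.mean, "hpd": at_env.hpd},
                "proportion_at_native": {"mean": at_native.mean, "hpd": at_native.hpd},
                "native_higher": not selection.hpd_overlap(at_env, at_native, 0.90)
                                 and at_native.mean > at_env.mean,
            }

    # ---- selection gradients and projections ---------------------------
    boot_seed = np.random.SeedSequence(seeds["boot"])
    report["selection"] = {}
    for (sp, env), child in zip(contexts, boot_seed.spawn(len(contexts))):
        sub = tabs[(sp, env)]
        try:
            selection.check_selection_estimable(sub, config.min_post_measurement_mortality)
            grad = selection.selection_gradient(sub)
        except (ValueError, RuntimeError) as err:
            report["selection"][_ctx_key(sp, env)] = {"estimable": False, "reason": str(err)}
            continue
        draws, n_failed = selection.bootstrap_beta(
            sub, n_boot=config.n_boot, seed=int(child.generate_state(1)[0] % (2**31 - 1)))
        native = config.native_env[sp]
        at_env = _project(draws, posts[(sp, env)], {"where": env})
        entry = {
            "estimable": True,
            "beta_logit": grad.logit, "beta_probability": grad.probability,
            "beta_relative": grad.relative, "direction": grad.direction,
            "mean_survival": grad.mean_survival,
            "wald_chi2": grad.wald_chi2, "wald_p": grad.wald_p,
            "bootstrap_failures": n_failed,
            "proportion_at_env": {"mean": at_env.mean, "hpd": at_env.hpd},
        }
        if env != native:
            at_native = _project(draws, posts[(sp, native)], {"where": native})
            entry["proportion_at_native"] = {"mean": at_native.mean, "hpd": at_native.hpd}
        report["selection"][_ctx_key(sp, env)] = entry

    # ---- native-phenotype projections ----------------------------------
    report["native_phenotype"] = {}
    for job in config.native_projections:
        sp, env, toward = job["species"], job["environment"], job["toward"]
        if (toward, env) not in [tuple(k) for k in means.index] or (sp, env) not in posts:
            raise ValueError(f"native projection references missing context {toward}@{env} or {sp}@{env}")
        dv = selection.native_direction(means.loc[(toward, env)].to_numpy(),
                                        means.loc[(sp, env)].to_numpy(),
                                        at_env=env, toward=toward)
        if dv.degenerate:
            report["native_phenotype"][f"{sp}@{env}->({toward})"] = {"degenerate": True}
            continue
        at_env = _project(dv.unit(), posts[(sp, env)], {"where": env})
        native = config.native_env[sp]
        entry = {"vector": dv.vector,
                 "proportion_at_env": {"mean": at_env.mean, "hpd": at_env.hpd}}
        if (sp, native) in posts and native != env:
            at_native = _project(dv.unit(), posts[(sp, native)], {"where": native})
            entry["proportion_at_native"] = {"mean": at_native.mean, "hpd": at_native.hpd}
        report["native_phenotype"][f"{sp}@{env}->({toward})"] = entry

    report_json = json.dumps(_plain(report), indent=2, sort_keys=True)
    (out / "report.json").write_text(report_json)
    log("done", f"report written to {out / 'report.json'}")
    return report


# ---------------------------------------------------------------------------
# bundled tiny fixtures
# ---------------------------------------------------------------------------

def scenario_config(scenario: str, seed: int = 0, offspring: int = 10,
                    n_blocks: int = 12) -> simdata.SimConfig:
    """Two-trait, two-environment G x E scenarios for tests and docs.

    ``aligned``: no G x E, g_max parallel to selection everywhere.
    ``gxe_gain``: at the novel environment G reorients to concentrate
    variance in the selected direction (trait 1).
    ``gxe_loss``: at the novel environment G loses variance in the selected
    direction — the constraint case.
    Selection at the novel environment acts on trait 1 only.  The G x E
    contrasts are strong (about a five-fold swap of the two sire variances)
    so that the qualitative ordering of projections is a property of the
    construction rather than of sampling luck at a desk-scale design.
    """
    base = dict(
        species=f"sp_{scenario}",
        n_blocks=n_blocks, environments=["native", "novel"],
        offspring_per_family_per_env=offspring,
        trait_names=["z1", "z2"],
        Sigma_dam=0.01 * np.eye(2), sigma2_block=0.002,
        Sigma_resid=0.15 * np.eye(2),
        mu={"native": np.array([1.0, 1.0]), "novel": np.array([0.9, 1.1])},
        beta_survival={"native": np.zeros(2), "novel": np.array([3.0, 0.0])},
        survival_intercept=0.0,
        seed=seed,
    )
    if scenario == "aligned":
        S = {"native": np.diag([0.04, 0.01]), "novel": np.diag([0.04, 0.01])}
    elif scenario == "gxe_gain":
        S = {"native": np.diag([0.008, 0.04]), "novel": np.diag([0.05, 0.008])}
    elif scenario == "gxe_loss":
        S = {"native": np.diag([0.04, 0.008]), "novel": np.diag([0.004, 0.04])}
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return simdata.SimConfig(Sigma_sire=S, **base)


def make_fixtures(seed: int = 0, outdir: str | Path = "fixtures") -> list[Path]:
    """Write three small scenario CSVs (<= 500 rows each); deterministic per seed."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, scenario in enumerate(["aligned", "gxe_gain", "gxe_loss"]):
        cfg = scenario_config(scenario, seed=seed + i, offspring=3, n_blocks=4)
        table = simdata.simulate_dataset(cfg)
        path = out / f"scenario_{scenario}.csv"
        core_io.write_phenotypes(table, path)
        paths.append(path)
    return paths
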