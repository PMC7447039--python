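"""End-to-end orchestration of the synthetic replication pipeline.

Stages: simulate cohort -> fit all three discount models per
participant-session (pre-session posteriors chained into post-session
priors) -> PSIS-LOO model comparison -> group statistics on parameter
changes -> time-travel RT interaction -> cross-task correlation -> PPI
coupling demo -> consolidated report.

Each stage writes its outputs under the run directory and is skipped on
rerun if its outputs already exist, so deleting any intermediate and
rerunning regenerates it identically (all randomness is keyed off the
master seed with named substreams).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import groupstats, timetravel
from .bayes import (
    McmcConfig,
    default_prior,
    fit_model,
    flat_prior,
    mean_looic_table,
    posterior_to_prior,
    psis_loo,
)
from .cohort import CohortConfig, simulate_cohort, substream, write_cohort
from .discount import MODELS, DiscountParams, auc_discount_curve
from .roiglm import build_design, ppi_session_contrast

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run."""

    cohort: CohortConfig = field(default_factory=lambda: CohortConfig(
        n_per_group=8, ctbs_effect_s=1.5, session_noise_sd=0.1,
        susceptibility_sd=0.5))
    mcmc: McmcConfig = field(default_factory=lambda: McmcConfig(
        chains=2, samples=1500, burn_in=500))
    tail: str = "one"
    bonferroni_m: int = 2
    ppi_replicates: int = 100
    ppi_coupling_pre: float = 0.5
    ppi_coupling_post: float = 0.2
    ppi_noise_sd: float = 1.0
    pre_prior: str = "default"  # "default" (weakly informative) or "flat"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.cohort, dict):
            self.cohort = CohortConfig.from_dict(self.cohort)
        if isinstance(self.mcmc, dict):
            self.mcmc = McmcConfig(**self.mcmc)
        # pipeline seed is authoritative for every stage
        self.cohort.seed = self.seed

    @classmethod
    def paper_scale(cls, seed: int = 0) -> "PipelineConfig":
        """Full-scale settings: 30 per group, 2 chains x 4,000 samples."""
        cfg = cls(seed=seed)
        cfg.cohort.n_per_group = 30
        cfg.mcmc = McmcConfig(chains=2, samples=4000, burn_in=1000)
        cfg.ppi_replicates = 500
        return cfg

    def to_dict(self) -> dict:
        out = asdict(self)
        out["cohort"] = self.cohort.to_dict()
        return out


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def stage_simulate(config: PipelineConfig, out: Path) -> dict:
    cohort_dir = out / "cohort"
    if (cohort_dir / "manifest.json").exists():
        log.info("simulate: cached")
        return {
            "choices": pd.read_csv(cohort_dir / "choices.csv",
                                   dtype={"participant_id": str}),
            "rts": pd.read_csv(cohort_dir / "rts.csv",
                               dtype={"participant_id": str},
                               float_precision="round_trip"),
            "params": pd.read_csv(cohort_dir / "true_params.csv",
                                  dtype={"participant_id": str}),
        }
    cohort = simulate_cohort(config.cohort)
    write_cohort(cohort, cohort_dir)
    return cohort


def stage_fit(config: PipelineConfig, out: Path, choices: pd.DataFrame) -> pd.DataFrame:
    """Fit every model to every participant-session; chain post priors."""
    path = out / "fits.csv"
    if path.exists():
        log.info("fit: cached")
        return pd.read_csv(path, dtype={"participant_id": str},
                           float_precision="round_trip")
    rows = []
    for (pid, group), df_p in choices.groupby(["participant_id", "group"], sort=True):
        for model in MODELS:
            pre_trials = df_p[df_p["session"] == "pre"]
            post_trials = df_p[df_p["session"] == "post"]
            pre_prior = (flat_prior(model) if config.pre_prior == "flat"
                         else default_prior(model))
            pre_fit = fit_model(
                pre_trials, model, prior=pre_prior, mcmc=config.mcmc,
                rng=substream(config.seed, "fit", pid, "pre", model))
            try:
                post_prior = posterior_to_prior(pre_fit)
            except ValueError:
                log.warning("chained prior unavailable for %s/%s; reusing the "
                            "pre-session prior", pid, model)
                post_prior = pre_prior
            post_fit = fit_model(
                post_trials, model, prior=post_prior, mcmc=config.mcmc,
                rng=substream(config.seed, "fit", pid, "post", model))
            for session, fit in (("pre", pre_fit), ("post", post_fit)):
                loo = psis_loo(fit.pointwise)
                row = {
                    "participant_id": pid, "group": group, "session": session,
                    "model": model, "looic": loo.looic, "elpd": loo.elpd,
                    "max_pareto_k": float(np.max(loo.pareto_k)),
                    "max_rhat": float(max(fit.rhat.values())),
                    "converged": fit.converged,
                }
                row.update({name: est for name, est in fit.point_estimates.items()})
                rows.append(row)
    fits = pd.DataFrame(rows)
    fits.to_csv(path, index=False)
    return fits


def stage_compare(out: Path, fits: pd.DataFrame) -> pd.DataFrame:
    path = out / "model_comparison.csv"
    if path.exists():
        log.info("compare: cached")
        return pd.read_csv(path)
    table = mean_looic_table({
        model: grp["looic"].tolist() for model, grp in fits.groupby("model")
    })
    table.to_csv(path, index=False)
    return table


# measure -> (column builder, one-tailed direction of the rTPJ hypothesis)
_MEASURES = {
    "k": ("x_greater", "one"),
    "s": ("x_greater", "one"),
    "beta_temp": (None, "two"),
    "auc": ("y_greater", "one"),
}


def stage_group_stats(config: PipelineConfig, out: Path, fits: pd.DataFrame) -> pd.DataFrame:
    path = out / "group_stats.csv"
    if path.exists():
        log.info("group-stats: cached")
        return pd.read_csv(path)
    gen = fits[fits["model"] == "generalized_hyperbolic"].copy()
    gen["auc"] = [
        auc_discount_curve(DiscountParams(model="generalized_hyperbolic",
                                          k=r.k, s=r.s, beta_temp=r.beta_temp))
        for r in gen.itertuples()
    ]
    wide = gen.pivot_table(index=["participant_id", "group"], columns="session",
                           values=["k", "s", "beta_temp", "auc"], observed=True)
    rows = []
    for measure, (direction, default_tail) in _MEASURES.items():
        delta = wide[(measure, "post")] - wide[(measure, "pre")]
        groups = delta.index.get_level_values("group")
        x = delta[groups == "rTPJ"].to_numpy()
        y = delta[groups == "vertex"].to_numpy()
        tail = default_tail if config.tail == "one" else "two"
        res = groupstats.mann_whitney(
            x, y, tail=tail, direction=direction if tail == "one" else None)
        rows.append({
            "measure": f"delta_{measure}", "u": res.u, "z": res.z, "p": res.p,
            "r": res.r, "n_total": res.n_total, "tail": res.tail,
            "median_rtpj": float(np.median(x)), "median_vertex": float(np.median(y)),
        })
    stats = pd.DataFrame(rows)
    stats.to_csv(path, index=False)
    return stats


def stage_rt(out: Path, rts: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    path = out / "rt_contrasts.csv"
    test_path = out / "rt_test.json"
    if path.exists() and test_path.exists():
        log.info("rt-analysis: cached")
        with open(test_path) as fh:
            return pd.read_csv(path, dtype={"participant_id": str},
                           float_precision="round_trip"), json.load(fh)
    contrasts = timetravel.compute_contrasts(rts)
    table = pd.DataFrame([{
        "participant_id": c.participant_id, "group": c.group,
        "pre_diff": c.pre_diff, "post_diff": c.post_diff,
        "interaction": c.interaction,
    } for c in contrasts])
    res = timetravel.interaction_test(contrasts)
    test = {"u": res.u, "z": res.z, "p": res.p, "r": res.r,
            "n_total": res.n_total, "tail": res.tail}
    table.to_csv(path, index=False)
    _json_dump(test, test_path)
    return table, test


def stage_correlate(out: Path, fits: pd.DataFrame, rt_table: pd.DataFrame) -> dict:
    path = out / "crosstask.json"
    if path.exists():
        log.info("correlate: cached")
        with open(path) as fh:
            return json.load(fh)
    gen = fits[fits["model"] == "generalized_hyperbolic"]
    wide = gen.pivot_table(index="participant_id", columns="session",
                           values="s", observed=True)
    delta_s = wide["post"] - wide["pre"]
    rt_scores = rt_table.set_index("participant_id")["interaction"]
    rho, p = timetravel.crosstask_correlation(
        rt_scores, delta_s.reindex(rt_scores.index), tail="one")
    result = {"spearman_rho": rho, "p": p, "tail": "one", "n": int(len(rt_scores))}
    _json_dump(result, path)
    return result


def stage_ppi(config: PipelineConfig, out: Path) -> dict:
    path = out / "ppi_demo.json"
    if path.exists():
        log.info("ppi-demo: cached")
        with open(path) as fh:
            return json.load(fh)
    events = pd.DataFrame({
        "onset_s": np.arange(20) * 12.0 + 2.0,
        "duration_s": 3.0,
        "condition": "offer",
        "modulator": np.tile(np.linspace(-2, 2, 5), 4),
    })
    design = build_design(events, n_scans=120)
    diffs = []
    for rep in range(config.ppi_replicates):
        rng = substream(config.seed, "ppi", rep)
        pre, post = ppi_session_contrast(
            design, {"offer": 1.0}, config.ppi_coupling_pre,
            config.ppi_coupling_post, config.ppi_noise_sd, rng)
        diffs.append(post - pre)
    diffs = np.asarray(diffs)
    result = {
        "replicates": config.ppi_replicates,
        "coupling_pre": config.ppi_coupling_pre,
        "coupling_post": config.ppi_coupling_post,
        "mean_post_minus_pre": float(diffs.mean()),
        "sd_post_minus_pre": float(diffs.std(ddof=1)),
        "frac_negative": float(np.mean(diffs < 0)),
    }
    _json_dump(result, path)
    return result


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute all stages and write ``report.json`` / ``report.txt``.

    Returns the report dict.  Any stage failure propagates with the stage
    name attached; outputs of completed stages remain on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _json_dump(config.to_dict(), out / "pipeline_config.json")

    stages = {}

    def run(name, fn, *args):
        log.info("stage %s", name)
        try:
            return fn(*args)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    cohort = run("simulate", stage_simulate, config, out)
    fits = run("fit", stage_fit, config, out, cohort["choices"])
    comparison = run("compare", stage_compare, out, fits)
    stats = run("group-stats", stage_group_stats, config, out, fits)
    rt_table, rt_test = run("rt-analysis", stage_rt, out, cohort["rts"])
    crosstask = run("correlate", stage_correlate, out, fits, rt_table)
    ppi = run("ppi-demo", stage_ppi, config, out)

    report = {
        "seed": config.seed,
        "n_participants": int(cohort["choices"]["participant_id"].nunique()),
        "model_comparison": comparison.to_dict(orient="records"),
        "group_stats": stats.to_dict(orient="records"),
        "rt_interaction": rt_test,
        "crosstask_correlation": crosstask,
        "ppi_demo": ppi,
    }
    _json_dump(report, out / "report.json")
    with open(out / "report.txt", "w") as fh:
        fh.write(format_report(report))
    return report


def format_report(report: dict) -> str:
    lines = [f"pipeline report (seed {report['seed']}, "
             f"{report['n_participants']} participants)", ""]
    lines.append("model comparison (mean LOOIC, lower is better):")
    for row in report["model_comparison"]:
        lines.append(f"  {row['model']:<24} {row['mean_looic']:9.2f}  (n={row['n_fits']})")
    lines.append("")
    lines.append("group tests on post-minus-pre changes (rTPJ vs vertex):")
    for row in report["group_stats"]:
        lines.append(f"  {row['measure']:<14} U={row['u']:7.1f}  Z={row['z']:6.2f}  "
                     f"p={row['p']:.3f} ({row['tail']}-tailed)  r={row['r']:.2f}")
    rt = report["rt_interaction"]
    lines.append("")
    lines.append(f"RT interaction (group x session x event time): "
                 f"Z={rt['z']:.2f}, p={rt['p']:.3f} ({rt['tail']}-tailed), r={rt['r']:.2f}")
    ct = report["crosstask_correlation"]
    lines.append(f"cross-task Spearman rho={ct['spearman_rho']:.2f}, "
                 f"p={ct['p']:.3f} ({ct['tail']}-tailed, n={ct['n']})")
    ppi = report["ppi_demo"]
    lines.append(f"PPI demo: mean post-minus-pre coupling estimate "
                 f"{ppi['mean_post_minus_pre']:.3f} over {ppi['replicates']} replicates "
                 f"({100 * ppi['frac_negative']:.0f}% negative)")
    lines.append("")
    return "\n".join(lines)
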