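"""Model comparison, recovery studies and condition summaries.

Model comparison follows leave-one-group-out cross-validation with
participants as groups: each fold refits every model hierarchically on the
retained participants and scores the held-out participants' trials by their
pointwise log predictive density under the fitted group-predictive
distribution. Models are compared by total elpd; a model is considered
better when |elpd_diff| >= 4 and >= 2 * se_diff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import (
    MODEL_SPECS,
    SamplerConfig,
    fit_hierarchical,
    heldout_pointwise_lpd,
    map_individual,
    split_participants,
)
from .observer import ObserverParams
from .synthetic import ExperimentDesign, generate_dataset

__all__ = [
    "ElpdReport",
    "RecoveryReport",
    "logo_cv",
    "parameter_recovery_study",
    "model_recovery_study",
    "condition_summaries",
    "make_cohort_params",
    "simulate_and_normalize",
]

logger = logging.getLogger(__name__)

ELPD_DIFF_RULE = 4.0  # decisive |elpd_diff| threshold
ELPD_SE_RULE = 2.0  # ... and at least this many se_diff


@dataclass
class ElpdReport:
    """LOGO-CV expected log pointwise predictive density per model."""

    totals: pd.DataFrame  # model, elpd, se, elpd_diff, se_diff, decisive
    pointwise: dict  # model -> concatenated pointwise lpd (aligned trials)
    folds: list  # fold -> list of held-out participant ids
    flagged_folds: list = field(default_factory=list)

    @property
    def best_model(self) -> str:
        return str(self.totals.iloc[0]["model"])


@dataclass
class RecoveryReport:
    table: pd.DataFrame  # true vs recovered values
    metrics: pd.DataFrame = None  # per-parameter bias, rmse, rank corr
    confusion: pd.DataFrame = None  # model recovery only
    reports: dict = None  # model recovery: generating model -> ElpdReport


def _fold_partition(participants: list[str], n_folds: int, holdout_size: int,
                    seed: int) -> list[list[str]]:
    """Seeded exact partition of participants into folds."""
    if len(participants) < n_folds * holdout_size:
        raise ValueError(
            f"need >= {n_folds * holdout_size} participants for "
            f"{n_folds} folds of {holdout_size}")
    rng = np.random.default_rng(seed)
    order = [participants[i] for i in rng.permutation(len(participants))]
    return [order[i * holdout_size:(i + 1) * holdout_size]
            for i in range(n_folds)]


def logo_cv(trials: pd.DataFrame, models: list[str] | None = None,
            n_folds: int = 10, holdout_size: int = 2, seed: int = 0,
            config: SamplerConfig | None = None,
            n_pred_draws: int = 150) -> ElpdReport:
    """Leave-one-group-out cross-validated elpd for each model variant."""
    models = models or list(MODEL_SPECS)
    config = config or SamplerConfig()
    data = {p.participant: p for p in split_participants(trials)}
    folds = _fold_partition(sorted(data), n_folds, holdout_size, seed)

    pointwise = {m: [] for m in models}
    flagged = []
    for k, heldout in enumerate(folds):
        retained = [data[p] for p in sorted(data) if p not in heldout]
        for m in models:
            cfg = SamplerConfig(**{**config.__dict__, "seed": config.seed + 13 * k})
            fit = fit_hierarchical(retained, m, cfg)
            if not fit.converged:
                flagged.append({"fold": k, "model": m,
                                "max_rhat": fit.diagnostics["max_rhat"]})
                logger.warning("fold %d model %s flagged (Rhat %.3f)", k, m,
                               fit.diagnostics["max_rhat"])
            for pid in heldout:
                lpd = heldout_pointwise_lpd(fit, data[pid], n_draws=n_pred_draws,
                                            seed=cfg.seed + 7)
                pointwise[m].append(lpd)

    pw = {m: np.concatenate(v) for m, v in pointwise.items()}
    n = len(next(iter(pw.values())))
    totals = pd.DataFrame({
        "model": models,
        "elpd": [pw[m].sum() for m in models],
        "se": [np.sqrt(n) * pw[m].std(ddof=1) for m in models],
    }).sort_values("elpd", ascending=False).reset_index(drop=True)
    best = totals.iloc[0]["model"]
    diffs, ses, decisive = [], [], []
    for m in totals["model"]:
        d = pw[m] - pw[best]
        diffs.append(d.sum())
        se_d = np.sqrt(n) * d.std(ddof=1)
        ses.append(se_d)
        decisive.append(bool(abs(d.sum()) >= ELPD_DIFF_RULE
                             and abs(d.sum()) >= ELPD_SE_RULE * se_d))
    totals["elpd_diff"] = diffs
    totals["se_diff"] = ses
    totals["decisive"] = decisive
    return ElpdReport(totals, pw, folds, flagged)


# ---------------------------------------------------------------------------
# Cohort helpers shared by the recovery drivers and the CLI
# ---------------------------------------------------------------------------

def make_cohort_params(n_participants: int,
                       group_medians: dict | None = None,
                       between_sd_log: float = 0.25,
                       sigma: float = 0.1,
                       report_noise_sd: float = 0.1,
                       seed: int = 0) -> list[ObserverParams]:
    """Draw a cohort's observer parameters log-normally around group medians."""
    g = {"w_choice": 2.17, "w_conf": 1.27, "b": 2.18}
    g.update(group_medians or {})
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_participants):
        draw = {k: float(np.exp(np.log(v) + between_sd_log * rng.standard_normal()))
                for k, v in g.items()}
        out.append(ObserverParams(w_choice=draw["w_choice"], w_conf=draw["w_conf"],
                                  b=draw["b"], sigma=sigma,
                                  report_noise_sd=report_noise_sd))
    return out


def simulate_and_normalize(params_list, design: ExperimentDesign | None = None,
                           seed: int = 0,
                           use_true_calibration: bool = True) -> pd.DataFrame:
    """Generate a cohort and attach normalized strengths.

    With ``use_true_calibration`` the generating sigma/bias are used for
    normalization (isolates weighting-parameter recovery from psychometric
    error); otherwise the psychometric calibration stage is run first.
    """
    from .psychometric import calibrate_participants, normalize_dataset

    main, control = generate_dataset(params_list, design, seed)
    if use_true_calibration:
        cal = pd.DataFrame({
            "participant": [f"sim{i + 1:03d}" for i in range(len(params_list))],
            "sigma": [p.sigma for p in params_list],
            "bias": [p.bias for p in params_list],
        })
    else:
        cal = calibrate_participants(main, control, seed=seed)
    return normalize_dataset(main, cal)


# ---------------------------------------------------------------------------
# Recovery studies
# ---------------------------------------------------------------------------

def parameter_recovery_study(true_params: list[ObserverParams],
                             design: ExperimentDesign | None = None,
                             seed: int = 0,
                             config: SamplerConfig | None = None,
                             model: str = "flexible") -> RecoveryReport:
    """Simulate each observer, refit individually, tabulate recovery metrics.

    Point estimates are MAP fits with the full (non-simplified) likelihood.
    """
    config = config or SamplerConfig()
    design = design or ExperimentDesign(n_participants=len(true_params))
    trials = simulate_and_normalize(true_params, design, seed)
    rows = []
    for i, (p, sub) in enumerate(zip(true_params,
                                     (g for _, g in trials.groupby("participant",
                                                                   sort=True)))):
        est = map_individual(sub, model=model, config=config)
        rows.append({
            "participant": f"sim{i + 1:03d}",
            "w_choice_true": p.w_choice, "w_conf_true": p.w_conf, "b_true": p.b,
            "w_choice_hat": est["w_choice"], "w_conf_hat": est["w_conf"],
            "b_hat": est["b"],
        })
    table = pd.DataFrame(rows)
    if table.empty:
        raise RuntimeError("no recoverable fits; recovery report not generated")
    metrics = []
    for par in ("w_choice", "w_conf", "b"):
        t = table[f"{par}_true"].to_numpy()
        h = table[f"{par}_hat"].to_numpy()
        rank = pd.Series(t).corr(pd.Series(h), method="spearman") \
            if np.unique(t).size > 1 else np.nan
        metrics.append({
            "parameter": par,
            "bias": float(np.mean(h - t)),
            "rmse": float(np.sqrt(np.mean((h - t) ** 2))),
            "rank_corr": float(rank) if rank == rank else np.nan,
        })
    return RecoveryReport(table, pd.DataFrame(metrics))


def model_recovery_study(models: list[str] | None = None,
                         generating_models: list[str] | None = None,
                         n_participants: int = 6,
                         design: ExperimentDesign | None = None,
                         n_folds: int = 2, holdout_size: int = 1,
                         n_reps: int = 1,
                         seed: int = 0,
                         config: SamplerConfig | None = None,
                         generating_params: dict | None = None) -> RecoveryReport:
    """Simulate cohorts from each generating model, refit all, record winners.

    The confusion matrix rows are generating models (summing to ``n_reps``),
    columns best-predicting models by LOGO-CV elpd at the configured
    (reduced) scale. The last fold report per generating model is kept for
    inspection of the decision rule.
    """
    models = models or list(MODEL_SPECS)
    generating_models = generating_models or models
    config = config or SamplerConfig()
    gen_medians = {
        "flexible": {"w_choice": 2.17, "w_conf": 1.27, "b": 2.18},
        "equal": {"w_choice": 2.0, "w_conf": 2.0, "b": 2.18},
        "optimal": {"w_choice": 1.0, "w_conf": 1.0, "b": 2.18},
        "flat_prior": {"w_choice": 50.0, "w_conf": 50.0, "b": 2.18},
    }
    if generating_params:
        gen_medians.update(generating_params)
    confusion = pd.DataFrame(0, index=generating_models, columns=models)
    rows, reports = [], {}
    for gi, gen in enumerate(generating_models):
        for rep_i in range(n_reps):
            s = seed + 1000 * rep_i + gi
            sd_log = 0.0 if gen == "optimal" else 0.15
            cohort = make_cohort_params(n_participants, gen_medians[gen],
                                        between_sd_log=sd_log, seed=s)
            if gen in ("equal", "flat_prior", "optimal"):
                # enforce the generating constraint exactly per participant
                cohort = [p.with_(w_conf=p.w_choice) for p in cohort]
            trials = simulate_and_normalize(cohort, design, seed=s + 100)
            report = logo_cv(trials, models, n_folds=n_folds,
                             holdout_size=holdout_size, seed=s,
                             config=config)
            winner = report.best_model
            confusion.loc[gen, winner] += 1
            rows.append({"generating": gen, "rep": rep_i, "winner": winner})
            reports[gen] = report
    return RecoveryReport(pd.DataFrame(rows), confusion=confusion,
                          reports=reports)


# ---------------------------------------------------------------------------
# Condition summaries (accuracy / confidence by posterior level x condition)
# ---------------------------------------------------------------------------

def condition_summaries(trials: pd.DataFrame) -> dict:
    """Group-level accuracy and confidence tables per posterior level/condition.

    Returns a dict of DataFrames: ``accuracy`` (target accuracy per posterior
    level x condition), ``confidence`` (mean confidence per posterior level x
    condition x target accuracy, the folded-X layout). Per-participant means
    are averaged so each participant counts equally; empty cells are NaN.
    """
    per_p_acc = (trials.groupby(["participant", "posterior_level", "condition"],
                                observed=True)["target_correct"]
                 .mean().reset_index())
    acc = (per_p_acc.groupby(["posterior_level", "condition"], observed=True)
           ["target_correct"].agg(["mean", "std", "count"]).reset_index()
           .rename(columns={"mean": "accuracy", "std": "sd",
                            "count": "n_participants"}))

    per_p_conf = (trials.groupby(["participant", "posterior_level", "condition",
                                  "target_correct"], observed=True)["conf_report"]
                  .mean().reset_index())
    conf = (per_p_conf.groupby(["posterior_level", "condition", "target_correct"],
                               observed=True)["conf_report"]
            .agg(["mean", "std", "count"]).reset_index()
            .rename(columns={"mean": "confidence", "std": "sd",
                             "count": "n_participants"}))

    folded = (trials.groupby(["participant", "posterior_level", "target_correct"],
                             observed=True)["conf_report"].mean().reset_index()
              .groupby(["posterior_level", "target_correct"], observed=True)
              ["conf_report"].agg(["mean", "std"]).reset_index()
              .rename(columns={"mean": "confidence", "std": "sd"}))
    return {"accuracy": acc, "confidence": conf, "folded_x": folded}
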