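"""Likelihood construction and Bayesian estimation of the observer models.

Four model variants are fit to trial tables of dual-decision data:

* ``flexible``   — free w_choice, w_conf, b
* ``flat_prior`` — prior probability of a rightward target fixed at exactly
  0.5 (lead information unused); free b
* ``optimal``    — w_choice = w_conf = 1; free b
* ``equal``      — one shared weight w = w_choice = w_conf; free b

Every model additionally fits the SD of a truncated-Gaussian observation
density for the confidence report on the [0.5, 1] scale.

Two likelihood routes are implemented. The *full* likelihood marginalizes
the latent lead response over the truncated normal implied by the observed
lead choice (choice), and integrates over both latent responses consistent
with the observed choices (confidence); it is used for individual fits. The
*simplified* likelihood substitutes the per-coherence-level mean stimulus
strengths for the latent responses, which places internal samples on the
correct side of the criterion and systematically underestimates confidence,
but keeps the hierarchical model tractable; it is used for group-level fits.

Sampling is by affine-invariant ensemble MCMC (emcee). For hierarchical
fits the participant-level random effects (log-normal around group means)
are integrated out with Gauss-Hermite quadrature, so the sampler only
explores the low-dimensional group posterior.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss as _leggauss_raw
from scipy.optimize import minimize
from scipy.special import log_ndtr, ndtr

from .observer import InvalidParameterError, posterior_confidence_right

__all__ = [
    "ModelSpec",
    "MODEL_SPECS",
    "SamplerConfig",
    "ParticipantData",
    "ModelFitResult",
    "choice_loglik",
    "confidence_loglik",
    "predicted_confidence",
    "fit_individual",
    "map_individual",
    "fit_hierarchical",
    "heldout_pointwise_lpd",
    "exclude_outliers",
]

logger = logging.getLogger(__name__)

_SQRT_2PI = math.sqrt(2.0 * math.pi)
_LOG_FLOOR = -40.0  # floor on per-trial log-likelihood terms (documented)


@lru_cache(maxsize=8)
def leggauss(n: int):
    return _leggauss_raw(n)


# ---------------------------------------------------------------------------
# Model specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Which observer parameters a model variant frees or fixes."""

    name: str
    free: tuple[str, ...]  # random-effect parameters, on the log scale
    flat_prior: bool = False

    @property
    def n_effects(self) -> int:
        return len(self.free)

    def expand(self, theta: np.ndarray) -> dict:
        """Map free-effect values (..., n_effects) to (w_choice, w_conf, b)."""
        theta = np.asarray(theta, dtype=float)
        out = {}
        if self.name == "flexible":
            out["w_choice"], out["w_conf"], out["b"] = (
                theta[..., 0], theta[..., 1], theta[..., 2])
        elif self.name == "equal":
            out["w_choice"] = out["w_conf"] = theta[..., 0]
            out["b"] = theta[..., 1]
        elif self.name in ("optimal", "flat_prior"):
            out["w_choice"] = out["w_conf"] = np.ones_like(theta[..., 0])
            out["b"] = theta[..., 0]
        else:
            raise InvalidParameterError(f"unknown model {self.name!r}")
        return out


MODEL_SPECS = {
    "flexible": ModelSpec("flexible", ("w_choice", "w_conf", "b")),
    "flat_prior": ModelSpec("flat_prior", ("b",), flat_prior=True),
    "optimal": ModelSpec("optimal", ("b",)),
    "equal": ModelSpec("equal", ("w", "b")),
}


@dataclass
class SamplerConfig:
    """Ensemble-sampler and quadrature settings (desk-scale defaults)."""

    n_walkers: int | None = None  # default: max(2*dim + 4, 12)
    n_steps: int = 900  # post burn-in steps per walker
    n_burn: int = 500
    thin: int = 1
    gh_nodes: int = 5  # Gauss-Hermite nodes per random-effect dimension
    conf_quad_nodes: int = 20  # per dimension, full confidence likelihood
    rhat_threshold: float = 1.1
    seed: int = 0


# ---------------------------------------------------------------------------
# Per-participant data container
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = (
    "s_lead_norm", "s_target_norm", "lead_choice", "target_choice",
    "lead_dir", "target_dir", "lead_level", "target_level", "conf_report",
)


@dataclass
class ParticipantData:
    """Numpy view of one participant's trials, ready for likelihood work."""

    participant: str
    s_lead: np.ndarray  # signed normalized lead strength (true stimulus)
    s_target: np.ndarray  # signed normalized target strength
    lead_choice: np.ndarray  # +/-1
    target_choice: np.ndarray  # +/-1
    conf: np.ndarray  # reported confidence in [0.5, 1]
    m_lead: np.ndarray  # level-mean |strength| substituted for |r_lead|
    r_target_simp: np.ndarray  # level-mean strength signed by true target dir

    @property
    def n_trials(self) -> int:
        return self.s_lead.size

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "ParticipantData":
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise InvalidParameterError(f"trial table lacks columns {missing}")
        pid = str(df["participant"].iloc[0]) if "participant" in df else "?"
        # mean |strength| per coherence level, pooling lead and target stimuli
        mags = pd.concat([
            pd.DataFrame({"level": df["lead_level"],
                          "mag": df["s_lead_norm"].abs()}),
            pd.DataFrame({"level": df["target_level"],
                          "mag": df["s_target_norm"].abs()}),
        ])
        level_mean = mags.groupby("level")["mag"].mean().to_dict()
        m_lead = df["lead_level"].map(level_mean).to_numpy(dtype=float)
        m_target = df["target_level"].map(level_mean).to_numpy(dtype=float)
        return cls(
            participant=pid,
            s_lead=df["s_lead_norm"].to_numpy(dtype=float),
            s_target=df["s_target_norm"].to_numpy(dtype=float),
            lead_choice=df["lead_choice"].to_numpy(dtype=int),
            target_choice=df["target_choice"].to_numpy(dtype=int),
            conf=np.clip(df["conf_report"].to_numpy(dtype=float), 0.5, 1.0),
            m_lead=m_lead,
            r_target_simp=df["target_dir"].to_numpy(dtype=float) * m_target,
        )


def split_participants(trials: pd.DataFrame) -> list[ParticipantData]:
    return [ParticipantData.from_table(sub)
            for _, sub in trials.groupby("participant", sort=True)]


# ---------------------------------------------------------------------------
# Truncated-normal report density on [0.5, 1]
# ---------------------------------------------------------------------------

def _truncnorm_pdf(x, mu, sd, lo=0.5, hi=1.0):
    z = (x - mu) / sd
    mass = np.maximum(ndtr((hi - mu) / sd) - ndtr((lo - mu) / sd), 1e-300)
    return np.exp(-0.5 * z * z) / (_SQRT_2PI * sd * mass)


def _log_truncnorm_pdf(x, mu, sd, lo=0.5, hi=1.0):
    z = (x - mu) / sd
    log_num = -0.5 * z * z - math.log(_SQRT_2PI) - np.log(sd)
    log_mass = np.log(np.maximum(ndtr((hi - mu) / sd) - ndtr((lo - mu) / sd),
                                 1e-300))
    return log_num - log_mass


# ---------------------------------------------------------------------------
# Choice likelihood
# ---------------------------------------------------------------------------

def _choice_ll_terms(data: ParticipantData, spec: ModelSpec, w_choice,
                     simplified: bool):
    """Per-trial log P(observed target choice); broadcasts over parameter axes.

    ``w_choice`` may be scalar or shape (K,) — output (T,) or (T, K).
    """
    sgn = data.target_choice.astype(float)  # +1 right, -1 left
    if spec.flat_prior:
        ll = log_ndtr(sgn * data.s_target)
        if np.ndim(w_choice) > 0:
            ll = np.broadcast_to(ll[:, None],
                                 (ll.size, np.shape(w_choice)[0])).copy()
        return np.maximum(ll, _LOG_FLOOR)
    w = np.asarray(w_choice, dtype=float)
    if simplified:
        arg = data.s_target[:, None] + data.m_lead[:, None] / w[None, :] \
            if w.ndim else data.s_target + data.m_lead / w
        p_right = ndtr(arg)
        p_right = np.clip(p_right, 1e-12, 1 - 1e-12)
        s = sgn[:, None] if w.ndim else sgn
        return np.maximum(np.where(s > 0, np.log(p_right), np.log1p(-p_right)),
                          _LOG_FLOOR)
    # full marginalization over the latent lead response; a lighter
    # Gauss-Legendre grid than the reference p_right_target, adequate for
    # repeated likelihood evaluation (checked against the reference in tests)
    if w.ndim:
        p_right = _p_right_quad(data.s_lead[:, None], data.s_target[:, None],
                                data.lead_choice[:, None], w[None, :])
        s = sgn[:, None]
    else:
        p_right = _p_right_quad(data.s_lead, data.s_target, data.lead_choice, w)
        s = sgn
    return np.maximum(np.where(s > 0, np.log(p_right), np.log1p(-p_right)),
                      _LOG_FLOOR)


def _p_right_quad(s_lead, s_target, lead_choice, w_choice, n_nodes: int = 96):
    """Marginal P(rightward target choice), fitting-grade quadrature."""
    x, wq = leggauss(n_nodes)
    cs = np.asarray(lead_choice, dtype=float) * s_lead
    upper = np.maximum(8.0, np.abs(cs) + 6.0)
    u = 0.5 * upper[..., None] * (x + 1.0)
    half_w = 0.5 * upper[..., None] * wq
    dens = np.exp(-0.5 * (u - cs[..., None]) ** 2) / _SQRT_2PI
    inner = ndtr(np.asarray(s_target)[..., None] + u / np.asarray(w_choice)[..., None])
    out = np.sum(inner * dens * half_w, axis=-1) / np.maximum(ndtr(cs), 1e-300)
    return np.clip(out, 1e-12, 1 - 1e-12)


# ---------------------------------------------------------------------------
# Confidence likelihood
# ---------------------------------------------------------------------------

def _simplified_conf_mu(data: ParticipantData, spec: ModelSpec, w_conf, b):
    """Model-predicted confidence report under mean-strength substitution.

    Broadcasts over parameter axes; returns the truncated mean mu in
    [0.5, 1] with shape (T,) or (T, K).
    """
    w_conf = np.asarray(w_conf, dtype=float)
    b = np.asarray(b, dtype=float)
    vec = w_conf.ndim or b.ndim
    m = data.m_lead[:, None] if vec else data.m_lead
    rt = data.r_target_simp[:, None] if vec else data.r_target_simp
    ch = data.target_choice[:, None] if vec else data.target_choice
    if spec.flat_prior:
        p_prior = 0.5
    else:
        p_prior = ndtr(m / (b * w_conf))
    p_like = ndtr(rt / b)
    conf_right = posterior_confidence_right(p_prior, p_like)
    conf_chosen = np.where(ch > 0, conf_right, 1.0 - conf_right)
    return np.clip(conf_chosen, 0.5, 1.0)


def _conf_ll_terms_simplified(data, spec, w_conf, b, sd):
    mu = _simplified_conf_mu(data, spec, w_conf, b)
    conf = data.conf[:, None] if mu.ndim == 2 else data.conf
    return np.maximum(_log_truncnorm_pdf(conf, mu, sd), _LOG_FLOOR)


def _conf_full_grids(data: ParticipantData, w_choice, w_conf, b, n_nodes):
    """Latent-response grids and weights for the full confidence likelihood.

    Returns (mu, weight) with shape (T, n1, n2): the model confidence report
    at each latent node and the (unnormalized) joint quadrature weight of
    the node conditional region implied by the observed choices.
    """
    x1, w1 = leggauss(n_nodes)
    x2, w2 = leggauss(n_nodes)
    T = data.n_trials

    du = data.lead_choice.astype(float)
    dt = data.target_choice.astype(float)
    cs = du * data.s_lead  # mean of |r_lead| distribution on the chosen side
    upper = np.maximum(8.0, np.abs(cs) + 6.0)
    u = 0.5 * upper[:, None] * (x1 + 1.0)  # (T, n1), u = |r_lead| > 0
    wu = 0.5 * upper[:, None] * w1
    dens_u = np.exp(-0.5 * (u - cs[:, None]) ** 2) / _SQRT_2PI

    theta = -u / w_choice  # criterion, (T, n1)
    # target response restricted to the side of theta matching the choice
    st = data.s_target[:, None]
    pos = dt[:, None] > 0
    hi = np.where(pos, np.maximum(theta, st) + 6.0, theta)
    lo = np.where(pos, theta, np.minimum(theta, st) - 6.0)
    width = hi - lo
    rt = lo[:, :, None] + 0.5 * width[:, :, None] * (x2 + 1.0)  # (T, n1, n2)
    wt = 0.5 * width[:, :, None] * w2
    dens_t = np.exp(-0.5 * (rt - st[:, None]) ** 2) / _SQRT_2PI

    p_prior = ndtr(u / (b * w_conf))  # (T, n1)
    p_like = ndtr(rt / b)
    conf_right = posterior_confidence_right(p_prior[:, :, None], p_like)
    conf_chosen = np.where(pos[:, :, None], conf_right, 1.0 - conf_right)
    mu = np.clip(conf_chosen, 0.5, 1.0)
    weight = dens_t * wt * (dens_u * wu)[:, :, None]
    return mu, weight


def _conf_ll_terms_full(data, spec, w_choice, w_conf, b, sd, n_nodes=20):
    """Per-trial log density of the observed report, full marginalization."""
    if spec.flat_prior:
        # no latent lead dependence; integrate over r_target only
        x2, w2 = leggauss(n_nodes)
        dt = data.target_choice.astype(float)
        st = data.s_target
        pos = dt > 0
        hi = np.where(pos, np.maximum(0.0, st) + 6.0, 0.0)
        lo = np.where(pos, 0.0, np.minimum(0.0, st) - 6.0)
        width = hi - lo
        rt = lo[:, None] + 0.5 * width[:, None] * (x2 + 1.0)
        wt = 0.5 * width[:, None] * w2
        dens = np.exp(-0.5 * (rt - st[:, None]) ** 2) / _SQRT_2PI
        conf_right = posterior_confidence_right(0.5, ndtr(rt / b))
        mu = np.clip(np.where(pos[:, None], conf_right, 1 - conf_right), 0.5, 1.0)
        tn = _truncnorm_pdf(data.conf[:, None], mu, sd)
        num = np.sum(tn * dens * wt, axis=-1)
        den = np.sum(dens * wt, axis=-1)
    else:
        mu, weight = _conf_full_grids(data, w_choice, w_conf, b, n_nodes)
        tn = _truncnorm_pdf(data.conf[:, None, None], mu, sd)
        num = np.sum(tn * weight, axis=(1, 2))
        den = np.sum(weight, axis=(1, 2))
    return np.maximum(np.log(np.maximum(num, 1e-300))
                      - np.log(np.maximum(den, 1e-300)), _LOG_FLOOR)


# ---------------------------------------------------------------------------
# Public likelihood surface
# ---------------------------------------------------------------------------

def _as_data(trials) -> ParticipantData:
    if isinstance(trials, ParticipantData):
        return trials
    return ParticipantData.from_table(trials)


def choice_loglik(trials, params: dict, model: str = "flexible",
                  use_simplification: bool = False) -> np.ndarray:
    """Per-trial log-probability of the observed target choices.

    ``params`` needs keys w_choice (ignored for flat_prior). The full
    version marginalizes the latent lead response; the simplified version
    substitutes the level-mean strength.
    """
    data = _as_data(trials)
    spec = MODEL_SPECS[model]
    return _choice_ll_terms(data, spec, float(params.get("w_choice", 1.0)),
                            use_simplification)


def confidence_loglik(trials, params: dict, model: str = "flexible",
                      use_simplification: bool = False,
                      report_noise_sd: float | None = None,
                      n_nodes: int = 20) -> np.ndarray:
    """Per-trial log-density of the observed confidence reports."""
    data = _as_data(trials)
    spec = MODEL_SPECS[model]
    sd = report_noise_sd if report_noise_sd is not None else params.get("report_noise_sd")
    if sd is None or sd <= 0:
        raise InvalidParameterError("report_noise_sd must be > 0")
    w_conf = float(params.get("w_conf", 1.0))
    b = float(params.get("b", 1.0))
    if use_simplification:
        return _conf_ll_terms_simplified(data, spec, w_conf, b, sd)
    return _conf_ll_terms_full(data, spec, float(params.get("w_choice", 1.0)),
                               w_conf, b, sd, n_nodes=n_nodes)


def predicted_confidence(trials, params: dict, model: str = "flexible",
                         use_simplification: bool = True,
                         n_nodes: int = 20) -> np.ndarray:
    """Model-expected confidence report per trial, conditional on the choices."""
    data = _as_data(trials)
    spec = MODEL_SPECS[model]
    w_conf = float(params.get("w_conf", 1.0))
    b = float(params.get("b", 1.0))
    if use_simplification:
        return _simplified_conf_mu(data, spec, w_conf, b)
    if spec.flat_prior:
        raise NotImplementedError("full predicted confidence for flat_prior")
    mu, weight = _conf_full_grids(data, float(params.get("w_choice", 1.0)),
                                  w_conf, b, n_nodes)
    return (np.sum(mu * weight, axis=(1, 2))
            / np.maximum(np.sum(weight, axis=(1, 2)), 1e-300))


def _total_ll_full(data, spec, w_choice, w_conf, b, sd, n_nodes):
    ll = _choice_ll_terms(data, spec, w_choice, simplified=False)
    ll = ll + _conf_ll_terms_full(data, spec, w_choice, w_conf, b, sd, n_nodes)
    return float(np.sum(ll))


def _trial_ll_simplified(data, spec, w_choice, w_conf, b, sd):
    """Per-trial (choice + confidence) log-likelihood; broadcasts over nodes."""
    ll = _choice_ll_terms(data, spec, w_choice, simplified=True)
    return ll + _conf_ll_terms_simplified(data, spec, w_conf, b, sd)


# ---------------------------------------------------------------------------
# Priors (sampling happens on unconstrained log parameters)
# ---------------------------------------------------------------------------

SD_PRIOR_SCALE = 0.15  # half-normal scale of the report-noise SD
EFFECT_PRIOR_SD = 1.0  # log-normal(log 1, 1) on w_choice, w_conf, b
GROUP_TAU_SCALE = 1.0  # half-normal(1) on group SDs (log scale)


def _log_prior_effects(log_theta: np.ndarray) -> float:
    return float(-0.5 * np.sum(log_theta ** 2) / EFFECT_PRIOR_SD ** 2)


def _log_prior_sd(log_sd: float) -> float:
    sd = math.exp(log_sd)
    # half-normal on sd plus the log-transform Jacobian
    return -0.5 * (sd / SD_PRIOR_SCALE) ** 2 + log_sd


# ---------------------------------------------------------------------------
# Fit result container
# ---------------------------------------------------------------------------

@dataclass
class ModelFitResult:
    """Posterior draws, summaries and diagnostics of one model fit."""

    model: str
    level: str  # "individual" | "hierarchical"
    draws: dict  # name -> flattened posterior draws
    chains: dict = field(repr=False, default=None)  # name -> (walkers, steps)
    summaries: pd.DataFrame = None
    diagnostics: dict = None
    seed: int = 0
    config: SamplerConfig = None

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))

    def point_estimates(self) -> dict:
        return {k: float(np.mean(v)) for k, v in self.draws.items()}


def _summarize_chains(chains: dict, rhat_threshold: float) -> tuple[pd.DataFrame, dict]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import arviz as az
        idata = az.from_dict(posterior={k: v for k, v in chains.items()})
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    rows = []
    for name, arr in chains.items():
        flat = arr.reshape(-1)
        lo, hi = np.quantile(flat, [0.055, 0.945])  # 89% equal-tailed interval
        r = float(rhat[name].values)
        n_eff = max(float(ess[name].values), 1.0)
        rows.append({
            "parameter": name,
            "mean": float(flat.mean()),
            "sd": float(flat.std(ddof=1)),
            "mcse": float(flat.std(ddof=1) / math.sqrt(n_eff)),
            "ci89_low": float(lo),
            "ci89_high": float(hi),
            "rhat": r,
            "ess": n_eff,
        })
    summary = pd.DataFrame(rows)
    max_rhat = float(summary["rhat"].max())
    diagnostics = {
        "max_rhat": max_rhat,
        "converged": max_rhat < rhat_threshold,
    }
    if not diagnostics["converged"]:
        logger.warning("fit flagged: max split-Rhat %.3f >= %.2f",
                       max_rhat, rhat_threshold)
    return summary, diagnostics


def _run_emcee(log_prob, x0_center, ndim, config: SamplerConfig, scatter=0.05):
    import emcee

    nw = config.n_walkers or max(2 * ndim + 4, 12)
    rng = np.random.default_rng(config.seed)
    p0 = x0_center + scatter * rng.standard_normal((nw, ndim))
    # differential-evolution moves mix much faster than the default stretch
    # move on the correlated group posteriors sampled here
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(nw, ndim, log_prob, moves=moves)
    sampler.random_state = np.random.RandomState(config.seed).get_state()
    state = sampler.run_mcmc(p0, config.n_burn, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, config.n_steps, progress=False)
    return sampler.get_chain()[:: config.thin]  # (steps, walkers, ndim)


# ---------------------------------------------------------------------------
# Individual fits (full likelihood)
# ---------------------------------------------------------------------------

def _individual_logpost(x, data, spec, n_nodes):
    log_theta = x[:-1]
    log_sd = x[-1]
    if np.any(np.abs(log_theta) > 6) or not (-7 < log_sd < 2):
        return -np.inf
    theta = np.exp(log_theta)
    pars = spec.expand(theta[None, :])
    sd = math.exp(log_sd)
    ll = _total_ll_full(data, spec,
                        float(pars["w_choice"][0]), float(pars["w_conf"][0]),
                        float(pars["b"][0]), sd, n_nodes)
    return ll + _log_prior_effects(log_theta) + _log_prior_sd(log_sd)


def _individual_logpost_simplified(x, data, spec):
    """Cheap surrogate posterior (mean-strength likelihood) used to locate
    good starting points for the full-likelihood optimization."""
    log_theta = x[:-1]
    log_sd = x[-1]
    if np.any(np.abs(log_theta) > 6) or not (-7 < log_sd < 2):
        return -np.inf
    pars = spec.expand(np.exp(log_theta)[None, :])
    ll = _trial_ll_simplified(data, spec, pars["w_choice"], pars["w_conf"],
                              pars["b"], math.exp(log_sd))
    return float(ll.sum()) + _log_prior_effects(log_theta) + _log_prior_sd(log_sd)


def map_individual(trials, model: str = "flexible",
                   config: SamplerConfig | None = None,
                   n_starts: int = 2) -> dict:
    """MAP point estimates of one participant's parameters (full likelihood).

    A fast pass on the simplified likelihood locates the high-posterior
    region; the full-likelihood optimum is then refined from there (plus
    jittered restarts).
    """
    config = config or SamplerConfig()
    data = _as_data(trials)
    spec = MODEL_SPECS[model]
    ndim = spec.n_effects + 1
    rng = np.random.default_rng(config.seed)
    x_init = np.concatenate([np.zeros(spec.n_effects), [math.log(0.12)]])
    pre = minimize(lambda x: -_individual_logpost_simplified(x, data, spec),
                   x_init, method="Nelder-Mead",
                   options={"maxiter": 300 * ndim, "xatol": 1e-3, "fatol": 1e-3})
    best = None
    for k in range(n_starts):
        x0 = pre.x if k == 0 else pre.x + rng.normal(0, 0.3, size=ndim)
        res = minimize(lambda x: -_individual_logpost(x, data, spec,
                                                      config.conf_quad_nodes),
                       x0, method="Nelder-Mead",
                       options={"maxiter": 200 * ndim, "xatol": 1e-3,
                                "fatol": 1e-3})
        if best is None or res.fun < best.fun:
            best = res
    theta = np.exp(best.x[:-1])
    pars = spec.expand(theta[None, :])
    return {
        "w_choice": float(pars["w_choice"][0]),
        "w_conf": float(pars["w_conf"][0]),
        "b": float(pars["b"][0]),
        "report_noise_sd": float(math.exp(best.x[-1])),
        "log_post": -float(best.fun),
    }


def fit_individual(trials, model: str = "flexible",
                   config: SamplerConfig | None = None) -> ModelFitResult:
    """Posterior over one participant's free parameters, full likelihood."""
    config = config or SamplerConfig()
    data = _as_data(trials)
    spec = MODEL_SPECS[model]
    ndim = spec.n_effects + 1

    def log_prob(x):
        return _individual_logpost(x, data, spec, config.conf_quad_nodes)

    x_init = np.concatenate([np.zeros(spec.n_effects), [math.log(0.12)]])
    pre = minimize(lambda x: -_individual_logpost_simplified(x, data, spec),
                   x_init, method="Nelder-Mead",
                   options={"maxiter": 300 * ndim, "xatol": 1e-3, "fatol": 1e-3})
    chain = _run_emcee(log_prob, pre.x, ndim, config)  # (steps, walkers, ndim)
    chain = np.moveaxis(chain, 0, 1)  # (walkers, steps, ndim)

    chains = {name: np.exp(chain[..., j]) for j, name in enumerate(spec.free)}
    chains["report_noise_sd"] = np.exp(chain[..., -1])
    if spec.name == "flexible":
        chains["w_choice_minus_w_conf"] = chains["w_choice"] - chains["w_conf"]
    summary, diagnostics = _summarize_chains(chains, config.rhat_threshold)
    draws = {k: v.reshape(-1) for k, v in chains.items()}
    return ModelFitResult(model, "individual", draws, chains, summary,
                          diagnostics, config.seed, config)


# ---------------------------------------------------------------------------
# Hierarchical fit (simplified likelihood, marginalized random effects)
# ---------------------------------------------------------------------------

class HierarchicalModel:
    """Group-level posterior with participant effects integrated out.

    Participant effects are log-normal around group means: for each free
    effect p, log p_i ~ Normal(mu_p, tau_p). The group parameter vector is
    [mu (d), log tau (d), log report_sd]; its posterior is explored by the
    ensemble sampler while each participant's marginal likelihood is
    computed with tensor Gauss-Hermite quadrature.

    The quadrature exploits the tensor structure: the choice likelihood
    depends on the node grid only through the weight axis, the confidence
    likelihood only through the (w_conf, b) axes, so per-trial terms are
    evaluated once per distinct axis value and recombined per node. All
    participants' trials are stacked into flat arrays and segment-summed.
    """

    def __init__(self, participants: list[ParticipantData], spec: ModelSpec,
                 config: SamplerConfig):
        self.participants = participants
        self.spec = spec
        self.config = config
        self.d = spec.n_effects
        z, w = np.polynomial.hermite_e.hermegauss(config.gh_nodes)
        self.z = z
        self.log_w1 = np.log(w / math.sqrt(2.0 * math.pi))
        # stacked trial arrays with participant offsets for reduceat
        self.offsets = np.cumsum([0] + [p.n_trials for p in participants])[:-1]
        self.m_lead = np.concatenate([p.m_lead for p in participants])
        self.s_target = np.concatenate([p.s_target for p in participants])
        self.r_target_simp = np.concatenate([p.r_target_simp for p in participants])
        self.sgn = np.concatenate([p.target_choice for p in participants]).astype(float)
        self.conf = np.concatenate([p.conf for p in participants])
        # The simplified confidence mean takes few distinct values per
        # participant (level-mean lead strength x level-mean signed target
        # strength x choice sign). The truncated-Gaussian log-density summed
        # over trials is a quadratic form in the report, so per-combination
        # sufficient statistics (count, sum, sum of squares of the reports)
        # replace the per-trial evaluation entirely.
        u_m, u_r, u_s, n_c, s_c, ss_c, offs = [], [], [], [], [], [], [0]
        for p in participants:
            key = np.stack([p.m_lead, p.r_target_simp,
                            p.target_choice.astype(float)], axis=1)
            uniq, idx = np.unique(key, axis=0, return_inverse=True)
            u_m.append(uniq[:, 0])
            u_r.append(uniq[:, 1])
            u_s.append(uniq[:, 2])
            n_c.append(np.bincount(idx).astype(float))
            s_c.append(np.bincount(idx, weights=p.conf))
            ss_c.append(np.bincount(idx, weights=p.conf ** 2))
            offs.append(offs[-1] + uniq.shape[0])
        self.u_m_lead = np.concatenate(u_m)
        self.u_r_target = np.concatenate(u_r)
        self.u_sgn = np.concatenate(u_s)
        self.combo_n = np.concatenate(n_c)
        self.combo_sum = np.concatenate(s_c)
        self.combo_sumsq = np.concatenate(ss_c)
        self.combo_offsets = np.array(offs[:-1])

    @property
    def ndim(self) -> int:
        return 2 * self.d + 1

    def _choice_terms(self, w_vals: np.ndarray | None) -> np.ndarray:
        """Per-participant summed choice loglik per w node; (P, nw)."""
        if w_vals is None:  # flat-prior model: lead information unused
            ll = np.maximum(log_ndtr(self.sgn * self.s_target), _LOG_FLOOR)[:, None]
        else:
            p_right = ndtr(self.s_target[:, None]
                           + self.m_lead[:, None] / w_vals[None, :])
            p_right = np.clip(p_right, 1e-12, 1 - 1e-12)
            ll = np.maximum(np.where(self.sgn[:, None] > 0, np.log(p_right),
                                     np.log1p(-p_right)), _LOG_FLOOR)
        return np.add.reduceat(ll, self.offsets, axis=0)

    def _conf_terms(self, wconf_vals, b_vals, sd) -> np.ndarray:
        """Per-participant summed confidence loglik per (w_conf, b) pair."""
        wb = (b_vals * wconf_vals)[None, :]
        p_prior = 0.5 if self.spec.flat_prior else ndtr(self.u_m_lead[:, None] / wb)
        p_like = ndtr(self.u_r_target[:, None] / b_vals[None, :])
        conf_right = posterior_confidence_right(p_prior, p_like)
        mu = np.clip(np.where(self.u_sgn[:, None] > 0, conf_right, 1 - conf_right),
                     0.5, 1.0)  # (U, npairs)
        log_mass = np.log(np.maximum(ndtr((1.0 - mu) / sd)
                                     - ndtr((0.5 - mu) / sd), 1e-300))
        n = self.combo_n[:, None]
        quad = (self.combo_sumsq[:, None] - 2.0 * self.combo_sum[:, None] * mu
                + n * mu * mu)
        ll = (-0.5 * quad / (sd * sd)
              - n * (math.log(_SQRT_2PI * sd) + log_mass))  # (U, npairs)
        return np.add.reduceat(ll, self.combo_offsets, axis=0)

    def _per_participant_marginal(self, mu, tau, sd) -> np.ndarray:
        """log p(data_i | group params) for every participant; (P,)."""
        nq = self.config.gh_nodes
        free = self.spec.free
        theta = {name: np.exp(mu[j] + tau[j] * self.z)
                 for j, name in enumerate(free)}  # per-axis node values
        if self.spec.name == "flexible":
            ch = self._choice_terms(theta["w_choice"])  # (P, nq)
            cf_pairs = self._conf_terms(
                np.repeat(theta["w_conf"], nq), np.tile(theta["b"], nq), sd)
            tot = (ch[:, :, None, None]
                   + cf_pairs.reshape(-1, nq, nq)[:, None, :, :])
            logw = (self.log_w1[:, None, None] + self.log_w1[None, :, None]
                    + self.log_w1[None, None, :])
        elif self.spec.name == "equal":
            ch = self._choice_terms(theta["w"])
            cf_pairs = self._conf_terms(
                np.repeat(theta["w"], nq), np.tile(theta["b"], nq), sd)
            tot = ch[:, :, None] + cf_pairs.reshape(-1, nq, nq)
            logw = self.log_w1[:, None] + self.log_w1[None, :]
        else:  # optimal / flat_prior: only b is a random effect
            w_vals = None if self.spec.flat_prior else np.ones(1)
            ch = self._choice_terms(w_vals)  # (P, 1)
            cf = self._conf_terms(np.ones(nq), theta["b"], sd)
            tot = ch + cf
            logw = self.log_w1
        tot = tot.reshape(tot.shape[0], -1) + logw.reshape(-1)[None, :]
        m = tot.max(axis=1, keepdims=True)
        return (m[:, 0] + np.log(np.sum(np.exp(tot - m), axis=1)))

    def log_prob(self, x: np.ndarray) -> float:
        mu = x[: self.d]
        log_tau = x[self.d: 2 * self.d]
        log_sd = x[-1]
        if np.any(np.abs(mu) > 6) or np.any(log_tau > 2) or np.any(log_tau < -7) \
                or not (-7 < log_sd < 2):
            return -np.inf
        tau = np.exp(log_tau)
        sd = math.exp(log_sd)
        lp = float(np.sum(self._per_participant_marginal(mu, tau, sd)))
        # hyperpriors: mu ~ N(0,1) (log-normal group medians centered on
        # optimality), tau ~ half-normal(1) with Jacobian, sd ~ half-normal
        lp += _log_prior_effects(mu)
        lp += float(np.sum(-0.5 * (tau / GROUP_TAU_SCALE) ** 2 + log_tau))
        lp += _log_prior_sd(log_sd)
        return lp

    def map_estimate(self) -> np.ndarray:
        """Posterior mode of the group parameters (warm start for sampling)."""
        x0 = np.concatenate([np.zeros(self.d),
                             np.full(self.d, math.log(0.3)),
                             [math.log(0.12)]])
        res = minimize(lambda x: -self.log_prob(x), x0, method="Nelder-Mead",
                       options={"maxiter": 250 * self.ndim, "xatol": 1e-3,
                                "fatol": 1e-2})
        return res.x

    def fit(self) -> ModelFitResult:
        x0 = self.map_estimate()
        chain = _run_emcee(self.log_prob, x0, self.ndim, self.config)
        chain = np.moveaxis(chain, 0, 1)  # (walkers, steps, ndim)
        chains = {}
        for j, name in enumerate(self.spec.free):
            chains[f"{name}_group"] = np.exp(chain[..., j])
            chains[f"tau_{name}"] = np.exp(chain[..., self.d + j])
        chains["report_noise_sd"] = np.exp(chain[..., -1])
        if self.spec.name == "flexible":
            chains["w_choice_minus_w_conf"] = (
                chains["w_choice_group"] - chains["w_conf_group"])
        summary, diagnostics = _summarize_chains(chains, self.config.rhat_threshold)
        draws = {k: v.reshape(-1) for k, v in chains.items()}
        draws["_mu"] = chain[..., : self.d].reshape(-1, self.d)
        draws["_tau"] = np.exp(chain[..., self.d: 2 * self.d]).reshape(-1, self.d)
        draws["_sd"] = np.exp(chain[..., -1]).reshape(-1)
        return ModelFitResult(self.spec.name, "hierarchical", draws, chains,
                              summary, diagnostics, self.config.seed, self.config)


def fit_hierarchical(trials, model: str = "flexible",
                     config: SamplerConfig | None = None) -> ModelFitResult:
    """Fit one model hierarchically to all participants' trials together.

    Uses the mean-strength simplified likelihood (the latent internal
    responses are not fit). Requires at least 2 participants.
    """
    config = config or SamplerConfig()
    participants = (trials if isinstance(trials, list)
                    else split_participants(trials))
    if len(participants) < 2:
        raise InvalidParameterError("hierarchical fit needs >= 2 participants")
    return HierarchicalModel(participants, MODEL_SPECS[model], config).fit()


def heldout_pointwise_lpd(fit: ModelFitResult, data: ParticipantData,
                          n_draws: int = 150, seed: int = 0) -> np.ndarray:
    """Pointwise log predictive density of a held-out participant's trials.

    For each retained posterior draw, a new participant's parameters are
    drawn from the fitted group distribution (group-predictive integration),
    the per-trial (choice + confidence) likelihood is evaluated, and the
    pointwise lpd is the log of the draw-averaged likelihood.
    """
    spec = MODEL_SPECS[fit.model]
    mu = fit.draws["_mu"]
    tau = fit.draws["_tau"]
    sds = fit.draws["_sd"]
    S = mu.shape[0]
    rng = np.random.default_rng(seed)
    idx = rng.choice(S, size=min(n_draws, S), replace=False)
    ll = np.empty((idx.size, data.n_trials))
    for k, s in enumerate(idx):
        theta = np.exp(rng.normal(mu[s], tau[s]))[None, :]
        pars = spec.expand(theta)
        ll[k] = _trial_ll_simplified(
            data, spec, pars["w_choice"], pars["w_conf"], pars["b"],
            float(sds[s]))[:, 0]
    m = ll.max(axis=0)
    return m + np.log(np.mean(np.exp(ll - m), axis=0))


def resample_from_simplified(trials: pd.DataFrame, params_by_participant: dict,
                             model: str = "flexible", seed: int = 0) -> pd.DataFrame:
    """Redraw target choices and confidence reports from the simplified model.

    Keeps every trial's stimuli, lead response and design labels, but
    replaces the target choice and confidence report with draws from the
    mean-strength simplified likelihood at the given parameters
    (dict participant -> {w_choice, w_conf, b, report_noise_sd}). This is
    the matching generative process for the hierarchical estimator, so
    recovery checks against it isolate estimation error from the documented
    simplification bias.
    """
    from .observer import _truncnorm_sample

    spec = MODEL_SPECS[model]
    rng = np.random.default_rng(seed)
    out = []
    for pid, sub in trials.groupby("participant", sort=True):
        sub = sub.copy()
        data = ParticipantData.from_table(sub)
        p = params_by_participant[pid]
        w_choice = float(p.get("w_choice", 1.0))
        if spec.flat_prior:
            p_right = ndtr(data.s_target)
        else:
            p_right = ndtr(data.s_target + data.m_lead / w_choice)
        choice = np.where(rng.random(data.n_trials) < p_right, 1, -1)
        data.target_choice = choice
        mu = _simplified_conf_mu(data, spec, float(p.get("w_conf", 1.0)),
                                 float(p.get("b", 1.0)))
        sub["target_choice"] = choice
        sub["target_correct"] = choice == sub["target_dir"].to_numpy()
        sub["conf_report"] = _truncnorm_sample(mu, float(p["report_noise_sd"]), rng)
        out.append(sub)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# Outlier exclusion
# ---------------------------------------------------------------------------

def exclude_outliers(estimates: pd.DataFrame, sd_threshold: float = 6.0,
                     parameters: tuple[str, ...] = ("w_choice", "w_conf", "b"),
                     ) -> tuple[list, list]:
    """Iteratively drop participants whose point estimate of any weighting
    parameter lies more than ``sd_threshold`` group SDs from the group mean.

    Each candidate is scored against the group statistics computed WITHOUT
    that candidate (leave-one-out): with the candidate included, the z-score
    of a single point in a group of n cannot exceed (n-1)/sqrt(n), which
    would mask any outlier under a 6-SD rule. Returns (retained participant
    ids, exclusion log). The most extreme offender is removed first, so the
    result is order-invariant.
    """
    df = estimates.sort_values("participant").reset_index(drop=True)
    params = [p for p in parameters if p in df.columns]
    excluded = []
    while len(df) > 2:
        worst = None
        for p in params:
            x = df[p].to_numpy(dtype=float)
            n = x.size
            # leave-one-out mean and SD for every candidate at once
            loo_mean = (x.sum() - x) / (n - 1)
            loo_var = ((np.square(x).sum() - x * x) / (n - 1)
                       - loo_mean ** 2) * (n - 1) / (n - 2)
            loo_sd = np.sqrt(np.maximum(loo_var, 0.0))
            with np.errstate(divide="ignore", invalid="ignore"):
                z = np.abs(x - loo_mean) / loo_sd
            z[~np.isfinite(z)] = 0.0
            i = int(np.argmax(z))
            if z[i] > sd_threshold and (worst is None or z[i] > worst[2]):
                worst = (i, p, float(z[i]))
        if worst is None:
            break
        i, p, z = worst
        pid = df.loc[i, "participant"]
        excluded.append({"participant": pid, "parameter": p, "z": z})
        logger.info("excluding %s: %s is %.2f group SDs from the mean", pid, p, z)
        df = df.drop(index=i).reset_index(drop=True)
    return df["participant"].tolist(), excluded
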