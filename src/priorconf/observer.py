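"""Generative Bayesian observer for the dual-decision task.

A trial consists of two random-dot-motion decisions. The correctness of the
first ("lead") decision deterministically sets the direction of the second
("target") stimulus: correct lead -> rightward target. An ideal observer
therefore carries its lead-decision confidence forward as the prior
probability of a rightward target.

All computations are performed on normalized stimulus strengths

    s = (dir * coh - bias) / sigma

so that internal noise is 1 everywhere downstream. The internal response to a
stimulus is r ~ Normal(s, 1).

The observer misweights the prior through two free parameters: ``w_choice``
scales the perceived variance of the prior in the target *choice* (criterion
shift theta = -|r_lead| / w_choice) and ``w_conf`` scales it in the
*confidence* computation. A confidence-bias parameter ``b`` scales the
perceived variance of both prior and likelihood, compressing (b > 1) or
expanding (b < 1) confidence around 50%.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import ndtr  # standard normal CDF, vectorized

__all__ = [
    "StimulusSpec",
    "ObserverParams",
    "InternalState",
    "TrialOutcome",
    "normalize_stimulus",
    "lead_confidence",
    "shifted_criterion",
    "p_right_target",
    "confidence_prior",
    "confidence_likelihood",
    "posterior_confidence_right",
    "simulate_trial",
    "simulate_trials",
]

logger = logging.getLogger(__name__)

#: Probabilities entering the posterior odds are clamped to
#: [PROB_EPS, 1 - PROB_EPS] to avoid 0/0 at extreme internal responses.
PROB_EPS = 1e-9
_clamp_warned = False

LEVELS = ("L", "M", "H")


class InvalidParameterError(ValueError):
    """A model parameter violates its support constraint."""


class NumericalAccuracyError(RuntimeError):
    """A quadrature failed to reach its documented tolerance."""


@dataclass(frozen=True)
class StimulusSpec:
    """One motion stimulus: signed direction, coherence, and level label."""

    direction: int  # -1 left, +1 right
    coherence: float  # in (0, 1)
    level_label: str = "M"  # one of L, M, H

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise InvalidParameterError(f"direction must be -1 or +1, got {self.direction}")
        if not (0.0 < self.coherence < 1.0):
            raise InvalidParameterError(f"coherence must lie in (0, 1), got {self.coherence}")
        if self.level_label not in LEVELS:
            raise InvalidParameterError(f"level_label must be one of {LEVELS}")

    @property
    def signed_coherence(self) -> float:
        return self.direction * self.coherence


@dataclass(frozen=True)
class ObserverParams:
    """Generative (or fitted) parameters of a single observer.

    w_choice, w_conf
        Multiplicative scalings of the prior's perceived variance in the
        choice and confidence computations. 1 is optimal; > 1 underweights
        the prior.
    b
        Confidence bias: joint misestimation of prior and likelihood
        variance. b > 1 compresses confidence toward 50%.
    sigma, bias
        Internal noise and decision bias in raw coherence units (used by
        stimulus normalization).
    lapse
        Probability that a choice is replaced by a fair coin flip.
    metacog_noise_sd, metacog_noise_family
        Optional corruption of the internal responses entering the
        confidence computation only (first-order choices are unaffected).
    report_noise_sd
        Truncated-Gaussian jitter of the reported confidence on the
        [0.5, 1] scale (0 disables it).
    """

    w_choice: float = 1.0
    w_conf: float = 1.0
    b: float = 1.0
    sigma: float = 0.1
    bias: float = 0.0
    lapse: float = 0.0
    metacog_noise_sd: float = 0.0
    metacog_noise_family: str = "none"  # none | gaussian | lognormal
    report_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("w_choice", "w_conf", "b", "sigma"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if not (0.0 <= self.lapse <= 0.5):
            raise InvalidParameterError(f"lapse must lie in [0, 0.5], got {self.lapse}")
        if self.metacog_noise_sd < 0:
            raise InvalidParameterError("metacog_noise_sd must be >= 0")
        if self.metacog_noise_family not in ("none", "gaussian", "lognormal"):
            raise InvalidParameterError(
                f"unknown metacog_noise_family {self.metacog_noise_family!r}"
            )
        if self.report_noise_sd < 0:
            raise InvalidParameterError("report_noise_sd must be >= 0")

    def with_(self, **kwargs) -> "ObserverParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class InternalState:
    """Latent per-trial quantities of a simulated observer."""

    s_lead: float
    s_target: float
    r_lead: float
    r_target: float


@dataclass(frozen=True)
class TrialOutcome:
    """Observable outcome of one simulated dual-decision trial."""

    lead_choice: int
    target_choice: int
    lead_correct: bool
    target_correct: bool
    conf_model: float  # posterior confidence in chosen target option, pre-clip
    conf_report: float  # reported confidence, in [0.5, 1]
    internal: InternalState = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Elementary model equations
# ---------------------------------------------------------------------------

def normalize_stimulus(stim: StimulusSpec, sigma: float, bias: float = 0.0) -> float:
    """Normalized stimulus strength s = (dir * coh - bias) / sigma."""
    if sigma <= 0:
        raise InvalidParameterError(f"sigma must be > 0, got {sigma}")
    return (stim.direction * stim.coherence - bias) / sigma


def lead_confidence(r_lead):
    """Posterior probability the lead choice (sign of r_lead) is correct.

    Under unit internal noise and a flat prior this is Phi(|r_lead|),
    always >= 0.5.
    """
    return ndtr(np.abs(r_lead))


def shifted_criterion(r_lead, w_choice):
    """Target decision criterion theta = -|r_lead| / w_choice (always <= 0).

    The shift favors "right", the direction the task rule promises after a
    correct lead decision. The target choice is "right" iff r_target > theta.
    """
    w_choice = np.asarray(w_choice, dtype=float)
    if np.any(w_choice <= 0):
        raise InvalidParameterError("w_choice must be > 0")
    return -np.abs(r_lead) / w_choice


def confidence_prior(r_lead, b, w_conf):
    """Prior for a rightward target in the confidence computation.

    p(R)_conf = Phi(|r_lead| / (b * w_conf)); equals lead confidence when
    b * w_conf = 1.
    """
    b = np.asarray(b, dtype=float)
    w_conf = np.asarray(w_conf, dtype=float)
    if np.any(b <= 0) or np.any(w_conf <= 0):
        raise InvalidParameterError("b and w_conf must be > 0")
    return ndtr(np.abs(r_lead) / (b * w_conf))


def confidence_likelihood(r_target, b):
    """Likelihood of the internal target response under a rightward stimulus.

    p(r_target | R) = Phi(r_target / b).
    """
    b = np.asarray(b, dtype=float)
    if np.any(b <= 0):
        raise InvalidParameterError("b must be > 0")
    return ndtr(np.asarray(r_target, dtype=float) / b)


def posterior_confidence_right(p_prior, p_like):
    """Bayes-rule combination of prior and likelihood for a rightward choice.

    conf_right = p_prior * p_like /
                 ((1 - p_prior)(1 - p_like) + p_prior * p_like)

    Confidence in a leftward choice is 1 - conf_right. Inputs at exactly 0
    or 1 are clamped to [PROB_EPS, 1 - PROB_EPS] with a warning.
    """
    global _clamp_warned
    p_prior = np.asarray(p_prior, dtype=float)
    p_like = np.asarray(p_like, dtype=float)
    if not _clamp_warned and np.any((p_prior <= 0) | (p_prior >= 1)
                                    | (p_like <= 0) | (p_like >= 1)):
        logger.warning("posterior_confidence_right: probabilities clamped to "
                       "[%g, %g] (warning emitted once)", PROB_EPS, 1 - PROB_EPS)
        _clamp_warned = True
    p_prior = np.clip(p_prior, PROB_EPS, 1 - PROB_EPS)
    p_like = np.clip(p_like, PROB_EPS, 1 - PROB_EPS)
    num = p_prior * p_like
    return num / ((1 - p_prior) * (1 - p_like) + num)


# ---------------------------------------------------------------------------
# Marginal choice probability (quadrature over the latent lead response)
# ---------------------------------------------------------------------------

#: Number of Gauss-Legendre nodes for the r_lead marginalization.
N_QUAD_NODES = 257
#: Base upper integration limit for |r_lead|; extended for strong stimuli.
QUAD_UPPER = 8.0

_GL_NODES, _GL_WEIGHTS = leggauss(N_QUAD_NODES)

_SQRT_2PI = math.sqrt(2.0 * math.pi)


def _norm_pdf(x):
    return np.exp(-0.5 * x * x) / _SQRT_2PI


def p_right_target(s_lead, s_target, lead_choice, w_choice):
    """Marginal probability of a rightward target choice.

    Integrates Phi(s_target - theta(r_lead)) against the truncated-normal
    density of r_lead given the observed lead choice and the lead stimulus
    (r_lead > 0 after a rightward lead choice, r_lead < 0 after leftward).
    Vectorized over broadcastable array arguments; returns values in (0, 1).
    """
    s_lead, s_target, lead_choice, w_choice = np.broadcast_arrays(
        np.asarray(s_lead, dtype=float),
        np.asarray(s_target, dtype=float),
        np.asarray(lead_choice, dtype=float),
        np.asarray(w_choice, dtype=float),
    )
    if np.any(w_choice <= 0):
        raise InvalidParameterError("w_choice must be > 0")

    # Work with u = |r_lead| in (0, upper]; density of u given the lead
    # choice c and strength s is phi(u - c*s) / Phi(c*s).
    cs = lead_choice * s_lead
    upper = np.maximum(QUAD_UPPER, np.abs(cs) + 6.0)
    # map Gauss-Legendre [-1, 1] nodes onto (0, upper]
    u = 0.5 * upper[..., None] * (_GL_NODES + 1.0)
    half_w = 0.5 * upper[..., None] * _GL_WEIGHTS

    dens = _norm_pdf(u - cs[..., None])
    mass = ndtr(cs)  # P(u > 0 side) = Phi(c*s)
    inner = ndtr(s_target[..., None] + u / w_choice[..., None])
    out = np.sum(inner * dens * half_w, axis=-1) / np.maximum(mass, 1e-300)

    out = np.clip(out, 1e-12, 1 - 1e-12)
    if not np.all(np.isfinite(out)):
        raise NumericalAccuracyError("non-finite marginal choice probability")
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Trial simulation
# ---------------------------------------------------------------------------

def _metacog_noised(r, params: ObserverParams, rng: np.random.Generator):
    """Internal responses as seen by the confidence stage."""
    if params.metacog_noise_family == "none" or params.metacog_noise_sd == 0.0:
        return r
    r = np.asarray(r, dtype=float)
    if params.metacog_noise_family == "gaussian":
        return r + rng.normal(0.0, params.metacog_noise_sd, size=r.shape)
    # lognormal: multiplicative, mean-1 noise on the magnitude
    sd = params.metacog_noise_sd
    factor = rng.lognormal(mean=-0.5 * sd * sd, sigma=sd, size=r.shape)
    return np.sign(r) * np.abs(r) * factor


def simulate_trials(
    params: ObserverParams,
    lead_dir,
    lead_coh,
    target_coh,
    rng: np.random.Generator,
):
    """Vectorized simulation of dual-decision trials.

    Parameters are arrays of the lead direction (+/-1) and the lead/target
    coherences. The target direction is set by the task rule (right iff the
    lead response was correct, including lapses). Returns a dict of arrays.
    """
    lead_dir = np.asarray(lead_dir, dtype=int)
    lead_coh = np.asarray(lead_coh, dtype=float)
    target_coh = np.asarray(target_coh, dtype=float)
    n = lead_dir.shape[0]

    s_lead = (lead_dir * lead_coh - params.bias) / params.sigma
    r_lead = rng.normal(s_lead, 1.0)
    lead_choice = np.where(r_lead > 0, 1, np.where(r_lead < 0, -1, 0))
    ties = lead_choice == 0
    if np.any(ties):  # measure-zero; fair coin
        lead_choice[ties] = rng.choice([-1, 1], size=int(ties.sum()))
    if params.lapse > 0:
        flip = rng.random(n) < params.lapse
        lead_choice = np.where(flip, rng.choice([-1, 1], size=n), lead_choice)
    lead_correct = lead_choice == lead_dir

    target_dir = np.where(lead_correct, 1, -1)
    s_target = (target_dir * target_coh - params.bias) / params.sigma
    r_target = rng.normal(s_target, 1.0)

    theta = shifted_criterion(r_lead, params.w_choice)
    target_choice = np.where(r_target > theta, 1, -1)
    if params.lapse > 0:
        flip = rng.random(n) < params.lapse
        target_choice = np.where(flip, rng.choice([-1, 1], size=n), target_choice)
    target_correct = target_choice == target_dir

    # confidence stage, possibly on metacognitively noised responses
    r_lead_c = _metacog_noised(r_lead, params, rng)
    r_target_c = _metacog_noised(r_target, params, rng)
    p_prior = confidence_prior(r_lead_c, params.b, params.w_conf)
    p_like = confidence_likelihood(r_target_c, params.b)
    conf_right = posterior_confidence_right(p_prior, p_like)
    conf_model = np.where(target_choice == 1, conf_right, 1.0 - conf_right)

    conf_report = np.clip(conf_model, 0.5, 1.0)
    if params.report_noise_sd > 0:
        conf_report = _truncnorm_sample(conf_report, params.report_noise_sd, rng)

    return {
        "s_lead": s_lead,
        "s_target": s_target,
        "r_lead": r_lead,
        "r_target": r_target,
        "lead_choice": lead_choice,
        "target_choice": target_choice,
        "lead_correct": lead_correct,
        "target_correct": target_correct,
        "target_dir": target_dir,
        "conf_model": conf_model,
        "conf_report": conf_report,
    }


def _truncnorm_sample(mu, sd, rng, lo=0.5, hi=1.0):
    """Draw from Normal(mu, sd) truncated to [lo, hi] by inverse CDF."""
    from scipy.special import ndtri

    mu = np.asarray(mu, dtype=float)
    a = ndtr((lo - mu) / sd)
    b = ndtr((hi - mu) / sd)
    u = rng.uniform(a, b)
    return np.clip(mu + sd * ndtri(np.clip(u, 1e-12, 1 - 1e-12)), lo, hi)


def simulate_trial(
    params: ObserverParams,
    lead_stim: StimulusSpec,
    target_coherence: float,
    rng: np.random.Generator | int,
) -> TrialOutcome:
    """Simulate a single dual-decision trial.

    The target *direction* is not an input: the task rule sets it to
    rightward iff the lead response is correct.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = simulate_trials(
        params,
        np.array([lead_stim.direction]),
        np.array([lead_stim.coherence]),
        np.array([target_coherence]),
        rng,
    )
    internal = InternalState(
        s_lead=float(out["s_lead"][0]),
        s_target=float(out["s_target"][0]),
        r_lead=float(out["r_lead"][0]),
        r_target=float(out["r_target"][0]),
    )
    return TrialOutcome(
        lead_choice=int(out["lead_choice"][0]),
        target_choice=int(out["target_choice"][0]),
        lead_correct=bool(out["lead_correct"][0]),
        target_correct=bool(out["target_correct"][0]),
        conf_model=float(out["conf_model"][0]),
        conf_report=float(out["conf_report"][0]),
        internal=internal,
    )
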