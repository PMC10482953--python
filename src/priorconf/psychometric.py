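"""Psychometric calibration of internal noise and decision bias.

Internal noise sigma and decision bias are estimated from prior-free
decisions (the control task plus the lead decision of every main-task
trial). Four cumulative-Gaussian psychometric variants are fit by maximum
likelihood,

    P(right | x) = lapse/2 + (1 - lapse) * Phi((x - bias) / sigma),

with absent parameters fixed at 0, and the per-parameter estimates are
combined with Akaike weights w_i proportional to exp(-dAIC_i / 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr

from .observer import InvalidParameterError

__all__ = [
    "PsychometricFit",
    "VARIANTS",
    "fit_psychometric",
    "fit_all_variants",
    "akaike_combine",
    "calibrate_participants",
    "normalize_dataset",
]

VARIANTS = ("noise_only", "noise_bias", "noise_lapse", "noise_bias_lapse")

_FREE = {
    "noise_only": ("sigma",),
    "noise_bias": ("sigma", "bias"),
    "noise_lapse": ("sigma", "lapse"),
    "noise_bias_lapse": ("sigma", "bias", "lapse"),
}


class FitFailureError(RuntimeError):
    """The psychometric fit could not be performed on the given data."""


@dataclass(frozen=True)
class PsychometricFit:
    variant: str
    sigma_hat: float
    bias_hat: float
    lapse_hat: float
    loglik: float
    aic: float
    akaike_weight: float = float("nan")


def _nll(theta, x, right, free):
    sigma = theta[0]
    bias = theta[1] if "bias" in free else 0.0
    lapse = theta[-1] if "lapse" in free else 0.0
    p = lapse / 2.0 + (1.0 - lapse) * ndtr((x - bias) / sigma)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -np.sum(np.where(right, np.log(p), np.log1p(-p)))


def fit_psychometric(decisions: pd.DataFrame, variant: str,
                     n_starts: int = 5, seed: int = 0) -> PsychometricFit:
    """ML fit of one psychometric variant.

    ``decisions`` needs columns ``signed_coherence`` and ``chose_right``.
    Bounded L-BFGS-B from several jittered starts; the best optimum is kept.
    """
    if variant not in VARIANTS:
        raise InvalidParameterError(f"unknown variant {variant!r}")
    x = decisions["signed_coherence"].to_numpy(dtype=float)
    right = decisions["chose_right"].to_numpy(dtype=bool)
    if np.unique(np.abs(x)).size < 2:
        raise FitFailureError("need at least 2 distinct coherence magnitudes")
    if right.all() or (~right).all():
        raise FitFailureError("both response categories must be present")

    free = _FREE[variant]
    lo = {"sigma": 1e-4, "bias": -0.5, "lapse": 0.0}
    hi = {"sigma": 5.0, "bias": 0.5, "lapse": 0.5}
    bounds = [(lo[p], hi[p]) for p in free]
    start = {"sigma": 0.1, "bias": 0.0, "lapse": 0.02}
    rng = np.random.default_rng(seed)

    best = None
    for k in range(n_starts):
        theta0 = np.array([start[p] for p in free])
        if k > 0:
            jitter = rng.uniform(0.5, 2.0, size=len(free))
            theta0 = np.clip(theta0 * jitter + rng.normal(0, 0.01, len(free)),
                             [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(_nll, theta0, args=(x, right, free), method="L-BFGS-B",
                       bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    sigma = float(theta[0])
    bias = float(theta[1]) if "bias" in free else 0.0
    lapse = float(theta[-1]) if "lapse" in free else 0.0
    loglik = -float(best.fun)
    k = len(free)
    return PsychometricFit(variant, sigma, bias, lapse, loglik,
                           aic=2.0 * k - 2.0 * loglik)


def fit_all_variants(decisions: pd.DataFrame, seed: int = 0) -> list[PsychometricFit]:
    """Fit all four variants on the same data and attach Akaike weights."""
    fits = [fit_psychometric(decisions, v, seed=seed) for v in VARIANTS]
    aics = np.array([f.aic for f in fits])
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    return [PsychometricFit(f.variant, f.sigma_hat, f.bias_hat, f.lapse_hat,
                            f.loglik, f.aic, float(wi))
            for f, wi in zip(fits, w)]


def akaike_combine(fits: list[PsychometricFit]) -> dict:
    """Akaike-weighted combination of the four variant estimates.

    Weights are recomputed from the AICs (so pre-attached weights are not
    required); absent parameters enter the average as 0.
    """
    if len(fits) != 4 or {f.variant for f in fits} != set(VARIANTS):
        raise InvalidParameterError("akaike_combine expects one fit per variant")
    aics = np.array([f.aic for f in fits])
    w = np.exp(-(aics - aics.min()) / 2.0)
    w = w / w.sum()
    return {
        "sigma": float(sum(wi * f.sigma_hat for wi, f in zip(w, fits))),
        "bias": float(sum(wi * f.bias_hat for wi, f in zip(w, fits))),
        "lapse": float(sum(wi * f.lapse_hat for wi, f in zip(w, fits))),
        "weights": {f.variant: float(wi) for f, wi in zip(fits, w)},
    }


def _prior_free_decisions(main: pd.DataFrame | None,
                          control: pd.DataFrame | None) -> pd.DataFrame:
    """Pool control-task decisions with the prior-free main-task lead decisions."""
    parts = []
    if control is not None and len(control):
        parts.append(pd.DataFrame({
            "participant": control["participant"],
            "signed_coherence": control["direction"] * control["coherence"],
            "chose_right": control["choice"] == 1,
        }))
    if main is not None and len(main):
        parts.append(pd.DataFrame({
            "participant": main["participant"],
            "signed_coherence": main["lead_dir"] * main["lead_coherence"],
            "chose_right": main["lead_choice"] == 1,
        }))
    if not parts:
        raise FitFailureError("no prior-free decisions supplied")
    return pd.concat(parts, ignore_index=True)


def calibrate_participants(main: pd.DataFrame | None, control: pd.DataFrame | None,
                           seed: int = 0) -> pd.DataFrame:
    """Per-participant Akaike-combined (sigma, bias, lapse) calibration table."""
    pooled = _prior_free_decisions(main, control)
    rows = []
    for pid, sub in pooled.groupby("participant", sort=True):
        fits = fit_all_variants(sub, seed=seed)
        comb = akaike_combine(fits)
        row = {"participant": pid, "sigma": comb["sigma"], "bias": comb["bias"],
               "lapse": comb["lapse"], "n_decisions": len(sub)}
        row.update({f"w_{v}": comb["weights"][v] for v in VARIANTS})
        rows.append(row)
    return pd.DataFrame(rows)


def normalize_dataset(trials: pd.DataFrame, calibration: pd.DataFrame) -> pd.DataFrame:
    """Attach normalized strengths s = (dir*coh - bias)/sigma to a trial table.

    Adds ``s_lead_norm`` and ``s_target_norm`` (signed, per the true stimulus
    directions) using each participant's calibrated sigma and bias.
    """
    cal = calibration.set_index("participant")
    if (cal["sigma"] <= 0).any():
        raise InvalidParameterError("calibrated sigma must be > 0")
    out = trials.merge(cal[["sigma", "bias"]], left_on="participant",
                       right_index=True, how="left", validate="many_to_one")
    if out["sigma"].isna().any():
        missing = sorted(set(trials["participant"]) - set(cal.index))
        raise FitFailureError(f"no calibration for participants: {missing}")
    out["s_lead_norm"] = (out["lead_dir"] * out["lead_coherence"] - out["bias"]) / out["sigma"]
    out["s_target_norm"] = (out["target_dir"] * out["target_coherence"] - out["bias"]) / out["sigma"]
    return out
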