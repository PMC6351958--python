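"""Posterior summarization, DIC, the spatial proportion eta, and convergence.

DIC = D_bar + p_D with p_D = D_bar - D_hat, where D_bar is the posterior
mean of the deviance and D_hat the deviance at the posterior means of all
stochastic nodes entering the linear predictor (coefficients, theta, phi).
DIC is not invariant to the choice of plug-in; the all-stochastic-parents
convention used here matches the classic BUGS behaviour for these models.

eta = sd(phi) / (sd(theta) + sd(phi)) measures the share of extra-Poisson
variability carried by the structured spatial effect. It is computed per
retained draw (SD taken across segments) and averaged over draws; the
alternative - SDs of the posterior-mean fields - is available via
``method="sd_of_means"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import CrashspatError
from .model_mcmc import PosteriorSamples, log_poisson_likelihood

#: parameters whose draws are strictly positive by construction; credible
#: intervals cannot straddle zero, so the exclusion-of-zero flag is not
#: meaningful and is reported as "n/a".
_VARIANCE_PARAMS = ("sigma_h", "sigma_c")


@dataclass
class FitSummary:
    parameters: dict               # name -> {mean, sd, ci90, ci95, significance}
    dic: Optional[dict] = None     # {D_bar, D_hat, p_D, DIC}
    eta: Optional[float] = None
    convergence: Optional[pd.DataFrame] = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, p in self.parameters.items():
            rows.append({"parameter": name, "mean": p["mean"], "sd": p["sd"],
                         "ci90_low": p["ci90"][0], "ci90_high": p["ci90"][1],
                         "ci95_low": p["ci95"][0], "ci95_high": p["ci95"][1],
                         "significance": p["significance"]})
        return pd.DataFrame(rows)


def _interval(draws, level):
    a = (1.0 - level) / 2.0
    return tuple(np.quantile(draws, [a, 1.0 - a]))


def summarize(samples: PosteriorSamples, levels=(0.90, 0.95)) -> FitSummary:
    """Posterior mean/SD, equal-tailed CIs, and significance per parameter.

    Significance is the highest credibility level whose equal-tailed
    interval excludes zero ("none" when even the lowest includes it); the
    flag is not applied to the variance parameters sigma_h, sigma_c, whose
    positive support makes it vacuous.
    """
    if samples.n_draws < 100:
        raise CrashspatError("need at least 100 retained draws to summarize")
    levels = sorted(levels)
    frame = samples.scalar_draws()
    params = {}
    for name in frame.columns:
        draws = frame[name].to_numpy()
        ci90 = _interval(draws, 0.90)
        ci95 = _interval(draws, 0.95)
        if name in _VARIANCE_PARAMS:
            sig = "n/a"
        else:
            sig = "none"
            for lvl in levels:
                lo, hi = _interval(draws, lvl)
                if lo > 0 or hi < 0:
                    sig = str(int(round(lvl * 100)))
                else:
                    break
        params[name] = {"mean": float(draws.mean()),
                        "sd": float(draws.std(ddof=1)) if draws.size > 1 else 0.0,
                        "ci90": ci90, "ci95": ci95, "significance": sig}
    return FitSummary(parameters=params)


def dic(samples: PosteriorSamples) -> dict:
    """Deviance information criterion block {D_bar, D_hat, p_D, DIC}."""
    if samples.deviance is None or samples.deviance.size == 0:
        raise CrashspatError("posterior samples carry no deviance trace")
    d_bar = float(samples.deviance.mean())
    eta_hat = samples.linear_predictor_at_means()
    d_hat = -2.0 * log_poisson_likelihood(samples.y, eta_hat)
    p_d = d_bar - d_hat
    return {"D_bar": d_bar, "D_hat": d_hat, "p_D": p_d, "DIC": d_bar + p_d}


def eta(samples: PosteriorSamples, method: str = "per_draw") -> float:
    """Proportion of extra-Poisson variation due to spatial autocorrelation.

    sd(phi) / (sd(theta) + sd(phi)); SDs are empirical across segments.
    Only defined for variants with a spatial effect (car, hybrid).
    """
    if samples.phi is None:
        raise CrashspatError("eta needs a spatial effect; not defined for "
                             "variant='spillover'")
    if method == "per_draw":
        sd_phi = samples.phi.std(axis=1, ddof=1)
        sd_theta = samples.theta.std(axis=1, ddof=1)
        denom = sd_theta + sd_phi
        ratio = np.where(denom > 0, sd_phi / np.where(denom > 0, denom, 1.0), 0.0)
        return float(ratio.mean())
    if method == "sd_of_means":
        sd_phi = samples.phi.mean(axis=0).std(ddof=1)
        sd_theta = samples.theta.mean(axis=0).std(ddof=1)
        denom = sd_theta + sd_phi
        return float(sd_phi / denom) if denom > 0 else 0.0
    raise CrashspatError(f"unknown eta method {method!r}")


def convergence_check(samples: PosteriorSamples, threshold: float = 0.05) -> pd.DataFrame:
    """Batch-means Monte-Carlo error relative to the posterior SD.

    Splits each scalar trace into ~sqrt(m) batches; MC error is the SD of
    the batch means over sqrt(#batches). Parameters with MC-error/SD at or
    above ``threshold`` are flagged; constant traces are reported as
    degenerate rather than flagged.
    """
    m = samples.n_draws
    if m < 1000:
        raise CrashspatError("need at least 1000 retained draws for the check")
    frame = samples.scalar_draws()
    nb = int(np.floor(np.sqrt(m)))
    bs = m // nb
    rows = []
    for name in frame.columns:
        trace = frame[name].to_numpy()[: nb * bs]
        sd = trace.std(ddof=1)
        if sd == 0:
            rows.append({"parameter": name, "mc_error": 0.0, "sd": 0.0,
                         "ratio": np.nan, "flagged": False, "degenerate": True})
            continue
        bmeans = trace.reshape(nb, bs).mean(axis=1)
        mc_err = bmeans.std(ddof=1) / np.sqrt(nb)
        ratio = mc_err / sd
        rows.append({"parameter": name, "mc_error": float(mc_err), "sd": float(sd),
                     "ratio": float(ratio), "flagged": bool(ratio >= threshold),
                     "degenerate": False})
    return pd.DataFrame(rows)


def full_summary(samples: PosteriorSamples, levels=(0.90, 0.95),
                 convergence_threshold: float = 0.05) -> FitSummary:
    """Complete fit report: parameter table, DIC block, eta, convergence."""
    out = summarize(samples, levels=levels)
    out.dic = dic(samples)
    if samples.phi is not None:
        out.eta = eta(samples)
    if samples.n_draws >= 1000:
        out.convergence = convergence_check(samples, convergence_threshold)
    return out


def compare_dic(fits: dict) -> pd.DataFrame:
    """Rank named fits by DIC (ascending); lower is better."""
    rows = [{"model": name, **dic(s)} for name, s in fits.items()]
    return pd.DataFrame(rows).sort_values("DIC").reset_index(drop=True)
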