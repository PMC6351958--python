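"""Bayesian Poisson count models for segment crash frequency, fit by MCMC.

Three model variants share the Poisson observation layer
``Y_i | lambda_i ~ Poisson(lambda_i)`` and differ in the link:

``car``
    log lambda_i = alpha + beta0 * log DVKT_i + beta' X_i + theta_i + phi_i
``spillover``
    log lambda_i = alpha + beta0 * log DVKT_i + beta' X_i
                   + beta_adj' X_adj_i + theta_i
``hybrid``
    log lambda_i = alpha + beta0 * log DVKT_i + beta' X_i
                   + beta_adj' X_adj_i + theta_i + phi_i

theta_i ~ N(0, 1/tau_h) is an exchangeable heterogeneity (over-dispersion)
effect; phi is an intrinsic CAR (Besag) spatial effect: conditionally
phi_i ~ N(mean of neighbours, 1/(tau_c * m_i)) with m_i the neighbour
count, jointly the improper pairwise-difference density

    p(phi | tau_c) propto tau_c^{(n-1)/2}
                   * exp(-tau_c/2 * sum_{i<j} w_ij (phi_i - phi_j)^2)

of rank n-1 on a connected graph. Identifiability of the intercept is
restored by re-centering phi to sum zero after every sweep and absorbing
the removed mean into alpha (the same constraint the classic disease-
mapping implementation imposes).

Priors are diffuse: N(0, 1e4) on every regression coefficient and
gamma(0.001, 0.001) on the precisions tau_h, tau_c; both configurable.

The sampler is Metropolis-within-Gibbs: element-wise adaptive random-walk
Metropolis for the coefficients, single-site random-walk Metropolis for
theta and phi (phi swept in graph-colour blocks, which are conditionally
independent and hence vectorizable), and conjugate Gibbs draws for the
precisions. Proposal scales adapt toward a target acceptance rate during
burn-in only. Covariates are centered internally for mixing; coefficients
are reported on the original scale (slopes are unchanged by centering and
the intercept is back-transformed draw by draw), and priors are evaluated
on the original-scale parameters, so the posterior sampled is exactly the
one stated above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import gammaln

from .adjacency import WeightMatrix, build_chain_weights, SpilloverSet
from .errors import ConfigError, CrashspatError

VARIANTS = ("car", "spillover", "hybrid")


@dataclass(frozen=True)
class ModelSpec:
    """Which variant to fit and which columns enter the link function."""

    variant: str
    covariates: tuple = ()
    spillover_covariates: tuple = ()
    exposure: Optional[str] = "log_dvkt"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigError(f"variant must be one of {VARIANTS}")
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "spillover_covariates", tuple(self.spillover_covariates))
        if self.variant == "car" and self.spillover_covariates:
            raise ConfigError("variant 'car' takes no spillover covariates")

    @property
    def has_phi(self) -> bool:
        return self.variant in ("car", "hybrid")


@dataclass(frozen=True)
class PriorConfig:
    """Diffuse priors: N(0, v) coefficients, gamma(a, b) precisions."""

    coef_prior_variance: float = 1e4
    tau_shape: float = 0.001
    tau_rate: float = 0.001

    def __post_init__(self):
        if min(self.coef_prior_variance, self.tau_shape, self.tau_rate) <= 0:
            raise ConfigError("prior hyperparameters must be strictly positive")


@dataclass(frozen=True)
class McmcConfig:
    iterations: int = 150_000
    burn_in: int = 100_000
    thin: int = 10
    seed: int = 0
    adapt_target: float = 0.44
    adapt_window: int = 100
    initial_scale: float = 0.1

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ConfigError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ConfigError("thin must be >= 1")
        if not 0 < self.adapt_target < 1:
            raise ConfigError("adapt_target must lie in (0, 1)")
        if self.adapt_window < 1:
            raise ConfigError("adapt_window must be >= 1")
        if self.initial_scale <= 0:
            raise ConfigError("proposal scale must be strictly positive")


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws of all model unknowns plus deviance."""

    spec: ModelSpec
    seed: int
    slope_names: tuple          # exposure first (if any), then covariates
    alpha: np.ndarray           # (m,)
    slopes: np.ndarray          # (m, p) original-scale coefficients
    theta: np.ndarray           # (m, n)
    phi: Optional[np.ndarray]   # (m, n) or None for variant='spillover'
    tau_h: np.ndarray           # (m,)
    tau_c: Optional[np.ndarray]
    deviance: np.ndarray        # (m,)
    acceptance: dict
    y: np.ndarray               # (n,) observed counts
    design: np.ndarray          # (n, p) original-scale design (no intercept)

    @property
    def n_draws(self) -> int:
        return self.alpha.size

    @property
    def n_segments(self) -> int:
        return self.y.size

    def scalar_draws(self) -> pd.DataFrame:
        """One column per scalar parameter (sigma's are 1/tau per draw)."""
        out = {"alpha": self.alpha}
        for j, name in enumerate(self.slope_names):
            out[name] = self.slopes[:, j]
        out["sigma_h"] = 1.0 / self.tau_h
        if self.tau_c is not None:
            out["sigma_c"] = 1.0 / self.tau_c
        return pd.DataFrame(out)

    def linear_predictor_at_means(self) -> np.ndarray:
        """log lambda evaluated at posterior means of all stochastic nodes."""
        eta = self.alpha.mean() + self.design @ self.slopes.mean(axis=0)
        eta = eta + self.theta.mean(axis=0)
        if self.phi is not None:
            eta = eta + self.phi.mean(axis=0)
        return eta


def log_poisson_likelihood(counts, log_rates) -> float:
    """Poisson log likelihood sum_i [y_i * log(lam_i) - lam_i - log(y_i!)]."""
    y = np.asarray(counts, dtype=float)
    eta = np.asarray(log_rates, dtype=float)
    if y.shape != eta.shape:
        raise CrashspatError("counts and log_rates must have equal length")
    if not np.all(np.isfinite(eta)):
        raise CrashspatError("log_rates must be finite")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise CrashspatError("counts must be non-negative integers")
    return float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1.0)))


def _pairwise_quadratic(phi: np.ndarray, w: WeightMatrix) -> float:
    """sum_{i<j} w_ij (phi_i - phi_j)^2 == phi' (D - W) phi."""
    return float(phi @ (w.degrees * phi) - phi @ (w.w @ phi))


def icar_log_density(phi, w: WeightMatrix, tau_c: float) -> float:
    """Joint intrinsic-CAR log density, up to an additive constant.

    Pairwise-difference form with rank n-1 on a connected graph:
    (n-1)/2 * log(tau_c) - tau_c/2 * sum_{i<j} w_ij (phi_i - phi_j)^2.
    Invariant under a constant shift of phi.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.size != w.n:
        raise CrashspatError("phi length must match the weight matrix")
    if tau_c <= 0:
        raise CrashspatError("tau_c must be strictly positive")
    return 0.5 * (w.n - 1) * np.log(tau_c) - 0.5 * tau_c * _pairwise_quadratic(phi, w)


def _check_connected(w: WeightMatrix) -> None:
    ncomp, _ = connected_components(csr_matrix(w.w), directed=False)
    if ncomp != 1:
        raise CrashspatError(
            "weight graph is disconnected; the rank-(n-1) ICAR update assumes "
            "a single connected component"
        )


def tau_h_posterior_params(theta, prior: PriorConfig):
    """Gamma full-conditional (shape, rate) for the heterogeneity precision."""
    theta = np.asarray(theta, dtype=float)
    return prior.tau_shape + theta.size / 2.0, prior.tau_rate + float(theta @ theta) / 2.0


def gibbs_update_tau_h(theta, prior: PriorConfig, rng: np.random.Generator) -> float:
    shape, rate = tau_h_posterior_params(theta, prior)
    return float(rng.gamma(shape, 1.0 / rate))


def tau_c_posterior_params(phi, w: WeightMatrix, prior: PriorConfig):
    """Gamma full-conditional (shape, rate) for the spatial precision.

    The ICAR precision matrix tau_c*(D - W) has rank n-1 on a connected
    graph, hence the exponent (n-1)/2 rather than n/2.
    """
    phi = np.asarray(phi, dtype=float)
    _check_connected(w)
    quad = _pairwise_quadratic(phi, w)
    return prior.tau_shape + (w.n - 1) / 2.0, prior.tau_rate + quad / 2.0


def gibbs_update_tau_c(phi, w: WeightMatrix, prior: PriorConfig, rng) -> float:
    shape, rate = tau_c_posterior_params(phi, w, prior)
    return float(rng.gamma(shape, 1.0 / rate))


def _greedy_colors(w: WeightMatrix):
    """Partition sites into colour classes with no within-class neighbours."""
    n = w.n
    color = np.full(n, -1, dtype=int)
    nbrs = [np.nonzero(w.w[i])[0] for i in range(n)]
    for i in range(n):
        used = {color[j] for j in nbrs[i] if color[j] >= 0}
        c = 0
        while c in used:
            c += 1
        color[i] = c
    return [np.nonzero(color == c)[0] for c in range(color.max() + 1)]


class _AdaptiveScale:
    """Random-walk scale with Robbins-Monro adaptation during burn-in."""

    def __init__(self, scale, target):
        self.scale = scale
        self.target = target
        self.accepted = 0.0
        self.proposed = 0.0
        self.total_accepted = 0.0
        self.total_proposed = 0.0

    def record(self, accepted, proposed=1.0):
        self.accepted += accepted
        self.proposed += proposed
        self.total_accepted += accepted
        self.total_proposed += proposed

    def adapt(self):
        if self.proposed > 0:
            rate = self.accepted / self.proposed
            self.scale *= float(np.exp(0.66 * (rate - self.target)))
            self.scale = float(np.clip(self.scale, 1e-6, 50.0))
        self.accepted = self.proposed = 0.0

    def freeze(self):
        """End of burn-in: report acceptance over the sampling phase only."""
        self.total_accepted = self.total_proposed = 0.0

    @property
    def overall_rate(self):
        return self.total_accepted / max(self.total_proposed, 1.0)


class MetropolisWithinGibbs:
    """The sampler for one model variant on one segment table.

    Exposes the individual update steps (coefficients, site effects,
    precisions) so each can be exercised on its own; :func:`run_mcmc` is
    the user-facing driver.
    """

    def __init__(self, y, design, slope_names, spec: ModelSpec,
                 priors: PriorConfig, cfg: McmcConfig, w: Optional[WeightMatrix]):
        self.y = np.asarray(y, dtype=float)
        if np.any(self.y < 0) or np.any(self.y != np.floor(self.y)):
            raise CrashspatError("crash counts must be non-negative integers")
        self.n = self.y.size
        self.design = np.asarray(design, dtype=float)
        self.slope_names = tuple(slope_names)
        self.spec = spec
        self.priors = priors
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self._logfact = float(gammaln(self.y + 1.0).sum())

        self.xbar = self.design.mean(axis=0) if self.design.size else np.zeros(0)
        self.Xc = self.design - self.xbar

        self.w = w
        if spec.has_phi:
            if w is None:
                raise ConfigError("CAR variants need a weight matrix")
            _check_connected(w)
            self.deg = w.degrees
            self.colors = _greedy_colors(w)

        # initial state: intercept at log mean count, everything else null
        p = self.design.shape[1] if self.design.ndim == 2 else 0
        self.alpha_c = float(np.log(max(self.y.mean(), 0.5 / self.n)))
        self.gamma = np.zeros(p)
        self.theta = np.zeros(self.n)
        self.phi = np.zeros(self.n) if spec.has_phi else None
        self.tau_h = 1.0
        self.tau_c = 1.0 if spec.has_phi else None
        self.eta = self._linear_predictor()
        if not np.all(np.isfinite(np.exp(self.eta))):
            raise CrashspatError("non-finite posterior at initialization")

        t = cfg.adapt_target
        s = cfg.initial_scale
        self.scale_alpha = _AdaptiveScale(s, t)
        self.scale_gamma = [_AdaptiveScale(s, t) for _ in range(p)]
        self.scale_theta = _AdaptiveScale(max(s, 0.3), t)
        self.scale_phi = _AdaptiveScale(max(s, 0.3), t) if spec.has_phi else None

    # -- state helpers -----------------------------------------------------
    def _linear_predictor(self):
        eta = self.alpha_c + (self.Xc @ self.gamma if self.gamma.size else 0.0)
        eta = eta + self.theta
        if self.phi is not None:
            eta = eta + self.phi
        return np.asarray(eta, dtype=float)

    @property
    def alpha_orig(self) -> float:
        """Intercept on the original (uncentered) covariate scale."""
        return self.alpha_c - float(self.xbar @ self.gamma)

    def log_likelihood(self) -> float:
        return float(np.sum(self.y * self.eta - np.exp(self.eta))) - self._logfact

    def deviance(self) -> float:
        return -2.0 * self.log_likelihood()

    # -- update steps ------------------------------------------------------
    def _coef_logprior(self, value):
        return -0.5 * value * value / self.priors.coef_prior_variance

    def update_coefficients(self):
        """Element-wise random-walk Metropolis on alpha and the slopes.

        Priors are evaluated on the original parameterization: a slope move
        also shifts the original-scale intercept alpha_orig = alpha_c -
        xbar . gamma, so both prior terms enter the ratio.
        """
        lam = np.exp(self.eta)
        # intercept (centered scale; orig intercept moves by the same delta)
        delta = self.scale_alpha.scale * self.rng.standard_normal()
        a0 = self.alpha_orig
        dloglik = float(self.y.sum() * delta - (np.exp(self.eta + delta) - lam).sum())
        dlogp = dloglik + self._coef_logprior(a0 + delta) - self._coef_logprior(a0)
        if np.log(self.rng.uniform()) < dlogp:
            self.alpha_c += delta
            self.eta += delta
            lam = np.exp(self.eta)
            self.scale_alpha.record(1.0)
        else:
            self.scale_alpha.record(0.0)

        for j in range(self.gamma.size):
            delta = self.scale_gamma[j].scale * self.rng.standard_normal()
            deta = delta * self.Xc[:, j]
            a0 = self.alpha_orig
            g0 = self.gamma[j]
            dloglik = float((self.y * deta).sum() - (np.exp(self.eta + deta) - lam).sum())
            dlogp = (
                dloglik
                + self._coef_logprior(g0 + delta) - self._coef_logprior(g0)
                + self._coef_logprior(a0 - delta * self.xbar[j]) - self._coef_logprior(a0)
            )
            if np.log(self.rng.uniform()) < dlogp:
                self.gamma[j] = g0 + delta
                self.eta += deta
                lam = np.exp(self.eta)
                self.scale_gamma[j].record(1.0)
            else:
                self.scale_gamma[j].record(0.0)

    def update_site_effects(self, target: str):
        """Single-site random-walk Metropolis sweep over theta or phi.

        theta sites are conditionally independent, so the whole sweep is a
        simultaneous element-wise accept/reject. phi sites interact through
        the CAR prior; the sweep runs over graph-colour blocks (no two
        sites of a colour are neighbours), which is equivalent to a
        sequential single-site scan. After a full phi sweep the field is
        re-centered to sum zero, with the removed mean absorbed into the
        intercept (the linear predictor is unchanged).
        """
        if target == "theta":
            s = self.scale_theta.scale
            prop = s * self.rng.standard_normal(self.n)
            new_theta = self.theta + prop
            d = (
                self.y * prop
                - (np.exp(self.eta + prop) - np.exp(self.eta))
                - 0.5 * self.tau_h * (new_theta**2 - self.theta**2)
            )
            accept = np.log(self.rng.uniform(size=self.n)) < d
            self.theta[accept] = new_theta[accept]
            self.eta[accept] += prop[accept]
            self.scale_theta.record(float(accept.sum()), float(self.n))
        elif target == "phi":
            if self.phi is None:
                raise ConfigError("this variant has no spatial effect")
            s = self.scale_phi.scale
            acc_total = 0.0
            for ids in self.colors:
                phibar = (self.w.w[ids] @ self.phi) / self.deg[ids]
                prop = s * self.rng.standard_normal(ids.size)
                old = self.phi[ids]
                new = old + prop
                d = (
                    self.y[ids] * prop
                    - (np.exp(self.eta[ids] + prop) - np.exp(self.eta[ids]))
                    - 0.5 * self.tau_c * self.deg[ids]
                    * ((new - phibar) ** 2 - (old - phibar) ** 2)
                )
                accept = np.log(self.rng.uniform(size=ids.size)) < d
                upd = ids[accept]
                self.phi[upd] = new[accept]
                self.eta[upd] += prop[accept]
                acc_total += float(accept.sum())
            m = float(self.phi.mean())
            self.phi -= m
            self.alpha_c += m          # eta is unchanged by the re-centering
            self.scale_phi.record(acc_total, float(self.n))
        else:
            raise ConfigError("target must be 'theta' or 'phi'")

    def update_precisions(self):
        self.tau_h = gibbs_update_tau_h(self.theta, self.priors, self.rng)
        if self.phi is not None:
            self.tau_c = gibbs_update_tau_c(self.phi, self.w, self.priors, self.rng)

    def sweep(self, adapting: bool, iteration: int):
        self.update_coefficients()
        self.update_site_effects("theta")
        if self.phi is not None:
            self.update_site_effects("phi")
        self.update_precisions()
        all_scales = [self.scale_alpha, *self.scale_gamma, self.scale_theta]
        if self.scale_phi is not None:
            all_scales.append(self.scale_phi)
        if adapting and (iteration + 1) % self.cfg.adapt_window == 0:
            for sc in all_scales:
                sc.adapt()
        if iteration + 1 == self.cfg.burn_in:
            for sc in all_scales:
                sc.freeze()


def _build_design(table: pd.DataFrame, spillover, spec: ModelSpec):
    frame = table
    if isinstance(spillover, SpilloverSet):
        extra = spillover.to_frame()
        extra.index = table.index
        frame = pd.concat([table, extra], axis=1)
    cols = []
    names = []
    if spec.exposure is not None:
        cols.append(spec.exposure)
        names.append(spec.exposure)
    cols.extend(spec.covariates)
    names.extend(spec.covariates)
    if spec.variant in ("spillover", "hybrid"):
        cols.extend(spec.spillover_covariates)
        names.extend(spec.spillover_covariates)
    for c in cols:
        if c not in frame.columns:
            raise ConfigError(f"column {c!r} named in the model spec is missing")
    X = frame[cols].to_numpy(dtype=float) if cols else np.zeros((len(frame), 0))
    return X, tuple(names)


def run_mcmc(table: pd.DataFrame, spillover=None, spec: ModelSpec = None,
             priors: PriorConfig = None, cfg: McmcConfig = None) -> PosteriorSamples:
    """Fit one model variant and return thinned post-burn-in draws.

    Deterministic given ``cfg.seed``. One sweep updates coefficients, then
    theta, then (for CAR variants) phi with re-centering, then the
    precisions; the deviance -2 log p(Y | lambda) is stored with every
    retained draw.
    """
    if spec is None:
        raise ConfigError("a ModelSpec is required")
    priors = priors or PriorConfig()
    cfg = cfg or McmcConfig()
    y = table["crash_count"].to_numpy()
    X, names = _build_design(table, spillover, spec)
    w = build_chain_weights(len(table)) if spec.has_phi else None
    sampler = MetropolisWithinGibbs(y, X, names, spec, priors, cfg, w)

    keep = [i for i in range(cfg.iterations)
            if i >= cfg.burn_in and (i - cfg.burn_in) % cfg.thin == 0]
    m = len(keep)
    n, p = sampler.n, X.shape[1]
    alpha = np.empty(m)
    slopes = np.empty((m, p))
    theta = np.empty((m, n))
    phi = np.empty((m, n)) if spec.has_phi else None
    tau_h = np.empty(m)
    tau_c = np.empty(m) if spec.has_phi else None
    deviance = np.empty(m)

    keep_set = set(keep)
    k = 0
    for it in range(cfg.iterations):
        sampler.sweep(adapting=(it < cfg.burn_in), iteration=it)
        if it in keep_set:
            alpha[k] = sampler.alpha_orig
            slopes[k] = sampler.gamma
            theta[k] = sampler.theta
            tau_h[k] = sampler.tau_h
            if spec.has_phi:
                phi[k] = sampler.phi
                tau_c[k] = sampler.tau_c
            deviance[k] = sampler.deviance()
            k += 1

    acceptance = {
        "alpha": sampler.scale_alpha.overall_rate,
        "theta": sampler.scale_theta.overall_rate,
    }
    for name, sc in zip(names, sampler.scale_gamma):
        acceptance[name] = sc.overall_rate
    if spec.has_phi:
        acceptance["phi"] = sampler.scale_phi.overall_rate

    return PosteriorSamples(
        spec=spec, seed=cfg.seed, slope_names=names,
        alpha=alpha, slopes=slopes, theta=theta, phi=phi,
        tau_h=tau_h, tau_c=tau_c, deviance=deviance,
        acceptance=acceptance, y=y.astype(int), design=X,
    )
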