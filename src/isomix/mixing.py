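"""Bayesian isotope mass-balance mixing model (SIAR-family likelihood).

Infers the posterior distribution of source contributions F_1..F_S to a
tropospheric mixture from replicate δ13C observations of one or two
tracers (formic and/or acetic acid).  The model is the standard
stable-isotope mixing model:

    δ_ti ~ Normal( Σ_s F_s μ_st ,  sqrt( Σ_s F_s² σ_st² + σ_res,t² ) )

independently across tracers t and replicates i, where (μ_st, σ_st) are
the per-source, per-tracer signature mean and SD, F lives on the simplex
with a Dirichlet prior, and σ_res,t is a per-tracer residual SD with a
uniform prior on (0, bound).  Source-signature uncertainty enters the
likelihood variance term (the published SIAR likelihood family), not as
latent per-source means.

Sampling is random-walk Metropolis in unconstrained coordinates: the
simplex is parameterised by a stick-breaking transform (with its exact
log-Jacobian so the Dirichlet prior is preserved) and the residual SDs by
their logarithms.  The proposal scale adapts toward ~30% acceptance during
burn-in and is frozen afterwards, so a given seed and chain configuration
always reproduce the same draws.

The estimator follows scikit-learn conventions: configuration in
``__init__``, data in ``fit``, results in trailing-underscore attributes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

__all__ = [
    "SourceProfile",
    "MixtureObservations",
    "MixingPrior",
    "ChainConfig",
    "PosteriorFractions",
    "AnalyticFractions",
    "PooledFractions",
    "IsotopeMixingModel",
    "fit_mixing_model",
    "analytic_fractions_when_determined",
    "summarize_posterior",
    "propagate_across_replicates",
]

#: default seed for reproducible chains
DEFAULT_SEED = 20210330


# ---------------------------------------------------------------------------
# domain containers


@dataclass(frozen=True)
class SourceProfile:
    """One emission source: per-tracer signature mean and SD in ‰.

    ``mean_delta`` and ``sd_delta`` map tracer name → value; the tracer
    sets must coincide and SDs must be ≥ 0.
    """

    name: str
    mean_delta: dict[str, float]
    sd_delta: dict[str, float]

    def __post_init__(self) -> None:
        if not self.mean_delta:
            raise ValueError(f"source {self.name!r} has no tracers")
        if set(self.mean_delta) != set(self.sd_delta):
            raise ValueError(
                f"source {self.name!r}: mean tracers {sorted(self.mean_delta)} "
                f"!= sd tracers {sorted(self.sd_delta)}"
            )
        for t, sd in self.sd_delta.items():
            if sd < 0:
                raise ValueError(f"source {self.name!r}, tracer {t!r}: sd {sd} < 0")


@dataclass(frozen=True)
class MixtureObservations:
    """Replicate δ13C measurements of one tropospheric environment.

    ``replicates`` maps tracer name → 1-D array of per-sample ‰ values.
    Tracers may have different replicate counts (e.g. acetic-only data).
    """

    environment: str
    replicates: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError(f"environment {self.environment!r} has no data")
        clean = {}
        for t, vals in self.replicates.items():
            arr = np.atleast_1d(np.asarray(vals, dtype=float))
            if arr.size < 1:
                raise ValueError(
                    f"environment {self.environment!r}, tracer {t!r}: no replicates"
                )
            clean[t] = arr
        object.__setattr__(self, "replicates", clean)

    @property
    def n(self) -> int:
        """Maximum replicate count over tracers."""
        return max(v.size for v in self.replicates.values())

    @property
    def tracers(self) -> list[str]:
        return sorted(self.replicates)


@dataclass(frozen=True)
class MixingPrior:
    """Prior configuration: Dirichlet α per source, residual-SD bounds in ‰."""

    dirichlet_alphas: np.ndarray | None = None  # None → flat Dirichlet(1,…,1)
    residual_sd_bounds: tuple[float, float] = (0.0, 20.0)

    def __post_init__(self) -> None:
        if self.dirichlet_alphas is not None:
            a = np.asarray(self.dirichlet_alphas, dtype=float)
            if np.any(a <= 0):
                raise ValueError(f"Dirichlet alphas must be > 0, got {a}")
            object.__setattr__(self, "dirichlet_alphas", a)
        lo, hi = self.residual_sd_bounds
        if not (0 <= lo < hi):
            raise ValueError(f"degenerate residual SD bounds {self.residual_sd_bounds}")


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run length and seed."""

    n_retained: int = 10_000
    n_burnin: int = 5_000
    thin: int = 1
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_retained < 1:
            raise ValueError("n_retained must be ≥ 1")
        if self.n_burnin < 0:
            raise ValueError("n_burnin must be ≥ 0")
        if self.thin < 1:
            raise ValueError("thin must be a positive integer")


@dataclass(frozen=True)
class PosteriorFractions:
    """Posterior sample of source fractions with summaries.

    ``draws`` is (n_retained, n_sources), every row on the simplex.
    ``ci95`` holds the equal-tailed 95% interval per source, shape (S, 2).
    """

    draws: np.ndarray
    source_names: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    ci95: np.ndarray
    residual_sd_draws: np.ndarray | None = None
    environment: str | None = None
    rhat: np.ndarray | None = None

    @property
    def n_sources(self) -> int:
        return self.draws.shape[1]


@dataclass(frozen=True)
class AnalyticFractions:
    """Exact linear-solve fractions for the determined case.

    ``feasible`` is False when the solution leaves the simplex — the
    geometric signal that the source set is incomplete.
    """

    fractions: np.ndarray
    source_names: tuple[str, ...]
    feasible: bool


@dataclass(frozen=True)
class PooledFractions:
    """Study-level mean fractions pooled over environments."""

    mean: np.ndarray
    sd: np.ndarray
    ci95: np.ndarray
    source_names: tuple[str, ...]
    n_environments: int = 1


# ---------------------------------------------------------------------------
# simplex transform


def _stick_breaking(u: np.ndarray) -> tuple[np.ndarray, float]:
    """Map R^(K−1) → interior of the K-simplex; return (F, log|Jacobian|).

    Uses the centred stick-breaking transform (offset −log(K−k) on break k)
    so u = 0 maps to the uniform composition.
    """
    K = u.size + 1
    F = np.empty(K)
    log_jac = 0.0
    rem = 1.0
    for k in range(K - 1):
        z = float(expit(u[k] - np.log(K - 1 - k)))
        z = min(max(z, 1e-300), 1.0 - 1e-16)
        F[k] = rem * z
        log_jac += np.log(z) + np.log1p(-z) + np.log(rem)
        rem *= 1.0 - z
    F[K - 1] = rem
    return F, log_jac


# ---------------------------------------------------------------------------
# estimator


class IsotopeMixingModel(BaseEstimator):
    """Bayesian source-apportionment estimator for δ13C mixtures.

    Parameters
    ----------
    source_means : array-like of shape (n_sources, n_tracers)
        Per-source, per-tracer signature means in ‰.
    source_sds : array-like of shape (n_sources, n_tracers)
        Per-source, per-tracer signature SDs in ‰ (≥ 0).
    source_names : sequence of str, optional
        Labels; defaults to ``S1..Sk``.
    dirichlet_alpha : float or array-like, default 1.0
        Dirichlet prior concentration(s) on the fractions.
    residual_sd_bound : float, default 20.0
        Upper bound of the uniform prior on each tracer's residual SD (‰).
    n_retained, n_burnin, thin : int
        Chain length configuration (defaults 10,000 / 5,000 / 1).
    random_state : int, default 20210330
        Seed; identical seed + configuration reproduces the draws exactly.

    Attributes
    ----------
    draws_ : ndarray of shape (n_retained, n_sources)
        Posterior fraction draws, each row on the simplex.
    mean_, sd_ : ndarray of shape (n_sources,)
        Posterior mean and SD per source.
    ci95_ : ndarray of shape (n_sources, 2)
        Equal-tailed 95% credible intervals.
    residual_sd_draws_ : ndarray of shape (n_retained, n_tracers)
        Posterior draws of the residual SDs.
    acceptance_rate_ : float
        Post-burn-in Metropolis acceptance rate.
    rhat_ : ndarray of shape (n_sources,)
        Split-chain potential-scale-reduction diagnostic on the fractions.
    """

    def __init__(
        self,
        source_means=None,
        source_sds=None,
        source_names=None,
        dirichlet_alpha=1.0,
        residual_sd_bound=20.0,
        n_retained=10_000,
        n_burnin=5_000,
        thin=1,
        random_state=DEFAULT_SEED,
    ):
        self.source_means = source_means
        self.source_sds = source_sds
        self.source_names = source_names
        self.dirichlet_alpha = dirichlet_alpha
        self.residual_sd_bound = residual_sd_bound
        self.n_retained = n_retained
        self.n_burnin = n_burnin
        self.thin = thin
        self.random_state = random_state

    # -- model -------------------------------------------------------------

    def _validate(self, X):
        mu = np.asarray(self.source_means, dtype=float)
        if mu.ndim == 1:
            mu = mu[:, None]
        sig = np.asarray(self.source_sds, dtype=float)
        if sig.ndim == 1:
            sig = sig[:, None]
        if mu.shape != sig.shape:
            raise ValueError(
                f"source_means {mu.shape} and source_sds {sig.shape} differ"
            )
        if mu.shape[0] < 2:
            raise ValueError("need at least 2 sources")
        if np.any(sig < 0):
            raise ValueError("source SDs must be ≥ 0")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != mu.shape[1]:
            raise ValueError(
                f"mixture has {X.shape[1]} tracer column(s) but sources define "
                f"{mu.shape[1]}"
            )
        if not np.isfinite(X).any(axis=0).all():
            raise ValueError("a tracer column contains no finite observations")
        names = self.source_names
        if names is None:
            names = tuple(f"S{i + 1}" for i in range(mu.shape[0]))
        elif len(names) != mu.shape[0]:
            raise ValueError("source_names length mismatch")
        return mu, sig, X, tuple(names)

    def _log_post(self, theta, mu, sig2, X, mask, alphas, sd_lo, sd_hi):
        S, T = mu.shape
        u, v = theta[: S - 1], theta[S - 1 :]
        F, log_jac = _stick_breaking(u)
        sigma_res = np.exp(v)
        if np.any(sigma_res <= sd_lo) or np.any(sigma_res >= sd_hi):
            return -np.inf, F
        log_jac += v.sum()  # Jacobian of σ = exp(v)
        lp = log_jac + float((alphas - 1.0) @ np.log(F))
        m = F @ mu  # (T,) mixture means
        var = (F * F) @ sig2 + sigma_res**2  # (T,) total variances
        resid2 = (X - m) ** 2
        ll = -0.5 * np.nansum(
            np.where(mask, resid2 / var + np.log(2.0 * np.pi * var), 0.0)
        )
        return lp + ll, F

    def fit(self, X, y=None):
        """Sample the posterior of source fractions given replicate δ13C.

        Parameters
        ----------
        X : array-like of shape (n_replicates, n_tracers)
            Replicate δ13C observations in ‰, one column per tracer in the
            same order as the columns of ``source_means``.  NaN marks a
            missing tracer value in a replicate.
        y : ignored
        """
        mu, sig, X, names = self._validate(X)
        S, T = mu.shape
        sig2 = sig**2
        mask = np.isfinite(X)
        alphas = np.broadcast_to(
            np.asarray(self.dirichlet_alpha, dtype=float), (S,)
        ).copy()
        if np.any(alphas <= 0):
            raise ValueError("dirichlet_alpha must be > 0")
        sd_lo, sd_hi = 0.0, float(self.residual_sd_bound)
        if sd_hi <= 0:
            raise ValueError("residual_sd_bound must be > 0")
        chain = ChainConfig(
            n_retained=self.n_retained,
            n_burnin=self.n_burnin,
            thin=self.thin,
            seed=self.random_state,
        )
        rng = np.random.default_rng(chain.seed)

        D = (S - 1) + T
        theta = np.zeros(D)
        # start residual SDs near the observed spread (clipped inside prior)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            obs_sd = np.nanstd(np.where(mask, X, np.nan), axis=0)
        obs_sd = np.where(np.isfinite(obs_sd) & (obs_sd > 0), obs_sd, 1.0)
        theta[S - 1 :] = np.log(np.clip(obs_sd, 1e-3, 0.5 * sd_hi))

        lp, F = self._log_post(theta, mu, sig2, X, mask, alphas, sd_lo, sd_hi)
        scale = 0.3
        n_iter = chain.n_burnin + chain.n_retained * chain.thin
        draws = np.empty((chain.n_retained, S))
        res_draws = np.empty((chain.n_retained, T))
        accepted_post = 0
        window_acc = 0
        kept = 0
        for it in range(n_iter):
            prop = theta + scale * rng.standard_normal(D)
            lp_new, F_new = self._log_post(
                prop, mu, sig2, X, mask, alphas, sd_lo, sd_hi
            )
            if np.log(rng.random()) < lp_new - lp:
                theta, lp, F = prop, lp_new, F_new
                window_acc += 1
                if it >= chain.n_burnin:
                    accepted_post += 1
            if it < chain.n_burnin:
                # Robbins–Monro-style adaptation toward ~30% acceptance
                if (it + 1) % 50 == 0:
                    rate = window_acc / 50.0
                    scale *= float(np.exp(1.5 * (rate - 0.30)))
                    scale = float(np.clip(scale, 1e-4, 10.0))
                    window_acc = 0
            else:
                if (it - chain.n_burnin) % chain.thin == 0:
                    draws[kept] = F
                    res_draws[kept] = np.exp(theta[S - 1 :])
                    kept += 1
        assert kept == chain.n_retained

        self.source_names_ = names
        self.draws_ = draws
        self.residual_sd_draws_ = res_draws
        self.mean_ = draws.mean(axis=0)
        self.sd_ = draws.std(axis=0, ddof=1) if chain.n_retained > 1 else np.zeros(S)
        self.ci95_ = np.quantile(draws, [0.025, 0.975], axis=0).T
        self.acceptance_rate_ = accepted_post / max(chain.n_retained * chain.thin, 1)
        self.rhat_ = _split_rhat(draws)
        self.n_features_in_ = T
        if np.any(self.rhat_ > 1.05):
            warnings.warn(
                f"split-chain R̂ up to {self.rhat_.max():.3f} > 1.05: chain may "
                "not have converged; consider longer burn-in",
                stacklevel=2,
            )
        return self

    def posterior_(self, environment: str | None = None) -> PosteriorFractions:
        """Package the fitted posterior as a :class:`PosteriorFractions`."""
        if not hasattr(self, "draws_"):
            raise AttributeError("model is not fitted yet; call fit first")
        return PosteriorFractions(
            draws=self.draws_,
            source_names=self.source_names_,
            mean=self.mean_,
            sd=self.sd_,
            ci95=self.ci95_,
            residual_sd_draws=self.residual_sd_draws_,
            environment=environment,
            rhat=self.rhat_,
        )


def _split_rhat(draws: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction factor, per column."""
    n = draws.shape[0] // 2
    if n < 2:
        return np.ones(draws.shape[1])
    halves = np.stack([draws[:n], draws[n : 2 * n]])  # (2, n, S)
    w = halves.var(axis=1, ddof=1).mean(axis=0)
    b = n * halves.mean(axis=1).var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt((w * (n - 1) / n + b / n) / w)
    return np.where(np.isfinite(rhat), rhat, 1.0)


# ---------------------------------------------------------------------------
# functional surface


def _tracer_order(sources: list[SourceProfile], tracers=None) -> list[str]:
    common = set(sources[0].mean_delta)
    for s in sources[1:]:
        if set(s.mean_delta) != common:
            raise ValueError(
                f"source {s.name!r} tracers {sorted(s.mean_delta)} differ from "
                f"{sorted(common)}"
            )
    if tracers is None:
        return sorted(common)
    missing = set(tracers) - common
    if missing:
        raise ValueError(f"tracers {sorted(missing)} absent from source profiles")
    return list(tracers)


def fit_mixing_model(
    mixture: MixtureObservations,
    sources: list[SourceProfile],
    prior: MixingPrior | None = None,
    chain: ChainConfig | None = None,
    tracers: list[str] | None = None,
) -> PosteriorFractions:
    """Fit the mixing model to one environment's replicates.

    ``tracers`` restricts the fit to a subset of tracers (e.g. acetic acid
    alone, the configuration used for apportioning tropospheric acetic
    acid); by default every tracer present in the source profiles is used,
    with tracers missing from the mixture ignored.
    """
    if len(sources) < 2:
        raise ValueError("need at least 2 sources")
    prior = prior or MixingPrior()
    chain = chain or ChainConfig()
    order = _tracer_order(sources, tracers)
    extra = set(mixture.replicates) - set(order)
    if tracers is None and extra - set(sources[0].mean_delta):
        raise ValueError(
            f"mixture tracers {sorted(extra)} not defined by the source profiles"
        )
    use = [t for t in order if t in mixture.replicates]
    if not use:
        raise ValueError(
            f"environment {mixture.environment!r} has no data for tracers {order}"
        )
    n_max = max(mixture.replicates[t].size for t in use)
    X = np.full((n_max, len(use)), np.nan)
    for j, t in enumerate(use):
        vals = mixture.replicates[t]
        X[: vals.size, j] = vals
    mu = np.array([[s.mean_delta[t] for t in use] for s in sources])
    sig = np.array([[s.sd_delta[t] for t in use] for s in sources])
    alphas = prior.dirichlet_alphas
    model = IsotopeMixingModel(
        source_means=mu,
        source_sds=sig,
        source_names=[s.name for s in sources],
        dirichlet_alpha=1.0 if alphas is None else alphas,
        residual_sd_bound=prior.residual_sd_bounds[1],
        n_retained=chain.n_retained,
        n_burnin=chain.n_burnin,
        thin=chain.thin,
        random_state=chain.seed,
    ).fit(X)
    return model.posterior_(environment=mixture.environment)


def analytic_fractions_when_determined(
    mixture_means,
    sources: list[SourceProfile] | np.ndarray,
    tracers: list[str] | None = None,
    tol: float = 1e-9,
) -> AnalyticFractions:
    """Exact fractions for the determined case (n_sources = n_tracers + 1).

    Solves the square linear system of one mass-balance row per tracer plus
    the sum-to-one row.  The solution may leave the simplex; it is then
    flagged infeasible rather than clipped — negative fractions signal that
    the source set cannot explain the mixture (a missing source).
    """
    if isinstance(sources, (list, tuple)) and sources and isinstance(
        sources[0], SourceProfile
    ):
        order = _tracer_order(list(sources), tracers)
        mu = np.array([[s.mean_delta[t] for t in order] for s in sources])
        names = tuple(s.name for s in sources)
    else:
        mu = np.asarray(sources, dtype=float)
        if mu.ndim == 1:
            mu = mu[:, None]
        names = tuple(f"S{i + 1}" for i in range(mu.shape[0]))
    m = np.atleast_1d(np.asarray(mixture_means, dtype=float))
    S, T = mu.shape
    if S != T + 1:
        raise ValueError(
            f"determined case needs n_sources = n_tracers + 1, got {S} sources "
            f"and {T} tracers"
        )
    if m.size != T:
        raise ValueError(f"expected {T} mixture mean(s), got {m.size}")
    A = np.vstack([mu.T, np.ones(S)])
    b = np.concatenate([m, [1.0]])
    if np.linalg.matrix_rank(A) < S:
        # identify a collinear pair for the error message
        culprit = ""
        for i in range(S):
            for j in range(i + 1, S):
                if np.allclose(mu[i], mu[j]):
                    culprit = f" (sources {names[i]!r} and {names[j]!r} coincide)"
        raise np.linalg.LinAlgError(
            f"singular mixing system: source signatures are collinear{culprit}"
        )
    F = np.linalg.solve(A, b)
    feasible = bool(np.all(F >= -tol) and abs(F.sum() - 1.0) <= max(tol, 1e-9))
    return AnalyticFractions(fractions=F, source_names=names, feasible=feasible)


def summarize_posterior(post: PosteriorFractions) -> pd.DataFrame:
    """Per-source mean, SD and equal-tailed 95% CI as a tidy DataFrame."""
    draws = post.draws
    n = draws.shape[0]
    sd = draws.std(axis=0, ddof=1) if n > 1 else np.zeros(draws.shape[1])
    lo, hi = np.quantile(draws, [0.025, 0.975], axis=0)
    return pd.DataFrame(
        {
            "environment": post.environment,
            "source": list(post.source_names),
            "mean": draws.mean(axis=0),
            "sd": sd,
            "ci_lo": lo,
            "ci_hi": hi,
        }
    )


def propagate_across_replicates(
    posteriors: list[PosteriorFractions],
    seed: int = DEFAULT_SEED,
    n_resample: int = 10_000,
) -> PooledFractions:
    """Pool per-environment posteriors into study-level mean fractions.

    The overall mean is the mean of per-environment posterior means; its
    uncertainty is propagated by Monte Carlo — each resample draws one
    posterior draw per environment and averages them, and the SD/CI of
    those resampled grand means is reported.  Deterministic under ``seed``.
    """
    if not posteriors:
        raise ValueError("need at least one posterior")
    names = posteriors[0].source_names
    for p in posteriors[1:]:
        if p.source_names != names:
            raise ValueError(
                f"source sets differ: {p.source_names} vs {names}"
            )
    rng = np.random.default_rng(seed)
    grand = np.zeros((n_resample, len(names)))
    for p in posteriors:
        idx = rng.integers(0, p.draws.shape[0], size=n_resample)
        grand += p.draws[idx]
    grand /= len(posteriors)
    lo, hi = np.quantile(grand, [0.025, 0.975], axis=0)
    return PooledFractions(
        mean=np.mean([p.mean for p in posteriors], axis=0),
        sd=grand.std(axis=0, ddof=1),
        ci95=np.stack([lo, hi], axis=1),
        source_names=names,
        n_environments=len(posteriors),
    )
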