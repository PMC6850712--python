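"""Gibbs samplers for the hierarchical and pooled multivariate-normal models.

Two models share one sampler core:

* **structured** (random-intercept): ``Y_i | group k ~ MVN(mu_k, Sigma)`` with
  ``mu_{j,k} ~ N(0, eps)`` independently over variables ``j`` and groups
  ``k``. The shared within-group covariance ``Sigma`` is the object of
  interest — its 95% confidence ellipsoid is the model-based hypervolume.
* **empirical** (structure ignored): the same model with a single group, so
  ``Sigma`` absorbs any between-group spread.

The precision ``Omega = Sigma^{-1}`` carries a Wishart prior with density
proportional to ``|Omega|^{(nu0 - J - 1)/2} exp(-tr(R0 Omega)/2)`` where
``R0`` is the pooled raw-data covariance and ``nu0 = J + 1`` — a weakly
informative prior centred so that, absent group structure, the posterior
covariance converges on the raw-data covariance. Both full conditionals are
conjugate, so the sampler is a two-block Gibbs scheme with no tuning:

* ``mu_k | Omega, Y ~ MVN(P_k^{-1} Omega s_k, P_k^{-1})`` with
  ``P_k = n_k Omega + eps^{-1} I`` and ``s_k`` the within-group sum;
* ``Omega | mu, Y ~ Wishart(nu0 + N, (R0 + S)^{-1})`` with ``S`` the
  within-group scatter about the current group means.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
import pandas as pd

from .data import CenteringTransform, GroupedObservations, raw_covariance
from .errors import (
    ConfigurationError,
    ConvergenceWarning,
    DiagnosticError,
    NumericalError,
)

__all__ = [
    "FitConfig",
    "PosteriorDraw",
    "PosteriorEnsemble",
    "fit_structured",
    "fit_empirical",
    "pooled_mean",
    "gelman_rubin",
    "check_convergence",
    "posterior_summary",
    "PosteriorSummary",
]

RHAT_THRESHOLD = 1.1


@dataclass(frozen=True)
class FitConfig:
    """MCMC settings.

    Defaults follow common practice for this model family: 100,000
    iterations with the first 50,000 discarded, three chains, thinning by
    10. ``epsilon`` is the *fixed* prior variance of the group-level mean
    intercepts (10,000 — weakly informative on centered data); it is a
    constant of the model, not an estimated hyperparameter.
    """

    n_iterations: int = 100_000
    n_burnin: int = 50_000
    n_chains: int = 3
    thin: int = 10
    epsilon: float = 10_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations <= 0 or self.n_chains <= 0 or self.thin <= 0:
            raise ConfigurationError("iterations, chains and thin must be positive")
        if self.n_burnin < 0 or self.n_burnin >= self.n_iterations:
            raise ConfigurationError("need 0 <= n_burnin < n_iterations")
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be positive")
        if self.n_retained < 100:
            raise ConfigurationError(
                f"(n_iterations - n_burnin)/thin = {self.n_retained} retained "
                "draws per chain; need at least 100"
            )

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.n_burnin) // self.thin


@dataclass(frozen=True)
class PosteriorDraw:
    """One retained state: group means ``(K, J)`` and covariance ``(J, J)``."""

    group_means: np.ndarray
    covariance: np.ndarray


@dataclass
class PosteriorEnsemble:
    """Retained MCMC draws with chain structure preserved.

    Attributes
    ----------
    group_means
        Array ``(n_chains, n_draws, K, J)``. For the empirical model K = 1.
    covariances
        Array ``(n_chains, n_draws, J, J)``; every draw is SPD.
    """

    group_means: np.ndarray
    covariances: np.ndarray
    model_kind: Literal["structured", "empirical"]
    config: FitConfig
    variable_names: tuple[str, ...]
    group_names: tuple[str, ...]
    centering: CenteringTransform | None = None

    @property
    def n_chains(self) -> int:
        return self.group_means.shape[0]

    @property
    def n_draws(self) -> int:
        return self.group_means.shape[1]

    @property
    def n_groups(self) -> int:
        return self.group_means.shape[2]

    @property
    def n_vars(self) -> int:
        return self.group_means.shape[3]

    def stacked_means(self) -> np.ndarray:
        """Group means with chains flattened: ``(n_chains*n_draws, K, J)``."""
        return self.group_means.reshape(-1, self.n_groups, self.n_vars)

    def stacked_covariances(self) -> np.ndarray:
        """Covariances with chains flattened: ``(n_chains*n_draws, J, J)``."""
        return self.covariances.reshape(-1, self.n_vars, self.n_vars)

    def iter_draws(self) -> Iterator[PosteriorDraw]:
        for mu, cov in zip(self.stacked_means(), self.stacked_covariances()):
            yield PosteriorDraw(group_means=mu, covariance=cov)

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize to a compressed ``.npz`` archive."""
        meta = {
            "model_kind": self.model_kind,
            "config": asdict(self.config),
            "variable_names": list(self.variable_names),
            "group_names": list(self.group_names),
            "centering": None if self.centering is None else json.loads(
                self.centering.to_json()
            ),
        }
        np.savez_compressed(
            path,
            group_means=self.group_means,
            covariances=self.covariances,
            meta=np.array(json.dumps(meta)),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorEnsemble":
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["meta"]))
            centering = meta["centering"]
            return cls(
                group_means=archive["group_means"],
                covariances=archive["covariances"],
                model_kind=meta["model_kind"],
                config=FitConfig(**meta["config"]),
                variable_names=tuple(meta["variable_names"]),
                group_names=tuple(meta["group_names"]),
                centering=None
                if centering is None
                else CenteringTransform(
                    np.asarray(centering["offsets"]),
                    np.asarray(centering["scales"]),
                ),
            )


# ---------------------------------------------------------------------------
# Sampler core
# ---------------------------------------------------------------------------


def _draw_wishart(
    rng: np.random.Generator, df: float, rate: np.ndarray
) -> np.ndarray:
    """Batched Wishart draws with *rate* parameterization.

    Returns ``W ~ Wishart(df, rate^{-1})`` for each ``(J, J)`` slice of
    ``rate`` (shape ``(..., J, J)``), via the Bartlett decomposition:
    ``W = L A A^T L^T`` with ``L = chol(rate^{-1})``, ``A`` lower triangular,
    ``A_ii^2 ~ chi2(df - i)`` and subdiagonal entries standard normal. The
    mean is ``df * rate^{-1}``.
    """
    j = rate.shape[-1]
    scale = np.linalg.inv(rate)
    scale = (scale + np.swapaxes(scale, -1, -2)) / 2.0
    chol = np.linalg.cholesky(scale)
    batch = rate.shape[:-2]
    a = np.zeros((*batch, j, j))
    diag_df = df - np.arange(j)
    chi = rng.chisquare(diag_df, size=(*batch, j))
    idx = np.arange(j)
    a[..., idx, idx] = np.sqrt(chi)
    rows, cols = np.tril_indices(j, k=-1)
    if rows.size:
        a[..., rows, cols] = rng.standard_normal((*batch, rows.size))
    la = chol @ a
    return la @ np.swapaxes(la, -1, -2)


def _draw_group_means(
    rng: np.random.Generator,
    omega: np.ndarray,
    group_sums: np.ndarray,
    group_sizes: np.ndarray,
    eps_inv: float,
) -> np.ndarray:
    """Draw ``mu_k | Omega, Y`` for all groups and batch elements.

    ``omega``: ``(B, J, J)``; ``group_sums``: ``(B, K, J)``. Returns
    ``(B, K, J)``. Conditional precision ``P_k = n_k Omega + eps^{-1} I``,
    conditional mean ``P_k^{-1} Omega s_k``.
    """
    j = omega.shape[-1]
    eye = np.eye(j)
    prec = group_sizes[:, None, None] * omega[:, None, :, :] + eps_inv * eye
    cov = np.linalg.inv(prec)
    cov = (cov + np.swapaxes(cov, -1, -2)) / 2.0
    mean = np.einsum("bkij,bjl,bkl->bki", cov, omega, group_sums)
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal(mean.shape)
    return mean + np.einsum("bkij,bkj->bki", chol, z)


def _gibbs(
    values: np.ndarray,
    codes: np.ndarray,
    n_groups: int,
    rate0: np.ndarray,
    config: FitConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the two-block Gibbs sampler on a batch of datasets/chains.

    ``values`` has shape ``(B, N, J)`` (independent chains may simply repeat
    the same data), ``rate0`` shape ``(B, J, J)`` — the Wishart prior rate
    (the pooled raw covariance). Returns retained ``(mu, Sigma)`` draws of
    shapes ``(B, D, K, J)`` and ``(B, D, J, J)``.
    """
    n_b, n_obs, j = values.shape
    eps_inv = 1.0 / config.epsilon
    df_post = (j + 1) + n_obs  # nu0 + N

    group_sizes = np.bincount(codes, minlength=n_groups).astype(float)
    group_sums = np.zeros((n_b, n_groups, j))
    np.add.at(group_sums, (slice(None), codes), values)

    # Initialize the precision at the inverse prior rate (= Sigma_R^{-1}),
    # ridge-stabilized; starts the chain in the posterior's bulk.
    ridge = 1e-8 * np.trace(rate0, axis1=-2, axis2=-1)[:, None, None] / j
    omega = np.linalg.inv(rate0 + ridge * np.eye(j))
    omega = (omega + np.swapaxes(omega, -1, -2)) / 2.0

    n_ret = config.n_retained
    mu_out = np.empty((n_b, n_ret, n_groups, j))
    om_out = np.empty((n_b, n_ret, j, j))

    kept = 0
    for it in range(config.n_iterations):
        mu = _draw_group_means(rng, omega, group_sums, group_sizes, eps_inv)
        resid = values - mu[:, codes, :]
        scatter = np.einsum("bni,bnj->bij", resid, resid)
        omega = _draw_wishart(rng, df_post, rate0 + scatter)
        if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
            if kept < n_ret:
                mu_out[:, kept] = mu
                om_out[:, kept] = omega
                kept += 1

    sigma_out = np.linalg.inv(om_out)
    sigma_out = (sigma_out + np.swapaxes(sigma_out, -1, -2)) / 2.0
    return mu_out[:, :kept], sigma_out[:, :kept]


def _check_finite(mu: np.ndarray, sigma: np.ndarray) -> None:
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(sigma))):
        bad = np.argwhere(~np.isfinite(sigma).all(axis=(-1, -2)))
        chain, draw = (int(bad[0][0]), int(bad[0][1])) if bad.size else (0, 0)
        raise NumericalError(
            f"non-finite draw encountered (chain {chain}, retained draw {draw})"
        )


def _warn_if_uncentered(data: GroupedObservations) -> None:
    means = np.abs(data.values.mean(axis=0))
    sds = data.values.std(axis=0, ddof=1)
    if np.any(means > 1e-6 * np.maximum(sds, np.finfo(float).tiny)):
        warnings.warn(
            "data do not appear centered; centering improves convergence "
            "(see mbhv.data.center)",
            UserWarning,
            stacklevel=3,
        )


def _fit(
    data: GroupedObservations,
    config: FitConfig,
    model_kind: Literal["structured", "empirical"],
    rate_matrix: np.ndarray | None,
    centering: CenteringTransform | None,
) -> PosteriorEnsemble:
    _warn_if_uncentered(data)
    rate0 = raw_covariance(data) if rate_matrix is None else np.asarray(rate_matrix)
    if model_kind == "structured":
        codes, n_groups = data.groups, data.n_groups
        group_names = data.group_names
    else:
        codes = np.zeros(data.n_obs, dtype=np.intp)
        n_groups, group_names = 1, ("pooled",)

    rng = np.random.default_rng(config.seed)
    batch_values = np.broadcast_to(
        data.values, (config.n_chains, *data.values.shape)
    ).copy()
    batch_rate = np.broadcast_to(
        rate0, (config.n_chains, *rate0.shape)
    ).copy()
    mu, sigma = _gibbs(batch_values, codes, n_groups, batch_rate, config, rng)
    _check_finite(mu, sigma)
    return PosteriorEnsemble(
        group_means=mu,
        covariances=sigma,
        model_kind=model_kind,
        config=config,
        variable_names=data.variable_names,
        group_names=group_names,
        centering=centering,
    )


def fit_structured(
    data: GroupedObservations,
    config: FitConfig = FitConfig(),
    rate_matrix: np.ndarray | None = None,
    centering: CenteringTransform | None = None,
) -> PosteriorEnsemble:
    """Fit the random-intercept model; ``Sigma`` is the within-group covariance.

    Parameters
    ----------
    rate_matrix
        Override for the Wishart prior rate ``R0`` (default: the pooled
        raw-data covariance). Exposed mainly for prior-sensitivity checks.
    centering
        Optional transform recorded in the ensemble so downstream inclusion
        tests can map new observations into the fitted coordinates.
    """
    return _fit(data, config, "structured", rate_matrix, centering)


def fit_empirical(
    data: GroupedObservations,
    config: FitConfig = FitConfig(),
    rate_matrix: np.ndarray | None = None,
    centering: CenteringTransform | None = None,
) -> PosteriorEnsemble:
    """Fit the structure-blind model (a single pooled group)."""
    return _fit(data, config, "empirical", rate_matrix, centering)


# ---------------------------------------------------------------------------
# Posterior functionals and diagnostics
# ---------------------------------------------------------------------------


def pooled_mean(ensemble: PosteriorEnsemble) -> np.ndarray:
    """Per-draw overall mean: the unweighted average of group means.

    Returns shape ``(n_chains, n_draws, J)``. For an empirical ensemble
    (K = 1) this is the identity.
    """
    return ensemble.group_means.mean(axis=2)


def _parameter_table(ensemble: PosteriorEnsemble) -> tuple[list[str], np.ndarray]:
    """Flatten an ensemble to named scalar traces ``(m_chains, n_draws, P)``.

    Parameters are every group mean ``mu[group,var]`` and every
    upper-triangular element of ``Sigma`` (diagonal included).
    """
    k, j = ensemble.n_groups, ensemble.n_vars
    names: list[str] = []
    cols: list[np.ndarray] = []
    for g in range(k):
        for v in range(j):
            names.append(f"mu[{ensemble.group_names[g]},{ensemble.variable_names[v]}]")
            cols.append(ensemble.group_means[:, :, g, v])
    for a in range(j):
        for b in range(a, j):
            names.append(
                f"Sigma[{ensemble.variable_names[a]},{ensemble.variable_names[b]}]"
            )
            cols.append(ensemble.covariances[:, :, a, b])
    return names, np.stack(cols, axis=-1)


def gelman_rubin(ensemble: PosteriorEnsemble) -> pd.Series:
    """Potential scale reduction factor R-hat per scalar parameter.

    Classic between/within formulation: with ``m`` chains of length ``n``,
    ``W`` the mean within-chain variance and ``B/n`` the variance of chain
    means, ``Rhat = sqrt(((n-1)/n W + B/n) / W)``. Values near 1 indicate
    the chains are sampling the same distribution.
    """
    if ensemble.n_chains < 2:
        raise DiagnosticError(
            "Gelman-Rubin requires at least 2 chains; refit with "
            "FitConfig(n_chains >= 2)"
        )
    names, traces = _parameter_table(ensemble)  # (m, n, P)
    n = traces.shape[1]
    w = traces.var(axis=1, ddof=1).mean(axis=0)
    b_over_n = traces.mean(axis=1).var(axis=0, ddof=1)
    w = np.maximum(w, np.finfo(float).tiny)
    var_plus = (n - 1) / n * w + b_over_n
    rhat = np.sqrt(var_plus / w)
    return pd.Series(rhat, index=names, name="rhat")


def check_convergence(
    ensemble: PosteriorEnsemble, threshold: float = RHAT_THRESHOLD
) -> pd.Series:
    """Return the parameters whose R-hat exceeds ``threshold`` (warning if any)."""
    rhat = gelman_rubin(ensemble)
    offenders = rhat[rhat > threshold]
    if len(offenders) > 0:
        worst = offenders.idxmax()
        warnings.warn(
            f"{len(offenders)} parameter(s) exceed R-hat {threshold:g} "
            f"(worst: {worst} = {offenders.max():.3f}); chains may not have "
            "converged — consider more iterations or longer burn-in",
            ConvergenceWarning,
            stacklevel=2,
        )
    return offenders


@dataclass(frozen=True)
class PosteriorSummary:
    """Per-parameter summary plus the posterior-mean hypervolume parameters."""

    table: pd.DataFrame
    mean_covariance: np.ndarray
    mean_center: np.ndarray


def posterior_summary(ensemble: PosteriorEnsemble) -> PosteriorSummary:
    """Mean, SD and central 95% interval per parameter.

    Also returns the posterior-mean covariance (an average of SPD matrices,
    hence itself SPD) and the pooled posterior-mean center.
    """
    names, traces = _parameter_table(ensemble)
    flat = traces.reshape(-1, traces.shape[-1])
    table = pd.DataFrame(
        {
            "parameter": names,
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1) if flat.shape[0] > 1 else 0.0,
            "q2.5": np.quantile(flat, 0.025, axis=0),
            "q97.5": np.quantile(flat, 0.975, axis=0),
        }
    )
    return PosteriorSummary(
        table=table,
        mean_covariance=ensemble.stacked_covariances().mean(axis=0),
        mean_center=pooled_mean(ensemble).reshape(-1, ensemble.n_vars).mean(axis=0),
    )
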