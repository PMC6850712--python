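"""Hypervolume geometry: ellipsoid volume, inclusion tests, overlap.

A hypervolume here is the level-``alpha`` confidence ellipsoid of a
multivariate normal ``(mu, Sigma)``: the set of points whose squared
Mahalanobis distance from ``mu`` is at most the ``alpha`` quantile ``c`` of a
chi-square with ``J`` degrees of freedom. Its semi-axes are ``sqrt(c *
lambda_i)`` for the eigenvalues ``lambda_i`` of ``Sigma`` and its volume is
the unit-ball volume times the product of the semi-axes.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import pi

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.special import gammaln

from .errors import GeometryError
from .inference import PosteriorEnsemble, pooled_mean

__all__ = [
    "Hypervolume",
    "InclusionResult",
    "OverlapResult",
    "ellipsoid_volume",
    "mahalanobis_sq",
    "inclusion_probability_analytic",
    "inclusion_probability_mc",
    "inclusion_probability_posterior",
    "sample_hypervolume",
    "overlap",
    "hypervolume_from_ensemble",
    "posterior_mean_volume",
]


def _unit_ball_volume(j: int) -> float:
    """Volume of the unit ball in ``j`` dimensions: pi^{j/2} / Gamma(j/2 + 1)."""
    return float(np.exp(j / 2 * np.log(pi) - gammaln(j / 2 + 1)))


@dataclass(frozen=True)
class Hypervolume:
    """A confidence ellipsoid: center ``mu``, SPD covariance ``Sigma``, level."""

    center: np.ndarray
    covariance: np.ndarray
    level: float = 0.95

    def __post_init__(self) -> None:
        center = np.atleast_1d(np.asarray(self.center, dtype=float))
        cov = np.atleast_2d(np.asarray(self.covariance, dtype=float))
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "covariance", (cov + cov.T) / 2.0)
        if not 0.0 < self.level < 1.0:
            raise GeometryError(f"level must be in (0, 1), got {self.level}")
        if cov.shape != (center.size, center.size):
            raise GeometryError(
                f"covariance shape {cov.shape} incompatible with center of "
                f"length {center.size}"
            )
        try:
            np.linalg.cholesky(self.covariance)
        except np.linalg.LinAlgError as exc:
            raise GeometryError("covariance is not positive definite") from exc

    @property
    def n_dims(self) -> int:
        return self.center.size

    @property
    def chi2_quantile(self) -> float:
        """The squared Mahalanobis radius of the ellipsoid boundary."""
        return float(stats.chi2.ppf(self.level, df=self.n_dims))


def ellipsoid_volume(hv: Hypervolume) -> tuple[np.ndarray, float]:
    """Semi-axis lengths (descending) and volume of the confidence ellipsoid.

    With eigenvalues ``lambda_i`` of ``Sigma`` and ``c`` the level quantile
    of chi-square(J): semi-axis ``a_i = sqrt(c * lambda_i)`` and
    ``volume = U_J * prod(a_i) = U_J * c^{J/2} * sqrt(det Sigma)`` where
    ``U_J`` is the unit-ball volume.
    """
    eigs = np.linalg.eigvalsh(hv.covariance)
    if eigs[0] <= 0:
        raise GeometryError("covariance is not positive definite")
    c = hv.chi2_quantile
    semi_axes = np.sqrt(eigs[::-1] * c)
    volume = _unit_ball_volume(hv.n_dims) * float(np.prod(semi_axes))
    return semi_axes, volume


def mahalanobis_sq(hv: Hypervolume, point: np.ndarray) -> float:
    """Squared Mahalanobis distance ``(y - mu)^T Sigma^{-1} (y - mu)``."""
    point = np.atleast_1d(np.asarray(point, dtype=float))
    if point.shape != hv.center.shape:
        raise GeometryError(
            f"point of length {point.size} vs hypervolume in {hv.n_dims} dims"
        )
    diff = point - hv.center
    factor = cho_factor(hv.covariance, lower=True)
    return float(diff @ cho_solve(factor, diff))


def _mahalanobis_sq_many(hv: Hypervolume, points: np.ndarray) -> np.ndarray:
    diff = np.atleast_2d(points) - hv.center
    factor = cho_factor(hv.covariance, lower=True)
    return np.einsum("ni,ni->n", diff, cho_solve(factor, diff.T).T)


@dataclass(frozen=True)
class InclusionResult:
    """Outcome of a probability-of-inclusion test.

    ``q`` is the multivariate-normal density at the tested point; ``p`` is
    the fraction of the fitted distribution with density at most ``q`` (the
    mass "more extreme" than the point). The point is inside the hypervolume
    when ``p >= 1 - level``.
    """

    q: float
    p: float
    decision: str
    threshold: float
    p_per_draw: np.ndarray | None = None


def inclusion_probability_analytic(hv: Hypervolume, point: np.ndarray) -> float:
    """Closed-form inclusion probability ``1 - F_chi2_J(d^2)``.

    For a multivariate normal, ordering by density equals ordering by
    Mahalanobis distance, and ``d^2`` of a random draw is chi-square with
    ``J`` degrees of freedom — so the fraction of the distribution less dense
    than the point is the chi-square survival function at ``d^2``.
    """
    d2 = mahalanobis_sq(hv, point)
    return float(stats.chi2.sf(d2, df=hv.n_dims))


def inclusion_probability_mc(
    hv: Hypervolume, point: np.ndarray, n_sim: int = 10_000, seed: int = 0
) -> InclusionResult:
    """Monte-Carlo inclusion probability.

    Simulates ``n_sim`` draws from ``MVN(mu, Sigma)``, builds the empirical
    distribution of their densities, and reports the fraction with density
    at most that of the tested point (ties count as more extreme).
    """
    if n_sim < 1_000:
        raise GeometryError("n_sim must be at least 1,000 for a stable estimate")
    dist = stats.multivariate_normal(mean=hv.center, cov=hv.covariance)
    logq = float(dist.logpdf(np.atleast_1d(point)))
    rng = np.random.default_rng(seed)
    sims = rng.multivariate_normal(hv.center, hv.covariance, size=n_sim)
    p = float(np.mean(dist.logpdf(sims) <= logq))
    threshold = 1.0 - hv.level
    return InclusionResult(
        q=float(np.exp(logq)),
        p=p,
        decision="inside" if p >= threshold else "outside",
        threshold=threshold,
    )


def inclusion_probability_posterior(
    ensemble: PosteriorEnsemble,
    point: np.ndarray,
    n_sim: int | None = None,
    seed: int = 0,
    summary: str = "mean",
    level: float = 0.95,
) -> InclusionResult:
    """Inclusion probability propagated over posterior draws.

    For each retained draw, the hypervolume center is the pooled (average
    over groups) mean and the covariance is that draw's ``Sigma``; ``p`` is
    computed per draw (closed form by default, Monte-Carlo when ``n_sim`` is
    given) and summarized by the mean or median. ``q`` is reported at the
    posterior-mean parameters.
    """
    if ensemble.n_draws == 0:
        raise GeometryError("empty posterior ensemble")
    if summary not in ("mean", "median"):
        raise GeometryError(f"summary must be 'mean' or 'median', got {summary!r}")
    point = np.atleast_1d(np.asarray(point, dtype=float))
    if point.size != ensemble.n_vars:
        raise GeometryError(
            f"point of length {point.size} vs ensemble in {ensemble.n_vars} dims"
        )
    centers = pooled_mean(ensemble).reshape(-1, ensemble.n_vars)
    covs = ensemble.stacked_covariances()
    j = ensemble.n_vars

    if n_sim is None:
        diff = point - centers
        d2 = np.einsum(
            "ni,ni->n", diff, np.linalg.solve(covs, diff[..., None])[..., 0]
        )
        p_draws = stats.chi2.sf(d2, df=j)
    else:
        p_draws = np.array(
            [
                inclusion_probability_mc(
                    Hypervolume(c, s, level), point, n_sim=n_sim, seed=seed + i
                ).p
                for i, (c, s) in enumerate(zip(centers, covs))
            ]
        )

    p = float(np.mean(p_draws) if summary == "mean" else np.median(p_draws))
    mean_hv = Hypervolume(centers.mean(axis=0), covs.mean(axis=0), level)
    q = float(
        stats.multivariate_normal(mean_hv.center, mean_hv.covariance).pdf(point)
    )
    threshold = 1.0 - level
    return InclusionResult(
        q=q,
        p=p,
        decision="inside" if p >= threshold else "outside",
        threshold=threshold,
        p_per_draw=p_draws,
    )


def sample_hypervolume(
    hv: Hypervolume, n_points: int, seed: int = 0
) -> np.ndarray:
    """Sample points uniformly-from-the-model *inside* the hypervolume.

    Draws from ``MVN(mu, Sigma)`` and rejects points outside the level
    ellipsoid, so the result is the normal distribution truncated to the
    hypervolume; the expected acceptance rate equals the level.
    """
    if n_points < 1:
        raise GeometryError("n_points must be at least 1")
    rng = np.random.default_rng(seed)
    c = hv.chi2_quantile
    chol = np.linalg.cholesky(hv.covariance)
    out = np.empty((n_points, hv.n_dims))
    got = 0
    while got < n_points:
        chunk = max(int((n_points - got) / hv.level * 1.2), 1_000)
        z = rng.standard_normal((chunk, hv.n_dims))
        keep = np.einsum("ni,ni->n", z, z) <= c  # d^2 of mu + L z is |z|^2
        pts = hv.center + z[keep] @ chol.T
        take = min(pts.shape[0], n_points - got)
        out[got : got + take] = pts[:take]
        got += take
    return out


@dataclass(frozen=True)
class OverlapResult:
    """Symmetric overlap and directional containments of two hypervolumes."""

    overlap: float
    containment_a_in_b: float
    containment_b_in_a: float
    n_points: int
    mc_se: float


def overlap(
    hv_a: Hypervolume, hv_b: Hypervolume, n_points: int = 50_000, seed: int = 0
) -> OverlapResult:
    """Monte-Carlo overlap: shared points over total points simulated.

    ``n_points`` are simulated inside each hypervolume; a point of A is
    shared when it falls inside B's level ellipsoid (analytic Mahalanobis
    membership) and vice versa. The symmetric overlap is
    ``(count_a_in_b + count_b_in_a) / (2 * n_points)``; the directional
    containments are the two fractions separately. Both hypervolumes are
    sampled from the same seed, which makes the result symmetric in its
    arguments at matched seeds.
    """
    if hv_a.n_dims != hv_b.n_dims:
        raise GeometryError(
            f"dimension mismatch: {hv_a.n_dims} vs {hv_b.n_dims}"
        )
    pts_a = sample_hypervolume(hv_a, n_points, seed=seed)
    pts_b = sample_hypervolume(hv_b, n_points, seed=seed)
    a_in_b = int(np.sum(_mahalanobis_sq_many(hv_b, pts_a) <= hv_b.chi2_quantile))
    b_in_a = int(np.sum(_mahalanobis_sq_many(hv_a, pts_b) <= hv_a.chi2_quantile))
    ov = (a_in_b + b_in_a) / (2 * n_points)
    mc_se = float(np.sqrt(max(ov * (1 - ov), 0.0) / (2 * n_points)))
    return OverlapResult(
        overlap=ov,
        containment_a_in_b=a_in_b / n_points,
        containment_b_in_a=b_in_a / n_points,
        n_points=n_points,
        mc_se=mc_se,
    )


# ---------------------------------------------------------------------------
# Posterior-ensemble helpers
# ---------------------------------------------------------------------------


def hypervolume_from_ensemble(
    ensemble: PosteriorEnsemble, level: float = 0.95
) -> Hypervolume:
    """Point-estimate hypervolume: pooled posterior-mean center and mean Sigma."""
    centers = pooled_mean(ensemble).reshape(-1, ensemble.n_vars)
    return Hypervolume(
        center=centers.mean(axis=0),
        covariance=ensemble.stacked_covariances().mean(axis=0),
        level=level,
    )


def posterior_mean_volume(ensemble: PosteriorEnsemble, level: float = 0.95) -> float:
    """Posterior mean of the per-draw ellipsoid volume.

    The volume is a nonlinear functional of ``Sigma``, so averaging per-draw
    volumes (rather than taking the volume of the average ``Sigma``)
    propagates posterior uncertainty through the functional.
    """
    covs = ensemble.stacked_covariances()
    j = ensemble.n_vars
    sign, logdet = np.linalg.slogdet(covs)
    if np.any(sign <= 0):
        raise GeometryError("non-SPD covariance draw in ensemble")
    c = float(stats.chi2.ppf(level, df=j))
    return float(
        _unit_ball_volume(j) * c ** (j / 2) * np.mean(np.exp(0.5 * logdet))
    )
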