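"""Two-parameter Bayesian logistic dose-toxicity model (BLRM).

The probability of a dose-limiting toxicity at dose ``x`` is

    logit p(x) = beta0 + exp(beta1) * log(x / xr)

with ``xr`` a fixed reference dose; ``exp(beta1)`` guarantees a positive
slope, so toxicity is monotone in dose.  The prior is bivariate normal on
(beta0, beta1), by default centred so that the prior probability of toxicity
at ``xr`` is 0.1 and the prior median slope is 1.

The posterior is represented on a deterministic dense 2-D grid rather than
by MCMC: with two parameters, quadrature is exact up to grid resolution and
fully reproducible.  Monte Carlo draws (for the MTD functional) are obtained
by sampling grid cells proportionally to their probability mass with uniform
within-cell jitter.

The maximum tolerated dose (MTD) for a target toxicity probability tau is
``x* = xr * exp((logit(tau) - beta0) / exp(beta1))``; downstream summaries
work on the dispersion-limiting log-ratio scale ``x** = log(x*/xr)``, with
the posterior of ``x**`` truncated at its 10th/90th percentiles before
density estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_expit, logit
from scipy.stats import gaussian_kde

from .trial_io import TrialDataset, TrialValidationError

__all__ = [
    "PriorSpec",
    "GridSpec",
    "KdeSpec",
    "BlrmPosterior",
    "MtdPosterior",
    "GridSupportError",
    "log_likelihood",
    "likelihood_exponents",
    "posterior_grid",
    "sample_posterior",
    "mtd_transform",
    "mtd_posterior",
    "simulate_trial",
    "trapezoid_weights",
]


class GridSupportError(RuntimeError):
    """The likelihood has no mass on the requested grid; widen the bounds."""


def trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    """Quadrature weights w such that sum(w * f) = trapezoid integral of f."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("grid must be 1-D with at least two points")
    d = np.diff(grid)
    w = np.zeros_like(grid)
    w[:-1] += d / 2.0
    w[1:] += d / 2.0
    return w


@dataclass(frozen=True)
class PriorSpec:
    """Bivariate normal prior for (beta0, beta1).

    Defaults: mean (logit(0.1), log 1) — prior toxicity probability 0.1 at
    the reference dose, prior median slope 1 — with covariance diag(4, 4),
    a weakly informative choice.
    """

    mean: tuple[float, float] = (float(logit(0.1)), 0.0)
    covariance: tuple[tuple[float, float], tuple[float, float]] = ((4.0, 0.0), (0.0, 4.0))

    def __post_init__(self) -> None:
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
            raise ValueError("covariance must be a symmetric 2x2 matrix")
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ValueError("covariance must be positive definite")

    @property
    def cov(self) -> np.ndarray:
        return np.asarray(self.covariance, dtype=float)

    def log_density(self, beta0: np.ndarray, beta1: np.ndarray) -> np.ndarray:
        cov = self.cov
        prec = np.linalg.inv(cov)
        d0 = np.asarray(beta0, dtype=float) - self.mean[0]
        d1 = np.asarray(beta1, dtype=float) - self.mean[1]
        quad = prec[0, 0] * d0**2 + 2.0 * prec[0, 1] * d0 * d1 + prec[1, 1] * d1**2
        # normalising constant irrelevant for grid posteriors but kept exact
        _, logdet = np.linalg.slogdet(cov)
        return -0.5 * (quad + logdet + 2.0 * np.log(2.0 * np.pi))


@dataclass(frozen=True)
class GridSpec:
    """Resolution and (optional) bounds of the posterior grid.

    ``bounds`` is ((beta0_lo, beta0_hi), (beta1_lo, beta1_hi)); when None the
    grid spans prior mean +/- 6 prior standard deviations per axis, widened
    automatically until less than 1e-6 of the mass sits on the boundary.
    """

    n_points: int = 400
    bounds: tuple[tuple[float, float], tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.n_points < 100:
            raise ValueError("grid resolution must be at least 100 points per axis")


@dataclass(frozen=True)
class KdeSpec:
    """Gaussian KDE settings for the 1-D MTD posterior.

    ``bandwidth="silverman"`` is Silverman's rule of thumb
    0.9 * min(sd, IQR/1.34) * n^(-1/5) — the IQR robustification matters for
    the heavily right-skewed MTD posteriors of weakly informative trials.
    A float is taken as an absolute bandwidth.
    """

    bandwidth: str | float = "silverman"
    n_grid: int = 1024
    pad_bandwidths: float = 3.0

    def resolve(self, samples: np.ndarray) -> float:
        if isinstance(self.bandwidth, (int, float)):
            return float(self.bandwidth)
        if self.bandwidth != "silverman":
            raise ValueError(f"unknown bandwidth rule {self.bandwidth!r}")
        sd = float(np.std(samples, ddof=1))
        iqr = float(np.subtract(*np.percentile(samples, [75, 25])))
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        return 0.9 * spread * samples.size ** (-0.2)


@dataclass
class BlrmPosterior:
    """Joint posterior (or normalised weighted likelihood) of (beta0, beta1) on a grid."""

    grid_beta0: np.ndarray
    grid_beta1: np.ndarray
    density: np.ndarray  # shape (len(grid_beta0), len(grid_beta1))
    exponent: float
    prior_kind: str  # "flat-on-support" | "proper-bivariate-normal"
    reference_dose: float

    @property
    def weights(self) -> np.ndarray:
        """2-D trapezoid quadrature weights matching ``density``."""
        return np.outer(trapezoid_weights(self.grid_beta0), trapezoid_weights(self.grid_beta1))

    def integral(self) -> float:
        return float(np.sum(self.density * self.weights))

    def mean(self) -> tuple[float, float]:
        """Posterior mean of (beta0, beta1) by grid quadrature."""
        w = self.density * self.weights
        b0 = np.sum(w * self.grid_beta0[:, None])
        b1 = np.sum(w * self.grid_beta1[None, :])
        return float(b0), float(b1)

    def variance(self) -> tuple[float, float]:
        m0, m1 = self.mean()
        w = self.density * self.weights
        v0 = np.sum(w * (self.grid_beta0[:, None] - m0) ** 2)
        v1 = np.sum(w * (self.grid_beta1[None, :] - m1) ** 2)
        return float(v0), float(v1)


@dataclass
class MtdPosterior:
    """Truncated posterior of x** = log(MTD / reference dose).

    ``samples`` are the retained draws (inside the 10th-90th percentile band
    of the untruncated posterior), ``density`` is a renormalised Gaussian KDE
    over ``density_grid``, ``median`` the sample median of the retained draws
    and ``map`` the KDE argmax within the truncation bounds.
    """

    samples: np.ndarray
    density_grid: np.ndarray
    density: np.ndarray
    median: float
    map: float
    truncation_bounds: tuple[float, float]
    bandwidth: float
    degenerate: bool = False
    _kde: object | None = field(default=None, repr=False, compare=False)

    def evaluate(self, grid: np.ndarray) -> np.ndarray:
        """KDE density re-evaluated on an arbitrary grid (unnormalised tails)."""
        grid = np.asarray(grid, dtype=float)
        if self.degenerate or self._kde is None:
            # point mass: narrow Gaussian spike so downstream integrals stay finite
            h = max(self.bandwidth, 1e-8)
            return np.exp(-0.5 * ((grid - self.median) / h) ** 2) / (h * np.sqrt(2 * np.pi))
        return np.asarray(self._kde(grid))


def log_likelihood(
    trial: TrialDataset,
    beta0: float | np.ndarray,
    beta1: float | np.ndarray,
    xr: float,
) -> float | np.ndarray:
    """Binomial log-likelihood of (beta0, beta1); broadcasts over arrays.

    Uses log-sigmoid forms throughout, so the result is finite for any
    finite parameters (an empty trial contributes 0).
    """
    if not xr > 0:
        raise ValueError("reference dose xr must be positive")
    beta0 = np.asarray(beta0, dtype=float)
    beta1 = np.asarray(beta1, dtype=float)
    total = np.zeros(np.broadcast_shapes(beta0.shape, beta1.shape))
    slope = np.exp(beta1)
    for lv in trial.dose_levels:
        if lv.n_patients == 0:
            continue
        eta = beta0 + slope * np.log(lv.dose / xr)
        total = total + lv.n_dlt * log_expit(eta) + (lv.n_patients - lv.n_dlt) * log_expit(-eta)
    return total if total.shape else float(total)


def likelihood_exponents(n_c: int, n_a: int) -> tuple[float, float]:
    """Power-likelihood exponents (min(1, n_a/n_c), min(1, n_c/n_a)).

    The larger trial's likelihood is flattened so that both carry comparable
    precision; at least one exponent is exactly 1.
    """
    if n_c < 1 or n_a < 1:
        raise TrialValidationError("trial sample sizes must be positive integers")
    return min(1.0, n_a / n_c), min(1.0, n_c / n_a)


def _auto_bounds(
    trial: TrialDataset, exponent: float, prior: PriorSpec, xr: float
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Prior mean +/- 6 sd per axis, widened until boundary mass < 1e-6."""
    sd = np.sqrt(np.diag(prior.cov))
    lo = np.array(prior.mean) - 6.0 * sd
    hi = np.array(prior.mean) + 6.0 * sd
    for _ in range(6):
        g0 = np.linspace(lo[0], hi[0], 201)
        g1 = np.linspace(lo[1], hi[1], 201)
        logpost = exponent * log_likelihood(trial, g0[:, None], g1[None, :], xr)
        logpost = logpost + prior.log_density(g0[:, None], g1[None, :])
        dens = np.exp(logpost - logpost.max())
        w = np.outer(trapezoid_weights(g0), trapezoid_weights(g1))
        mass = dens * w
        total = mass.sum()
        edge = mass[0, :].sum() + mass[-1, :].sum() + mass[:, 0].sum() + mass[:, -1].sum()
        if edge < 1e-6 * total:
            break
        lo -= 1.5 * sd
        hi += 1.5 * sd
    return (float(lo[0]), float(hi[0])), (float(lo[1]), float(hi[1]))


def posterior_grid(
    trial: TrialDataset,
    exponent: float,
    prior: PriorSpec | None,
    xr: float,
    grid_spec: GridSpec = GridSpec(),
) -> BlrmPosterior:
    """Weighted posterior density of (beta0, beta1) on a dense grid.

    ``density ∝ L(beta|D)^exponent * prior(beta)``, normalised to integrate
    to 1 by the trapezoid rule.  ``prior=None`` means a flat prior on the
    grid support (the compact-support convention used for the raw
    likelihood-distance); then explicit ``grid_spec.bounds`` are required.
    """
    if not 0.0 < exponent <= 1.0:
        raise ValueError("likelihood exponent must be in (0, 1]")
    if prior is None:
        if grid_spec.bounds is None:
            raise ValueError("flat-on-support posterior requires explicit grid bounds")
        bounds = grid_spec.bounds
    else:
        bounds = grid_spec.bounds or _auto_bounds(trial, exponent, prior, xr)

    g0 = np.linspace(bounds[0][0], bounds[0][1], grid_spec.n_points)
    g1 = np.linspace(bounds[1][0], bounds[1][1], grid_spec.n_points)
    logpost = exponent * log_likelihood(trial, g0[:, None], g1[None, :], xr)
    if prior is not None:
        logpost = logpost + prior.log_density(g0[:, None], g1[None, :])
    peak = np.max(logpost)
    if not np.isfinite(peak):
        raise GridSupportError(
            "posterior has no finite mass on the grid; widen the grid bounds"
        )
    density = np.exp(logpost - peak)
    w = np.outer(trapezoid_weights(g0), trapezoid_weights(g1))
    norm = float(np.sum(density * w))
    if norm <= 0.0 or not np.isfinite(norm):
        raise GridSupportError(
            "all posterior mass lies outside the grid; widen the grid bounds"
        )
    density /= norm
    return BlrmPosterior(
        grid_beta0=g0,
        grid_beta1=g1,
        density=density,
        exponent=float(exponent),
        prior_kind="flat-on-support" if prior is None else "proper-bivariate-normal",
        reference_dose=float(xr),
    )


def sample_posterior(
    posterior: BlrmPosterior,
    n_samples: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> np.ndarray:
    """Draw (n_samples, 2) parameter vectors from a grid posterior.

    Grid nodes are sampled proportionally to their quadrature mass, then
    jittered uniformly within the node's cell; reproducible for a fixed seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mass = (posterior.density * posterior.weights).ravel()
    p = mass / mass.sum()
    cdf = np.cumsum(p)
    cdf[-1] = 1.0
    flat_idx = np.searchsorted(cdf, rng.random(n_samples), side="right")
    i, j = np.unravel_index(flat_idx, posterior.density.shape)
    step0 = posterior.grid_beta0[1] - posterior.grid_beta0[0]
    step1 = posterior.grid_beta1[1] - posterior.grid_beta1[0]
    b0 = posterior.grid_beta0[i] + (rng.random(n_samples) - 0.5) * step0
    b1 = posterior.grid_beta1[j] + (rng.random(n_samples) - 0.5) * step1
    return np.column_stack([b0, b1])


def mtd_transform(
    beta0: float | np.ndarray, beta1: float | np.ndarray, tau: float
) -> float | np.ndarray:
    """x** = log(MTD / xr) = (logit(tau) - beta0) / exp(beta1)."""
    if not 0.0 < tau < 1.0:
        raise ValueError("target toxicity tau must lie in (0, 1)")
    return (logit(tau) - np.asarray(beta0, dtype=float)) / np.exp(
        np.asarray(beta1, dtype=float)
    )


def mtd_posterior(
    param_samples: np.ndarray,
    tau: float,
    kde_spec: KdeSpec = KdeSpec(),
) -> MtdPosterior:
    """Truncated MTD posterior on the x** scale from joint parameter draws.

    Maps each draw through :func:`mtd_transform`, truncates at the empirical
    10th/90th percentiles (linear-interpolation quantiles), and fits a
    Gaussian KDE (Silverman bandwidth by default) to the retained 80%.
    """
    params = np.asarray(param_samples, dtype=float)
    if params.ndim != 2 or params.shape[1] != 2 or params.shape[0] < 1000:
        raise ValueError("need an (n, 2) array with n >= 1000 parameter draws")
    x = mtd_transform(params[:, 0], params[:, 1], tau)
    lo, hi = np.percentile(x, [10.0, 90.0])
    kept = x[(x >= lo) & (x <= hi)]
    median = float(np.median(kept))
    if np.ptp(kept) == 0.0:
        warnings.warn("degenerate MTD posterior: all retained draws identical")
        grid = np.array([median - 1e-6, median, median + 1e-6])
        dens = np.array([0.0, 1e6, 0.0])
        return MtdPosterior(
            samples=kept,
            density_grid=grid,
            density=dens,
            median=median,
            map=median,
            truncation_bounds=(float(lo), float(hi)),
            bandwidth=0.0,
            degenerate=True,
        )
    h = kde_spec.resolve(kept)
    kde = gaussian_kde(kept, bw_method=h / kept.std(ddof=1))
    pad = kde_spec.pad_bandwidths * h
    grid = np.linspace(lo - pad, hi + pad, kde_spec.n_grid)
    dens = np.asarray(kde(grid))
    dens /= np.trapezoid(dens, grid)
    inside = (grid >= lo) & (grid <= hi)
    map_ = float(grid[inside][np.argmax(dens[inside])])
    return MtdPosterior(
        samples=kept,
        density_grid=grid,
        density=dens,
        median=median,
        map=map_,
        truncation_bounds=(float(lo), float(hi)),
        bandwidth=h,
        _kde=kde,
    )


def simulate_trial(
    beta0: float,
    beta1: float,
    doses: list[float],
    n_per_dose: int | list[int],
    xr: float,
    rng: np.random.Generator | int,
    label: str = "simulated",
) -> TrialDataset:
    """Simulate per-dose DLT counts from the logistic dose-toxicity model."""
    from scipy.special import expit

    from .trial_io import DoseLevel

    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if isinstance(n_per_dose, int):
        n_per_dose = [n_per_dose] * len(doses)
    levels = []
    for dose, n in zip(doses, n_per_dose):
        p = expit(beta0 + np.exp(beta1) * np.log(dose / xr))
        levels.append(DoseLevel(dose, int(rng.binomial(n, p)), int(n)))
    return TrialDataset(label=label, dose_levels=tuple(levels))
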