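"""Commensurability indicators between two completed Phase I trials.

Five measures of how far apart two dose-toxicity analyses are:

``d``
    Hellinger distance between the two sample-size-weighted normalised
    likelihoods of (beta0, beta1), each restricted to a compact support
    (equivalently, posteriors under a flat prior on that support).
``dmod``
    The same distance after replacing the flat prior by a single proper
    bivariate normal prior shared by both trials; more stable numerically.
``dmtd``
    Hellinger distance between the two truncated posterior densities of
    x** = log(MTD/xr) — a one-dimensional summary of the curve comparison.
``dp1`` / ``dp2``
    Relative MTD point-estimate discrepancies exp(|Δ|) - 1 computed from the
    medians (dp1) and the KDE modes / maximum a posteriori (dp2) of the two
    truncated x** posteriors: "how many times larger is the bigger MTD".

d, dmod and dmtd live in [0, 1]; dp1 and dp2 are >= 0 and unbounded above.
The overall commensurability is gamma = d**q (default q = 1).

The likelihood of the larger trial is raised to the power min(1, n_other/n)
before normalisation, so the two curves are compared at matched precision.
Monte-Carlo seeds are derived from the comparison seed plus a fingerprint of
each trial's count table, which makes every indicator exactly invariant to
the order of the two arguments.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .blrm import (
    BlrmPosterior,
    GridSpec,
    KdeSpec,
    MtdPosterior,
    PriorSpec,
    _auto_bounds,
    likelihood_exponents,
    mtd_posterior,
    posterior_grid,
    sample_posterior,
    trapezoid_weights,
)
from .trial_io import TrialDataset

__all__ = [
    "ComparisonConfig",
    "CommensurabilityReport",
    "hellinger_distance",
    "distance_d",
    "distance_dmod",
    "distance_dmtd",
    "distance_dp1",
    "distance_dp2",
    "compare_trials",
]

DEFAULT_FLAT_SUPPORT: tuple[tuple[float, float], tuple[float, float]] = (
    (-10.0, 10.0),
    (-5.0, 5.0),
)


@dataclass(frozen=True)
class ComparisonConfig:
    """All knobs of one pairwise comparison.

    tau is the target toxicity probability defining the MTD;
    reference_dose is xr of the logistic model; flat_support is the compact
    support used for the raw likelihood distance d.
    """

    tau: float
    reference_dose: float
    prior: PriorSpec = PriorSpec()
    flat_support: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_FLAT_SUPPORT
    q: float = 1.0
    n_samples: int = 100_000
    seed: int = 20210209
    grid_spec: GridSpec = GridSpec()
    kde_spec: KdeSpec = KdeSpec()

    def __post_init__(self) -> None:
        if not 0.0 < self.tau < 1.0:
            raise ValueError("tau must be in (0, 1)")
        if not self.reference_dose > 0:
            raise ValueError("reference_dose must be positive")
        if not self.q > 0:
            raise ValueError("distance exponent q must be positive")


@dataclass(frozen=True)
class CommensurabilityReport:
    """The five indicators plus the settings that produced them."""

    d: float
    dmod: float
    dmtd: float
    dp1: float
    dp2: float
    gamma: float
    medians: tuple[float, float]  # x** scale, (first trial, second trial)
    maps: tuple[float, float]
    exponents: tuple[float, float]
    labels: tuple[str, str]
    config: ComparisonConfig
    mtd_posteriors: tuple[MtdPosterior, MtdPosterior] | None = field(
        default=None, repr=False, compare=False
    )

    def to_dict(self) -> dict:
        """JSON-serialisable full-precision record (config echoed)."""
        cfg = self.config
        return {
            "labels": list(self.labels),
            "indicators": {
                "d": self.d,
                "dmod": self.dmod,
                "dmtd": self.dmtd,
                "dp1": self.dp1,
                "dp2": self.dp2,
                "gamma": self.gamma,
            },
            "mtd_log_ratio": {
                "medians": list(self.medians),
                "maps": list(self.maps),
            },
            "exponents": list(self.exponents),
            "config": {
                "tau": cfg.tau,
                "reference_dose": cfg.reference_dose,
                "prior_mean": list(cfg.prior.mean),
                "prior_covariance": [list(r) for r in cfg.prior.covariance],
                "flat_support": [list(b) for b in cfg.flat_support],
                "q": cfg.q,
                "n_samples": cfg.n_samples,
                "seed": cfg.seed,
                "grid_points": cfg.grid_spec.n_points,
                "kde_grid": cfg.kde_spec.n_grid,
            },
        }

    def rounded_row(self) -> dict[str, float]:
        """Two-decimal presentation of the indicator row (display only)."""
        return {
            k: round(v, 2)
            for k, v in zip(
                ("d", "dmod", "dmtd", "dp1", "dp2"),
                (self.d, self.dmod, self.dmtd, self.dp1, self.dp2),
            )
        }


def hellinger_distance(
    density_p: np.ndarray, density_q: np.ndarray, integration_weights: np.ndarray
) -> float:
    """Hellinger distance sqrt(0.5 * integral (sqrt p - sqrt q)^2).

    Densities must share a support (same shape) and integrate to 1 under the
    given quadrature weights to within 1e-3.  Returns a value in [0, 1];
    symmetric, and 0 iff the densities coincide on the support.
    """
    p = np.asarray(density_p, dtype=float)
    q = np.asarray(density_q, dtype=float)
    w = np.asarray(integration_weights, dtype=float)
    if p.shape != q.shape or p.shape != w.shape:
        raise ValueError("densities and weights must share one shape")
    for name, dens in (("p", p), ("q", q)):
        total = float(np.sum(dens * w))
        if abs(total - 1.0) > 1e-3:
            raise ValueError(f"density {name} integrates to {total:.6f}, not 1")
    h2 = 0.5 * float(np.sum(w * (np.sqrt(p) - np.sqrt(q)) ** 2))
    return float(np.sqrt(np.clip(h2, 0.0, 1.0)))


def _grid_hellinger(post_p: BlrmPosterior, post_q: BlrmPosterior) -> float:
    if post_p.density.shape != post_q.density.shape or not (
        np.allclose(post_p.grid_beta0, post_q.grid_beta0)
        and np.allclose(post_p.grid_beta1, post_q.grid_beta1)
    ):
        raise ValueError("posteriors must be evaluated on a common grid")
    return hellinger_distance(post_p.density, post_q.density, post_p.weights)


def _flat_pair(
    trial_c: TrialDataset, trial_a: TrialDataset, config: ComparisonConfig
) -> tuple[BlrmPosterior, BlrmPosterior]:
    e_c, e_a = likelihood_exponents(trial_c.total_n, trial_a.total_n)
    spec = replace(config.grid_spec, bounds=config.flat_support)
    xr = config.reference_dose
    return (
        posterior_grid(trial_c, e_c, None, xr, spec),
        posterior_grid(trial_a, e_a, None, xr, spec),
    )


def _proper_pair(
    trial_c: TrialDataset, trial_a: TrialDataset, config: ComparisonConfig
) -> tuple[BlrmPosterior, BlrmPosterior]:
    e_c, e_a = likelihood_exponents(trial_c.total_n, trial_a.total_n)
    xr = config.reference_dose
    if config.grid_spec.bounds is None:
        bc = _auto_bounds(trial_c, e_c, config.prior, xr)
        ba = _auto_bounds(trial_a, e_a, config.prior, xr)
        bounds = tuple(
            (min(x[0], y[0]), max(x[1], y[1])) for x, y in zip(bc, ba)
        )
    else:
        bounds = config.grid_spec.bounds
    spec = replace(config.grid_spec, bounds=bounds)
    return (
        posterior_grid(trial_c, e_c, config.prior, xr, spec),
        posterior_grid(trial_a, e_a, config.prior, xr, spec),
    )


def distance_d(
    trial_c: TrialDataset, trial_a: TrialDataset, config: ComparisonConfig
) -> float:
    """Hellinger distance between weighted normalised likelihoods (flat support)."""
    return _grid_hellinger(*_flat_pair(trial_c, trial_a, config))


def distance_dmod(
    trial_c: TrialDataset, trial_a: TrialDataset, config: ComparisonConfig
) -> float:
    """Hellinger distance between proper-prior weighted posteriors."""
    return _grid_hellinger(*_proper_pair(trial_c, trial_a, config))


def _trial_fingerprint(trial: TrialDataset) -> int:
    """Deterministic 32-bit fingerprint of the count table (not the labels)."""
    canon = ";".join(
        f"{lv.dose:.12g}:{lv.n_dlt}:{lv.n_patients}" for lv in trial.dose_levels
    )
    return zlib.crc32(canon.encode()) & 0x7FFFFFFF


def _mtd_pair(
    trial_c: TrialDataset, trial_a: TrialDataset, config: ComparisonConfig
) -> tuple[MtdPosterior, MtdPosterior]:
    post_c, post_a = _proper_pair(trial_c, trial_a, config)
    out = []
    for trial, post in ((trial_c, post_c), (trial_a, post_a)):
        seed = np.random.SeedSequence([config.seed, _trial_fingerprint(trial)])
        draws = sample_posterior(post, config.n_samples, np.random.default_rng(seed))
        out.append(mtd_posterior(draws, config.tau, config.kde_spec))
    return out[0], out[1]


def _dmtd_from_mtd(mtd_c: MtdPosterior, mtd_a: MtdPosterior, n_grid: int = 2048) -> float:
    if mtd_c.degenerate or mtd_a.degenerate:
        raise ValueError("cannot compute a density distance from a degenerate MTD posterior")
    lo = min(mtd_c.density_grid[0], mtd_a.density_grid[0])
    hi = max(mtd_c.density_grid[-1], mtd_a.density_grid[-1])
    grid = np.linspace(lo, hi, n_grid)
    w = trapezoid_weights(grid)
    dens = []
    for m in (mtd_c, mtd_a):
        d = m.evaluate(grid)
        d = d / float(np.sum(d * w))
        dens.append(d)
    return hellinger_distance(dens[0], dens[1], w)


def distance_dmtd(
    trial_c: TrialDataset, trial_a: TrialDataset, config: ComparisonConfig
) -> float:
    """Hellinger distance between the two truncated x** posterior densities.

    Both KDEs are re-evaluated on the union of their supports and
    renormalised before the distance is taken, since the underlying integral
    runs over a single shared MTD axis.
    """
    return _dmtd_from_mtd(*_mtd_pair(trial_c, trial_a, config))


def distance_dp1(mtd_c: MtdPosterior, mtd_a: MtdPosterior) -> float:
    """Median-based relative MTD discrepancy exp(|med_c - med_a|) - 1."""
    return float(np.expm1(abs(mtd_c.median - mtd_a.median)))


def distance_dp2(mtd_c: MtdPosterior, mtd_a: MtdPosterior) -> float:
    """MAP-based relative MTD discrepancy exp(|map_c - map_a|) - 1."""
    return float(np.expm1(abs(mtd_c.map - mtd_a.map)))


def compare_trials(
    trial_c: TrialDataset,
    trial_a: TrialDataset,
    config: ComparisonConfig,
    keep_posteriors: bool = True,
) -> CommensurabilityReport:
    """Compute all five indicators (and gamma = d**q) for one pair of trials.

    Exponents, grids and Monte-Carlo draws are shared across the indicators;
    nothing is rounded internally — use :meth:`CommensurabilityReport.rounded_row`
    for two-decimal display.
    """
    e_c, e_a = likelihood_exponents(trial_c.total_n, trial_a.total_n)
    d = distance_d(trial_c, trial_a, config)
    dmod = distance_dmod(trial_c, trial_a, config)
    mtd_c, mtd_a = _mtd_pair(trial_c, trial_a, config)
    dmtd = _dmtd_from_mtd(mtd_c, mtd_a)
    dp1 = distance_dp1(mtd_c, mtd_a)
    dp2 = distance_dp2(mtd_c, mtd_a)
    return CommensurabilityReport(
        d=d,
        dmod=dmod,
        dmtd=dmtd,
        dp1=dp1,
        dp2=dp2,
        gamma=d**config.q,
        medians=(mtd_c.median, mtd_a.median),
        maps=(mtd_c.map, mtd_a.map),
        exponents=(e_c, e_a),
        labels=(trial_c.label, trial_a.label),
        config=config,
        mtd_posteriors=(mtd_c, mtd_a) if keep_posteriors else None,
    )
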