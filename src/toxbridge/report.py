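"""Run driver, tabular reporting and graphical displays.

Provides: per-case-study default settings (target toxicity tau and
reference dose xr), a three-zone similarity classification, overlay plots of
the two truncated MTD posteriors, the two-factor gradient display placing a
comparison on a (curve distance, MTD distance) canvas, and
:func:`reproduce_table3`, which recomputes the indicator table for all nine
bundled Caucasian/Japanese pairs and flags agreement with the published
values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from .blrm import GridSpec, KdeSpec, MtdPosterior, PriorSpec
from .commensurability import CommensurabilityReport, ComparisonConfig, compare_trials
from .trial_io import BUNDLED_PAIRS, TrialDataset, bundled_dataset, load_trial_csv

__all__ = [
    "CASE_SETTINGS",
    "PUBLISHED_INDICATORS",
    "RunConfig",
    "classify_zone",
    "plot_mtd_posteriors",
    "plot_gradient",
    "run_comparison",
    "reproduce_table3",
]

#: bundled pair -> (tau, reference dose) used in the original case studies.
#: tau = 0.3 for the synthetic calibration sets (model-based designs),
#: 0.25 for the literature case studies (algorithm-based allocation).
CASE_SETTINGS: dict[str, tuple[float, float]] = {
    "synthetic1": (0.3, 400.0),
    "synthetic2": (0.3, 400.0),
    "synthetic3": (0.3, 400.0),
    "erilubin": (0.25, 1.0),
    "lapatinib": (0.25, 900.0),
    "sorafenib": (0.25, 200.0),
    "ixabepilone": (0.25, 30.0),
    "edotecarin": (0.25, 8.0),
    "e7070": (0.25, 700.0),
}

#: Published indicator values (d, dmod, dmtd, dp1, dp2) for the nine bundled
#: pairs, used only to flag agreement in reproduce_table3 output — never as
#: a computation input.
PUBLISHED_INDICATORS: dict[str, tuple[float, float, float, float, float]] = {
    "synthetic1": (0.23, 0.18, 0.19, 0.00, 0.00),
    "synthetic2": (0.53, 0.37, 0.41, 0.02, 0.02),
    "synthetic3": (0.91, 0.83, 1.00, 1.50, 1.27),
    "erilubin": (0.92, 0.83, 0.91, 0.47, 0.43),
    "lapatinib": (0.58, 0.39, 0.50, 7.29, 0.35),
    "sorafenib": (0.45, 0.43, 0.57, 10.07, 0.75),
    "ixabepilone": (0.77, 0.56, 0.62, 0.34, 0.26),
    "edotecarin": (0.38, 0.24, 0.32, 0.32, 0.04),
    "e7070": (0.63, 0.63, 0.88, 0.59, 0.23),
}

ZONES = ("small", "moderate", "high")


def classify_zone(value: float, axis_max: float = 1.0) -> str:
    """Classify a distance into thirds of [0, axis_max]: small/moderate/high.

    Values above ``axis_max`` clamp to "high"; negative values are invalid.
    """
    if not axis_max > 0:
        raise ValueError("axis_max must be positive")
    if value < 0:
        raise ValueError("distances are non-negative")
    if value < axis_max / 3.0:
        return "small"
    if value < 2.0 * axis_max / 3.0:
        return "moderate"
    return "high"


def plot_mtd_posteriors(
    mtd_c: MtdPosterior,
    mtd_a: MtdPosterior,
    path: str | Path,
    labels: tuple[str, str] = ("Caucasian", "Japanese"),
    title: str = "",
) -> Path:
    """Overlay the two truncated x** posterior densities.

    Medians are marked with a circle (first trial) and a triangle (second);
    each maximum a posteriori is drawn as a dashed vertical line.
    """
    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 4))
    styles = (
        dict(color="tab:blue", marker="o", dash=(0, (5, 3))),
        dict(color="tab:orange", marker="^", dash=(0, (3, 2, 1, 2))),
    )
    for m, lab, st in zip((mtd_c, mtd_a), labels, styles):
        ax.plot(m.density_grid, m.density, color=st["color"], label=lab)
        med_y = float(np.interp(m.median, m.density_grid, m.density))
        ax.plot([m.median], [med_y], st["marker"], color=st["color"], ms=8)
        ax.axvline(m.map, color=st["color"], linestyle=st["dash"], alpha=0.8)
    ax.set_xlabel(r"$x^{**} = \log(\mathrm{MTD}/x_r)$")
    ax.set_ylabel("posterior density")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_gradient(
    dmod: float,
    dp2: float,
    path: str | Path,
    dp2_axis_max: float = 1.0,
    label: str = "",
) -> Path:
    """Place a comparison on the 3x3 (curve distance, MTD distance) canvas.

    The y axis is the curve distance dmod in [0, 1]; the x axis the MAP-based
    MTD discrepancy dp2, clamped at ``dp2_axis_max``.  Shading darkens with
    distance, and the (small curve distance, high MTD distance) cell is the
    darkest: similar curves cannot honestly produce very different MTDs, so
    that combination is flagged as incoherent.
    """
    if not 0.0 <= dmod <= 1.0 + 1e-9:
        raise ValueError("dmod must lie in [0, 1]")
    if dp2 < 0:
        raise ValueError("dp2 is non-negative")
    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 5))
    # shade[i][j]: row i = dmod zone (bottom->top), column j = dp2 zone
    shade = np.array(
        [
            [0.10, 0.55, 0.95],  # small curve distance; incoherent at high dp2
            [0.30, 0.50, 0.70],
            [0.45, 0.60, 0.80],
        ]
    )
    third_x = dp2_axis_max / 3.0
    for i in range(3):
        for j in range(3):
            ax.add_patch(
                plt.Rectangle(
                    (j * third_x, i / 3.0),
                    third_x,
                    1.0 / 3.0,
                    color=str(1.0 - shade[i, j]),
                    zorder=0,
                )
            )
    x = min(dp2, dp2_axis_max)
    ax.plot([x], [dmod], "o", color="tab:red", ms=9, zorder=3)
    if label:
        ax.annotate(label, (x, dmod), textcoords="offset points", xytext=(6, 6))
    ax.set_xlim(0, dp2_axis_max)
    ax.set_ylim(0, 1)
    ax.set_xticks([0, third_x, 2 * third_x, dp2_axis_max])
    ax.set_yticks([0, 1 / 3, 2 / 3, 1])
    ax.set_xlabel(r"MTD distance $d_{p2}$")
    ax.set_ylabel(r"curve distance $d_{mod}$")
    for k, zone in enumerate(ZONES):
        ax.text((k + 0.5) * third_x, 1.01, zone, ha="center", va="bottom", fontsize=8)
        ax.text(-0.02 * dp2_axis_max, (k + 0.5) / 3, zone, ha="right", va="center",
                rotation=90, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


@dataclass
class RunConfig:
    """One comparison run: input trials, model settings, outputs.

    Each trial is given either as a bundled pair name (then the Caucasian /
    Japanese member is taken for trial_c / trial_a respectively) or as a CSV
    path — exactly one source per trial.
    """

    trial_c: str
    trial_a: str
    tau: float
    reference_dose: float
    outdir: str | Path = "toxbridge_out"
    prior_mean: tuple[float, float] | None = None
    prior_covariance: tuple[tuple[float, float], tuple[float, float]] | None = None
    flat_support: tuple[tuple[float, float], tuple[float, float]] | None = None
    q: float = 1.0
    n_samples: int = 100_000
    seed: int = 20210209
    grid_points: int = 400
    kde_grid: int = 1024
    plots: bool = True
    dp2_axis_max: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        valid = set(cls.__dataclass_fields__)
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; valid keys: {sorted(valid)}"
            )
        return cls(**raw)

    def comparison_config(self) -> ComparisonConfig:
        prior_kwargs = {}
        if self.prior_mean is not None:
            prior_kwargs["mean"] = tuple(self.prior_mean)
        if self.prior_covariance is not None:
            prior_kwargs["covariance"] = tuple(
                tuple(row) for row in self.prior_covariance
            )
        cfg = ComparisonConfig(
            tau=self.tau,
            reference_dose=self.reference_dose,
            prior=PriorSpec(**prior_kwargs),
            q=self.q,
            n_samples=self.n_samples,
            seed=self.seed,
            grid_spec=GridSpec(n_points=self.grid_points),
            kde_spec=KdeSpec(n_grid=self.kde_grid),
        )
        if self.flat_support is not None:
            cfg = replace(
                cfg, flat_support=tuple(tuple(b) for b in self.flat_support)
            )
        return cfg


def _resolve_trial(source: str, which: int) -> TrialDataset:
    key = source.strip().lower().replace("-", "")
    if key in BUNDLED_PAIRS or key in ("edotecarinalt",):
        return bundled_dataset(source)[which]
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(
            f"{source!r} is neither a bundled dataset name "
            f"({', '.join(BUNDLED_PAIRS)}) nor an existing CSV file"
        )
    return load_trial_csv(path)


def run_comparison(config: RunConfig) -> CommensurabilityReport:
    """Run one comparison and write report.json, report.csv, run.log (+ plots).

    report.json holds the five indicators at full precision together with a
    complete config echo; report.csv is the two-decimal presentation row;
    run.log records exponents, grid bounds and retained sample counts.
    Outputs are deterministic for a fixed seed (byte-identical on re-run).
    """
    trial_c = _resolve_trial(config.trial_c, 0)
    trial_a = _resolve_trial(config.trial_a, 1)
    ccfg = config.comparison_config()
    report = compare_trials(trial_c, trial_a, ccfg, keep_posteriors=True)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    row = report.rounded_row()
    pd.DataFrame([{"trial_c": trial_c.label, "trial_a": trial_a.label, **row}]).to_csv(
        outdir / "report.csv", index=False
    )

    mtd_c, mtd_a = report.mtd_posteriors
    log_lines = [
        f"trial_c: {config.trial_c} (label={trial_c.label}, n={trial_c.total_n})",
        f"trial_a: {config.trial_a} (label={trial_a.label}, n={trial_a.total_n})",
        f"tau={ccfg.tau} reference_dose={ccfg.reference_dose} q={ccfg.q}",
        f"seed={ccfg.seed} n_samples={ccfg.n_samples} grid_points={ccfg.grid_spec.n_points}",
        f"prior mean={list(ccfg.prior.mean)} covariance={[list(r) for r in ccfg.prior.covariance]}",
        f"flat_support={[list(b) for b in ccfg.flat_support]}",
        f"exponents=({report.exponents[0]:.6f}, {report.exponents[1]:.6f})",
        f"retained_samples=({mtd_c.samples.size}, {mtd_a.samples.size})",
        f"truncation_bounds_c={mtd_c.truncation_bounds} truncation_bounds_a={mtd_a.truncation_bounds}",
        "indicators "
        + " ".join(f"{k}={v:.6f}" for k, v in zip("d dmod dmtd dp1 dp2".split(),
                                                  (report.d, report.dmod, report.dmtd,
                                                   report.dp1, report.dp2))),
    ]
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")

    if config.plots:
        plot_mtd_posteriors(
            mtd_c, mtd_a, outdir / "mtd_posteriors.png",
            labels=(trial_c.label or "trial C", trial_a.label or "trial A"),
        )
        plot_gradient(
            report.dmod, report.dp2, outdir / "gradient.png",
            dp2_axis_max=config.dp2_axis_max,
        )
    return report


#: agreement bands used when flagging reproduce_table3 output: absolute
#: tolerance 0.10 for the bounded distances and dp2; dp1 is flagged only on
#: the synthetic sets (0.15), being median-based and unstable under the
#: heavy-tailed posteriors of the literature case studies.
_TOL = {"d": 0.10, "dmod": 0.10, "dmtd": 0.10, "dp2": 0.10, "dp1": 0.15}
_SYNTHETIC = ("synthetic1", "synthetic2", "synthetic3")


def reproduce_table3(
    seed: int | None = None,
    n_samples: int = 100_000,
    grid_points: int = 400,
    prior: PriorSpec | None = None,
    names: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Recompute the indicator table for the nine bundled pairs.

    Returns one row per pair with the computed indicators, the published
    values (``*_ref`` columns) and boolean agreement flags.  ``prior``
    overrides the default bivariate normal prior (e.g. for sensitivity
    analyses); ``seed=None`` keeps each comparison's default seed.
    """
    rows = []
    for name in names or tuple(CASE_SETTINGS):
        tau, xr = CASE_SETTINGS[name]
        trial_c, trial_a = bundled_dataset(name)
        cfg = ComparisonConfig(
            tau=tau,
            reference_dose=xr,
            n_samples=n_samples,
            grid_spec=GridSpec(n_points=grid_points),
        )
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        if prior is not None:
            cfg = replace(cfg, prior=prior)
        rep = compare_trials(trial_c, trial_a, cfg, keep_posteriors=False)
        row: dict[str, object] = {"pair": name, "tau": tau, "xr": xr}
        computed = {"d": rep.d, "dmod": rep.dmod, "dmtd": rep.dmtd,
                    "dp1": rep.dp1, "dp2": rep.dp2}
        ref = PUBLISHED_INDICATORS[name]
        for (k, v), r in zip(computed.items(), ref):
            row[k] = v
            row[f"{k}_ref"] = r
            if k == "dp1" and name not in _SYNTHETIC:
                row[f"{k}_ok"] = None  # documented as unstable; not flagged
            else:
                row[f"{k}_ok"] = bool(abs(v - r) <= _TOL[k])
        rows.append(row)
    return pd.DataFrame(rows)
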