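"""Visualise the truncated MTD posteriors and the similarity gradient.

Runs the dissimilar synthetic calibration pair (different curve AND
different MTD), saves the overlaid MTD-posterior densities and the 3x3
gradient canvas, and prints where the comparison lands.
"""

from pathlib import Path

from toxbridge import (
    ComparisonConfig,
    bundled_dataset,
    classify_zone,
    compare_trials,
    plot_gradient,
    plot_mtd_posteriors,
)

outdir = Path("example_plots")
outdir.mkdir(exist_ok=True)

caucasian, japanese = bundled_dataset("synthetic3")
config = ComparisonConfig(tau=0.3, reference_dose=400.0)
report = compare_trials(caucasian, japanese, config)

mtd_c, mtd_a = report.mtd_posteriors
p1 = plot_mtd_posteriors(mtd_c, mtd_a, outdir / "synthetic3_mtd.png",
                         labels=("Caucasian", "Japanese"))
p2 = plot_gradient(report.dmod, report.dp2, outdir / "synthetic3_gradient.png")

print("indicators:", report.rounded_row())
print(f"curve distance dmod={report.dmod:.2f} -> {classify_zone(report.dmod)} zone")
print(f"MTD distance   dp2={report.dp2:.2f} -> {classify_zone(min(report.dp2, 1.0))} zone")
print(f"plots written: {p1}, {p2}")
print(
    "\nThe two posterior modes are visibly separated: these trials disagree"
    "\nboth on the shape of the dose-toxicity curve and on the MTD itself."
)
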