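"""Compare two trials supplied as plain CSV files.

Writes two small per-dose summary files (columns dose,n_dlt,n_patients),
loads them with full validation, and compares them.  This is the workflow
for your own data: one CSV per trial, one row per dose level.
"""

import tempfile
from pathlib import Path

from toxbridge import ComparisonConfig, compare_trials, load_trial_csv

workdir = Path(tempfile.mkdtemp())
(workdir / "region_a.csv").write_text(
    "dose,n_dlt,n_patients\n100,0,3\n200,0,6\n400,1,9\n600,3,6\n"
)
(workdir / "region_b.csv").write_text(
    "dose,n_dlt,n_patients\n200,0,3\n400,2,9\n600,3,5\n"
)

trial_a = load_trial_csv(workdir / "region_a.csv", label="region A")
trial_b = load_trial_csv(workdir / "region_b.csv", label="region B")

config = ComparisonConfig(tau=0.3, reference_dose=200.0)
report = compare_trials(trial_a, trial_b, config)

print(f"{trial_a.label} (n={trial_a.total_n}) vs {trial_b.label} (n={trial_b.total_n})")
print("indicators:", report.rounded_row())
print("MTD log-ratio medians (x** scale):",
      [round(m, 3) for m in report.medians])
print(
    "\nDistances in the lower third of [0, 1] put this pair in the 'small'"
    "\nsimilarity zone: once sample sizes are precision-matched, the two"
    "\nregions' dose-toxicity information overlaps substantially, and the MTD"
    "\npoint estimates differ by well under a factor of 1.5."
)
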