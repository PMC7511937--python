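"""Full weekly detection experiment on a cohort written to disk.

Mirrors the study design: features per (mouse, week), concatenation
from week 2 through each analysis week, embedding, clustering, scoring.
Writes report.json, a run log, and one embedding scatter per week.
"""

import tempfile
from pathlib import Path

from thermoliver import (
    EmbeddingConfig,
    ExperimentConfig,
    SyntheticCohortSpec,
    generate_cohort,
    make_figures,
    run_experiment,
)

root = Path(tempfile.mkdtemp(prefix="thermoliver_run_"))
generate_cohort(SyntheticCohortSpec(seed=7), root)

config = ExperimentConfig(
    manifest=str(root / "manifest.csv"),
    analysis_weeks=(2, 3, 4, 5),
    embedding=EmbeddingConfig(seed=7),
    out_dir=str(root / "out"),
    seed=7,
)
report = run_experiment(config)

for W in sorted(report.weeks):
    e = report.weeks[W]
    print(f"week {W}: {e['n_correct']}/{e['N']} mice correct "
          f"(rate {e['detection_rate']:.2f}, {e['dimension']}-dim input)")

files = make_figures(report, root / "figures")
print(f"report and {len(files)} figures under {root}")
# Rates of 1.0 from week 3 on reproduce the study's 100% detection claim
# on the synthetic analogue of its cohort.
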