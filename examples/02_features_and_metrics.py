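"""Windowing, Hudgins features and the pattern-quality metrics.

WD (lower = more consistent contractions), IDNN/IDAN (higher = more
separable movement patterns) summarise the normalized feature space the
regressor must work with. Increasing the generator's pattern overlap makes
movements less separable, which the metrics should report.
"""

import myogym
from myogym.metrics import labelled_features, metric_report, session_summary

movements = ["fine_pinch", "hand_open", "wrist_flexion"]

for overlap in (0.0, 0.5):
    params = myogym.GeneratorParams(seed=5, overlap=overlap)
    session = myogym.generate_session(params, movements, n_procedures=3)
    report = metric_report(session)
    means = session_summary(report)
    print(f"overlap={overlap}: WD={means['wd']:.2f} "
          f"IDNN={means['idnn']:.2f} IDAN={means['idan']:.2f}")

# per-movement feature clouds of one procedure
params = myogym.GeneratorParams(seed=5, overlap=0.0)
session = myogym.generate_session(params, movements, n_procedures=1)
groups = labelled_features(
    [r for r in session[0].recordings if 0 < r.level < 1.0]
)
for movement, X in groups.items():
    print(f"{movement}: {X.shape[0]} plateau windows x {X.shape[1]} features")
# higher overlap should have printed lower IDNN/IDAN above.
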