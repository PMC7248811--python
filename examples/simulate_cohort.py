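"""Generate a small synthetic threatened-preterm-labor cohort.

Builds 12 thirty-minute bipolar EHG recordings (4 imminent-labor, 8
non-imminent at the 7-day horizon) with obstetric covariates, and prints
the cohort manifest. Recording CSVs land under ./example_out/cohort/.
"""

from ehgkit import SyntheticCohortConfig, generate_cohort
from ehgkit.simulate import write_cohort

config = SyntheticCohortConfig(
    n_per_class=(4, 8),   # (TTD < 7 days, TTD >= 7 days)
    duration_s=1800.0,    # 30-min recordings
    class_effect=1.0,     # default class separation
    seed=42,
    horizon=7,
)
cohort = generate_cohort(config)
write_cohort(cohort, "example_out/cohort", write_signals=True)

print(cohort.manifest.round(2).to_string(index=False))
print()
rec = cohort.recordings[0]
print(f"first recording: {rec.n_samples} samples at {rec.fs} Hz "
      f"({rec.duration_s / 60:.0f} min), TTD {rec.metadata['ttd_days']:.1f} days")
# Rows are one recording each: time-to-delivery (days), the binary labels
# for both horizons, and the six obstetric covariates. The imminent class
# has a visibly shorter cervical length, as in the emulated cohort.
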