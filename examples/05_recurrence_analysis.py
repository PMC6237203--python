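"""Cox recurrence analysis of extracted biomarkers with clinical factors.

Runs the full pipeline, then reports the evaluation table: each screened
biomarker feature fit jointly with the clinical covariates, with hazard
ratios and the held-out C-index, plus a permuted-outcome control.
"""

from histofusion.pipeline import (RunConfig, permuted_control_cindex, run)
from histofusion.synthetic import SyntheticCohortConfig, generate_cohort

cohort = generate_cohort(SyntheticCohortConfig(n_patients=60, seed=1))
result = run(RunConfig(mode="cnn-lstm-ps", seed=1), cohort=cohort)

best = result.report.best
print(f"Gleason-7 patients in the survival model: {len(result.g7_ids)}")
print(f"biomarker features passing the Wald screen (p<0.05): "
      f"{len(result.report.selected)}")
print("\nbest row of the evaluation table (maximum biomarker HR):")
print(best.round(3).to_string())
print(f"\nheld-out C-index: {result.cindex:.3f} "
      "(0.5 = chance, 1.0 = perfect risk ranking)")
control = permuted_control_cindex(result, seed=1)
print(f"permuted-outcome control C-index: {control:.3f} "
      "(should sit near 0.5)")
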