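"""Run the complete study end to end on a reduced synthetic cohort.

Synthesis -> preprocessing -> EEA detection -> spectra and landmarks ->
source mapping -> mixed ANOVA + Duncan + Grubbs -> ROC. Deterministic
given the seed; stage tables can be written to a directory.
"""

import rsdelta as rd

config = rd.StudyConfig(
    cohort=rd.CohortConfig(n_per_group=(8, 10, 8), duration_s=60.0,
                           delta_effect_size=1.0, seed=42),
    epoch_span_s=60.0,
    grid_mm=8.0,
    use_ground_truth_groups=True,   # group patients by generator labels
)

report = rd.run_study(config, out_dir="scratch/example_study")
print(report.render_text())
# The EEA group's temporal delta activity sits above the noEEA group's;
# the ROC block reports how well that activity separates individual
# patients. At this reduced cohort size the Duncan contrast does not
# always clear the corrected 0.002 threshold -- the full study
# conditions (19 and 13 patients, longer recordings) do so in the
# majority of replicates.
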