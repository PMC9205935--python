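"""Perturbation robustness: re-extract features under 81 image variants
and filter them by the ICC(1,1) confidence-interval rule.

A feature survives when the lower bound of its 95% ICC confidence
interval (subjects as targets, perturbed variants as repeats) is at
least 0.8. For speed this example uses 6 subjects and a reduced
perturbation grid; the default grid has the full 81 variants.
"""

from radsig.phantom import OutcomeSpec, PhantomConfig, generate_cohort
from radsig.preprocess import preprocess_subject
from radsig.robustness import (enumerate_perturbations, icc_filter,
                               perturb_and_extract, stability_table)

config = PhantomConfig(grid_shape=(20, 20, 14), voxel_spacing_mm=(1, 1, 1),
                       gtv_radius_mm=4.0)
bundle = generate_cohort(config, OutcomeSpec(), n=6, seed=3)

full = enumerate_perturbations()
print(f"default perturbation grid: {len(full)} variants")
settings = enumerate_perturbations(translations_mm=(0.0, 0.75), base_seed=3)
print(f"this example runs {len(settings)} variants per subject")

tables = {}
for subj in bundle.subjects:
    pre = preprocess_subject(subj["mr"], subj["ct"], subj["mask_mr"],
                             subj["mask_ct"])
    tables[subj["subject_id"]] = perturb_and_extract(pre, settings)

results = icc_filter(tables)
report = stability_table(results)
kept = report[report["kept"]]
print(f"{len(kept)} / {len(report)} features stable "
      "(ICC 95% CI lower bound >= 0.8)")
print(report.nlargest(5, "icc")[["icc", "ci_low", "kept"]].round(3))
# Morphological features tolerate the +-15% volume changes best; noisy
# extrema (e.g. stat_max) and sparse-zone texture features drop out.
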