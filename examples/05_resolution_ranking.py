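"""Full experiment: which wavelet bases keep their AUC when resolution drops?

Runs the pipeline on a small synthetic dataset over the A/A2/A4 pyramid for
three wavelet bases, then derives the selection conditions: top performers
per resolution (Condition 1), the single best (Condition 2), and the
resolution-invariant ranking by SUM of AUC over the three resolutions
(Conditions 3-5, ordered by the priority resolution's AUC).
"""

import tempfile

import wavederm as wd

config = wd.ExperimentConfig(
    synthetic=wd.TextureSpec(
        image_height=64, image_width=64, n_pos=20, n_neg=20,
        effect_size=0.25, seed=17,
    ),
    wavelet_ids=(1, 26, 46),
    kernels=("gaussian",),
    n_folds=10,
    bo_budget=8,
    seed=5,
    output_dir=tempfile.mkdtemp(prefix="wavederm_demo_"),
    make_figures=False,
)
report = wd.run_experiment(config)

print("\nAUC grid (wavelet x resolution, gaussian kernel):")
print(report.auc_grid.to_frame().pivot(index="wavelet_id", columns="resolution",
                                       values="auc").round(3).to_string())
print("\nselection conditions:")
print(report.condition_tables.to_string(index=False))
print("\naverage AUC per resolution (mean over wavelet ids):")
print(report.average_auc.to_string(index=False))
print(f"\nall tables and the config were written to {report.output_dir}")
print("-> a base listed first under condition_3/4/5 classifies well at every")
print("   resolution: downscaled images could be used without losing accuracy.")
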