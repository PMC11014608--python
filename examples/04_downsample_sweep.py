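"""Read-downsampling sweep with the 5% sufficiency rule.

For each fraction the counts are binomially thinned, the pipeline is
rerun, and the run is compared with the full-size run.  The sufficiency
fraction per metric is the smallest fraction whose concordance with the
full run is at least as good (within 5%) as the cross-preset variability
at full size — i.e. how little data reproduces the full result no worse
than switching toolkits would.
"""

import warnings

import sccompare as sc

cfg = sc.SynthConfig(n_cells=240, n_genes=200, n_clusters=3,
                     de_effect=2.0, de_fraction=0.2, seed=1)
cm, _ = sc.generate_counts(cfg)
overrides = {"filter": {"min_genes_per_cell": 30, "min_umi": 50,
                        "max_mito_pct": 50.0},
             "hvg": {"top_n": 60}}

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    sweep = sc.downsample_sweep(cm, axis="reads", preset="seurat_like",
                                fractions=[0.05, 0.1, 0.25, 0.5, 1.0],
                                seed=0, overrides=overrides)

print(f"axis: {sweep.axis}; grid: {sweep.fractions}")
print(f"{'metric':32s} {'v_ref':>8s} {'sufficient at':>14s}")
for metric, frac in sorted(sweep.sufficiency.items()):
    ref = sweep.v_ref[metric]
    ref_s = f"{ref:.3f}" if ref is not None else "--"
    print(f"{metric:32s} {ref_s:>8s} {str(frac):>14s}")
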