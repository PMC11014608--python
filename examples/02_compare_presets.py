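"""Compare the two toolkit-style presets on identical input.

Every divergent stage uses its own documented default in each preset, so
the per-stage metrics quantify how much each divergence matters: Jaccard
and ARI values of 1 (and sine / flip values of 0) mean the stage agreed
perfectly; lower Jaccard/ARI or higher sine/flip mean divergence.
"""

import sccompare as sc

cfg = sc.SynthConfig(n_cells=240, n_genes=200, n_clusters=3,
                     de_effect=2.0, de_fraction=0.2, seed=1)
cm, _ = sc.generate_counts(cfg)
overrides = {"filter": {"min_genes_per_cell": 30, "min_umi": 50,
                        "max_mito_pct": 50.0},
             "hvg": {"top_n": 60}}

a = sc.run_pipeline(cm, "seurat_like", seed=0, overrides=overrides)
b = sc.run_pipeline(cm, "scanpy_like", seed=0, overrides=overrides)
report = sc.compare_runs(a, b)

for name, value in report.metrics.items():
    if isinstance(value, list):
        head = ", ".join(f"{v:.3f}" for v in value[:3])
        print(f"{name:32s} [{head}, ...] (per PC)")
    elif value is None:
        print(f"{name:32s} (missing)")
    else:
        print(f"{name:32s} {value:.4f}")
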