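"""Run the full pipeline on the three hypothetical population structures.

Each scenario plants a different relationship between the preparatory and
movement subspaces; the pipeline's report shows how the three diagnostics
(correlation R^2, alignment percentile, linkage shuffle p) separate them.
"""

from orthospace import PipelineConfig, run_pipeline

for scenario in ("orthogonal_linked", "overlapping", "independent"):
    cfg = PipelineConfig(seed=1, scenario=scenario,
                         n_null=1000, n_shuffles=500, n_boot=300, n_boot_dip=500)
    r = run_pipeline(cfg)
    print(f"{scenario:18s} corr R^2={r['correlation']['r_squared']:.2f}  "
          f"alignment={r['alignment']['index']:.2f} "
          f"(pct {r['alignment']['percentile']:.2f})  "
          f"link R^2={r['link']['r_squared']:.2f} "
          f"(shuffle p={r['link']['shuffle_p']:.3f})  "
          f"-> classified: {r['classification']['label']}")
print("\noverlapping preserves correlations and alignment; independent breaks")
print("the linkage; orthogonal-but-linked is misaligned yet predictable.")
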