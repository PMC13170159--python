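"""Full single-slide run: simulate, acquire, focus, reconstruct, interpret.

The slide-level call combines per-object Gram reaction (hue), shape
(aspect ratio) and arrangement (proximity-graph geometry) with an
Undefined fallback when the evidence is mixed.
"""

import holostain as hs

config = hs.PipelineConfig(optical=hs.small_config(384, z_jitter=30.0))
record = hs.process_slide(config, "GPC_pairs_chains", seed=3)

print(f"ground truth:   {record['true_label']} "
      f"(stain quality {record['stain_quality']:+.2f})")
print(f"triage:         valid fraction {record['valid_fraction']:.2f}")
print(f"detections:     {record['n_objects']}")
print(f"votes:          {record['evidence']}")
print(f"slide call:     {record['call']}")
print(f"elapsed:        {record['elapsed_s']:.1f} s")
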