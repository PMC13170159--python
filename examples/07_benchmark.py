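"""A small end-to-end benchmark: synthetic slides through the whole
pipeline, scored against their ground truth.

The full 30-slide version (10 per class, seeds 1-30) is what
scripts/acceptance.py runs; this trimmed run keeps the example quick.
"""

import holostain as hs

accuracy, cm, records = hs.benchmark_accuracy(n_per_class=2, seed_start=1)

for r in records:
    mark = "ok " if r["call"] == r["true_label"] else "MISS"
    print(f"{mark} seed {r['seed']:2d} {r['true_label']:18s} -> {r['call']}")
print(f"\nslide-call accuracy: {100 * accuracy:.1f}% "
      f"over {sum(r['status'] == 'ok' for r in records)} accepted slides")
if cm is not None:
    print(cm.to_dataframe().to_string())
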