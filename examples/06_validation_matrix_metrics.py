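"""Accuracy metrics from the bundled validation confusion matrices.

Two matrices ship with the package: a 65-slide automated whole-slide
interpretation validation and a 96-interpretation reader study where an
Indeterminate option was allowed. All headline percentages derive from
the raw counts with explicit half-up rounding.
"""

import holostain as hs

t1 = hs.automated_interpretation_matrix()
print("automated interpretation (65 accepted slides):")
print(t1.to_dataframe().to_string())
print(f"  overall accuracy:        {hs.overall_accuracy(t1, 1)}%")
for cls in t1.row_labels:
    print(f"  {cls:18s} {hs.per_class_accuracy(t1, cls, 1)}%")
gn, gp = hs.binary_gram_accuracy(t1, round_to=1)
print(f"  binary Gram:             GN {gn}%, GP {hs.round_half_up(gp, 0):g}%")

t2 = hs.human_reader_matrix()
rate, acc = hs.call_rate_and_called_accuracy(t2, round_to=1)
print(f"\nreader study ({t2.total} interpretations):")
print(f"  call rate (non-indeterminate): {rate}%")
print(f"  accuracy where called:         {hs.round_half_up(acc, 0):g}%")
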