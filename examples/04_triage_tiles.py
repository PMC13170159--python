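"""Quality triage: gate acquisition tiles before reconstruction.

Only tiles with valid sparse/dense specimen content proceed; empty,
too-thick, failed or debris-dominated tiles are rejected, mirroring how a
laboratory scientist skips uninformative slide areas.
"""

import holostain as hs

tiles = [hs.make_tile(category, seed=40 + i)
         for i, category in enumerate(
             ["valid_sparse", "valid_dense", "no_sample",
              "invalid_too_thick", "hardware_failure", "undefined_debris"])]

result = hs.triage_slide(tiles)
for holo, label in zip(tiles, result.labels):
    f = label.features
    print(f"{holo.tile_id:24s} -> {label.category:18s} "
          f"(occupancy {f['occupancy']:.3f}, fringe {f['fringe_energy']:.2f}, "
          f"transmission {f['mean_transmission']:.2f})")
print(f"valid fraction: {result.valid_fraction:.2f}"
      + ("  [slide rejected]" if result.rejected else ""))
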