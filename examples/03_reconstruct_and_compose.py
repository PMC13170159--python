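"""Multi-wavelength phase retrieval and colour composition.

The Gerchberg–Saxton loop alternates between the sensor plane (where the
measured amplitudes are enforced) and the sample plane (where the specimen
is a passive, phase-retarding object), sharing one optical-path-length map
across the three wavelengths. The converged field is propagated to a
30-slice z-stack and fused into an RGB image.
"""

import numpy as np

import holostain as hs

config = hs.small_config(256, z_jitter=30.0)
phantom = hs.generate_phantom(config, "GPC_clusters", density=2000, seed=3,
                              z_span=0.0)
hologram = hs.record_hologram(phantom, config, seed=3, noise=hs.NOISELESS)

stack = hs.gs_reconstruct(hologram, hologram.z_true, max_iters=50, tol=1e-5)
print(f"iterations: {len(stack.gs_residuals)}, converged: {stack.converged}")
print(f"sensor residual: {stack.gs_residuals[0]:.4f} -> "
      f"{stack.gs_residuals[-1]:.4f} (relative amplitude mismatch)")

for c, wl in enumerate(stack.wavelengths):
    rec = np.abs(stack.slices[c, 15])
    corr = np.corrcoef(rec.ravel(), phantom.amplitude[c].ravel())[0, 1]
    print(f"  {wl:.2f} µm channel: in-focus correlation with truth {corr:.3f}")

image = hs.compose_color(stack)
hs.save_color_image(image, "scratch_recon")
print("wrote scratch_recon.png — purple cocci clusters on a bright field")
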