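"""Why PIV-seeded particle tracking beats either method alone.

Builds a full synthetic scene (300 Pa dipole on a soft gel; bead
displacements up to ~10 px), then links the equilibrium and stressed bead
detections with a small 2 px exploration radius — once unseeded and once
seeded with the PIV field — and reports how many beads were paired with
their true partner.
"""

import numpy as np
from scipy.spatial import cKDTree

from tfmlab import detect_particles, link_particles, make_scene, piv_displacement

scene = make_scene(rng_seed=5, n_t=1, drift_step_px=0.0)
h = scene.pixel_size_um
umax = np.hypot(scene.displacement_truth.ux, scene.displacement_truth.uy).max()
print(f"max bead displacement: {umax:.2f} µm = {umax / h:.1f} px; "
      f"exploration radius: 2 px")

ref = scene.render_reference()
frame = scene.render_stressed_frame(0)
ref_set = detect_particles(ref)
str_set = detect_particles(frame)
print(f"detected {len(ref_set)} reference and {len(str_set)} stressed beads")

piv = piv_displacement(frame, ref, window_px=32, overlap_fraction=0.75)
plain = link_particles(ref_set, str_set, 2.0 * h)
seeded = link_particles(ref_set, str_set, 2.0 * h, seed_field=piv,
                        seed_coverage_margin_um=16.0 * h)

eq = np.array([(p.x, p.y) for p in scene.bead_positions])
st = np.array([(p.x, p.y) for p in scene.bead_positions_stressed])
_, ri = cKDTree(eq).query(ref_set.positions)
_, si = cKDTree(st).query(str_set.positions)
assignable = np.isin(ri, si).sum()
for name, m in (("unseeded", plain), ("PIV-seeded", seeded)):
    ok = (ri[m.pairs[:, 0]] == si[m.pairs[:, 1]]).sum()
    print(f"{name:>11}: {len(m)} pairs, {100 * ok / assignable:.1f}% of "
          f"assignable beads linked to their true partner")
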