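"""Ripley's K clustering analysis of membrane-associated ribosomes.

Compares a Thomas-clustered decoration (35 nm scale) against complete
spatial randomness, both scored with K(r)/K_CSR(r) over r = 27-166 nm
against a surface-matched Monte-Carlo null.  A ratio above 1 flags
clustering; the interval maxima localize its scale.
"""

import numpy as np

from mitomorph import (
    TriangleSurface,
    compute_k_curve,
    decorate_particles,
    icosphere,
    interval_max_at,
    interval_maxima,
)
from mitomorph.io import particle_positions

v, f = icosphere(radius=3000.0, subdivisions=2)
omm = TriangleSurface(v, f, surface_id="OMM")

clustered, _ = decorate_particles(omm, n=300, mode="clustered", cluster_scale=35.0,
                                  standoff=0.0, seed=1)
random, _ = decorate_particles(omm, n=300, mode="csr", standoff=0.0, seed=2)

for name, particles in (("clustered (35 nm)", clustered), ("CSR", random)):
    curve = compute_k_curve(particle_positions(particles), omm, seed=3)
    print(f"{name}:")
    print(f"  mean K/K_CSR over 27-166 nm : {np.nanmean(curve['ratio']):.2f}")
    print(f"  max  K/K_CSR in (30,40] nm  : {interval_max_at(curve, 30, 40):.2f}")
    im = interval_maxima(curve)
    peak_row = im.loc[im["max_ratio"].idxmax()]
    print(f"  strongest interval          : ({peak_row.r_lo_nm:.0f},{peak_row.r_hi_nm:.0f}] nm "
          f"ratio {peak_row.max_ratio:.2f}")
# CSR should hover near 1 at all scales; the clustered decoration should
# exceed it, most strongly around the planted 35 nm scale.
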