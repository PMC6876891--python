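"""Render the illustrative 3-D landscape surface.

The surface V(x, y) = a*f + b*g combines cell-centred Gaussian wells
(widths scaled by each cluster's self-weight, so heavy metastable
clusters dig broader wells) with a plane fitted to the cluster
potentials.  Writes landscape_surface.png next to this script.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from ldd import drift_diffusion_spec, run_ldd, simulate_drift_diffusion
from ldd.landscape import SurfaceSpec, landscape_surface

ds = simulate_drift_diffusion(drift_diffusion_spec(seed=1))
res = run_ldd(ds.expression, n_clusters=4, seed=1)

coords = res.embedding.coords
gx, gy, V = landscape_surface(
    coords, res.clusters.labels, res.clusters.P_tilde, res.V_hat,
    SurfaceSpec(grid_size=120, sigma=0.08, a=1.0, b=0.02),
)

fig = plt.figure(figsize=(11, 4.5))
ax1 = fig.add_subplot(1, 2, 1)
sc = ax1.scatter(coords[:, 0], coords[:, 1], c=res.pseudotime, s=8, cmap="viridis")
fig.colorbar(sc, ax=ax1, label="pseudo-time")
ax1.set(xlabel="PC1", ylabel="PC2", title="cells coloured by pseudo-time")
ax2 = fig.add_subplot(1, 2, 2, projection="3d")
import numpy as np

X, Y = np.meshgrid(gx, gy)
ax2.plot_surface(X, Y, V, cmap="terrain", linewidth=0)
ax2.set(xlabel="PC1", ylabel="PC2", title="illustrative landscape")

out = Path(__file__).with_name("landscape_surface.png")
fig.tight_layout()
fig.savefig(out, dpi=150)
print(f"wrote {out}")
print(
    "Cells roll from the high plateau (pluripotent, early pseudo-time) "
    "down the two valleys (committed branches)."
)
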