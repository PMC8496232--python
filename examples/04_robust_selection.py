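"""Robust marker selection: stability selection and marginal FDR control.

Both methods trade power for reliability: stability selection keeps
markers chosen in most half-sample refits; mFDR selection picks the most
liberal lambda whose estimated marginal false discovery rate stays below
10%.
"""

import numpy as np

import gpqtl
from gpqtl.robust_selection import (mfdr_path, select_at_mfdr,
                                    stability_selection)

cfg = gpqtl.CrossSimConfig(n_offspring=188, n_chromosomes=5,
                           markers_per_chromosome=60, seed=8)
gm, geno = gpqtl.simulate_cross(cfg)
X = gpqtl.encode_design(geno)
panel = gpqtl.trait_sim.simulate_replicate(
    X, gm, gpqtl.SimulationConfig(s=4, h2=0.7, base_seed=9)
)
y = panel.Y[:, 0]
truth = set(panel.effects.qtl_markers[0])
print("true QTL markers:", sorted(truth))

ss = stability_selection(X.X, y, "LASSO",
                         lambda_grid_values=np.geomspace(0.3, 0.02, 12),
                         n_subsamples=60, pi_threshold=0.6, seed=10,
                         design=X, tol=1e-4)
print(f"stability selection (pi >= 0.6): {ss.selected_markers}")

path = mfdr_path(X.X, y, "EN", alpha=0.7, tol=1e-4)
sel = select_at_mfdr(path, level=0.10, design=X)
print(f"EN.mFDR at 10%: {sel.selected_markers}")
print("markers within ~2 cM of a true QTL count as correct finds; "
      "both lists should be short and close to the truth.")
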