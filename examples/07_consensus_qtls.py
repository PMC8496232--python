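"""Call consensus QTL intervals from several selection methods.

Combines MIM and mFDR-controlled elastic-net selections: each selection is
expanded with linkage disequilibrium, markers found by both methods become
"highly reliable", each anchors a +/- 3 cM interval converted to physical
coordinates by a monotone loess fit, and the variance explained by the
anchors is summarized as adjusted R-squared.
"""

import gpqtl
from gpqtl import consensus as cq
from gpqtl import interval_mapping as im
from gpqtl.robust_selection import mfdr_path, select_at_mfdr

cfg = gpqtl.CrossSimConfig(n_offspring=188, n_chromosomes=5,
                           markers_per_chromosome=60, seed=17)
gm, geno = gpqtl.simulate_cross(cfg)
X = gpqtl.encode_design(geno)
panel = gpqtl.trait_sim.simulate_replicate(
    X, gm, gpqtl.SimulationConfig(s=3, h2=0.9, base_seed=18)
)
y = panel.Y[:, 0]
print("true QTL markers:", panel.effects.qtl_markers[0])

ldm = cq.compute_ld(geno)
print(f"LD threshold (95% quantile of within-chromosome r2): "
      f"{ldm.ld_threshold:.3f}")

grid = im.calc_genoprob(geno, gm, step_cM=None)
thr = im.permutation_threshold(grid, y, n_perm=200, seed=19)
model = im.mim_stepwise(grid, y, max_qtl=4, penalty=thr, seed=20)
mim_markers = im.nearest_markers(model.position_table(), gm)

path = mfdr_path(X.X, y, "EN", alpha=0.7, tol=1e-4)
en = select_at_mfdr(path, level=0.10, design=X)

selections = [
    ("MIM", cq.ld_expand(mim_markers, ldm)),
    ("EN.mFDR", cq.ld_expand(en.selected_markers, ldm)),
]
reliable = cq.tally_reliable(selections)
print(f"highly reliable markers (EN.mFDR & MIM rule): {reliable}")

smoother = cq.fit_cm_bp_smoother(gm)
intervals = cq.build_intervals(reliable, gm, trait="trait1",
                               smoother=smoother)
for iv in intervals:
    iv.pve = cq.pve_adjusted_r2(geno, iv.anchor_markers, y)
print(cq.intervals_to_frame(intervals).to_string(index=False))
print("each interval should contain one true QTL; adjusted_R2 is the "
      "variance its anchor markers explain.")
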