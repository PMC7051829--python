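"""Robustness of the association to density-peak placement.

Perturbs the two seeds of a well-separated Gaussian pair by increasing
fractions of the dataset's bounding-box diagonal (5 random replicas
each), re-solves, and prints mean pairwise F1 for the path solver and
for CDP* (the local rule forced to use the perturbed seeds).
"""

from pathclust import (compute_delta, estimate_density, make_gaussian_mixture_hd,
                       perturbation_assay, select_peaks_topn)

sample = make_gaussian_mixture_hd(2, n_per_cluster=80, n_clusters=2, seed=5)
points, gt = sample.points, sample.gt_labels

density = estimate_density(points)
compute_delta(points, density)
peaks = select_peaks_topn(density, 2)

table = perturbation_assay(points, gt, peaks,
                           magnitudes=[0.0, 0.1, 0.3, 0.6, 1.0],
                           replicas=5, seed=0, density=density)
print(table.groupby("magnitude")[["f1_path", "f1_cdp_star"]].mean().round(3))
kept = table[table.seeds_in_distinct_clusters]
print(f"\nreplicas with both seeds still in distinct clusters: {len(kept)} of "
      f"{len(table)}; their minimum F1 is {kept.f1_path.min():.3f}")
# As long as the displaced seeds land in distinct true clusters the
# shortest-path association recovers the same partition, so F1 stays at
# its unperturbed value; it degrades only when both seeds collapse into
# the same cluster and an artificial split is forced.
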