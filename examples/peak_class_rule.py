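"""The peak-class averaging rule on a tiny worked histogram.

Eighty-five nuclei fall into four 0.1 pg classes with counts 5 / 40 / 30 /
10.  The peak class is the second one (40 nuclei); its right neighbour (30 >
half of 40) is included, the others (5, 10) are excluded; the estimate is
the mean DNA content over the nuclei in the included classes.  The rule
trims stray high- and low-C nuclei without fitting a mixture model.
"""

import numpy as np

from dapicyto.ploidy import build_frequency_distribution, peak_class_mean, pg_to_mb

values = np.concatenate([
    np.full(5, 0.65), np.full(40, 0.75), np.full(30, 0.85), np.full(10, 0.95),
])
dist = build_frequency_distribution(values, class_width=0.1)
print("classes:", [f"[{a:.1f},{b:.1f})" for a, b in zip(dist.edges, dist.edges[1:])])
print("counts: ", [int(c) for c in dist.counts])

est = peak_class_mean(dist)
lo, hi = est.included_class_indices
print(f"included classes: indices {lo}..{hi} "
      f"([{dist.edges[lo]:.1f}, {dist.edges[hi + 1]:.1f}) pg)")
print(f"peak-class mean: {est.mean_pg:.4f} pg over {est.n_included}/{est.n_total} nuclei")
print(f"genome-size equivalent: {pg_to_mb(est.mean_pg):.0f} Mb (1 pg = 980 Mb)")
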