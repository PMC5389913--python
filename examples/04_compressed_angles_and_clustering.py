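"""Compressed-angle labeling and k-means clustering in 6-angle space.

Mixes normal octahedral Ca sites with bidentate carboxylate sites whose
O-metal-O angle is compressed to ~56 degrees, labels them with the
band-plus-random-forest scheme, and clusters the 6-angle vectors.
"""

import numpy as np

from metalcg import (
    SyntheticSpec,
    angles_from_positions,
    classify_compressed,
    generate_batch,
    kmeans_six_angle,
    six_angle_reduction,
    stability_measures,
)

specs = [
    SyntheticSpec(metal="Ca", cg_code="Oct", n_sites=120, angle_noise_sd=3.0,
                  seed=5),
    SyntheticSpec(metal="Ca", cg_code="Oct", n_sites=80, angle_noise_sd=3.0,
                  bidentate_fraction=1.0, seed=6),
]
sites, labels_truth, vectors, feats = [], [], [], []
for spec in specs:
    batch, truths = generate_batch(spec)
    for s, t in zip(batch, truths):
        prof = angles_from_positions([a.coords for a in s.ligand_atoms],
                                     s.metal_coords)
        vectors.append(six_angle_reduction(prof).as_array())
        small, pair = min((a, p) for a, p in prof.angles)
        a1, a2 = s.ligand_atoms[pair[0]], s.ligand_atoms[pair[1]]
        feats.append((small, (a1.element, a2.element),
                      a1.residue_id == a2.residue_id))
        labels_truth.append(t.label)

labels = classify_compressed(
    [f[0] for f in feats], [f[1] for f in feats], [f[2] for f in feats],
    band=(55.0, 65.0), seed=7,
)
agree = np.mean([l.label == t for l, t in zip(labels, labels_truth)])
n_pred = sum(l.source == "predicted" for l in labels)
print(f"normal/compressed agreement with truth: {100 * agree:.1f}% "
      f"({n_pred} in-band sites labelled by the forest)")

runs = [kmeans_six_angle(np.asarray(vectors), k=2, seed=s) for s in (1, 2, 3)]
jaccard, center_diff = stability_measures(runs)
print(f"k-means k=2: mean matched Jaccard {jaccard:.3f}, "
      f"center measure {center_diff:.3f} (0 is perfectly stable)")
for i, c in enumerate(runs[0].centers):
    print(f"  cluster {i} center: " + ", ".join(f"{a:6.1f}" for a in c))
print(
    "\nThe compressed cluster's center shows the hallmark ~56-degree"
    " smallest-opposite angle that no canonical geometry explains --"
    " an aberrant coordination geometry caused by bidentation."
)
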