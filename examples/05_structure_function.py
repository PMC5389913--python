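"""Structure-function correlation and term enrichment on planted data.

Six structural classes (four normal, two compressed) are generated, given
annotations whose overlap grades with structural distance plus 5% noise,
clustered at k=6, and the Spearman correlation between structural and
functional cluster distances is computed.  Term enrichment then contrasts
the normal and compressed groups.
"""

import numpy as np

from metalcg import (
    SyntheticSpec,
    angles_from_positions,
    cluster_rho,
    generate_batch,
    hypergeometric_enrichment,
    kmeans_six_angle,
    six_angle_reduction,
)
from metalcg.synthetic_data import planted_annotations

classes = [
    ("Zn", "Tet", 0.0), ("Zn", "Tbp", 0.0), ("Fe", "Oct", 0.0),
    ("Ca", "Pbp", 0.0), ("Zn", "Oct", 1.0), ("Ca", "Tet", 1.0),
]
vectors, labels, group = [], [], []
for ci, (metal, code, bid) in enumerate(classes):
    spec = SyntheticSpec(metal=metal, cg_code=code, n_sites=150,
                         angle_noise_sd=3.0, bidentate_fraction=bid,
                         seed=100 + ci)
    batch, truths = generate_batch(spec)
    for s, t in zip(batch, truths):
        prof = angles_from_positions([a.coords for a in s.ligand_atoms],
                                     s.metal_coords)
        vectors.append(six_angle_reduction(prof).as_array())
        labels.append(ci)
        group.append(t.label)
vectors = np.asarray(vectors)

anns = planted_annotations(vectors, labels, noise=0.05, seed=3)
run = kmeans_six_angle(vectors, k=6, seed=4)
rho, p = cluster_rho(run.centers, run.assignments, anns)
print(f"n = {len(vectors)} sites, k = 6")
print(f"structure-function Spearman rho = {rho:.3f} (p = {p:.2e})")

site_ids = [f"s{i}" for i in range(len(labels))]
terms = {
    site_ids[i]: {("NT" if group[i] == "normal" else "CT") + str(labels[i])}
    for i in range(len(site_ids))
}
for name, members in (
    ("normal", [site_ids[i] for i, g in enumerate(group) if g == "normal"]),
    ("compressed", [site_ids[i] for i, g in enumerate(group) if g == "compressed"]),
):
    res = hypergeometric_enrichment(members, site_ids, terms, name)
    sig = sorted(r.term_id for r in res if r.significant)
    print(f"terms enriched in the {name} group: {sig}")
print(
    "\nA rho this high means clusters that are structurally close carry"
    " similar annotation profiles; the enriched-term lists are disjoint"
    " between normal and compressed coordination, mirroring their distinct"
    " biological roles."
)
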