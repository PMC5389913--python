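"""Chi-square classification of a mixed coordination-geometry cohort.

Generates noisy tetrahedral and octahedral sites, refines per-model angle
statistics iteratively and reports the per-class recovery.
"""

from collections import Counter

from metalcg import SyntheticSpec, generate_batch, iterate_statistics

batches = {}
for code, seed in [("Tet", 1), ("Oct", 2)]:
    spec = SyntheticSpec(metal="Zn", cg_code=code, n_sites=80,
                         angle_noise_sd=3.0, seed=seed)
    batches[code] = generate_batch(spec)

sites = [s for batch, _ in batches.values() for s in batch]
truth = {s.site_id: code for code, (batch, _) in batches.items() for s in batch}

stats, classifications = iterate_statistics(sites, {"Zn": 68.0})
confusion = Counter(
    (truth[c.site_id], c.cg_code) for c in classifications if c.fit
)
print("generating -> classified (count):")
for (gen, got), n in sorted(confusion.items()):
    print(f"  {gen:>3} -> {got:<3} {n}")
hits = sum(n for (g, c), n in confusion.items() if g == c)
print(f"recovery: {hits}/{len(classifications)} "
      f"({100 * hits / len(classifications):.1f}%)")
for code in ("Tet", "Oct"):
    mean = stats[code].angle_means
    print(f"converged {code} ordered-angle means: "
          + ", ".join(f"{a:.1f}" for a in mean))
print(
    "\nEach site is fitted against all 18 canonical models over its viable"
    " ligand combinations; the model with the highest chi-square upper-tail"
    " probability wins, and per-model statistics are re-estimated until"
    " they converge."
)
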