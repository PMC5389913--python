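"""The 18 canonical coordination-geometry models and their 6-angle vectors.

Every model is built from ideal unit-vector ligand positions; the 6-angle
vector (largest, smallest/33rd/66th-quantile/largest middle, smallest
opposite angle) is what downstream clustering operates on.  Geometries with
different coordination numbers become comparable in this space.
"""

from metalcg import list_canonical_cgs

print(f"{'code':<5} {'name':<38} {'n':>2}  six-angle vector (degrees)")
for model in list_canonical_cgs():
    vec = ", ".join(f"{a:6.1f}" for a in model.six_angle_vector().as_array())
    kind = "major" if model.is_major else f"minor of {model.parent_major}"
    print(f"{model.code:<5} {model.name:<38} {model.coordination_number:>2}  [{vec}]  ({kind})")

print(
    "\nEach row is one ideal polyhedron; e.g. the tetrahedron is all 109.5"
    " and the octahedron reads (180, 90, 90, 90, 180, 90). Note that the"
    " square pyramid (Spy) collapses onto the octahedron's vector: the"
    " reduction cannot distinguish them, only coordination number does."
)
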