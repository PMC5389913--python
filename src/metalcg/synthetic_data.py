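"""Synthetic metal-site structure fixtures with known ground truth.

The generator emulates every phenomenon the detection pipeline must
handle:

* canonical coordination geometries with Gaussian angle and bond-length
  noise, wrapped in minimal amino-acid residues (Cys S, Asp O, His N) or
  waters;
* bidentate compressed-angle sites, where two adjacent ligand positions
  are replaced by both carboxylate oxygens of one residue at a compressed
  angle (default Normal(56, 3.5) degrees);
* second-shell carbon decoys, covalently attached (~1.45 A) to a true
  ligand at the metal's characteristic carbon-mode distance;
* misassigned-metal sites whose bond lengths are all systematically
  inflated.

Sites can be used directly as in-memory :class:`~metalcg.structure_io.MetalSite`
objects or written to PDB files (with a far-away poly-alanine chain so the
entries pass the 20-amino-acid filter) plus a TSV truth manifest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

from .cg_models import get_cg
from .structure_io import AtomRecord, MetalSite

__all__ = [
    "SyntheticSpec",
    "TruthRecord",
    "make_site",
    "make_bidentate_site",
    "add_decoys",
    "make_misassigned_site",
    "generate_batch",
    "write_benchmark",
]

#: default mean metal-ligand bond lengths (A) per metal and element;
#: most-abundant-element values match the shipped per-metal parameters
DEFAULT_BOND_MEANS: dict[str, dict[str, float]] = {
    "Zn": {"S": 2.341, "O": 2.065, "N": 2.091},
    "Mg": {"O": 2.100, "N": 2.180},
    "Ca": {"O": 2.481, "N": 2.500},
    "Fe": {"N": 2.063, "S": 2.300, "O": 2.050},
    "Na": {"O": 2.450, "N": 2.500},
}

#: default carbon-decoy distance (A) per metal: the main carbon mode
DEFAULT_CARBON_MODES = {"Zn": 3.071, "Mg": 3.067, "Ca": 3.432, "Fe": 3.081, "Na": 3.568}

#: characteristic bond-length standard deviations (A) per metal and element
#: (the scale of real crystallographic scatter; misassignment inflation is
#: expressed in these units)
DEFAULT_BOND_SDS: dict[str, dict[str, float]] = {
    "Zn": {"S": 0.152, "O": 0.150, "N": 0.150},
    "Mg": {"O": 0.368, "N": 0.300},
    "Ca": {"O": 0.271, "N": 0.270},
    "Fe": {"N": 0.134, "S": 0.150, "O": 0.150},
    "Na": {"O": 0.369, "N": 0.350},
}

#: residue scaffold per ligand element: (residue name, ligand atom name,
#: anchor carbon atom name, carbon-ligand covalent distance)
_SCAFFOLDS = {
    "S": ("CYS", "SG", "CB", 1.81),
    "O": ("ASP", "OD1", "CG", 1.25),
    "N": ("HIS", "NE2", "CD2", 1.37),
}

_CARBOXYLATE_CO = 1.25  # A, carboxylate C-O bond


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic site batch."""

    metal: str = "Zn"
    cg_code: str = "Tet"
    n_sites: int = 100
    angle_noise_sd: float = 3.0  # degrees
    bond_noise_sd: float = 0.05  # A
    bond_means: dict[str, float] | None = None
    bond_sds: dict[str, float] | None = None  # characteristic per-element sd
    ligand_elements: tuple[str, ...] | None = None
    bidentate_fraction: float = 0.0
    compressed_angle_mean: float = 56.0
    compressed_angle_sd: float = 3.5
    decoy_carbon_distance: float | None = None
    decoys_per_site: int = 0
    misassign_fraction: float = 0.0
    misassign_inflation: float = 1.5
    resolution: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for frac in (self.bidentate_fraction, self.misassign_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.angle_noise_sd < 0 or self.bond_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        get_cg(self.cg_code)  # raises for unknown codes

    @property
    def effective_bond_means(self) -> dict[str, float]:
        return self.bond_means or DEFAULT_BOND_MEANS[self.metal]

    @property
    def effective_elements(self) -> tuple[str, ...]:
        if self.ligand_elements:
            return self.ligand_elements
        return tuple(self.effective_bond_means)[:1]

    @property
    def effective_bond_sds(self) -> dict[str, float]:
        return self.bond_sds or DEFAULT_BOND_SDS[self.metal]

    @property
    def effective_carbon_distance(self) -> float:
        if self.decoy_carbon_distance is not None:
            return self.decoy_carbon_distance
        return DEFAULT_CARBON_MODES[self.metal]


@dataclass
class TruthRecord:
    """Ground truth for one generated site."""

    site_id: str
    cg_code: str
    label: str  # normal | compressed | misassigned
    bidentate: bool
    ligand_keys: tuple[str, ...]  # residue_id:atom_name of true ligands
    decoy_keys: tuple[str, ...] = ()
    annotation_id: str = ""


def _rng_for(spec: SyntheticSpec, index: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, index])


def _perturb_direction(
    v: np.ndarray, sd_deg: float, rng: np.random.Generator
) -> np.ndarray:
    """Rotate a unit vector by N(0, sd) degrees about a random normal axis."""
    if sd_deg <= 0:
        return v
    delta = math.radians(rng.normal(0.0, sd_deg))
    # random axis perpendicular to v
    r = rng.normal(size=3)
    axis = r - (r @ v) * v
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        return v
    axis /= norm
    return v * math.cos(delta) + np.cross(axis, v) * math.sin(delta)


def _perp_unit(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    r = rng.normal(size=3)
    w = r - (r @ v) * v / (v @ v)
    return w / np.linalg.norm(w)


def _residue_atoms(
    element: str,
    position: np.ndarray,
    residue_index: int,
    rng: np.random.Generator,
) -> list[AtomRecord]:
    """Minimal residue scaffold: the ligand atom plus its anchor carbon."""
    name, atom_name, c_name, c_dist = _SCAFFOLDS[element]
    rid = f"A.{residue_index}"
    direction = position / np.linalg.norm(position)
    c_pos = position + c_dist * direction  # carbon points away from the metal
    return [
        AtomRecord(element=element, coords=position, residue_name=name,
                   residue_id=rid, atom_name=atom_name),
        AtomRecord(element="C", coords=c_pos, residue_name=name,
                   residue_id=rid, atom_name=c_name),
    ]


def _water_atom(position: np.ndarray, residue_index: int) -> list[AtomRecord]:
    return [
        AtomRecord(element="O", coords=position, residue_name="HOH",
                   residue_id=f"W.{residue_index}", atom_name="O", is_water=True)
    ]


def make_site(spec: SyntheticSpec, index: int) -> tuple[MetalSite, TruthRecord]:
    """One noisy monodentate site of the spec's canonical CG.

    The metal sits at the origin; ligand positions are the CG's ideal unit
    vectors perturbed by Gaussian angular noise and scaled to the element's
    bond mean plus Gaussian bond noise.
    """
    rng = _rng_for(spec, index)
    cg = get_cg(spec.cg_code)
    means = spec.effective_bond_means
    elements = spec.effective_elements

    atoms: list[AtomRecord] = []
    ligand_atoms: list[AtomRecord] = []
    for i, pos in enumerate(cg.ideal_positions):
        el = elements[i % len(elements)]
        direction = _perturb_direction(np.asarray(pos), spec.angle_noise_sd, rng)
        length = means[el] + rng.normal(0.0, spec.bond_noise_sd)
        if el == "W":
            res = _water_atom(direction * length, i + 1)
        else:
            res = _residue_atoms(el, direction * length, i + 1, rng)
        atoms.extend(res)
        ligand_atoms.append(res[0])

    site_id = f"{spec.metal}{spec.cg_code}.{index}"
    site = MetalSite(
        site_id=site_id,
        metal_element=spec.metal,
        metal_coords=np.zeros(3),
        resolution=spec.resolution,
        entry_id=site_id,
        candidate_atoms=atoms,
        ligand_atoms=ligand_atoms,
    )
    truth = TruthRecord(
        site_id=site_id,
        cg_code=spec.cg_code,
        label="normal",
        bidentate=False,
        ligand_keys=tuple(f"{a.residue_id}:{a.atom_name}" for a in ligand_atoms),
    )
    return site, truth


def make_bidentate_site(spec: SyntheticSpec, index: int) -> tuple[MetalSite, TruthRecord]:
    """A compressed-angle site with one bidentate carboxylate.

    The two ideal positions forming the smallest ideal angle are replaced
    by both carboxylate oxygens of a single Asp/Glu-like residue whose
    O-metal-O angle is drawn from Normal(compressed_angle_mean, sd).
    Raises when the requested angle exceeds the ideal adjacent angle.
    """
    rng = _rng_for(spec, index)
    cg = get_cg(spec.cg_code)
    if cg.coordination_number < 4:
        raise ValueError("bidentate sites need a CG with >= 4 ligands")
    prof = cg.angle_profile()
    ideal_small, (i, j) = min(
        ((a, p) for a, p in prof.angles), key=lambda t: (t[0], t[1])
    )
    theta = rng.normal(spec.compressed_angle_mean, spec.compressed_angle_sd)
    if theta >= ideal_small:
        raise ValueError(
            f"requested compressed angle {theta:.1f} deg is not below the "
            f"ideal adjacent angle {ideal_small:.1f} deg of {cg.code}"
        )
    means = spec.effective_bond_means
    elements = spec.effective_elements
    r_o = means.get("O", 2.1)

    vi = np.asarray(cg.ideal_positions[i])
    vj = np.asarray(cg.ideal_positions[j])
    bisector = vi + vj
    bisector /= np.linalg.norm(bisector)
    tangent = vj - (vj @ bisector) * bisector
    tangent /= np.linalg.norm(tangent)
    half = math.radians(theta / 2.0)
    o1 = r_o * (math.cos(half) * bisector + math.sin(half) * tangent)
    o2 = r_o * (math.cos(half) * bisector - math.sin(half) * tangent)
    # carboxylate carbon on the bisector, C-O = 1.25 A
    s = r_o * math.sin(half)
    c_along = r_o * math.cos(half) + math.sqrt(max(_CARBOXYLATE_CO**2 - s**2, 0.01))
    c_pos = c_along * bisector

    rid = "A.1"
    atoms = [
        AtomRecord(element="O", coords=o1, residue_name="ASP", residue_id=rid,
                   atom_name="OD1"),
        AtomRecord(element="O", coords=o2, residue_name="ASP", residue_id=rid,
                   atom_name="OD2"),
        AtomRecord(element="C", coords=c_pos, residue_name="ASP", residue_id=rid,
                   atom_name="CG"),
    ]
    ligand_atoms = atoms[:2]
    for idx_pos, pos in enumerate(cg.ideal_positions):
        if idx_pos in (i, j):
            continue
        el = elements[idx_pos % len(elements)]
        direction = _perturb_direction(np.asarray(pos), spec.angle_noise_sd, rng)
        length = means[el] + rng.normal(0.0, spec.bond_noise_sd)
        res = _residue_atoms(el, direction * length, idx_pos + 2, rng)
        atoms.extend(res)
        ligand_atoms.append(res[0])

    site_id = f"{spec.metal}{spec.cg_code}bi.{index}"
    site = MetalSite(
        site_id=site_id,
        metal_element=spec.metal,
        metal_coords=np.zeros(3),
        resolution=spec.resolution,
        entry_id=site_id,
        candidate_atoms=atoms,
        ligand_atoms=ligand_atoms,
    )
    truth = TruthRecord(
        site_id=site_id,
        cg_code=spec.cg_code,
        label="compressed",
        bidentate=True,
        ligand_keys=tuple(f"{a.residue_id}:{a.atom_name}" for a in ligand_atoms),
    )
    return site, truth


def add_decoys(
    site: MetalSite,
    truth: TruthRecord,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> tuple[MetalSite, TruthRecord]:
    """Attach second-shell carbon decoys to random true ligands.

    Each decoy carbon sits ~1.45 A from its anchor ligand at a metal
    distance drawn from Normal(carbon mode, 0.15), pointing away from the
    metal; truth marks decoys as non-ligands.
    """
    if rng is None:
        import zlib

        rng = _rng_for(spec, zlib.crc32(truth.site_id.encode()) % (2**31))
    decoy_keys = list(truth.decoy_keys)
    n_existing = len([a for a in site.candidate_atoms if a.residue_id.startswith("D.")])
    for d in range(spec.decoys_per_site):
        anchor = site.ligand_atoms[rng.integers(len(site.ligand_atoms))]
        bond = rng.uniform(1.42, 1.48)
        d_anchor = float(np.linalg.norm(anchor.coords))
        target = rng.normal(spec.effective_carbon_distance, 0.15)
        lo, hi = abs(d_anchor - bond) + 0.05, d_anchor + bond - 0.05
        target = float(np.clip(target, lo, hi))
        u = anchor.coords / d_anchor
        alpha = (d_anchor**2 + target**2 - bond**2) / (2.0 * d_anchor)
        beta = math.sqrt(max(target**2 - alpha**2, 0.0))
        w = _perp_unit(u, rng)
        pos = alpha * u + beta * w
        rid = f"D.{n_existing + d + 1}"
        atom = AtomRecord(element="C", coords=pos, residue_name="LIG",
                          residue_id=rid, atom_name="CD")
        site.candidate_atoms.append(atom)
        decoy_keys.append(f"{rid}:CD")
    return site, replace_truth(truth, decoy_keys=tuple(decoy_keys))


def replace_truth(truth: TruthRecord, **kwargs) -> TruthRecord:
    data = truth.__dict__ | kwargs
    return TruthRecord(**data)


def make_misassigned_site(spec: SyntheticSpec, index: int) -> tuple[MetalSite, TruthRecord]:
    """A site whose bond lengths are all systematically inflated.

    Every atom is pushed outward by misassign_inflation times the
    element's characteristic bond-length sd (the crystallographic scatter
    scale, not the small generation noise), emulating a smaller ion
    modelled into a larger ion's electron density -- the radial error is
    on the ionic-radius-difference scale.
    """
    site, truth = make_site(spec, index)
    sds = spec.effective_bond_sds
    default_sd = float(np.mean(list(sds.values())))
    for atom in site.candidate_atoms:
        d = float(np.linalg.norm(atom.coords))
        if d > 1e-9:
            shift = spec.misassign_inflation * sds.get(atom.element, default_sd)
            atom.coords = atom.coords * ((d + shift) / d)
    return site, replace_truth(truth, label="misassigned")


def generate_batch(spec: SyntheticSpec) -> tuple[list[MetalSite], list[TruthRecord]]:
    """Generate spec.n_sites sites with the spec's mixture of phenomena.

    The first ``round(bidentate_fraction * n)`` indices become bidentate
    compressed sites and the next ``round(misassign_fraction * n)``
    misassigned sites; the rest are normal.  Decoys are attached to every
    site when ``decoys_per_site`` > 0.  Fully reproducible from the spec.
    """
    n = spec.n_sites
    n_bid = int(round(spec.bidentate_fraction * n))
    n_mis = int(round(spec.misassign_fraction * n))
    sites, truths = [], []
    for i in range(n):
        if i < n_bid:
            site, truth = make_bidentate_site(spec, i)
        elif i < n_bid + n_mis:
            site, truth = make_misassigned_site(spec, i)
        else:
            site, truth = make_site(spec, i)
        if spec.decoys_per_site > 0:
            rng = np.random.default_rng([spec.seed, i, 7])
            site, truth = add_decoys(site, truth, spec, rng)
        sites.append(site)
        truths.append(truth)
    return sites, truths


def planted_annotations(
    vectors: Sequence[Sequence[float]],
    labels: Sequence[int],
    noise: float = 0.05,
    seed: int = 0,
    prefix: str = "A",
) -> list[frozenset[str]]:
    """Per-site annotation sets with a planted structure-function association.

    Every site carries its class's annotation (mislabelled with probability
    ``noise``) plus, with probability exp(-d/tau), the annotation of each
    other class at 6-angle-space distance d -- so annotation profiles of
    structurally close classes overlap more, giving functional distances
    that grade with structural distances instead of being uniformly
    dissimilar.  tau is half the median inter-class distance.
    """
    x = np.asarray(vectors, dtype=float)
    lab = np.asarray(labels)
    classes = sorted(set(int(c) for c in lab))
    centers = np.array([x[lab == c].mean(axis=0) for c in classes])
    dist = np.linalg.norm(centers[:, None] - centers[None, :], axis=2)
    positive = dist[dist > 0]
    tau = float(np.median(positive)) / 2.0 if positive.size else 1.0
    rng = np.random.default_rng(seed)
    out = []
    for c in lab:
        ci = classes.index(int(c))
        if rng.random() < noise:
            ci = int(rng.integers(len(classes)))
        terms = {f"{prefix}{classes[ci]}"}
        for dj in range(len(classes)):
            if dj != ci and rng.random() < math.exp(-dist[ci, dj] / tau):
                terms.add(f"{prefix}{classes[dj]}")
        out.append(frozenset(terms))
    return out


# ---------------------------------------------------------------------------
# PDB output
# ---------------------------------------------------------------------------

_METAL_OFFSET = 20.0  # A between site origins within one entry


def _site_to_gemmi(site: MetalSite, origin: np.ndarray, model: gemmi.Model) -> None:
    chain_names = sorted({a.residue_id.split(".")[0] for a in site.candidate_atoms})
    metal_chain = gemmi.Chain("M" if "M" not in chain_names else "X")
    res = gemmi.Residue()
    res.name = site.metal_element.upper()
    res.seqid = gemmi.SeqId(1, " ")
    res.het_flag = "H"
    atom = gemmi.Atom()
    atom.name = site.metal_element.upper()
    atom.element = gemmi.Element(site.metal_element)
    p = site.metal_coords + origin
    atom.pos = gemmi.Position(*p)
    atom.occ = 1.0
    res.add_atom(atom)
    metal_chain.add_residue(res)
    model.add_chain(metal_chain)

    by_residue: dict[str, list[AtomRecord]] = {}
    for a in site.candidate_atoms:
        by_residue.setdefault(a.residue_id, []).append(a)
    chains: dict[str, gemmi.Chain] = {}
    for seq, (rid, atoms) in enumerate(sorted(by_residue.items()), start=1):
        cname = rid.split(".")[0]
        if cname not in chains:
            chains[cname] = gemmi.Chain(cname)
        r = gemmi.Residue()
        r.name = atoms[0].residue_name
        r.seqid = gemmi.SeqId(seq, " ")
        if atoms[0].is_water or not atoms[0].is_polymer:
            r.het_flag = "H" if atoms[0].is_water else "A"
        for a in atoms:
            g = gemmi.Atom()
            g.name = a.atom_name
            g.element = gemmi.Element(a.element)
            g.pos = gemmi.Position(*(a.coords + origin))
            g.occ = a.occupancy
            g.b_iso = a.b_factor
            r.add_atom(g)
        chains[cname].add_residue(r)
    for c in chains.values():
        model.add_chain(c)


def _polyala_chain(n_res: int = 20, offset: float = 100.0) -> gemmi.Chain:
    # far-away scaffold chain so entries pass the 20-amino-acid filter
    chain = gemmi.Chain("Z")
    for i in range(n_res):
        r = gemmi.Residue()
        r.name = "ALA"
        r.seqid = gemmi.SeqId(i + 1, " ")
        a = gemmi.Atom()
        a.name = "CA"
        a.element = gemmi.Element("C")
        a.pos = gemmi.Position(offset + 3.8 * i, offset, offset)
        a.occ = 1.0
        r.add_atom(a)
        chain.add_residue(r)
    return chain


def write_site_pdb(
    site: MetalSite, path: str | Path, resolution: float | None = None
) -> None:
    """Write one site (plus the scaffold chain) as a PDB file."""
    st = gemmi.Structure()
    st.name = site.entry_id[:78]
    st.resolution = resolution if resolution is not None else site.resolution
    model = gemmi.Model("1")
    _site_to_gemmi(site, np.zeros(3), model)
    model.add_chain(_polyala_chain())
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def write_benchmark(
    specs: Sequence[SyntheticSpec],
    out_dir: str | Path,
    plant_annotations: bool = False,
    annotation_noise: float = 0.05,
    annotation_seed: int = 0,
) -> Path:
    """Write a benchmark: one PDB per site, a truth manifest, annotations.

    The truth manifest ``truth.tsv`` lists site_id, cg, label, bidentate,
    ligand atoms and decoy atoms.  With ``plant_annotations`` an annotation
    table ``annotations.tsv`` is written in which each site carries a
    domain identifier determined by its generating (CG, label) class,
    randomly reassigned with probability ``annotation_noise`` -- a planted
    structure-function association.

    Site ids in both tables carry the ``.M.1`` suffix that
    :func:`~metalcg.structure_io.find_metal_sites` assigns when the written
    files are parsed back (each entry holds one metal, chain M residue 1).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = ["site_id\tmetal\tcg\tlabel\tbidentate\tligand_atoms\tdecoy_atoms"]
    ann_rows = ["site_id\tresidue_id\tannotation_id\tterm_ids"]
    rng = np.random.default_rng(annotation_seed)

    classes = sorted({(s.metal, s.cg_code) for s in specs})
    for spec in specs:
        sites, truths = generate_batch(spec)
        for site, truth in zip(sites, truths):
            write_site_pdb(site, out / f"{truth.site_id}.pdb", spec.resolution)
            parsed_id = f"{truth.site_id}.M.1"
            manifest.append(
                "\t".join(
                    [
                        parsed_id,
                        spec.metal,
                        truth.cg_code,
                        truth.label,
                        str(truth.bidentate),
                        ",".join(truth.ligand_keys),
                        ",".join(truth.decoy_keys),
                    ]
                )
            )
            if plant_annotations:
                cls = (spec.metal, spec.cg_code, truth.label)
                if rng.random() < annotation_noise:
                    other = classes[rng.integers(len(classes))]
                    cls = (other[0], other[1], truth.label)
                ann = f"IPR_{cls[0]}_{cls[1]}_{cls[2]}"
                term = f"TERM:{cls[1]}_{cls[2]}"
                residue = truth.ligand_keys[0].split(":")[0]
                ann_rows.append(f"{parsed_id}\t{residue}\t{ann}\t{term}")

    (out / "truth.tsv").write_text("\n".join(manifest) + "\n")
    if plant_annotations:
        (out / "annotations.tsv").write_text("\n".join(ann_rows) + "\n")
    return out
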