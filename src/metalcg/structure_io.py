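"""Structure parsing and metal-site extraction with quality filters.

PDB and mmCIF files are read with :mod:`gemmi`.  Candidate metal sites are
the non-clustered metal HETATM ions of entries with at least 20 SEQRES
amino acids; site-level filters enforce best alternate locations, sane
ligand-ligand distances (1.5-6.0 A), no symmetry copies outside the
declared assembly, and a non-water ligand majority.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .params import DetectionConfig

__all__ = [
    "AtomRecord",
    "StructureEntry",
    "MetalSite",
    "FilterResult",
    "parse_structure",
    "find_metal_sites",
    "apply_site_filters",
    "site_table_tsv",
    "ParseError",
    "EmptyEntryError",
]

_WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

# metals the pipeline analyses by default; others are still recognised as
# metals for the cluster filter
_METAL_ELEMENTS = frozenset(
    {
        "LI", "NA", "K", "RB", "CS", "BE", "MG", "CA", "SR", "BA", "MN",
        "FE", "CO", "NI", "CU", "ZN", "CD", "HG", "AL", "GA", "V", "CR",
        "MO", "W", "PB", "PT", "AU", "AG", "TL", "Y", "LA", "CE", "PR",
        "SM", "EU", "GD", "TB", "DY", "HO", "ER", "YB", "LU", "IR", "RH",
        "PD", "OS", "RU", "SB", "BI", "IN",
    }
)


class ParseError(ValueError):
    """The structure file could not be read."""


class EmptyEntryError(ValueError):
    """The structure file contains no atom coordinates."""


@dataclass(eq=False)  # identity semantics: atoms are unique physical records
class AtomRecord:
    """One atom of a structure, with the flags the site filters consume."""

    element: str
    coords: np.ndarray
    residue_name: str
    residue_id: str  # chain + sequence number + insertion code
    atom_name: str = ""
    alt_loc: str = ""
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_water: bool = False
    is_symmetry_copy: bool = False
    is_polymer: bool = False
    in_assembly: bool = True

    def distance_to(self, point: Sequence[float]) -> float:
        return float(np.linalg.norm(self.coords - np.asarray(point, dtype=float)))


@dataclass
class StructureEntry:
    """A parsed structure entry: atoms, metals and entry-level metadata."""

    entry_id: str
    resolution: float
    method: str
    seqres_length: int
    atoms: list[AtomRecord]
    metals: list[tuple[str, np.ndarray, str]]  # element, coords, site tag
    assembly_info: dict[str, bool] = field(default_factory=dict)
    exclusion_reason: str = ""


@dataclass
class MetalSite:
    """One metal ion with its candidate and accepted ligand atoms."""

    site_id: str
    metal_element: str
    metal_coords: np.ndarray
    resolution: float
    entry_id: str = ""
    candidate_atoms: list[AtomRecord] = field(default_factory=list)
    #: refined classification pool: whitelisted atoms within the updated
    #: cutoff after the triangular rule (set by ligand detection)
    shell_atoms: list[AtomRecord] = field(default_factory=list)
    ligand_atoms: list[AtomRecord] = field(default_factory=list)
    exclusion_reason: str = ""

    @property
    def dentation_map(self) -> dict[str, int]:
        """Ligand-atom count contributed by each residue."""
        out: dict[str, int] = {}
        for a in self.ligand_atoms:
            out[a.residue_id] = out.get(a.residue_id, 0) + 1
        return out

    @property
    def is_bidentate(self) -> bool:
        return any(n >= 2 for n in self.dentation_map.values())


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reasons: tuple[str, ...]
    atoms: tuple[AtomRecord, ...]

    @property
    def reason(self) -> str:
        return self.reasons[0] if self.reasons else ""


def _seqres_length(st: gemmi.Structure) -> int:
    total = 0
    for entity in st.entities:
        if entity.entity_type == gemmi.EntityType.Polymer and entity.full_sequence:
            total += len(entity.full_sequence) * max(1, len(entity.subchains))
    if total:
        return total
    # entries without SEQRES metadata: fall back to modelled polymer residues
    if len(st) == 0:
        return 0
    count = 0
    for chain in st[0]:
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            if info and info.is_amino_acid():
                count += 1
    return count


def parse_structure(path: str | Path, nmr_resolution: float = 2.5) -> StructureEntry:
    """Parse a PDB or mmCIF file into a :class:`StructureEntry`.

    NMR entries (or any entry without a stated resolution) are assigned
    ``nmr_resolution`` (2.5 A by default).  Missing occupancies default to
    1.0.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such structure file: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path.name}: {exc}") from exc
    st.setup_entities()

    method = st.info["_exptl.method"] if "_exptl.method" in st.info else ""
    resolution = float(st.resolution) if st.resolution else 0.0
    if resolution <= 0.0:
        resolution = nmr_resolution

    if len(st) == 0:
        raise EmptyEntryError(f"{path.name}: no models with coordinates")
    model = st[0]

    atoms: list[AtomRecord] = []
    metals: list[tuple[str, np.ndarray, str]] = []
    n_atoms = 0
    for chain in model:
        for res in chain:
            is_water = res.name in _WATER_NAMES
            res_info = gemmi.find_tabulated_residue(res.name)
            is_polymer = bool(
                res_info
                and (res_info.is_amino_acid() or res_info.is_nucleic_acid())
            )
            for atom in res:
                n_atoms += 1
                el = atom.element.name.upper()
                coords = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                occ = atom.occ if atom.occ > 0 else 1.0
                rid = f"{chain.name}.{res.seqid.num}{res.seqid.icode}".strip()
                if el in _METAL_ELEMENTS and not is_polymer:
                    metals.append(
                        (atom.element.name, coords, f"{chain.name}.{res.seqid.num}")
                    )
                    continue
                if el == "H" or el == "D":
                    continue
                atoms.append(
                    AtomRecord(
                        element=atom.element.name,
                        coords=coords,
                        residue_name=res.name,
                        residue_id=rid,
                        atom_name=atom.name,
                        alt_loc=atom.altloc or "",
                        occupancy=float(occ),
                        b_factor=float(atom.b_iso),
                        is_water=is_water,
                        is_polymer=is_polymer,
                    )
                )
    if n_atoms == 0:
        raise EmptyEntryError(f"{path.name}: no atom records")

    entry_id = path.stem or st.name.strip()
    return StructureEntry(
        entry_id=entry_id,
        resolution=resolution,
        method=method,
        seqres_length=_seqres_length(st),
        atoms=atoms,
        metals=metals,
    )


def find_metal_sites(
    entry: StructureEntry,
    metals: Iterable[str] | None = None,
    config: DetectionConfig | None = None,
) -> list[MetalSite]:
    """Extract candidate metal sites after entry-level filters.

    Entries with fewer than 20 SEQRES amino acids yield no sites.  Any two
    metal atoms within 3 A of each other form a metal cluster and both are
    excluded.  The remaining metals of the requested elements become
    :class:`MetalSite` records; excluded metals are returned with an
    ``exclusion_reason`` so that site counts remain auditable.
    """
    config = config or DetectionConfig()
    wanted = {m.capitalize() for m in metals} if metals is not None else None

    if entry.seqres_length < config.min_seqres_length:
        entry.exclusion_reason = "short-seqres"
        return []

    n = len(entry.metals)
    clustered = [False] * n
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(entry.metals[i][1] - entry.metals[j][1]))
            if d < config.metal_cluster_distance:
                clustered[i] = clustered[j] = True

    sites: list[MetalSite] = []
    for (element, coords, tag), is_clustered in zip(entry.metals, clustered):
        if wanted is not None and element.capitalize() not in wanted:
            continue
        site = MetalSite(
            site_id=f"{entry.entry_id}.{tag}",
            metal_element=element.capitalize(),
            metal_coords=coords,
            resolution=entry.resolution,
            entry_id=entry.entry_id,
            exclusion_reason="metal-cluster" if is_clustered else "",
        )
        sites.append(site)
    return sites


def _best_alternates(atoms: Sequence[AtomRecord]) -> list[AtomRecord]:
    """Keep only the best alternate location per (residue, atom name).

    Best = highest occupancy, ties broken by alphabetically first altloc.
    Atoms without alternates pass through unchanged.
    """
    groups: dict[tuple[str, str], list[AtomRecord]] = {}
    order: list[tuple[str, str]] = []
    for a in atoms:
        key = (a.residue_id, a.atom_name or str(id(a)))
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(a)
    out = []
    for key in order:
        group = groups[key]
        out.append(min(group, key=lambda a: (-a.occupancy, a.alt_loc)))
    return out


def apply_site_filters(
    site: MetalSite,
    atom_set: Sequence[AtomRecord],
    config: DetectionConfig | None = None,
) -> FilterResult:
    """Apply the four site-level quality filters to a candidate atom set.

    Filters (evaluated on the alternate-reduced set, all reasons reported):

    * ``bad-pair-distance`` -- some ligand-ligand distance < 1.5 A or > 6.0 A
    * ``symmetry`` -- a symmetry copy outside the declared assembly whose
      copies are not all water
    * ``water-majority`` -- strictly more than half of the atoms are water
    """
    config = config or DetectionConfig()
    if not atom_set:
        raise ValueError("empty candidate atom set")
    atoms = _best_alternates(atom_set)

    reasons = []
    n = len(atoms)
    bad_pair = False
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(atoms[i].coords - atoms[j].coords))
            if d < config.pair_distance_min or d > config.pair_distance_max:
                bad_pair = True
    if bad_pair:
        reasons.append("bad-pair-distance")

    sym = [a for a in atoms if a.is_symmetry_copy and not a.in_assembly]
    if sym and not all(a.is_water for a in sym):
        reasons.append("symmetry")

    n_water = sum(a.is_water for a in atoms)
    if 2 * n_water > n:
        reasons.append("water-majority")

    return FilterResult(
        passed=not reasons, reasons=tuple(sorted(reasons)), atoms=tuple(atoms)
    )


def site_table_tsv(sites: Iterable[MetalSite]) -> str:
    """Site summary table (TSV): id, metal, resolution, counts, exclusion."""
    lines = ["site_id\tmetal\tresolution\tn_candidates\tn_ligands\texclusion_reason"]
    for s in sites:
        lines.append(
            f"{s.site_id}\t{s.metal_element}\t{s.resolution:.2f}\t"
            f"{len(s.candidate_atoms)}\t{len(s.ligand_atoms)}\t{s.exclusion_reason}"
        )
    return "\n".join(lines) + "\n"
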