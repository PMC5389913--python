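"""Canonical coordination-geometry (CG) models and the 6-angle-space reduction.

A metal site's first coordination shell is described by the multiset of
ligand-metal-ligand angles.  Eighteen canonical CG models are defined here:
seven "major" geometries (tetrahedral through square antiprismatic) and
eleven "minor" geometries obtained by deleting ligand positions from a major
one.  Every model carries ideal unit-vector ligand positions from which its
ideal angle multiset is computed.

To compare shells with different coordination numbers, the full angle
multiset is reduced to six representative angles: the largest angle, the
smallest angle sharing no ligand with it (the smallest *opposite* angle),
and four order statistics of the remaining *middle* angles (smallest, 33rd
quantile, 66th quantile, largest).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

__all__ = [
    "AngleProfile",
    "CanonicalCG",
    "SixAngleVector",
    "angles_from_positions",
    "six_angle_reduction",
    "list_canonical_cgs",
    "get_cg",
    "ordered_angle_vector",
    "cg_table_tsv",
    "DegenerateInputError",
    "InvalidCoordinateError",
    "NotReducibleError",
]


class DegenerateInputError(ValueError):
    """Fewer ligand positions than the operation requires."""


class InvalidCoordinateError(ValueError):
    """A ligand position coincides with the metal center."""


class NotReducibleError(ValueError):
    """No opposite angle exists, so the 6-angle reduction is undefined."""


@dataclass(frozen=True)
class AngleProfile:
    """All pairwise ligand-metal-ligand angles of one shell.

    ``angles`` holds ``(degrees, (i, j))`` tuples for every ligand index
    pair i < j.  ``smallest_pair_elements`` and ``smallest_is_bidentate``
    are optional annotations used downstream by the compressed-angle
    classifier; they stay None when the profile was built from bare
    coordinates.
    """

    angles: tuple[tuple[float, tuple[int, int]], ...]
    smallest_pair_elements: tuple[str, str] | None = None
    smallest_is_bidentate: bool | None = None

    @property
    def n_ligands(self) -> int:
        return max(max(p) for _, p in self.angles) + 1

    @property
    def smallest_angle(self) -> float:
        return min(a for a, _ in self.angles)

    @property
    def smallest_pair(self) -> tuple[int, int]:
        return min(self.angles, key=lambda t: (t[0], t[1]))[1]

    def values(self) -> np.ndarray:
        return np.array([a for a, _ in self.angles])


@dataclass(frozen=True)
class SixAngleVector:
    """Reduced 6-angle representation of a coordination shell."""

    largest: float
    smallest_middle: float
    q33_middle: float
    q66_middle: float
    largest_middle: float
    smallest_opposite: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.largest,
                self.smallest_middle,
                self.q33_middle,
                self.q66_middle,
                self.largest_middle,
                self.smallest_opposite,
            ]
        )

    @staticmethod
    def component_names() -> tuple[str, ...]:
        return (
            "largest",
            "smallest_middle",
            "q33_middle",
            "q66_middle",
            "largest_middle",
            "smallest_opposite",
        )


@dataclass(frozen=True)
class CanonicalCG:
    """One ideal coordination-geometry model.

    ``ideal_positions`` are unit vectors from the metal center.  For a minor
    CG, ``parent_major`` names the major model it derives from and
    ``removed_vertices`` the parent position indices deleted; a major CG is
    its own parent.
    """

    code: str
    name: str
    coordination_number: int
    ideal_positions: tuple[tuple[float, float, float], ...]
    parent_major: str
    removed_vertices: tuple[int, ...] = ()
    is_major: bool = field(default=False)

    @property
    def ideal_angles(self) -> np.ndarray:
        """Sorted multiset of ideal pairwise angles in degrees."""
        prof = angles_from_positions(self.ideal_positions, (0.0, 0.0, 0.0))
        return np.sort(prof.values())

    def angle_profile(self) -> AngleProfile:
        return angles_from_positions(self.ideal_positions, (0.0, 0.0, 0.0))

    def six_angle_vector(self) -> SixAngleVector:
        return six_angle_reduction(self.angle_profile())


def angles_from_positions(
    positions: Sequence[Sequence[float]], center: Sequence[float]
) -> AngleProfile:
    """Compute all C(n,2) ligand-metal-ligand angles in degrees.

    Raises ``DegenerateInputError`` for fewer than two positions and
    ``InvalidCoordinateError`` when a position coincides with the center.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[0] < 2:
        raise DegenerateInputError("need at least 2 ligand positions")
    vecs = pos - np.asarray(center, dtype=float)
    norms = np.linalg.norm(vecs, axis=1)
    if np.any(norms < 1e-12):
        raise InvalidCoordinateError("ligand position coincides with metal center")
    units = vecs / norms[:, None]
    angles = []
    for i, j in combinations(range(len(units)), 2):
        c = float(np.clip(units[i] @ units[j], -1.0, 1.0))
        angles.append((math.degrees(math.acos(c)), (i, j)))
    return AngleProfile(angles=tuple(angles))


def _nearest_rank(q: float, m: int) -> int:
    # nearest-rank index on an ascending list of m values, half rounds up
    return int(math.floor(q * (m - 1) + 0.5))


def six_angle_reduction(profile: AngleProfile) -> SixAngleVector:
    """Reduce a full angle profile to the 6-angle representation.

    The largest angle anchors the shell's orientation (ties broken by the
    lexicographically smallest ligand-index pair).  Opposite angles share no
    ligand with the largest; the smallest of them is kept.  The remaining
    middle angles are sorted ascending and sampled at the nearest-rank
    positions {0, 0.33, 0.66, 1}.
    """
    angs = sorted(profile.angles, key=lambda t: (-t[0], t[1]))
    largest, largest_pair = angs[0]
    opposite = [
        (a, p) for a, p in profile.angles if not (set(p) & set(largest_pair))
    ]
    if not opposite:
        raise NotReducibleError(
            "no angle shares zero ligands with the largest angle"
        )
    smallest_opp, opp_pair = min(opposite, key=lambda t: (t[0], t[1]))
    middles = sorted(
        a
        for k, (a, p) in enumerate(profile.angles)
        if (a, p) != (largest, largest_pair) and (a, p) != (smallest_opp, opp_pair)
    )
    m = len(middles)
    if m == 0:
        raise NotReducibleError("no middle angles available")
    return SixAngleVector(
        largest=largest,
        smallest_middle=middles[0],
        q33_middle=middles[_nearest_rank(0.33, m)],
        q66_middle=middles[_nearest_rank(0.66, m)],
        largest_middle=middles[-1],
        smallest_opposite=smallest_opp,
    )


def ordered_angle_vector(profile: AngleProfile) -> np.ndarray:
    """Full ordered angle vector: largest, ascending middles, smallest opposite.

    This ordering anchors the shell orientation at the vector ends and sorts
    the middles, so two shells of equal coordination number can be compared
    component-wise without an all-to-all ligand mapping.
    """
    angs = sorted(profile.angles, key=lambda t: (-t[0], t[1]))
    largest, largest_pair = angs[0]
    opposite = [(a, p) for a, p in profile.angles if not (set(p) & set(largest_pair))]
    if not opposite:
        raise NotReducibleError("no opposite angle exists")
    smallest_opp, opp_pair = min(opposite, key=lambda t: (t[0], t[1]))
    middles = sorted(
        a
        for a, p in profile.angles
        if (a, p) != (largest, largest_pair) and (a, p) != (smallest_opp, opp_pair)
    )
    return np.array([largest] + middles + [smallest_opp])


# ---------------------------------------------------------------------------
# ideal position constructions
# ---------------------------------------------------------------------------

_S3 = 1.0 / math.sqrt(3.0)


def _ring(n: int, radius: float, z: float, phase_deg: float = 0.0):
    out = []
    for k in range(n):
        phi = math.radians(phase_deg + 360.0 * k / n)
        out.append((radius * math.cos(phi), radius * math.sin(phi), z))
    return out


def _tet():
    return [
        (_S3, _S3, _S3),
        (_S3, -_S3, -_S3),
        (-_S3, _S3, -_S3),
        (-_S3, -_S3, _S3),
    ]


def _bipyramid(n_eq: int):
    # axial pair first, then the equatorial ring
    return [(0.0, 0.0, 1.0), (0.0, 0.0, -1.0)] + _ring(n_eq, 1.0, 0.0)


def _oct():
    return [
        (0.0, 0.0, 1.0),
        (0.0, 0.0, -1.0),
        (1.0, 0.0, 0.0),
        (-1.0, 0.0, 0.0),
        (0.0, 1.0, 0.0),
        (0.0, -1.0, 0.0),
    ]


def _tpr():
    # eclipsed triangular prism; ring radius sqrt(2/3), half-height 1/sqrt(3)
    # gives the 70.5 / 90 / 131.8 ideal angle multiset
    a = math.sqrt(2.0 / 3.0)
    return _ring(3, a, _S3) + _ring(3, a, -_S3)


def _sqa():
    # square antiprism; same radius/height as the prism reproduces the
    # 70.5 / 82 / 109.5 / 143.6 multiset
    a = math.sqrt(2.0 / 3.0)
    return _ring(4, a, _S3) + _ring(4, a, -_S3, phase_deg=45.0)


def _minor(parent_positions, removed: tuple[int, ...]):
    return [p for i, p in enumerate(parent_positions) if i not in removed]


def _build_registry() -> dict[str, CanonicalCG]:
    tbp = _bipyramid(3)
    oct_ = _oct()
    pbp = _bipyramid(5)
    hbp = _bipyramid(6)
    tpr = _tpr()
    sqa = _sqa()

    def major(code, name, pos):
        return CanonicalCG(
            code=code,
            name=name,
            coordination_number=len(pos),
            ideal_positions=tuple(tuple(p) for p in pos),
            parent_major=code,
            is_major=True,
        )

    def minor(code, name, parent_code, parent_pos, removed):
        pos = _minor(parent_pos, removed)
        return CanonicalCG(
            code=code,
            name=name,
            coordination_number=len(pos),
            ideal_positions=tuple(tuple(p) for p in pos),
            parent_major=parent_code,
            removed_vertices=tuple(removed),
        )

    models = [
        # 4-ligand
        major("Tet", "tetrahedral", _tet()),
        minor("Bva", "trigonal bipyramidal vacancy axial", "Tbp", tbp, (1,)),
        minor("Bvp", "trigonal bipyramidal vacancy planar", "Tbp", tbp, (2,)),
        minor("Pyv", "square pyramidal vacancy", "Oct", oct_, (1, 5)),
        minor("Spl", "square planar", "Oct", oct_, (0, 1)),
        # 5-ligand
        major("Tbp", "trigonal bipyramidal", tbp),
        minor("Spy", "square pyramidal", "Oct", oct_, (1,)),
        minor("Tpv", "trigonal prismatic vacancy", "Tpr", tpr, (5,)),
        # 6-ligand
        major("Oct", "octahedral", oct_),
        minor("Pva", "pentagonal bipyramidal vacancy axial", "Pbp", pbp, (1,)),
        minor("Pvp", "pentagonal bipyramidal vacancy planar", "Pbp", pbp, (2,)),
        major("Tpr", "trigonal prismatic", tpr),
        # 7-ligand
        major("Pbp", "pentagonal bipyramidal", pbp),
        minor("Hva", "hexagonal bipyramidal vacancy axial", "Hbp", hbp, (1,)),
        minor("Hvp", "hexagonal bipyramidal vacancy planar", "Hbp", hbp, (2,)),
        minor("Sav", "square antiprismatic vacancy", "Sqa", sqa, (7,)),
        # 8-ligand
        major("Hbp", "hexagonal bipyramidal", hbp),
        major("Sqa", "square antiprismatic", sqa),
    ]
    ordered = sorted(models, key=lambda m: (m.coordination_number, m.code))
    return {m.code: m for m in ordered}


_REGISTRY = _build_registry()

#: models used in the first bootstrap round of ligand detection
BOOTSTRAP_CODES = ("Tet", "Tbp", "Oct", "Pbp")

#: models whose angle correlation matrix is ill-conditioned; the chi-square
#: fit treats their components as independent with a 1.5 variance multiplier
INDEPENDENT_MODE_CODES = ("Tpr", "Tpv", "Sqa", "Sav", "Hbp", "Hva", "Hvp")


def list_canonical_cgs() -> list[CanonicalCG]:
    """All 18 canonical CG models, ordered by coordination number then code."""
    return list(_REGISTRY.values())


def get_cg(code: str) -> CanonicalCG:
    try:
        return _REGISTRY[code]
    except KeyError:
        raise KeyError(f"unknown canonical CG code: {code!r}") from None


def cg_table_tsv() -> str:
    """The model table (code, name, n, ideal angles) as a TSV string."""
    lines = ["code\tname\tcoordination_number\tideal_angles"]
    for m in list_canonical_cgs():
        angles = ", ".join(f"{a:.1f}" for a in m.ideal_angles)
        lines.append(f"{m.code}\t{m.name}\t{m.coordination_number}\t{angles}")
    return "\n".join(lines) + "\n"
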