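"""Chi-square classification of metal sites against canonical CG models.

Each coordination shell is reduced to an *ordered* angle vector (largest
angle, ascending middle angles, smallest opposite angle) so that shells of
equal coordination number are component-wise comparable without an
all-to-all ligand mapping.  A chi-square statistic measures the deviation
of the observed vector (optionally extended with per-ligand bond lengths)
from a model's means.  Two variants exist:

* correlated mode -- Mahalanobis form with the estimated angle covariance,
  plus independent bond-length z-square terms;
* independent mode -- plain z-square sum with a 1.5 variance multiplier,
  used for the prism/antiprism family (Tpr, Sqa, Hbp and their minors)
  whose angle correlation matrices are too ill-conditioned to invert
  reliably, and as an automatic fallback on singular covariances.

The model with the highest upper-tail chi-square probability wins.  Model
statistics are refined iteratively: classify all sites, re-estimate per-CG
means and correlations, repeat until the statistics converge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .cg_models import (
    INDEPENDENT_MODE_CODES,
    CanonicalCG,
    NotReducibleError,
    angles_from_positions,
    get_cg,
    list_canonical_cgs,
    ordered_angle_vector,
)
from .params import DetectionConfig
from .structure_io import AtomRecord, MetalSite, apply_site_filters

logger = logging.getLogger(__name__)

__all__ = [
    "CGModelStats",
    "CGFit",
    "SiteClassification",
    "chi2_fit",
    "classify_site",
    "iterate_statistics",
    "characterize_cluster",
    "ideal_model_stats",
    "six_angle_model_stats",
]

#: prior angle standard deviation (degrees) for ideal-model statistics
DEFAULT_ANGLE_SD = 5.0


@dataclass
class CGModelStats:
    """Angle statistics of one CG model in a fixed ordering convention.

    ``angle_cov`` is None in independent mode, where per-component
    variances ``angle_vars`` (multiplied by 1.5 inside the fit) are used
    instead.
    """

    cg_code: str
    angle_means: np.ndarray
    angle_vars: np.ndarray
    angle_cov: np.ndarray | None = None
    independent_mode: bool = False
    variance_multiplier: float = 1.5
    n_members: int = 0

    @property
    def dim(self) -> int:
        return len(self.angle_means)


@dataclass(frozen=True)
class CGFit:
    cg_code: str
    chi2: float
    dof: int
    probability: float


@dataclass
class SiteClassification:
    site_id: str
    fit: CGFit | None
    ligands: tuple[AtomRecord, ...] = ()
    ordered_angles: np.ndarray | None = None

    @property
    def cg_code(self) -> str | None:
        return self.fit.cg_code if self.fit else None


def _ideal_stats_for(
    model: CanonicalCG, means: np.ndarray, angle_sd: float
) -> CGModelStats:
    independent = model.code in INDEPENDENT_MODE_CODES
    return CGModelStats(
        cg_code=model.code,
        angle_means=means,
        angle_vars=np.full(len(means), angle_sd**2),
        angle_cov=None,
        independent_mode=independent,
    )


def ideal_model_stats(angle_sd: float = DEFAULT_ANGLE_SD) -> dict[str, CGModelStats]:
    """Prior statistics for all 18 models in the full ordered-angle space."""
    out = {}
    for m in list_canonical_cgs():
        means = ordered_angle_vector(m.angle_profile())
        out[m.code] = _ideal_stats_for(m, means, angle_sd)
    return out


def six_angle_model_stats(
    angle_sd: float = DEFAULT_ANGLE_SD,
    coordination_numbers: Iterable[int] | None = None,
) -> dict[str, CGModelStats]:
    """Prior statistics in the reduced 6-angle space.

    Used for characterising k-means clusters, whose members live in the
    6-angle space.  ``coordination_numbers`` restricts the models, e.g. to
    the 6-ligand family when characterising 6-ligand clusters.
    """
    wanted = set(coordination_numbers) if coordination_numbers is not None else None
    out = {}
    for m in list_canonical_cgs():
        if wanted is not None and m.coordination_number not in wanted:
            continue
        means = m.six_angle_vector().as_array()
        out[m.code] = _ideal_stats_for(m, means, angle_sd)
    return out


def chi2_fit(
    angles: Sequence[float],
    model: CGModelStats,
    bond_lengths: Sequence[float] | None = None,
    bond_means: Sequence[float] | None = None,
    bond_sds: Sequence[float] | None = None,
) -> CGFit:
    """Chi-square fit of an ordered angle (+ bond length) vector to a model.

    Bond lengths enter as independent z-square terms with their per-element
    means and (resolution-adjusted) sds.  dof is the total vector length.
    """
    x = np.asarray(angles, dtype=float)
    if x.shape != model.angle_means.shape:
        raise ValueError(
            f"dimension mismatch: {x.shape} vs model {model.angle_means.shape}"
        )
    d = x - model.angle_means

    independent = model.independent_mode
    chi2 = 0.0
    if not independent and model.angle_cov is not None:
        try:
            solved = np.linalg.solve(model.angle_cov, d)
            chi2 = float(d @ solved)
            if chi2 < 0:  # numerically indefinite covariance
                raise np.linalg.LinAlgError("indefinite covariance")
        except np.linalg.LinAlgError:
            logger.warning(
                "singular covariance for %s; falling back to independent mode",
                model.cg_code,
            )
            independent = True
    elif not independent:
        # correlated mode requested but no covariance estimated yet
        chi2 = float(np.sum(d**2 / model.angle_vars))

    if independent:
        chi2 = float(np.sum(d**2 / (model.variance_multiplier * model.angle_vars)))

    n_bonds = 0
    if bond_lengths is not None:
        bl = np.asarray(bond_lengths, dtype=float)
        bm = np.asarray(bond_means, dtype=float)
        bs = np.asarray(bond_sds, dtype=float)
        z2 = (bl - bm) ** 2 / bs**2
        if independent:
            z2 = z2 / model.variance_multiplier
        chi2 += float(np.sum(z2))
        n_bonds = len(bl)

    dof = len(x) + n_bonds
    prob = float(sps.chi2.sf(chi2, dof))
    return CGFit(cg_code=model.cg_code, chi2=chi2, dof=dof, probability=prob)


def _model_sizes(stats_by_cg: Mapping[str, CGModelStats]) -> dict[int, list[str]]:
    sizes: dict[int, list[str]] = {}
    for code in stats_by_cg:
        cn = get_cg(code).coordination_number
        sizes.setdefault(cn, []).append(code)
    return sizes


def classify_site(
    site: MetalSite,
    stats_by_cg: Mapping[str, CGModelStats],
    small_angle_cut: float,
    config: DetectionConfig | None = None,
    bond_stats: Mapping[str, tuple[float, float]] | None = None,
) -> SiteClassification:
    """Best CG model over all viable ligand combinations of a site.

    Combinations containing any angle below the metal-specific small-angle
    cutoff are discarded, as are combinations failing the site-level
    quality filters.  ``bond_stats`` maps element to (mean, adjusted sd)
    for the bond-length terms; omit it to fit on angles alone.

    The largest viable combination is preferred: the coordination number
    is fixed by ligand detection, and dropping atoms is only warranted
    when a combination fails the angle or quality filters.  (A minor CG's
    ideal positions are a strict subset of its parent's, so a bare
    highest-probability rule over all subset sizes would systematically
    re-assign noisy major-CG shells to their own minor-CG subsets, which
    fit fewer degrees of freedom.)  Within a size the highest chi-square
    probability wins; remaining ties break toward the alphabetically
    first model code.
    """
    config = config or DetectionConfig()
    # combinations are searched over the refined cutoff shell when
    # detection provides one: an atom the per-ligand z test dropped is
    # still within the cutoff and may complete the best-fitting shell
    atoms = site.shell_atoms or site.ligand_atoms or site.candidate_atoms
    sizes = _model_sizes(stats_by_cg)

    best: tuple[int, float, str] | None = None  # (size, prob, code) ordering key
    best_fit: CGFit | None = None
    best_combo: tuple[AtomRecord, ...] = ()
    best_angles: np.ndarray | None = None

    for size, codes in sorted(sizes.items()):
        if len(atoms) < size:
            continue
        for combo in combinations(atoms, size):
            prof = angles_from_positions([a.coords for a in combo], site.metal_coords)
            if prof.smallest_angle < small_angle_cut:
                continue
            if not apply_site_filters(site, combo, config).passed:
                continue
            try:
                ordered = ordered_angle_vector(prof)
            except NotReducibleError:
                continue
            bl = bm = bs = None
            if bond_stats is not None:
                try:
                    bl = [a.distance_to(site.metal_coords) for a in combo]
                    bm = [bond_stats[a.element][0] for a in combo]
                    bs = [bond_stats[a.element][1] for a in combo]
                except KeyError:
                    continue
            for code in codes:
                fit = chi2_fit(ordered, stats_by_cg[code], bl, bm, bs)
                key = (size, fit.probability, code)
                if best is None or (key[0], key[1], _neg_code(key[2])) > (
                    best[0],
                    best[1],
                    _neg_code(best[2]),
                ):
                    best = key
                    best_fit = fit
                    best_combo = combo
                    best_angles = ordered
    return SiteClassification(
        site_id=site.site_id,
        fit=best_fit,
        ligands=best_combo,
        ordered_angles=best_angles,
    )


def _neg_code(code: str) -> tuple[int, ...]:
    # make alphabetically-earlier codes win under max()
    return tuple(-ord(c) for c in code)


def iterate_statistics(
    sites: Sequence[MetalSite],
    small_angle_cuts: Mapping[str, float] | float,
    initial_stats: Mapping[str, CGModelStats] | None = None,
    config: DetectionConfig | None = None,
    bond_stats_for: Mapping[str, Mapping[str, tuple[float, float]]] | None = None,
    angle_tol: float = 0.1,
    max_iter: int = 50,
    min_members_factor: int = 3,
    mean_anchor_tol: float = 10.0,
    cov_eig_floor: float = 0.25,
) -> tuple[dict[str, CGModelStats], list[SiteClassification]]:
    """Alternate classify-all / re-estimate until the statistics converge.

    Per-CG angle means, variances and (with >= 3*dim members) covariances
    are recomputed from the sites classified to each model; a model whose
    class empties reverts to its ideal prior.  Convergence: the largest
    absolute change of any angle mean falls below ``angle_tol`` degrees
    (or the assignment state repeats).  Deterministic given input order.

    Two stabilisers keep the refinement honest.  A class whose estimated
    mean drifts more than ``mean_anchor_tol`` degrees from its ideal
    geometry reverts to the prior: a CG class is defined by its canonical
    polyhedron, and a class hijacked by outliers of a *different* geometry
    would otherwise adapt to them and snowball.  Estimated covariances
    have their eigenvalues floored at ``cov_eig_floor`` (degrees squared):
    ordered angle vectors carry near-deterministic linear relations whose
    tiny eigenvalues would dominate the Mahalanobis distance.
    """
    config = config or DetectionConfig()
    priors = ideal_model_stats()
    current: dict[str, CGModelStats] = dict(initial_stats or priors)

    def cut_for(site: MetalSite) -> float:
        if isinstance(small_angle_cuts, Mapping):
            return small_angle_cuts.get(site.metal_element, 0.0)
        return float(small_angle_cuts)

    classifications: list[SiteClassification] = []
    seen_assignments: set[tuple] = set()
    for iteration in range(1, max_iter + 1):
        classifications = []
        members: dict[str, list[np.ndarray]] = {code: [] for code in current}
        for site in sites:
            bond_stats = (
                bond_stats_for.get(site.metal_element) if bond_stats_for else None
            )
            cls = classify_site(site, current, cut_for(site), config, bond_stats)
            classifications.append(cls)
            if cls.fit is not None and cls.ordered_angles is not None:
                members[cls.fit.cg_code].append(cls.ordered_angles)

        max_shift = 0.0
        new_stats: dict[str, CGModelStats] = {}
        for code, vecs in members.items():
            prior = priors[code]
            if not vecs:
                new_stats[code] = prior
                shift = float(np.max(np.abs(current[code].angle_means - prior.angle_means)))
                max_shift = max(max_shift, shift)
                continue
            arr = np.vstack(vecs)
            means = arr.mean(axis=0)
            if float(np.max(np.abs(means - prior.angle_means))) > mean_anchor_tol:
                # class contaminated by another geometry's sites
                new_stats[code] = prior
                shift = float(
                    np.max(np.abs(current[code].angle_means - prior.angle_means))
                )
                max_shift = max(max_shift, shift)
                continue
            variances = (
                arr.var(axis=0, ddof=1) if len(arr) > 1 else prior.angle_vars.copy()
            )
            variances = np.maximum(variances, 1e-4)
            cov = None
            if (
                not prior.independent_mode
                and len(arr) >= min_members_factor * arr.shape[1]
            ):
                cov = np.cov(arr, rowvar=False)
                w, v = np.linalg.eigh(cov)
                cov = (v * np.maximum(w, cov_eig_floor)) @ v.T
            new_stats[code] = CGModelStats(
                cg_code=code,
                angle_means=means,
                angle_vars=variances,
                angle_cov=cov,
                independent_mode=prior.independent_mode,
                n_members=len(arr),
            )
            shift = float(np.max(np.abs(current[code].angle_means - means)))
            max_shift = max(max_shift, shift)
        current = new_stats
        if max_shift < angle_tol:
            break
        # a repeated assignment state means the iteration entered a limit
        # cycle of borderline sites; the statistics will not move further
        assignment_state = tuple(c.cg_code for c in classifications)
        if assignment_state in seen_assignments:
            break
        seen_assignments.add(assignment_state)
    else:
        logger.warning("statistics did not converge within %d iterations", max_iter)
    return current, classifications


def characterize_cluster(
    cluster_vectors: Sequence[Sequence[float]],
    stats_by_cg: Mapping[str, CGModelStats],
) -> tuple[str, dict[str, float]]:
    """Cluster-level CG: the model with the highest cluster-average probability.

    Each member vector (full ordered angles or the 6-angle reduction,
    matching the space of ``stats_by_cg``) is fitted against every model;
    members whose dimension does not match a model contribute probability 0
    for it.  Returns the winning code and the full average-probability
    table.
    """
    if len(cluster_vectors) == 0:
        raise ValueError("empty cluster")
    table: dict[str, float] = {}
    for code, model in stats_by_cg.items():
        probs = []
        for vec in cluster_vectors:
            v = np.asarray(vec, dtype=float)
            if v.shape != model.angle_means.shape:
                probs.append(0.0)
            else:
                probs.append(chi2_fit(v, model).probability)
        table[code] = float(np.mean(probs))
    best = max(table, key=lambda c: (table[c], _neg_code(c)))
    return best, table
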