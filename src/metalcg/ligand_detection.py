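"""Bootstrap ligand detection and bond-length statistics.

The first coordination shell of a metal ion is found in two bootstrap
rounds.  Round one collects all non-hydrogen atoms (carbon included) within
an atomic-radius-based cutoff, prunes second-shell atoms with the
*triangular rule*, and picks the atom subset that best fits one of the four
common canonical geometries (Tet, Tbp, Oct, Pbp) by angle variance.  The
resulting per-element bond-length statistics calibrate an updated, tighter
cutoff: the midpoint between (most-abundant-element mean + 1 sd) and the
main mode of the fictional metal-carbon distances.  Round two repeats the
search under the updated cutoff with carbon dropped and rare elements
(<= 5% occurrence) removed.

Final acceptance is a per-ligand z test: a bond length is kept when it lies
within 2.5 *resolution-adjusted* standard deviations of its element's mean,

    sd_x = m * (R_x - R_avg) + sd_avg

where m is the combined slope of bond-length sd versus crystallographic
resolution pooled over all metal-element pairs.  Sites whose ligand bond
lengths are *systematically* inflated (average mode-normalized deviation
> 0.91) are flagged as likely metal misassignments and removed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import signal, stats

from .cg_models import (
    BOOTSTRAP_CODES,
    CanonicalCG,
    angles_from_positions,
    get_cg,
)
from .params import DetectionConfig, MetalParams
from .structure_io import AtomRecord, MetalSite, apply_site_filters

logger = logging.getLogger(__name__)

__all__ = [
    "BondLengthStats",
    "BootstrapFit",
    "initial_shell",
    "triangular_rule",
    "bootstrap_canonical_fit",
    "element_bond_stats",
    "updated_upper_cutoff",
    "fit_resolution_slope",
    "resolution_adjusted_sd",
    "ligand_accept",
    "avg_normalized_deviation",
    "detect_modes",
    "estimate_error_rate",
    "InsufficientSampleError",
    "UndefinedRateError",
]


class InsufficientSampleError(ValueError):
    """Too few observations for the requested statistic."""


class UndefinedRateError(ZeroDivisionError):
    """Error-rate denominator is zero."""


@dataclass
class BondLengthStats:
    """Bond-length statistics for one metal-element pair.

    ``sd`` is the overall standard deviation (sd_avg of the resolution
    adjustment), ``slope`` the combined sd-versus-resolution slope, and
    ``r_avg`` the mean crystallographic resolution of contributing entries.
    ``mode`` is the major bond-length mode -- the chemically expected
    monodentate bond length -- with any further modes in ``modes``.
    """

    metal: str
    ligand_element: str
    mean: float
    sd: float
    mode: float
    modes: tuple[float, ...]
    n: int
    r_avg: float
    slope: float = 0.0

    def adjusted_sd(self, site_resolution: float, floor: float = 0.01) -> float:
        return resolution_adjusted_sd(self, site_resolution, floor)


@dataclass(frozen=True)
class BootstrapFit:
    """Best subset/model pair from the bootstrap CG search."""

    ligands: tuple[AtomRecord, ...]
    cg_code: str
    angle_variance: float


def initial_shell(
    site: MetalSite,
    lower: float,
    upper: float,
    atoms: Sequence[AtomRecord] | None = None,
) -> list[AtomRecord]:
    """Non-hydrogen atoms with metal distance in [lower, upper].

    ``atoms`` defaults to the site's candidate atoms; pass the full entry
    atom list when building shells from scratch.
    """
    pool = site.candidate_atoms if atoms is None else atoms
    out = []
    for a in pool:
        d = a.distance_to(site.metal_coords)
        if lower <= d <= upper:
            out.append(a)
    return out


def triangular_rule(
    metal_coords: Sequence[float],
    candidates: Sequence[AtomRecord],
    factor: float = 1.5,
) -> list[AtomRecord]:
    """Drop second-shell atoms sitting "behind" a closer candidate.

    Candidate ``a`` is removed when some other candidate ``b`` satisfies
    both d(M,a) >= factor * d(M,b) and d(M,a) >= factor * d(a,b): the atom
    is much farther from the metal than ``b`` and is covalently close to
    it, so it belongs to the local chemical environment rather than the
    first shell.  Removal is decided against the original candidate set and
    applied simultaneously.
    """
    center = np.asarray(metal_coords, dtype=float)
    dm = [a.distance_to(center) for a in candidates]
    keep = []
    for i, a in enumerate(candidates):
        removed = False
        for j, b in enumerate(candidates):
            if i == j:
                continue
            dab = float(np.linalg.norm(a.coords - b.coords))
            if dm[i] >= factor * dm[j] and dm[i] >= factor * dab:
                removed = True
                break
        if not removed:
            keep.append(a)
    return keep


def bootstrap_canonical_fit(
    site: MetalSite,
    candidates: Sequence[AtomRecord],
    models: Sequence[CanonicalCG] | None = None,
    config: DetectionConfig | None = None,
) -> BootstrapFit | None:
    """Pick the candidate subset best matching a canonical CG.

    Every subset whose size equals a model's coordination number is scored
    by the variance of (sorted observed - sorted ideal) angles; subsets
    failing the site-level quality filters are skipped.  Returns None when
    no subset of any model's size passes the filters.
    """
    config = config or DetectionConfig()
    if models is None:
        models = [get_cg(c) for c in BOOTSTRAP_CODES]
    by_size: dict[int, list[CanonicalCG]] = {}
    for m in models:
        by_size.setdefault(m.coordination_number, []).append(m)

    best: BootstrapFit | None = None
    for size, size_models in sorted(by_size.items()):
        if len(candidates) < size:
            continue
        ideal_sorted = {m.code: np.sort(m.ideal_angles) for m in size_models}
        for subset in combinations(candidates, size):
            result = apply_site_filters(site, subset, config)
            if not result.passed:
                continue
            prof = angles_from_positions(
                [a.coords for a in subset], site.metal_coords
            )
            obs = np.sort(prof.values())
            for m in size_models:
                var = float(np.var(obs - ideal_sorted[m.code]))
                if best is None or var < best.angle_variance - 1e-12:
                    best = BootstrapFit(tuple(subset), m.code, var)
    return best


def element_bond_stats(
    detected: Iterable[tuple[str, str, float, float]],
    config: DetectionConfig | None = None,
) -> tuple[dict[tuple[str, str], BondLengthStats], dict[str, tuple[str, ...]]]:
    """Per metal-element bond-length statistics and element whitelists.

    ``detected`` yields (metal, element, bond length, resolution) records.
    Elements at or below 5% occurrence within a metal are dropped from that
    metal's whitelist; carbon is always dropped from the whitelist but its
    statistics (needed for the cutoff calibration) are retained.
    """
    config = config or DetectionConfig()
    samples: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for metal, element, length, resolution in detected:
        samples.setdefault((metal, element), []).append((length, resolution))

    stats_out: dict[tuple[str, str], BondLengthStats] = {}
    totals: dict[str, int] = {}
    for (metal, element), rows in samples.items():
        lengths = np.array([r[0] for r in rows])
        resolutions = np.array([r[1] for r in rows])
        n = len(lengths)
        totals[metal] = totals.get(metal, 0) + n
        sd = float(np.std(lengths, ddof=1)) if n > 1 else 0.0
        try:
            modes = detect_modes(lengths)
        except InsufficientSampleError:
            modes = (float(np.median(lengths)),)
        stats_out[(metal, element)] = BondLengthStats(
            metal=metal,
            ligand_element=element,
            mean=float(np.mean(lengths)),
            sd=sd,
            mode=modes[0],
            modes=modes,
            n=n,
            r_avg=float(np.mean(resolutions)),
        )

    whitelist: dict[str, tuple[str, ...]] = {}
    for metal, total in totals.items():
        kept = []
        for (m, element), st in stats_out.items():
            if m != metal or element == "C":
                continue
            if st.n / total > config.element_min_fraction:
                kept.append(element)
        whitelist[metal] = tuple(sorted(kept))
    return stats_out, whitelist


def updated_upper_cutoff(
    abundant_mean: float,
    abundant_sd: float,
    carbon_mode: float | None,
    initial_upper: float | None = None,
) -> float:
    """Updated shell cutoff: midpoint of (mean + 1 sd) and the carbon mode.

    The carbon distance mode estimates where accidentally-aligned
    second-shell atoms start to appear; the mean + sd of the most abundant
    true ligand element marks where real ligands end.  Falls back to the
    initial cutoff (with a warning) when no carbon mode is available.
    """
    if abundant_mean <= 0 or abundant_sd <= 0:
        raise ValueError("degenerate bond-length statistics")
    if carbon_mode is None or carbon_mode <= 0:
        if initial_upper is None:
            raise ValueError("no carbon mode and no initial cutoff to fall back on")
        logger.warning("no carbon distance mode; keeping initial cutoff %.3f",
                       initial_upper)
        return initial_upper
    return (abundant_mean + abundant_sd + carbon_mode) / 2.0


def fit_resolution_slope(
    per_resolution_sds: Iterable[tuple[str, str, float, float, int]],
    config: DetectionConfig | None = None,
) -> float:
    """Combined slope of bond-length sd versus crystallographic resolution.

    Each (metal, element, resolution, sd, n) series is first centred by its
    own n-weighted mean sd (putting all pairs on the same level), then the
    centred points with resolution <= 3.5 A and n > 30 are pooled and a
    least-squares line fitted; its slope is returned.
    """
    config = config or DetectionConfig()
    series: dict[tuple[str, str], list[tuple[float, float, int]]] = {}
    for metal, element, resolution, sd, n in per_resolution_sds:
        series.setdefault((metal, element), []).append((resolution, sd, n))

    xs, ys = [], []
    for rows in series.values():
        usable = [
            (r, s, n)
            for r, s, n in rows
            if r <= config.resolution_fit_cap and n > config.min_points_per_resolution
        ]
        if not usable:
            continue
        weights = np.array([n for _, _, n in usable], dtype=float)
        sds = np.array([s for _, s, _ in usable])
        center = float(np.average(sds, weights=weights))
        for r, s, _ in usable:
            xs.append(r)
            ys.append(s - center)
    if len(xs) < 2 or len(set(xs)) < 2:
        raise InsufficientSampleError(
            "fewer than 2 usable resolution bins; cannot fit slope"
        )
    slope = float(np.polyfit(np.array(xs), np.array(ys), 1)[0])
    return slope


def resolution_adjusted_sd(
    stats: BondLengthStats, site_resolution: float, floor: float = 0.01
) -> float:
    """sd_x = m (R_x - R_avg) + sd_avg, floored at a small positive value."""
    sd_x = stats.slope * (site_resolution - stats.r_avg) + stats.sd
    return max(sd_x, floor)


def ligand_accept(
    bond_length: float,
    stats: BondLengthStats | None,
    sd_x: float,
    z_cut: float = 2.5,
) -> tuple[bool, str]:
    """Accept a ligand when its bond length is within z_cut * sd_x of the mean.

    Returns (accepted, reason); reason is "element" for non-whitelisted
    elements (stats is None) and "z" for a failed distance test.
    """
    if stats is None:
        return False, "element"
    if abs(bond_length - stats.mean) <= z_cut * sd_x:
        return True, ""
    return False, "z"


def avg_normalized_deviation(
    lengths: Sequence[float],
    modes: Sequence[float],
    sds: Sequence[float],
    cutoff: float = 0.91,
) -> tuple[float, bool]:
    """Average signed mode-normalized bond-length deviation of one site.

    mean over ligands of (length - mode) / sd, with the per-element major
    mode as the chemically expected value and the resolution-adjusted sd as
    the scale.  A site is flagged as a likely metal misassignment when the
    average exceeds the cutoff (0.91, from the bimodal separation of the Na
    deviation histogram): systematic inflation of *all* bonds indicates a
    smaller ion modelled into a larger ion's density.
    """
    if len(lengths) == 0:
        raise ValueError("no whitelisted ligands; deviation undefined")
    if not (len(lengths) == len(modes) == len(sds)):
        raise ValueError("lengths, modes and sds must align")
    zs = [(l - m) / s for l, m, s in zip(lengths, modes, sds)]
    value = float(np.mean(zs))
    return value, value > cutoff


def detect_modes(
    lengths: Sequence[float],
    min_n: int = 30,
    prominence_fraction: float = 0.05,
    grid_size: int = 512,
) -> tuple[float, ...]:
    """Bond-length modes via Gaussian KDE peaks, major mode first.

    Silverman-bandwidth kernel density is evaluated on a regular grid and
    peaks with prominence >= 5% of the maximum density are reported sorted
    by density height.  A (near-)constant sample has a single mode at its
    value.
    """
    x = np.asarray(lengths, dtype=float)
    if x.size < min_n:
        raise InsufficientSampleError(f"need >= {min_n} values, got {x.size}")
    if np.ptp(x) < 1e-9:
        return (float(x[0]),)
    kde = stats.gaussian_kde(x, bw_method="silverman")
    pad = 3.0 * x.std() * kde.factor
    grid = np.linspace(x.min() - pad, x.max() + pad, grid_size)
    dens = kde(grid)
    peaks, props = signal.find_peaks(dens, prominence=prominence_fraction * dens.max())
    if peaks.size == 0:
        return (float(grid[np.argmax(dens)]),)
    order = np.argsort(dens[peaks])[::-1]
    return tuple(float(grid[p]) for p in peaks[order])


def estimate_error_rate(
    counts: Mapping[int, int], max_valid_n: int
) -> float:
    """Ligand-detection error rate from coordination-number counts.

    Sites with more ligands than the physiochemically valid maximum carry
    (n - max_valid_n) erroneous ligands each; the rate divides those excess
    ligands by all ligands of sites at or above the valid maximum, assuming
    a uniform per-ligand error probability.
    """
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be non-negative")
    numerator = sum(
        c * (n - max_valid_n) for n, c in counts.items() if n > max_valid_n
    )
    denominator = sum(c * n for n, c in counts.items() if n >= max_valid_n)
    if numerator == 0:
        return 0.0
    if denominator == 0:
        raise UndefinedRateError("no ligands at or above the valid maximum")
    return numerator / denominator
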