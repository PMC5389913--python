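"""End-to-end orchestration: detect -> classify -> label -> cluster -> enrich.

``run`` executes the whole workflow on a directory of structure files and
writes one tabular artifact per stage into a run directory; ``report``
aggregates them.  The per-metal detection core (two bootstrap rounds,
cutoff calibration, resolution adjustment, acceptance and misassignment
filters) is exposed as :func:`detect_metal` so that library users and the
test-bench can run it on in-memory sites without file I/O.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import function_analysis as fa
from .cg_classification import SiteClassification, iterate_statistics
from .cg_models import (
    NotReducibleError,
    angles_from_positions,
    six_angle_reduction,
)
from .cluster_analysis import (
    ClusterResult,
    classify_compressed,
    kmeans_six_angle,
    select_k,
    stability_measures,
)
from .ligand_detection import (
    BondLengthStats,
    InsufficientSampleError,
    avg_normalized_deviation,
    bootstrap_canonical_fit,
    detect_modes,
    element_bond_stats,
    fit_resolution_slope,
    initial_shell,
    ligand_accept,
    resolution_adjusted_sd,
    triangular_rule,
    updated_upper_cutoff,
)
from .params import DEFAULT_METALS, DetectionConfig, MetalParams, load_metal_params
from .structure_io import MetalSite, find_metal_sites, parse_structure, site_table_tsv

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "DetectionOutput", "PipelineHalt", "detect_metal",
           "run", "report"]

#: highest physiochemically valid coordination number per metal
DEFAULT_MAX_VALID_N = {"Zn": 6, "Mg": 6, "Ca": 8, "Fe": 6, "Na": 8}


class PipelineHalt(RuntimeError):
    """A stage produced zero surviving records; the run stops cleanly."""

    def __init__(self, stage: str, message: str = ""):
        self.stage = stage
        super().__init__(f"stage '{stage}' left no records" + (f": {message}" if message else ""))


@dataclass
class PipelineConfig:
    metals: tuple[str, ...] = DEFAULT_METALS
    metal_params: dict[str, MetalParams] = field(default_factory=load_metal_params)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    max_valid_n: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_MAX_VALID_N))
    k_values: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    stability_runs: int = 3
    seed: int = 0
    annotations: str | None = None
    parent_map: str | None = None


@dataclass
class DetectionOutput:
    """Result of the per-metal detection core."""

    metal: str
    sites: list[MetalSite]  # surviving sites with final ligand_atoms
    excluded: dict[str, str]  # site_id -> exclusion reason
    bond_stats: dict[str, BondLengthStats]  # element -> stats (round 2)
    whitelist: tuple[str, ...]
    updated_upper: float
    carbon_mode: float | None
    slope: float
    deviations: dict[str, float]  # site_id -> avg normalized deviation

    def coordination_counts(self) -> dict[int, int]:
        return dict(Counter(len(s.ligand_atoms) for s in self.sites))


def _assign_candidates(site: MetalSite, atoms, upper: float) -> None:
    site.candidate_atoms = [
        a for a in atoms if a.distance_to(site.metal_coords) <= upper + 0.5
    ]


def detect_metal(
    sites: Sequence[MetalSite],
    params: MetalParams,
    config: DetectionConfig | None = None,
) -> DetectionOutput:
    """Two-round bootstrap ligand detection for all sites of one metal.

    Round 1 fits candidate shells (carbon included, atomic-radius cutoff)
    to the four common canonical CGs and derives per-element bond-length
    statistics plus the carbon distance mode from the shell carbons.
    Round 2 repeats the search under the recalibrated cutoff with the
    element whitelist.  Final shells are the whitelisted atoms passing the
    2.5-adjusted-sd test; sites with systematically inflated bonds
    (average mode-normalized deviation > 0.91) are removed as likely
    misassignments.
    """
    config = config or DetectionConfig()
    excluded: dict[str, str] = {}
    active: list[MetalSite] = []
    for s in sites:
        if s.exclusion_reason:
            excluded[s.site_id] = s.exclusion_reason
        else:
            active.append(s)
    if not active:
        raise PipelineHalt("site-extraction", params.metal)

    # ---- round 1: atomic-radius shell, carbon included -------------------
    round1: list[tuple[str, str, float, float]] = []
    carbon_dists: list[float] = []
    shells1: dict[str, list] = {}
    for s in active:
        shell = initial_shell(s, params.lower, params.initial_upper)
        shell = triangular_rule(s.metal_coords, shell, config.triangular_factor)
        shells1[s.site_id] = shell
        carbon_dists.extend(
            a.distance_to(s.metal_coords) for a in shell if a.element == "C"
        )
        fit = bootstrap_canonical_fit(s, [a for a in shell], config=config)
        if fit is None:
            continue
        for a in fit.ligands:
            round1.append(
                (params.metal, a.element, a.distance_to(s.metal_coords), s.resolution)
            )
    if not round1:
        raise PipelineHalt("bootstrap-round-1", params.metal)
    stats1, whitelist1 = element_bond_stats(round1, config)
    whitelist = whitelist1.get(params.metal, ())
    if not whitelist:
        raise PipelineHalt("element-whitelist", params.metal)

    abundant = max(
        (st for st in stats1.values() if st.ligand_element != "C"),
        key=lambda st: st.n,
    )
    carbon_mode: float | None
    try:
        carbon_mode = detect_modes(carbon_dists)[0]
    except InsufficientSampleError:
        carbon_mode = params.carbon_mode  # shipped calibration default
        logger.info(
            "%s: too few shell carbons for a mode; using shipped %.3f",
            params.metal, carbon_mode,
        )
    updated = updated_upper_cutoff(
        abundant.mean, max(abundant.sd, 1e-3), carbon_mode, params.initial_upper
    )

    # ---- round 2: updated cutoff, whitelist, no carbon -------------------
    round2: list[tuple[str, str, float, float]] = []
    shells2: dict[str, list] = {}
    for s in active:
        shell = [
            a
            for a in initial_shell(s, params.lower, updated)
            if a.element in whitelist
        ]
        shell = triangular_rule(s.metal_coords, shell, config.triangular_factor)
        shells2[s.site_id] = shell
        fit = bootstrap_canonical_fit(s, shell, config=config)
        ligs = fit.ligands if fit is not None else shell
        for a in ligs:
            round2.append(
                (params.metal, a.element, a.distance_to(s.metal_coords), s.resolution)
            )
    if not round2:
        raise PipelineHalt("bootstrap-round-2", params.metal)
    stats2, _ = element_bond_stats(round2, config)
    by_element = {st.ligand_element: st for st in stats2.values()}

    # ---- resolution slope -------------------------------------------------
    bins: dict[tuple[str, float], list[float]] = {}
    for _, el, dist, res in round2:
        bins.setdefault((el, round(res, 2)), []).append(dist)
    slope_rows = [
        (params.metal, el, res, float(np.std(v, ddof=1)), len(v))
        for (el, res), v in bins.items()
        if len(v) > 1
    ]
    try:
        slope = fit_resolution_slope(slope_rows, config)
    except InsufficientSampleError:
        slope = 0.0
    for st in by_element.values():
        st.slope = slope

    # ---- step 4: per-ligand acceptance + misassignment filter ------------
    # The element statistics feeding the average-deviation filter are
    # re-estimated from the unflagged sites until the flag set stabilises:
    # a contaminated cohort otherwise inflates the scale (and pulls the
    # mode) toward the misassigned sites, masking them.
    from .structure_io import apply_site_filters

    def _accept_site(s, stats_map):
        shell = shells2.get(s.site_id, [])
        accepted = []
        for a in shell:
            st = stats_map.get(a.element)
            if st is None:
                continue
            sd_x = resolution_adjusted_sd(st, s.resolution, config.sd_floor)
            ok, _ = ligand_accept(
                a.distance_to(s.metal_coords), st, sd_x, config.accept_z
            )
            if ok:
                accepted.append(a)
        return accepted

    survivors: list[MetalSite] = []
    deviations: dict[str, float] = {}
    flagged_ids: set[str] = set()
    stats_map = by_element
    for _ in range(10):
        survivors = []
        deviations = {}
        new_flagged: set[str] = set()
        step_excluded: dict[str, str] = {}
        for s in active:
            # misassignment is judged on the whole cutoff shell *before*
            # the per-ligand z test: the z test would censor exactly the
            # inflated bonds the deviation filter needs to see
            shell = [a for a in shells2.get(s.site_id, []) if a.element in stats_map]
            if not shell:
                step_excluded[s.site_id] = "no-ligand"
                continue
            lengths = [a.distance_to(s.metal_coords) for a in shell]
            modes = [stats_map[a.element].mode for a in shell]
            sds = [
                resolution_adjusted_sd(stats_map[a.element], s.resolution,
                                       config.sd_floor)
                for a in shell
            ]
            value, flagged = avg_normalized_deviation(
                lengths, modes, sds, config.misassign_cutoff
            )
            deviations[s.site_id] = value
            if flagged:
                new_flagged.add(s.site_id)
                step_excluded[s.site_id] = "misassigned"
                continue
            accepted = _accept_site(s, stats_map)
            if not accepted:
                step_excluded[s.site_id] = "no-ligand"
                continue
            result = apply_site_filters(s, accepted, config)
            if not result.passed:
                step_excluded[s.site_id] = result.reason
                continue
            s.ligand_atoms = list(result.atoms)
            survivors.append(s)
        if new_flagged == flagged_ids:
            excluded.update(step_excluded)
            break
        flagged_ids = new_flagged
        # refresh the statistics from the currently unflagged shells
        clean_rows = [
            (params.metal, a.element, a.distance_to(s.metal_coords), s.resolution)
            for s in survivors
            for a in s.ligand_atoms
        ]
        if not clean_rows:
            excluded.update(step_excluded)
            break
        clean_stats, _ = element_bond_stats(clean_rows, config)
        stats_map = {st.ligand_element: st for st in clean_stats.values()}
        for st in stats_map.values():
            st.slope = slope
    else:
        excluded.update(step_excluded)
    by_element = stats_map
    if not survivors:
        raise PipelineHalt("ligand-acceptance", params.metal)
    for s in survivors:
        s.shell_atoms = shells2.get(s.site_id, [])

    return DetectionOutput(
        metal=params.metal,
        sites=survivors,
        excluded=excluded,
        bond_stats=by_element,
        whitelist=whitelist,
        updated_upper=updated,
        carbon_mode=carbon_mode,
        slope=slope,
        deviations=deviations,
    )


def _six_angle_rows(sites: Sequence[MetalSite]) -> tuple[list[MetalSite], np.ndarray, list[dict]]:
    """6-angle vectors plus smallest-angle features for usable (>3-ligand) sites."""
    usable, vectors, feats = [], [], []
    for s in sites:
        if len(s.ligand_atoms) < 4:
            continue
        prof = angles_from_positions(
            [a.coords for a in s.ligand_atoms], s.metal_coords
        )
        try:
            vec = six_angle_reduction(prof)
        except NotReducibleError:
            continue
        small, pair = min((a, p) for a, p in prof.angles)
        a1, a2 = s.ligand_atoms[pair[0]], s.ligand_atoms[pair[1]]
        usable.append(s)
        vectors.append(vec.as_array())
        feats.append(
            {
                "smallest_angle": small,
                "elements": (a1.element, a2.element),
                "bidentate": a1.residue_id == a2.residue_id,
            }
        )
    return usable, (np.vstack(vectors) if vectors else np.empty((0, 6))), feats


def run(
    config: PipelineConfig,
    inputs: Sequence[str | Path] | str | Path,
    out_dir: str | Path,
) -> Path:
    """Run the full workflow on structure files and write stage artifacts.

    ``inputs`` is a directory of PDB/mmCIF files or an explicit file list.
    Artifacts per metal: site table, bond statistics, classification,
    normal/compressed labels, cluster assignments and measures, and (with
    an annotation table configured) enrichment results.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(inputs, (str, Path)):
        files = sorted(Path(inputs).glob("*.pdb")) + sorted(Path(inputs).glob("*.cif"))
    else:
        files = [Path(p) for p in inputs]
    if not files:
        raise PipelineHalt("input", "no structure files found")

    all_sites: dict[str, list[MetalSite]] = {m: [] for m in config.metals}
    for path in files:
        entry = parse_structure(path, config.detection.nmr_resolution)
        for site in find_metal_sites(entry, config.metals, config.detection):
            _assign_candidates(
                site, entry.atoms, config.metal_params[site.metal_element].initial_upper
            )
            all_sites[site.metal_element].append(site)

    summary: dict[str, dict] = {}
    for metal in config.metals:
        sites = all_sites.get(metal, [])
        if not sites:
            continue
        params = config.metal_params[metal]
        det = detect_metal(sites, params, config.detection)
        logger.info("%s: %d sites survive detection (%d excluded)",
                    metal, len(det.sites), len(det.excluded))

        mdir = out / metal
        mdir.mkdir(exist_ok=True)
        (mdir / "sites.tsv").write_text(site_table_tsv(sites))
        _write_bond_stats(mdir / "bond_stats.tsv", det)

        counts = det.coordination_counts()
        usable, vectors, feats = _six_angle_rows(det.sites)

        # chi-square classification of usable sites
        stats_by_cg, classifications = iterate_statistics(
            usable,
            {metal: params.small_angle_cut},
            config=config.detection,
        )
        _write_classifications(mdir / "classification.tsv", classifications)

        # compressed/normal labeling
        labels = None
        if feats:
            try:
                labels = classify_compressed(
                    [f["smallest_angle"] for f in feats],
                    [f["elements"] for f in feats],
                    [f["bidentate"] for f in feats],
                    params.rf_band,
                    seed=config.seed,
                )
            except ValueError as exc:
                logger.warning("%s: labeling skipped (%s)", metal, exc)
        if labels is not None:
            _write_labels(mdir / "labels.tsv", usable, labels)

        # k-means over the candidate range with stability measures
        cluster_summary = {}
        if len(vectors) >= 2:
            measures_by_k = {}
            runs_by_k: dict[int, ClusterResult] = {}
            for k in config.k_values:
                if k > len(vectors):
                    continue
                runs = [
                    kmeans_six_angle(vectors, k, seed=config.seed + 17 * r + k)
                    for r in range(config.stability_runs)
                ]
                jac, cdiff = stability_measures(runs)
                runs_by_k[k] = runs[0]
                measures_by_k[k] = (jac, cdiff)
            if measures_by_k:
                chosen = select_k(measures_by_k, n_sites=len(vectors))
                best = runs_by_k[chosen]
                _write_clusters(mdir, usable, best, measures_by_k)
                cluster_summary = {"k": chosen,
                                   "measures": {str(k): list(v) for k, v in measures_by_k.items()}}

        from .ligand_detection import estimate_error_rate

        max_valid = config.max_valid_n.get(metal, max(counts) if counts else 0)
        try:
            error_rate = estimate_error_rate(counts, max_valid) if counts else None
        except ZeroDivisionError:
            error_rate = None
        summary[metal] = {
            "n_input_sites": len(sites),
            "n_detected": len(det.sites),
            "n_usable": len(usable),
            "excluded": dict(Counter(det.excluded.values())),
            "updated_upper": det.updated_upper,
            "whitelist": list(det.whitelist),
            "slope": det.slope,
            "coordination_counts": {str(k): v for k, v in sorted(counts.items())},
            "error_rate": error_rate,
            "clustering": cluster_summary,
        }

    if config.annotations:
        _annotation_stage(config, all_sites, out, summary)

    (out / "report.json").write_text(json.dumps(summary, indent=2))
    return out


def _annotation_stage(config, all_sites, out, summary):
    ligand_map = {
        s.site_id: {a.residue_id for a in s.ligand_atoms}
        for sites in all_sites.values()
        for s in sites
        if s.ligand_atoms
    }
    try:
        table = fa.load_annotations(config.annotations, ligand_map, config.parent_map)
    except ValueError as exc:
        logger.warning("annotation stage skipped: %s", exc)
        return
    terms = table.terms_by_site()
    universe = sorted(table.universe)
    results = fa.hypergeometric_enrichment(
        universe, universe, terms, group_name="all"
    )
    df = pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "group": r.group,
                "n": r.n_annotated_in_group,
                "p": r.p,
                "p_adjusted": r.p_adjusted,
                "significant": r.significant,
            }
            for r in results
        ]
    )
    df.to_csv(out / "enrichment_all.tsv", sep="\t", index=False)
    summary["annotations"] = {"n_rows": len(table.rows), "n_sites": len(universe)}


def _write_bond_stats(path: Path, det: DetectionOutput) -> None:
    lines = ["metal\telement\tmean\tsd\tmode\tn\tr_avg\tslope"]
    for el, st in sorted(det.bond_stats.items()):
        lines.append(
            f"{st.metal}\t{el}\t{st.mean:.3f}\t{st.sd:.3f}\t{st.mode:.3f}\t"
            f"{st.n}\t{st.r_avg:.2f}\t{st.slope:.4f}"
        )
    path.write_text("\n".join(lines) + "\n")


def _write_classifications(path: Path, classifications: Sequence[SiteClassification]) -> None:
    lines = ["site_id\tcg_code\tprobability\tn_ligands"]
    for c in classifications:
        if c.fit is None:
            lines.append(f"{c.site_id}\t-\t-\t{len(c.ligands)}")
        else:
            lines.append(
                f"{c.site_id}\t{c.fit.cg_code}\t{c.fit.probability:.4f}\t{len(c.ligands)}"
            )
    path.write_text("\n".join(lines) + "\n")


def _write_labels(path: Path, sites, labels) -> None:
    lines = ["site_id\tsmallest_angle\tbidentate\tlabel\tsource"]
    for s, l in zip(sites, labels):
        lines.append(
            f"{s.site_id}\t{l.angle:.2f}\t{l.bidentate}\t{l.label}\t{l.source}"
        )
    path.write_text("\n".join(lines) + "\n")


def _write_clusters(mdir: Path, sites, best: ClusterResult, measures_by_k) -> None:
    lines = ["site_id\tcluster"]
    for s, c in zip(sites, best.assignments):
        lines.append(f"{s.site_id}\t{int(c)}")
    (mdir / "clusters.tsv").write_text("\n".join(lines) + "\n")
    mlines = ["k\tjaccard\tcenter_diff"]
    for k, (j, d) in sorted(measures_by_k.items()):
        mlines.append(f"{k}\t{j:.4f}\t{d:.4f}")
    (mdir / "measures.tsv").write_text("\n".join(mlines) + "\n")
    centers = {
        "k": best.k,
        "centers": [[round(float(x), 2) for x in c] for c in best.centers],
    }
    (mdir / "centers.json").write_text(json.dumps(centers, indent=2))


def report(run_dir: str | Path) -> dict:
    """Aggregate a run directory into a summary dictionary.

    Mirrors the per-metal ligand-count table with estimated error rates
    and the measures-versus-k tables; missing artifacts produce warnings
    and a partial report.
    """
    run_dir = Path(run_dir)
    path = run_dir / "report.json"
    if not path.exists():
        logger.warning("no report.json in %s; returning empty report", run_dir)
        return {}
    summary = json.loads(path.read_text())
    table = []
    for metal, info in summary.items():
        if not isinstance(info, dict) or "coordination_counts" not in info:
            continue
        row = {"metal": metal, "error_rate": info.get("error_rate")}
        row.update(
            {f"{n}-ligand": c for n, c in info["coordination_counts"].items()}
        )
        table.append(row)
    summary["ligand_count_table"] = table
    return summary
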