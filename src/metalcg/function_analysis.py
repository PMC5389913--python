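"""Structure-function correlation and term enrichment of metal-site groups.

Functional annotations (domain identifiers with optional ontology-term
mappings, e.g. from an InterProScan run) are joined to metal sites through
their ligand residues.  Three analyses are provided:

* a cluster-level structure-function Spearman correlation: structural
  distances between cluster centers in 6-angle space versus cosine
  distances between cluster annotation-frequency vectors;
* hypergeometric term enrichment of the normal and compressed site groups,
  Benjamini-Hochberg adjusted, with significance requiring >= 2 annotated
  sites and raw p <= 0.05;
* random-walk (walktrap) grouping of enriched terms on a shared-site
  overlap graph, after removing edges with weight < 0.8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations, permutations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import igraph
import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationTable",
    "EnrichmentResult",
    "load_annotations",
    "cluster_functional_distance",
    "structure_function_rho",
    "cluster_rho",
    "hypergeometric_enrichment",
    "group_terms",
    "consistency_check",
]


@dataclass
class AnnotationTable:
    """Functional annotations joined to metal sites.

    ``rows`` has columns site_id, residue_id, annotation_id, terms (a
    frozenset of ontology term ids, parent-augmented when a parent map was
    supplied).  ``universe`` is the set of annotated site ids.
    """

    rows: pd.DataFrame
    n_dropped: int = 0

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.rows["site_id"])

    def annotations_by_site(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for sid, ann in zip(self.rows["site_id"], self.rows["annotation_id"]):
            out.setdefault(sid, set()).add(ann)
        return {k: frozenset(v) for k, v in out.items()}

    def terms_by_site(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for sid, terms in zip(self.rows["site_id"], self.rows["terms"]):
            out.setdefault(sid, set()).update(terms)
        return {k: frozenset(v) for k, v in out.items()}


@dataclass
class EnrichmentResult:
    term_id: str
    group: str
    n_annotated_in_group: int
    p: float
    p_adjusted: float
    significant: bool
    group_id: int | None = None


def _read_parent_map(path: str | Path) -> dict[str, set[str]]:
    parents: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            logger.warning("skipping malformed parent-map line: %r", line)
            continue
        parents.setdefault(parts[0], set()).add(parts[1])
    return parents


def load_annotations(
    path: str | Path,
    site_ligand_residues: Mapping[str, Iterable[str]],
    parent_map: str | Path | None = None,
) -> AnnotationTable:
    """Load a TSV annotation table, keeping rows that overlap a ligand residue.

    Expected columns: site_id, residue_id, annotation_id, term_ids
    (semicolon-separated, may be empty).  Rows whose residue is not among
    the site's ligand residues are dropped (count logged).  With a parent
    map (child<TAB>parent lines) each row's term set is closed by one
    ancestor level.
    """
    parents = _read_parent_map(parent_map) if parent_map else {}
    ligands = {k: set(v) for k, v in site_ligand_residues.items()}

    kept, dropped, skipped = [], 0, 0
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#") or (
            lineno == 1 and line.lower().startswith("site_id")
        ):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            logger.warning("skipping malformed annotation row %d: %r", lineno, line)
            skipped += 1
            continue
        site_id, residue_id, annotation_id = parts[0], parts[1], parts[2]
        raw_terms = parts[3] if len(parts) > 3 else ""
        if residue_id not in ligands.get(site_id, set()):
            dropped += 1
            continue
        terms = {t for t in raw_terms.split(";") if t}
        for t in list(terms):
            terms |= parents.get(t, set())
        kept.append(
            {
                "site_id": site_id,
                "residue_id": residue_id,
                "annotation_id": annotation_id,
                "terms": frozenset(terms),
            }
        )
    if dropped:
        logger.info("dropped %d annotation rows without ligand overlap", dropped)
    if not kept:
        raise ValueError("annotation table empty after filtering")
    return AnnotationTable(
        rows=pd.DataFrame(kept, columns=["site_id", "residue_id", "annotation_id", "terms"]),
        n_dropped=dropped + skipped,
    )


def cluster_functional_distance(
    cluster_annotations: Sequence[Iterable[str]],
) -> np.ndarray:
    """Pairwise cosine distance between cluster annotation-frequency vectors.

    ``cluster_annotations`` gives, per cluster, the multiset (any iterable,
    repeats counted) of annotation ids of its member sites.  Clusters with
    no annotations must be excluded by the caller.
    """
    counts = [pd.Series(list(a)).value_counts() for a in cluster_annotations]
    if any(c.empty for c in counts):
        raise ValueError("every cluster needs at least one annotation")
    vocab = sorted(set().union(*[set(c.index) for c in counts]))
    mat = np.zeros((len(counts), len(vocab)))
    for i, c in enumerate(counts):
        for term, n in c.items():
            mat[i, vocab.index(term)] = n
    norms = np.linalg.norm(mat, axis=1)
    cos = (mat @ mat.T) / np.outer(norms, norms)
    dist = 1.0 - np.clip(cos, -1.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    return dist


def _to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(linkage)

    def walk(node) -> str:
        if node.is_leaf():
            return f"{labels[node.id]}:{node.dist:.4f}"
        left, right = walk(node.left), walk(node.right)
        return f"({left},{right}):{node.dist:.4f}"

    return f"({walk(tree.left)},{walk(tree.right)});"


def structure_function_rho(
    struct_dist: np.ndarray,
    func_dist: np.ndarray,
    labels: Sequence[str] | None = None,
    p_method: str = "asymptotic",
) -> tuple[float, float, tuple[str, str]]:
    """Spearman correlation between structural and functional cluster distances.

    The correlation is over the k(k-1)/2 corresponding off-diagonal pairs.
    The p-value uses the asymptotic t approximation by default;
    ``p_method="permutation"`` computes the exact cluster-relabelling
    permutation distribution instead (its granularity is 2/k!, so it
    cannot fall below 0.01 for k <= 5 and is mainly useful as a
    cross-check).  Also returns average-linkage dendrograms of both
    matrices in Newick format.
    """
    s = np.asarray(struct_dist, dtype=float)
    f = np.asarray(func_dist, dtype=float)
    k = s.shape[0]
    if s.shape != f.shape or s.shape != (k, k):
        raise ValueError("matrices must be square and share cluster labels")
    if k < 3:
        raise ValueError("need at least 3 clusters for a rank correlation")
    sv = squareform(s, checks=False)
    fv = squareform(f, checks=False)
    rho = float(sps.spearmanr(sv, fv).statistic)

    if p_method == "permutation":
        count, total = 0, 0
        for perm in permutations(range(k)):
            fp = f[np.ix_(perm, perm)]
            r = sps.spearmanr(sv, squareform(fp, checks=False)).statistic
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = count / total
    else:
        p = float(sps.spearmanr(sv, fv).pvalue)

    labels = list(labels) if labels is not None else [str(i) for i in range(k)]
    dendros = (
        _to_newick(hierarchy.average(sv), labels),
        _to_newick(hierarchy.average(fv), labels),
    )
    return rho, p, dendros


def cluster_rho(
    centers: np.ndarray,
    assignments: np.ndarray,
    site_annotations: Sequence[Iterable[str]],
) -> tuple[float | None, float | None]:
    """Structure-function rho of one clustering run.

    Structural distances are Euclidean between 6-angle cluster centers;
    functional distances are cosine distances between cluster
    annotation-frequency vectors.  Clusters without annotated sites are
    excluded (with a warning); returns (None, None) when fewer than 3
    annotated clusters remain.
    """
    k = len(centers)
    cluster_anns: list[list[str]] = [[] for _ in range(k)]
    for idx, anns in zip(assignments, site_annotations):
        cluster_anns[int(idx)].extend(anns)
    keep = [i for i in range(k) if cluster_anns[i]]
    if len(keep) < k:
        logger.warning("excluding %d clusters with no annotated sites", k - len(keep))
    if len(keep) < 3:
        return None, None
    centers_k = np.asarray(centers)[keep]
    struct = np.linalg.norm(centers_k[:, None, :] - centers_k[None, :, :], axis=2)
    func = cluster_functional_distance([cluster_anns[i] for i in keep])
    rho, p, _ = structure_function_rho(struct, func)
    return rho, p


def hypergeometric_enrichment(
    group_sites: Iterable[str],
    universe: Iterable[str],
    terms_by_site: Mapping[str, Iterable[str]],
    group_name: str = "group",
    p_cutoff: float = 0.05,
    min_sites: int = 2,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of terms in a site group.

    For a term annotating K of the N universe sites, the p-value is the
    probability of >= x annotated sites in a group of size n.  p-values
    are Benjamini-Hochberg adjusted across terms; significance requires
    >= ``min_sites`` annotated group sites and raw p <= ``p_cutoff``.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    group = frozenset(group_sites)
    if not group <= universe:
        raise ValueError("group must be a subset of the universe")

    term_sites: dict[str, set[str]] = {}
    for sid in universe:
        for t in terms_by_site.get(sid, ()):
            term_sites.setdefault(t, set()).add(sid)

    n_univ, n_group = len(universe), len(group)
    records = []
    for term in sorted(term_sites):
        hits = term_sites[term]
        x = len(hits & group)
        p = float(sps.hypergeom.sf(x - 1, n_univ, len(hits), n_group))
        records.append((term, x, p))
    if not records:
        return []
    pvals = [r[2] for r in records]
    adjusted = multipletests(pvals, method="fdr_bh")[1]
    return [
        EnrichmentResult(
            term_id=term,
            group=group_name,
            n_annotated_in_group=x,
            p=p,
            p_adjusted=float(p_adj),
            significant=(x >= min_sites and p <= p_cutoff),
        )
        for (term, x, p), p_adj in zip(records, adjusted)
    ]


def group_terms(
    results: Sequence[EnrichmentResult],
    term_sites: Mapping[str, Iterable[str]],
    weight_cutoff: float = 0.8,
    walk_steps: int = 4,
) -> dict[str, int]:
    """Random-walk grouping of significant terms on a shared-site graph.

    Edge weight between two terms is |shared annotated sites| / |union|
    (a normalized overlap); edges below ``weight_cutoff`` are removed and
    walktrap community detection assigns group ids.  Singletons allowed.
    """
    sig = [r for r in results if r.significant]
    terms = sorted({r.term_id for r in sig})
    if not terms:
        return {}
    sets = {t: frozenset(term_sites.get(t, ())) for t in terms}
    edges, weights = [], []
    for i, j in combinations(range(len(terms)), 2):
        a, b = sets[terms[i]], sets[terms[j]]
        union = len(a | b)
        w = len(a & b) / union if union else 0.0
        if w >= weight_cutoff:
            edges.append((i, j))
            weights.append(w)
    g = igraph.Graph(n=len(terms), edges=edges)
    if edges:
        clustering = g.community_walktrap(weights=weights, steps=walk_steps).as_clustering()
    else:
        clustering = igraph.VertexClustering(g, membership=list(range(len(terms))))
    return {terms[i]: int(m) for i, m in enumerate(clustering.membership)}


def consistency_check(
    combined: Sequence[EnrichmentResult],
    sub_strata: Mapping[str, Sequence[EnrichmentResult]],
    metal_counts: Mapping[str, Mapping[str, int]] | None = None,
    max_metal_fraction: float = 0.5,
) -> pd.DataFrame:
    """Check combined-stratum enrichments against the per-stratum results.

    A term is *consistent* when no sub-stratum finds it significant in the
    opposite group from the combined analysis.  With ``metal_counts``
    (term -> metal -> annotated-site count) the maximum per-metal usage
    fraction is reported and the final filter keeps consistent terms with
    max fraction < 0.5.
    """
    sig_by_term_sub: dict[str, set[str]] = {}
    for rows in sub_strata.values():
        for r in rows:
            if r.significant:
                sig_by_term_sub.setdefault(r.term_id, set()).add(r.group)

    records = []
    for r in combined:
        opposite_hits = sig_by_term_sub.get(r.term_id, set()) - {r.group}
        consistent = not (r.significant and opposite_hits)
        max_metal, perc = "", float("nan")
        if metal_counts and r.term_id in metal_counts:
            counts = metal_counts[r.term_id]
            total = sum(counts.values())
            if total:
                max_metal = max(counts, key=lambda m: (counts[m], m))
                perc = counts[max_metal] / total
        records.append(
            {
                "term_id": r.term_id,
                "group": r.group,
                "significant": r.significant,
                "consistent": consistent,
                "max_metal": max_metal,
                "perc": perc,
                "passes_filter": bool(
                    consistent
                    and (np.isnan(perc) or perc < max_metal_fraction)
                ),
            }
        )
    return pd.DataFrame(
        records,
        columns=[
            "term_id", "group", "significant", "consistent",
            "max_metal", "perc", "passes_filter",
        ],
    )
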