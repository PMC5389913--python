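"""Compressed-angle labeling and k-means clustering in 6-angle space.

The smallest ligand-metal-ligand angle of a site is either *normal*
(explained by a canonical CG) or *compressed* (typically < 60 degrees,
almost always a bidentate carboxylate).  Sites whose smallest angle falls
clearly below / above a per-metal training band are labelled directly;
sites inside the band are labelled by a random forest trained on the
smallest angle, the element pair composing it, and its bidentation status.

Sites are then clustered by k-means on their 6-angle vectors.  Four
measures guide the choice of k: cluster-overlap stability (mean matched
Jaccard index across repeated runs), center stability (negated sum of
matched center distances), and -- when at least 600 sites are available --
the structure-function Spearman rho and its -log10 p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "CompressedLabel",
    "ClusterResult",
    "build_training_set",
    "classify_compressed",
    "kmeans_six_angle",
    "stability_measures",
    "select_k",
    "subsample_rho_curve",
    "MIN_SITES_FOR_RHO",
]

#: below this data size the structure-function rho is unreliable and is
#: ignored when selecting k
MIN_SITES_FOR_RHO = 600

NORMAL = "normal"
COMPRESSED = "compressed"


@dataclass(frozen=True)
class CompressedLabel:
    """Normal/compressed label of one site's smallest angle."""

    label: str  # "normal" | "compressed"
    source: str  # "training" | "predicted"
    angle: float
    elements: tuple[str, str]
    bidentate: bool


@dataclass
class ClusterResult:
    """One k-means run with optional quality measures."""

    k: int
    assignments: np.ndarray
    centers: np.ndarray
    inertia: float
    jaccard: float | None = None
    center_diff: float | None = None
    rho: float | None = None
    neg_log_p: float | None = None


def build_training_set(
    angles: Sequence[float], band: tuple[float, float]
) -> list[str | None]:
    """Band-threshold training labels for smallest angles.

    Angles strictly below the band are *compressed*, strictly above it
    *normal*; angles inside [low, high] get None and are left for the
    classifier.  Raises when either training class is empty.
    """
    low, high = band
    labels: list[str | None] = []
    for a in angles:
        if a < low:
            labels.append(COMPRESSED)
        elif a > high:
            labels.append(NORMAL)
        else:
            labels.append(None)
    present = {l for l in labels if l is not None}
    if present != {NORMAL, COMPRESSED}:
        raise ValueError(
            f"cannot train: classes present outside the band = {sorted(present)}"
        )
    return labels


def _encode_features(
    angles: Sequence[float],
    element_pairs: Sequence[tuple[str, str]],
    bidentate: Sequence[bool],
    categories: list[str],
) -> np.ndarray:
    idx = {el: i for i, el in enumerate(categories)}
    n = len(angles)
    x = np.zeros((n, 2 + len(categories)))
    x[:, 0] = np.asarray(angles, dtype=float)
    x[:, 1] = np.asarray(bidentate, dtype=float)
    for row, pair in enumerate(element_pairs):
        for el in sorted(pair):
            x[row, 2 + idx[el]] += 1.0
    return x


def classify_compressed(
    angles: Sequence[float],
    element_pairs: Sequence[tuple[str, str]],
    bidentate: Sequence[bool],
    band: tuple[float, float],
    seed: int = 0,
    n_trees: int = 500,
) -> list[CompressedLabel]:
    """Label every site normal or compressed.

    Out-of-band sites keep their training labels; in-band sites receive
    random-forest predictions from the three feature groups (smallest
    angle, element pair as bag-of-elements counts, bidentation flag).
    Deterministic given the seed.
    """
    training = build_training_set(angles, band)
    categories = sorted({el for pair in element_pairs for el in pair})
    x = _encode_features(angles, element_pairs, bidentate, categories)

    train_idx = [i for i, l in enumerate(training) if l is not None]
    pred_idx = [i for i, l in enumerate(training) if l is None]
    y_train = [training[i] for i in train_idx]
    if len(set(y_train)) < 2:
        raise ValueError("degenerate training set: a single class")

    labels: list[str] = [l or "" for l in training]
    if pred_idx:
        forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        forest.fit(x[train_idx], y_train)
        for i, pred in zip(pred_idx, forest.predict(x[pred_idx])):
            labels[i] = str(pred)

    return [
        CompressedLabel(
            label=labels[i],
            source="training" if training[i] is not None else "predicted",
            angle=float(angles[i]),
            elements=tuple(sorted(element_pairs[i])),
            bidentate=bool(bidentate[i]),
        )
        for i in range(len(angles))
    ]


def kmeans_six_angle(
    vectors: Sequence[Sequence[float]],
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
) -> ClusterResult:
    """k-means on 6-angle vectors (Euclidean on raw degrees, best of restarts)."""
    x = np.asarray(vectors, dtype=float)
    if k > len(x):
        raise ValueError(f"k={k} exceeds the number of vectors ({len(x)})")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    assignments = km.fit_predict(x)
    return ClusterResult(
        k=k,
        assignments=assignments,
        centers=km.cluster_centers_,
        inertia=float(km.inertia_),
    )


def _greedy_match(
    a: ClusterResult, b: ClusterResult
) -> list[tuple[int, int, float]]:
    """Greedy maximum-Jaccard matching of clusters between two runs."""
    sets_a = {i: set(np.flatnonzero(a.assignments == i)) for i in range(a.k)}
    sets_b = {j: set(np.flatnonzero(b.assignments == j)) for j in range(b.k)}
    pairs = []
    for i, sa in sets_a.items():
        for j, sb in sets_b.items():
            union = len(sa | sb)
            jac = len(sa & sb) / union if union else 1.0
            pairs.append((jac, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = []
    for jac, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((i, j, jac))
    return matched


def stability_measures(runs: Sequence[ClusterResult]) -> tuple[float, float]:
    """Cross-run cluster stability: (mean matched Jaccard, -sum center dist).

    Clusters are matched greedily by maximum Jaccard over every pair of
    runs.  The center measure is the sum of Euclidean distances between
    matched centers, negated so that larger is better for both measures.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 runs")
    if len({r.k for r in runs}) != 1:
        raise ValueError("runs have mismatched k")
    jacs, diffs = [], []
    for a_i in range(len(runs)):
        for b_i in range(a_i + 1, len(runs)):
            matched = _greedy_match(runs[a_i], runs[b_i])
            jacs.extend(j for _, _, j in matched)
            diffs.append(
                sum(
                    float(np.linalg.norm(runs[a_i].centers[i] - runs[b_i].centers[j]))
                    for i, j, _ in matched
                )
            )
    return float(np.mean(jacs)), -float(np.mean(diffs))


def select_k(
    measures_by_k: Mapping[int, tuple[float, float]],
    n_sites: int,
    rho_by_k: Mapping[int, tuple[float, float]] | None = None,
) -> int:
    """Choose k by rank-sum of the quality measures.

    ``measures_by_k`` maps k to (jaccard, center_diff) with both oriented
    larger-is-better.  With >= 600 sites and rho available, the Spearman
    rho and -log10(p) join the rank-sum and candidates must have
    p < 0.01 (if none qualifies, the stability-only rule applies).  Ties
    go to the smaller k.
    """
    if not measures_by_k:
        raise ValueError("no candidate k values")
    candidates = sorted(measures_by_k)

    use_rho = (
        n_sites >= MIN_SITES_FOR_RHO
        and rho_by_k is not None
        and any(k in rho_by_k for k in candidates)
    )
    if use_rho:
        qualified = [
            k for k in candidates if k in rho_by_k and rho_by_k[k][1] < 0.01
        ]
        if qualified:
            scores = _rank_sum(
                qualified,
                [
                    [measures_by_k[k][0] for k in qualified],
                    [measures_by_k[k][1] for k in qualified],
                    [rho_by_k[k][0] for k in qualified],
                    [-np.log10(max(rho_by_k[k][1], 1e-300)) for k in qualified],
                ],
            )
            return _argmax_smallest_k(qualified, scores)

    scores = _rank_sum(
        candidates,
        [
            [measures_by_k[k][0] for k in candidates],
            [measures_by_k[k][1] for k in candidates],
        ],
    )
    return _argmax_smallest_k(candidates, scores)


def _rank_sum(candidates: list[int], measure_lists: list[list[float]]) -> list[float]:
    total = np.zeros(len(candidates))
    for values in measure_lists:
        order = np.argsort(np.argsort(values))  # rank, larger value -> larger rank
        total += order
    return list(total)


def _argmax_smallest_k(candidates: list[int], scores: list[float]) -> int:
    best = max(zip(scores, [-k for k in candidates]))
    return -best[1]


def subsample_rho_curve(
    vectors: Sequence[Sequence[float]],
    annotations: Sequence[Iterable[str]],
    fractions: Sequence[float],
    repeats: int,
    k_values: Sequence[int],
    seed: int = 0,
) -> pd.DataFrame:
    """Mean structure-function rho as a function of subsample size.

    For each fraction of the data (sampled without replacement, ``repeats``
    times) and each k, sites are clustered in 6-angle space and the
    Spearman correlation between cluster structural distances (Euclidean
    between centers) and functional distances (cosine distance between
    annotation-frequency vectors) is computed.  Returns a table with
    columns size, k, mean_rho.
    """
    from .function_analysis import cluster_rho  # local import; no cycle

    x = np.asarray(vectors, dtype=float)
    ann = [frozenset(a) for a in annotations]
    if any(f > 1.0 or f <= 0.0 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        size = max(2, int(round(frac * len(x))))
        for k in k_values:
            rhos = []
            for _ in range(repeats):
                idx = rng.choice(len(x), size=size, replace=False)
                if k > size:
                    continue
                sub_seed = int(rng.integers(0, 2**31 - 1))
                run = kmeans_six_angle(x[idx], k=k, seed=sub_seed)
                rho, _ = cluster_rho(
                    run.centers, run.assignments, [ann[i] for i in idx]
                )
                if rho is not None:
                    rhos.append(rho)
            if rhos:
                rows.append(
                    {"size": size, "k": k, "mean_rho": float(np.mean(rhos))}
                )
    return pd.DataFrame(rows, columns=["size", "k", "mean_rho"])
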