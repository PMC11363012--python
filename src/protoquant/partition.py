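"""Cell-population structure: clustering, marker-based typing, summaries.

Untargeted intensities are compared across cells after log-transforming and
normalizing by each cell's computed volume (larger cells yield more signal
for the same concentration).  Hierarchical clustering reveals co-occurrence
of metabolites in cells; k-means with k=4 reduces each tissue to a small
set of metabolic cell states; marker metabolites (serpentine for
idioblasts, loganic acid for IPAP cells) give interpretable type labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans

from .io import CompoundRecord
from .quantify import FLAG_QUANTIFIED, QuantMatrix

__all__ = [
    "MarkerRule",
    "MarkerRules",
    "ClusterResult",
    "HCAResult",
    "default_marker_rules",
    "log_volume_normalize",
    "hierarchical_cluster",
    "kmeans_cluster",
    "annotate_cell_types",
    "population_summary",
    "cluster_mean_heatmap",
]


@dataclass(frozen=True)
class MarkerRule:
    compound: str
    threshold: float  # mM, exceed to assign
    label: str

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError(f"{self.label}: threshold must be positive")


@dataclass(frozen=True)
class MarkerRules:
    """Ordered marker rules; the first rule whose marker exceeds its
    threshold wins, otherwise the fallback label applies."""

    rules: tuple[MarkerRule, ...]
    fallback: str = "unassigned"

    def __post_init__(self) -> None:
        labels = [r.label for r in self.rules]
        if len(set(labels)) != len(labels):
            raise ValueError("marker rule labels must be unique")


def default_marker_rules(threshold: float = 0.1) -> MarkerRules:
    """Serpentine marks idioblasts (checked first — idioblasts may also
    contain iridoids), loganic acid marks IPAP cells."""
    return MarkerRules(
        rules=(
            MarkerRule("serpentine", threshold, "idioblast"),
            MarkerRule("loganic acid", threshold, "ipap"),
        ),
        fallback="unassigned",
    )


def log_volume_normalize(
    areas: pd.DataFrame, volumes: Sequence[float], pseudocount: float = 1.0
) -> pd.DataFrame:
    """``log10(area / volume + pseudocount)`` per cell (row) and feature.

    ``areas`` is cells × features; ``volumes`` (pL) aligns with the rows.
    """
    volumes = np.asarray(volumes, dtype=float)
    if volumes.shape != (len(areas),):
        raise ValueError("one volume per cell (row) required")
    if (volumes <= 0).any():
        raise ValueError("cell volumes must be positive")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    scaled = areas.div(volumes, axis=0) + pseudocount
    return np.log10(scaled)


@dataclass
class HCAResult:
    """Hierarchical clustering output: scipy linkage + deterministic leaf order."""

    linkage: np.ndarray
    leaf_order: list[int]
    labels: list[str]

    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]

    def to_newick(self) -> str:
        n = len(self.labels)

        def render(node: int) -> str:
            if node < n:
                return self.labels[node].replace(",", "_").replace("(", "_").replace(")", "_")
            left, right, dist, _ = self.linkage[node - n]
            a, b = _ordered_children(self.linkage, n, int(left), int(right))
            return f"({render(a)},{render(b)}):{dist:.6g}"

        return render(2 * n - 2) + ";"

    def cut(self, k: int) -> np.ndarray:
        """Flat cluster labels (1..k) from cutting the tree."""
        return hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")


def _subtree_size(linkage: np.ndarray, n: int, node: int) -> int:
    return 1 if node < n else int(linkage[node - n, 3])


def _min_leaf(linkage: np.ndarray, n: int, node: int) -> int:
    while node >= n:
        node = int(min(linkage[node - n, 0], linkage[node - n, 1]))
    return node


def _ordered_children(linkage: np.ndarray, n: int, left: int, right: int) -> tuple[int, int]:
    # denser (larger) subtree first; ties broken by smallest leaf index
    key = lambda node: (-_subtree_size(linkage, n, node), _min_leaf(linkage, n, node))
    return tuple(sorted((left, right), key=key))  # type: ignore[return-value]


def hierarchical_cluster(
    matrix: pd.DataFrame, distance: str = "euclidean", linkage: str = "ward"
) -> HCAResult:
    """Agglomerative clustering of cells (rows) with deterministic leaf order.

    Defaults are Euclidean distance with Ward linkage on the transformed
    intensity matrix.  At every merge the denser subtree is placed first,
    so the leaf ordering is a pure function of the input.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 cells to cluster")
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("matrix contains missing values")
    Z = hierarchy.linkage(values, method=linkage, metric=distance)
    n = len(matrix)

    order: list[int] = []

    def walk(node: int) -> None:
        if node < n:
            order.append(node)
            return
        left, right, _, _ = Z[node - n]
        a, b = _ordered_children(Z, n, int(left), int(right))
        walk(a)
        walk(b)

    walk(2 * n - 2)
    return HCAResult(linkage=Z, leaf_order=order, labels=[str(i) for i in matrix.index])


@dataclass(frozen=True)
class ClusterResult:
    """k-means partition of cells; labels are 1-based and renumbered by
    first occurrence so identical inputs give identical outputs."""

    labels: np.ndarray
    k: int
    seed: int
    inertia: float  # within-cluster sum of squared distances

    def __post_init__(self) -> None:
        if len(self.labels) and not (
            (self.labels >= 1).all() and (self.labels <= self.k).all()
        ):
            raise ValueError("labels must lie in 1..k")


def kmeans_cluster(
    matrix: pd.DataFrame,
    k: int = 4,
    seed: int = 0,
    n_restarts: int = 50,
    standardize: bool = True,
) -> ClusterResult:
    """Best-of-``n_restarts`` k-means on (optionally standardized) intensities.

    Per-compound standardization removes the scale disparity between
    compound classes; without it the most abundant compound dominates the
    Euclidean geometry.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds the number of cells ({len(matrix)})")
    values = matrix.to_numpy(dtype=float)
    if standardize:
        std = values.std(axis=0)
        std[std == 0] = 1.0
        values = (values - values.mean(axis=0)) / std
    model = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = model.fit_predict(values)
    # renumber clusters by order of first appearance
    mapping: dict[int, int] = {}
    labels = np.empty(len(raw), dtype=int)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        labels[i] = mapping[lab]
    return ClusterResult(labels=labels, k=k, seed=seed, inertia=float(model.inertia_))


def annotate_cell_types(quant: QuantMatrix, rules: MarkerRules) -> pd.Series:
    """Assign each cell the label of the first marker rule it satisfies.

    A rule fires when its marker compound is quantified above the rule's
    threshold (mM); censored entries count as zero.
    """
    for rule in rules.rules:
        if rule.compound not in quant.compounds:
            raise ValueError(f"unknown marker compound {rule.compound!r}")
    values = quant.values_filled(0.0)
    labels = pd.Series(rules.fallback, index=quant.concentrations.index, name="cell_type")
    unassigned = pd.Series(True, index=labels.index)
    for rule in rules.rules:
        hit = unassigned & (values[rule.compound] > rule.threshold)
        labels[hit] = rule.label
        unassigned &= ~hit
    return labels


def population_summary(
    quant: QuantMatrix,
    library: Sequence[CompoundRecord] | None = None,
    thresholds: Mapping[str, float] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-compound and per-cell statistics of a quantified population.

    Per compound: fraction of cells quantified, fraction above an optional
    threshold (mM), maximum, and median of quantified values (NaN when
    nothing is quantified).  Per cell: total concentration per compound
    class when a library is supplied, including ``total_alkaloid``.
    """
    if len(quant.cells) == 0:
        raise ValueError("empty quantification matrix")
    thresholds = thresholds or {}
    n = len(quant.cells)
    rows = []
    for compound in quant.compounds:
        flagged = quant.flags[compound] == FLAG_QUANTIFIED
        values = quant.concentrations[compound][flagged]
        threshold = thresholds.get(compound)
        rows.append(
            {
                "compound": compound,
                "fraction_quantified": flagged.sum() / n,
                "fraction_above_threshold": (
                    float((values > threshold).sum()) / n if threshold is not None else np.nan
                ),
                "max_mM": values.max() if len(values) else np.nan,
                "median_mM": values.median() if len(values) else np.nan,
            }
        )
    per_compound = pd.DataFrame(rows).set_index("compound")

    per_cell = pd.DataFrame(index=quant.concentrations.index)
    if library is not None:
        classes = {c.name: c.compound_class for c in library}
        filled = quant.values_filled(0.0)
        for klass in sorted({v for v in classes.values() if v != "internal_standard"}):
            members = [c for c in quant.compounds if classes.get(c) == klass]
            per_cell[f"total_{klass}"] = filled[members].sum(axis=1) if members else 0.0
    return {"per_compound": per_compound, "per_cell": per_cell}


def cluster_mean_heatmap(matrix: pd.DataFrame, labels: Sequence[int]) -> pd.DataFrame:
    """Cluster × compound mean intensity table, rows ordered by cluster id."""
    labels = np.asarray(labels)
    if labels.shape != (len(matrix),):
        raise ValueError("one label per cell (row) required")
    out = matrix.groupby(labels).mean()
    out.index.name = "cluster"
    return out.sort_index()
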