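"""COG-category odds-ratio enrichment and hierarchical clustering of samples
on the four community evolutionary variables (rER, dN/dS, transposase level,
ACE richness)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "EnrichmentResult",
    "EnrichmentError",
    "cog_odds_ratio",
    "habitat_enrichment_profile",
    "assemble_matrix",
    "hierarchical_cluster",
    "adjusted_rand_index",
    "EVO_VARIABLES",
]

EVO_VARIABLES = ["community_rer", "community_dnds", "transposase_level", "ace"]


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    a: int  # focal genes in category
    b: int  # focal genes in other categories
    c: int  # background genes in category
    d: int  # background genes in other categories
    log_odds_ratio: float
    p_value: float  # one-tailed Fisher in the direction of the observed OR
    significance: str  # "", "*", "**" at the configured alpha levels


def cog_odds_ratio(
    a: int, b: int, c: int, d: int,
    category: str = "",
    alpha_star: float = 0.01,
    alpha_double: float = 0.001,
) -> EnrichmentResult:
    """ln odds ratio of a 2x2 focal/background table with one-tailed Fisher p.

    The Haldane-Anscombe +0.5 correction is applied to every cell for the
    odds ratio when any cell is zero; the Fisher test uses the raw counts.
    The tail follows the direction of the observed odds ratio.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise EnrichmentError("negative count in contingency table")
    if a + b == 0 or c + d == 0:
        raise EnrichmentError("empty focal or background margin")
    if any(x == 0 for x in cells):
        aa, bb, cc, dd = (x + 0.5 for x in cells)
    else:
        aa, bb, cc, dd = cells
    log_or = float(np.log((aa * dd) / (bb * cc)))
    alternative = "greater" if log_or >= 0 else "less"
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative).pvalue)
    stars = "**" if p < alpha_double else ("*" if p < alpha_star else "")
    return EnrichmentResult(category, a, b, c, d, log_or, p, stars)


def habitat_enrichment_profile(
    focal: Dict[str, int],
    background: Dict[str, int],
    alpha_star: float = 0.01,
    alpha_double: float = 0.001,
) -> List[EnrichmentResult]:
    """Per-category enrichment of a habitat's summed COG counts against a
    reference background; categories absent from both universes are skipped."""
    categories = sorted(set(focal) | set(background))
    focal_total = sum(focal.values())
    bg_total = sum(background.values())
    if focal_total == 0 or bg_total == 0:
        raise EnrichmentError("focal or background universe is empty")
    out = []
    for cat in categories:
        fa = int(focal.get(cat, 0))
        ca = int(background.get(cat, 0))
        if fa == 0 and ca == 0:
            continue
        out.append(
            cog_odds_ratio(
                fa, focal_total - fa, ca, bg_total - ca,
                category=cat, alpha_star=alpha_star, alpha_double=alpha_double,
            )
        )
    return out


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": r.category,
                "focal_in": r.a,
                "focal_out": r.b,
                "background_in": r.c,
                "background_out": r.d,
                "ln_odds_ratio": r.log_odds_ratio,
                "p_value": r.p_value,
                "significance": r.significance,
            }
            for r in results
        ]
    )


def assemble_matrix(
    metrics: Dict[str, pd.DataFrame],
    habitats: Optional[Dict[str, str]] = None,
    annotations: Optional[Dict[str, str]] = None,
) -> pd.DataFrame:
    """Join the per-sample metric tables into the samples x 4 matrix and
    z-score each column.

    ``metrics`` maps variable name (see EVO_VARIABLES) to a frame with
    ``sample_id`` and the variable column.  Samples missing any variable are
    dropped with a named warning.  Constant columns standardize to zero.
    """
    missing_tables = [v for v in EVO_VARIABLES if v not in metrics]
    if missing_tables:
        raise EnrichmentError(f"missing metric tables: {missing_tables}")
    merged: Optional[pd.DataFrame] = None
    for var in EVO_VARIABLES:
        t = metrics[var][["sample_id", var]]
        merged = t if merged is None else merged.merge(t, on="sample_id", how="outer")
    assert merged is not None
    incomplete = merged[merged[EVO_VARIABLES].isna().any(axis=1)]["sample_id"]
    for sid in incomplete:
        warnings.warn(f"sample {sid!r} lacks at least one variable; dropped")
    merged = merged.dropna().sort_values("sample_id", kind="mergesort")
    merged = merged.set_index("sample_id")
    for col in EVO_VARIABLES:
        sd = merged[col].std(ddof=0)
        if sd == 0:
            warnings.warn(f"variable {col!r} is constant; standardized to zeros")
            merged[col] = 0.0
        else:
            merged[col] = (merged[col] - merged[col].mean()) / sd
    if habitats:
        merged["habitat"] = [habitats.get(s, "") for s in merged.index]
    if annotations:
        merged["annotation"] = [annotations.get(s, "") for s in merged.index]
    return merged


def hierarchical_cluster(
    matrix: pd.DataFrame,
    distance: str = "euclidean",
    linkage: str = "complete",
    k: int = 2,
) -> Tuple[str, pd.Series]:
    """Agglomerative clustering of the standardized variable matrix.

    Returns the dendrogram as a newick string (heights as branch lengths) and
    the k-cut cluster labels, both deterministic for a fixed input order.
    """
    data = matrix[EVO_VARIABLES].to_numpy(dtype=float)
    n = data.shape[0]
    if n < 2:
        raise EnrichmentError("need at least 2 samples to cluster")
    if k > n:
        raise EnrichmentError(f"k={k} exceeds number of samples n={n}")
    Z = hierarchy.linkage(pdist(data, metric=distance), method=linkage)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    tree = hierarchy.to_tree(Z)
    names = list(matrix.index)

    def to_newick(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = to_newick(node.left, node.dist)
        right = to_newick(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    newick = to_newick(tree, tree.dist) + ";"
    return newick, pd.Series(labels, index=matrix.index, name="cluster")


def adjusted_rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """Adjusted Rand index between two labelings (permutation-invariant)."""
    a = pd.Series(list(labels_a))
    b = pd.Series(list(labels_b))
    if len(a) != len(b):
        raise EnrichmentError("labelings differ in length")
    n = len(a)
    contingency = pd.crosstab(a, b).to_numpy()

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_cells = comb2(contingency).sum()
    sum_rows = comb2(contingency.sum(axis=1)).sum()
    sum_cols = comb2(contingency.sum(axis=0)).sum()
    total = comb2(np.array(n))
    expected = sum_rows * sum_cols / total if total else 0.0
    max_index = 0.5 * (sum_rows + sum_cols)
    if max_index == expected:
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))
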