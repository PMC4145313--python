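"""Relative evolutionary rates (rERs) and habitat-level statistics.

A marker's rER is the normalized deviation of its placed root-to-tip branch
length from the median root-to-tip length of reference taxa in the same
phylum; a sample's community rER is the median over its markers, and a
habitat's rER is the mean over its samples.  An absolute-difference variant
is available via ``formula="absolute"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "marker_rer",
    "community_rer",
    "habitat_rer",
    "habitat_association",
    "pairwise_habitat_tests",
    "build_rer_table",
    "HabitatComparison",
    "RerError",
]


class RerError(ValueError):
    pass


def marker_rer(query_length: float, phylum_median: float, formula: str = "relative") -> float:
    """rER of one placed marker.

    relative: (L_query - median) / median  (scale-invariant, default)
    absolute: L_query - median
    """
    if phylum_median is None or not np.isfinite(phylum_median):
        raise RerError("missing phylum median")
    if formula == "relative":
        if phylum_median <= 0:
            raise RerError("phylum median must be > 0 for the relative formula")
        return (query_length - phylum_median) / phylum_median
    if formula == "absolute":
        return query_length - phylum_median
    raise RerError(f"unknown rER formula: {formula}")


def community_rer(marker_rers: Sequence[float]) -> float:
    """Median marker rER of one sample (even counts: mean of central pair)."""
    arr = np.asarray(marker_rers, dtype=float)
    if arr.size == 0:
        raise RerError(
            "no marker rERs for sample; pool sparse samples before calling"
        )
    return float(np.median(arr))


def habitat_rer(community_rers: Sequence[float]) -> float:
    """Arithmetic mean of community rERs across a habitat's samples."""
    arr = np.asarray(community_rers, dtype=float)
    if arr.size == 0:
        raise RerError("no community rERs for habitat")
    return float(arr.mean())


def habitat_association(
    community_rers: Sequence[float],
    habitat_scores: Sequence[float],
    n_perm: int = 999,
    seed: int = 0,
) -> Tuple[float, float]:
    """Spearman correlation between community rERs and an ordinal habitat
    score, with a permutation p-value.

    p = (1 + #{|rho_perm| >= |rho_obs|}) / (1 + n_perm).
    """
    x = np.asarray(community_rers, dtype=float)
    s = np.asarray(habitat_scores, dtype=float)
    if x.size != s.size:
        raise RerError("rER and score vectors differ in length")
    if len(set(s.tolist())) < 2:
        raise RerError("need at least 2 habitats (distinct scores)")
    if n_perm < 99:
        raise RerError("n_perm must be >= 99")
    if np.all(x == x[0]):
        return 0.0, 1.0
    # Spearman rho = Pearson correlation of (average) ranks; permutations of
    # the score vector are evaluated in one matrix product for speed.
    rx = stats.rankdata(x) - (x.size + 1) / 2.0
    rs = stats.rankdata(s) - (s.size + 1) / 2.0
    denom = np.sqrt((rx**2).sum() * (rs**2).sum())
    rho_obs = float(rx @ rs / denom)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(rs) for _ in range(n_perm)])
    rho_perm = perms @ rx / denom
    hits = int((np.abs(rho_perm) >= abs(rho_obs) - 1e-12).sum())
    return rho_obs, (1 + hits) / (1 + n_perm)


@dataclass(frozen=True)
class HabitatComparison:
    habitat_a: str
    habitat_b: str
    u_statistic: float
    p_value: float
    p_adjusted: float
    alternative: str


def pairwise_habitat_tests(
    groups: Dict[str, Sequence[float]],
    alternative: str = "two-sided",
    exact_limit: int = 12,
) -> List[HabitatComparison]:
    """All pairwise Mann-Whitney U tests between habitats with BH adjustment.

    Exact enumeration when n1 + n2 <= ``exact_limit`` (and no ties); normal
    approximation with tie correction otherwise.  ``alternative`` follows
    scipy semantics for ``mannwhitneyu(a, b)`` where a is the habitat that
    sorts first.
    """
    if alternative not in ("two-sided", "less", "greater"):
        raise RerError(f"invalid alternative: {alternative}")
    usable = {}
    for name, vals in sorted(groups.items()):
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            warnings.warn(f"habitat {name!r} has <2 values; excluded from tests")
            continue
        usable[name] = arr
    names = sorted(usable)
    if len(names) < 2:
        raise RerError("need at least 2 habitats with >=2 values each")

    raw: List[Tuple[str, str, float, float]] = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            xa, xb = usable[a], usable[b]
            method = "exact" if xa.size + xb.size <= exact_limit else "asymptotic"
            if method == "exact" and len(np.unique(np.concatenate([xa, xb]))) < xa.size + xb.size:
                method = "asymptotic"  # scipy exact method disallows ties
            res = stats.mannwhitneyu(xa, xb, alternative=alternative, method=method)
            raw.append((a, b, float(res.statistic), float(res.pvalue)))

    adjusted = stats.false_discovery_control([r[3] for r in raw], method="bh")
    return [
        HabitatComparison(a, b, u, p, float(p_adj), alternative)
        for (a, b, u, p), p_adj in zip(raw, adjusted)
    ]


def build_rer_table(
    rows: Sequence[dict],
    phylum_medians: Dict[str, float],
    formula: str = "relative",
) -> pd.DataFrame:
    """Assemble the per-query rER table.

    ``rows`` carry sample_id, marker_id, phylum and query_tip_length (as
    produced by the placement module plus the sample manifest); the returned
    frame adds phylum_median and rer, sorted by (sample_id, marker_id,
    query_id) for deterministic output.
    """
    records = []
    for row in rows:
        phylum = row["phylum"]
        if phylum not in phylum_medians:
            raise RerError(
                f"query {row.get('query_id')}: phylum {phylum!r} has no "
                "reference median"
            )
        med = phylum_medians[phylum]
        records.append(
            {
                "sample_id": row["sample_id"],
                "query_id": row.get("query_id", ""),
                "marker_id": row["marker_id"],
                "phylum": phylum,
                "query_tip_length": float(row["query_tip_length"]),
                "phylum_median": med,
                "rer": marker_rer(row["query_tip_length"], med, formula=formula),
            }
        )
    df = pd.DataFrame.from_records(records)
    return df.sort_values(["sample_id", "marker_id", "query_id"], kind="mergesort").reset_index(drop=True)


def per_sample_rers(rer_table: pd.DataFrame) -> pd.DataFrame:
    """Community rER per sample from the per-query table."""
    out = (
        rer_table.groupby("sample_id", sort=True)["rer"]
        .agg(community_rer="median", n_markers="size")
        .reset_index()
    )
    return out


def per_habitat_rers(sample_table: pd.DataFrame, habitats: Dict[str, str]) -> pd.DataFrame:
    """Habitat rER (mean community rER) given sample -> habitat labels."""
    df = sample_table.copy()
    unknown = set(df["sample_id"]) - set(habitats)
    if unknown:
        raise RerError(f"samples without habitat labels: {sorted(unknown)[:5]}")
    df["habitat"] = df["sample_id"].map(habitats)
    return (
        df.groupby("habitat", sort=True)["community_rer"]
        .agg(habitat_rer="mean", n_samples="size")
        .reset_index()
    )
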