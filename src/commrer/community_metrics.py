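"""Per-sample companion estimators: annotation-hit filtering, ACE richness,
average genome size, optimal growth temperature, transposase level, and the
transposase-vs-HGT validation correlation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetricsError",
    "filter_hits",
    "ace_richness",
    "average_genome_size",
    "ogt_estimate",
    "transposase_level",
    "hgt_proxy_validation",
    "DEFAULT_HIT_THRESHOLDS",
]


class MetricsError(ValueError):
    pass


# reliable-hit standard for annotation evidence
DEFAULT_HIT_THRESHOLDS = {
    "min_match_length": 100,
    "min_identity": 50.0,
    "min_coverage": 50.0,
    "min_score": 60.0,
}

ANNOTATION_COLUMNS = [
    "gene_id",
    "match_length",
    "identity",
    "coverage",
    "score",
    "cog_category",
    "is_transposase",
]

OGT_RESIDUES = frozenset("IVYWREL")


def filter_hits(
    table: pd.DataFrame, thresholds: Dict[str, float] | None = None
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Keep annotation rows passing all reliability thresholds.

    Returns the filtered table and the per-criterion count of rows failing
    each threshold (a row can fail several).  Idempotent.
    """
    th = dict(DEFAULT_HIT_THRESHOLDS)
    th.update(thresholds or {})
    fails = {
        "match_length": table["match_length"] < th["min_match_length"],
        "identity": table["identity"] < th["min_identity"],
        "coverage": table["coverage"] < th["min_coverage"],
        "score": table["score"] < th["min_score"],
    }
    removed = {k: int(v.sum()) for k, v in fails.items()}
    keep = ~np.logical_or.reduce(list(fails.values()))
    out = table.loc[keep].reset_index(drop=True)
    if out.empty:
        warnings.warn("no annotation rows passed the hit filter")
    return out, removed


def ace_richness(counts: Sequence[int], rare_threshold: int = 10) -> float:
    """Abundance-based coverage estimator (Chao & Lee) of species richness.

    S_abund = taxa with count > threshold; rare taxa (count <= threshold)
    contribute via sample coverage C = 1 - F1/N_rare and the rare-taxa
    coefficient of variation gamma^2.  Falls back to Chao1 when every rare
    taxon is a singleton (C = 0), and to observed richness when N_rare <= 1.
    """
    arr = np.asarray(counts, dtype=float)
    arr = arr[arr > 0]
    if arr.size == 0 or arr.sum() <= 0:
        raise MetricsError("abundance vector has no positive counts")
    if not np.all(arr == np.floor(arr)):
        raise MetricsError("abundances must be integer counts")
    s_obs = arr.size
    rare = arr[arr <= rare_threshold]
    s_abund = int((arr > rare_threshold).sum())
    s_rare = rare.size
    if s_rare == 0:
        return float(s_obs)
    n_rare = rare.sum()
    f1 = int((rare == 1).sum())
    if n_rare <= 1:
        warnings.warn("N_rare <= 1; returning observed richness")
        return float(s_obs)
    c = 1.0 - f1 / n_rare
    if c == 0.0:
        # all rare taxa are singletons: Chao1 fallback
        f2 = int((arr == 2).sum())
        warnings.warn("all rare taxa are singletons; falling back to Chao1")
        return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))
    freq = np.arange(1, rare_threshold + 1)
    f_i = np.array([(rare == i).sum() for i in freq], dtype=float)
    gamma2 = max(
        (s_rare / c) * float((freq * (freq - 1) * f_i).sum()) / (n_rare * (n_rare - 1))
        - 1.0,
        0.0,
    )
    return float(s_abund + s_rare / c + (f1 / c) * gamma2)


def average_genome_size(
    avg_read_length: float,
    marker_hits: Dict[str, int] | int,
    total_bp: float,
    marker_bp_per_genome: float = 15_000.0,
) -> float:
    """Average genome size (bp) from the density of marker-gene hits.

    marker density d = (sum_m R_m * L) / R_total; AGS = marker_bp_per_genome/d.
    ``marker_bp_per_genome`` is a calibration constant: the approximate summed
    length of the universal single-copy marker genes per genome.
    """
    if avg_read_length <= 0:
        raise MetricsError("average read length must be > 0")
    total_hits = (
        sum(marker_hits.values()) if isinstance(marker_hits, dict) else int(marker_hits)
    )
    if total_hits <= 0:
        raise MetricsError("no marker hits; AGS undefined")
    marker_bp = total_hits * avg_read_length
    if marker_bp > total_bp:
        raise MetricsError(
            f"marker bp ({marker_bp:.3g}) exceeds total sequenced bp ({total_bp:.3g})"
        )
    density = marker_bp / total_bp
    return marker_bp_per_genome / density


def ogt_estimate(proteins: str) -> float:
    """Community optimal growth temperature: OGT = 937*F - 335, with F the
    fraction of residues in {I,V,Y,W,R,E,L}."""
    residues = [r for r in proteins.upper() if r.isalpha() and r != "*"]
    if not residues:
        raise MetricsError("no protein residues supplied")
    f = sum(r in OGT_RESIDUES for r in residues) / len(residues)
    return 937.0 * f - 335.0


def transposase_level(table: pd.DataFrame) -> float:
    """Fraction of (filtered) annotated genes flagged as transposases."""
    if len(table) == 0:
        raise MetricsError("no annotated genes")
    return float(np.asarray(table["is_transposase"], dtype=bool).mean())


def hgt_proxy_validation(
    transposase_counts: Sequence[float], hgt_counts: Sequence[float]
) -> Tuple[float, float]:
    """Spearman correlation between per-genome transposase counts and HGT
    event counts (the proxy's sanity check); ties via average ranks."""
    x = np.asarray(transposase_counts, dtype=float)
    y = np.asarray(hgt_counts, dtype=float)
    if x.size != y.size:
        raise MetricsError("count vectors differ in length")
    if x.size < 5:
        raise MetricsError("need >= 5 genomes")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant column; correlation undefined, returning 0")
        return 0.0, 1.0
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def read_annotation_table(path) -> pd.DataFrame:
    """Read an annotation TSV with the standard column set."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise MetricsError(f"annotation table missing columns: {missing}")
    df["is_transposase"] = df["is_transposase"].astype(bool)
    return df


def read_abundance_table(path) -> Dict[str, int]:
    """Read a ``taxon<TAB>count`` TSV (header required)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise MetricsError("abundance table needs taxon and count columns")
    taxa = df.iloc[:, 0].astype(str)
    counts = df.iloc[:, 1].astype(int)
    if (counts < 0).any():
        raise MetricsError("negative abundance count")
    return dict(zip(taxa, counts))
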