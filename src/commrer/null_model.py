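"""Composition-matched resampling null for community rERs.

All marker records of a habitat are pooled; communities are re-created by
drawing records stratified by phylum to match each sample's phylogenetic
composition, at the size of the smallest sample in the habitat.  The
observed marker-rER distribution is then compared to the simulated one with
a two-sided Kolmogorov-Smirnov test, BH-corrected across samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HabitatPool",
    "DeviationResult",
    "NullModelError",
    "pool_habitat_markers",
    "largest_remainder_allocation",
    "simulate_community",
    "expected_rer_distribution",
    "ks_deviation_test",
    "run_deviation_tests",
]

logger = logging.getLogger(__name__)


class NullModelError(ValueError):
    pass


@dataclass
class HabitatPool:
    habitat: str
    rers: np.ndarray  # pooled marker rERs
    phyla: np.ndarray  # matching phylum label per record
    n_min: int  # smallest member sample's marker count

    def __post_init__(self):
        self.rers = np.asarray(self.rers, dtype=float)
        self.phyla = np.asarray(self.phyla, dtype=object)
        if self.rers.size != self.phyla.size:
            raise NullModelError("rer/phylum arrays differ in length")
        if self.n_min < 1:
            raise NullModelError("n_min must be >= 1")

    @property
    def size(self) -> int:
        return int(self.rers.size)

    def by_phylum(self) -> Dict[str, np.ndarray]:
        out: Dict[str, np.ndarray] = {}
        for ph in sorted(set(self.phyla.tolist())):
            out[ph] = self.rers[self.phyla == ph]
        return out


@dataclass
class DeviationResult:
    sample_id: str
    observed_rer: float
    expected_rers: np.ndarray  # simulated community rERs
    ks_statistic: float
    p_value: float
    p_adjusted: float = np.nan
    deviation: float = np.nan  # observed - median expected
    low_confidence: bool = False


def pool_habitat_markers(
    samples: Dict[str, Tuple[Sequence[float], Sequence[str]]], habitat: str = ""
) -> HabitatPool:
    """Pool the (rER, phylum) marker records of >=2 samples from one habitat."""
    if len(samples) < 2:
        raise NullModelError(
            "composition-matched null requires >=2 samples per habitat"
        )
    rers: List[float] = []
    phyla: List[str] = []
    sizes = []
    for sid in sorted(samples):
        r, p = samples[sid]
        if len(r) != len(p):
            raise NullModelError(f"sample {sid}: rer/phylum length mismatch")
        if len(r) == 0:
            raise NullModelError(f"sample {sid}: empty marker set")
        sizes.append(len(r))
        rers.extend(float(v) for v in r)
        phyla.extend(p)
    return HabitatPool(
        habitat=habitat, rers=np.array(rers), phyla=np.array(phyla, dtype=object),
        n_min=min(sizes),
    )


def largest_remainder_allocation(proportions: Dict[str, float], n: int) -> Dict[str, int]:
    """Integer stratum counts summing to n: floor shares plus largest-remainder
    top-up (remainder ties broken by stratum name)."""
    keys = sorted(proportions)
    probs = np.array([proportions[k] for k in keys], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise NullModelError(f"composition sums to {probs.sum():.9f}, not 1")
    shares = probs * n
    counts = np.floor(shares).astype(int)
    remainder = n - counts.sum()
    order = sorted(range(len(keys)), key=lambda i: (-(shares[i] - counts[i]), keys[i]))
    for i in order[:remainder]:
        counts[i] += 1
    return {k: int(c) for k, c in zip(keys, counts)}


def simulate_community(
    pool: HabitatPool,
    composition: Dict[str, float],
    n: int,
    seed: int,
    return_draw: bool = False,
):
    """Draw one simulated community of size n from the pool, stratified by
    phylum, and return its community rER (the median of the drawn marker
    rERs).

    Counts per phylum follow the largest-remainder allocation of the target
    composition.  Within a stratum, records are drawn without replacement;
    if a stratum is exhausted the overflow is drawn with replacement (logged).
    """
    strata = pool.by_phylum()
    missing = sorted(set(composition) - set(strata))
    if missing:
        raise NullModelError(f"composition phyla absent from pool: {missing}")
    counts = largest_remainder_allocation(composition, n)
    rng = np.random.default_rng(seed)
    draw: List[np.ndarray] = []
    for ph in sorted(counts):
        k = counts[ph]
        if k == 0:
            continue
        values = strata[ph]
        if k <= values.size:
            draw.append(rng.choice(values, size=k, replace=False))
        else:
            logger.info(
                "stratum %r exhausted (%d available, %d requested); "
                "sampling overflow with replacement", ph, values.size, k,
            )
            draw.append(values)
            draw.append(rng.choice(values, size=k - values.size, replace=True))
    drawn = np.concatenate(draw) if draw else np.array([])
    if drawn.size == 0:
        raise NullModelError("empty simulated community")
    med = float(np.median(drawn))
    return (med, drawn) if return_draw else med


def expected_rer_distribution(
    pool: HabitatPool,
    composition: Dict[str, float],
    n: int,
    B: int = 1000,
    seed: int = 0,
    min_B: int = 100,
):
    """B independent simulated communities.

    Returns ``(community_rers, marker_rers)``: the B simulated community rERs
    and the pooled marker-rER draws across replicates (used as the expected
    distribution in the KS deviation test).  Replicate r uses derived seed
    ``seed + r`` so the chain is reproducible and restartable.
    """
    if B < 1:
        raise NullModelError("B must be >= 1")
    if B < min_B:
        warnings.warn(f"B={B} < {min_B}: expected distribution will be coarse")
    community = np.empty(B)
    draws = []
    for r in range(B):
        med, drawn = simulate_community(pool, composition, n, seed=seed + r, return_draw=True)
        community[r] = med
        draws.append(drawn)
    return community, np.concatenate(draws)


def ks_deviation_test(
    observed: Sequence[float],
    expected_markers: Sequence[float],
    expected_community: Optional[Sequence[float]] = None,
    sample_id: str = "",
) -> DeviationResult:
    """Two-sided two-sample KS test of observed marker rERs against the
    pooled simulated marker rERs.

    The signed deviation is observed community rER minus the median of the
    simulated community rERs (falling back to the median of the expected
    marker sample when community replicates are not supplied).
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected_markers, dtype=float)
    if obs.size == 0 or exp.size == 0:
        raise NullModelError("both samples must be non-empty")
    low_conf = obs.size < 3 or exp.size < 3
    if low_conf:
        warnings.warn(
            f"sample {sample_id or '<unnamed>'}: n < 3; KS p is low-confidence"
        )
    res = stats.ks_2samp(obs, exp, alternative="two-sided", method="auto")
    obs_rer = float(np.median(obs))
    exp_center = float(
        np.median(expected_community if expected_community is not None else exp)
    )
    return DeviationResult(
        sample_id=sample_id,
        observed_rer=obs_rer,
        expected_rers=np.asarray(
            expected_community if expected_community is not None else [], dtype=float
        ),
        ks_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        deviation=obs_rer - exp_center,
        low_confidence=low_conf,
    )


def run_deviation_tests(
    habitat_samples: Dict[str, Dict[str, Tuple[Sequence[float], Sequence[str]]]],
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Composition-matched deviation test for every sample, BH-corrected
    across all samples of the run.

    ``habitat_samples`` maps habitat -> {sample_id: (marker rERs, phyla)}.
    Per-sample seeds are chained from the master seed by habitat/sample index
    so results are deterministic and independent of dict ordering.
    """
    results: List[DeviationResult] = []
    sample_counter = 0
    for habitat in sorted(habitat_samples):
        samples = habitat_samples[habitat]
        pool = pool_habitat_markers(samples, habitat=habitat)
        for sid in sorted(samples):
            rers, phyla = samples[sid]
            comp_counts: Dict[str, int] = {}
            for ph in phyla:
                comp_counts[ph] = comp_counts.get(ph, 0) + 1
            total = sum(comp_counts.values())
            composition = {ph: c / total for ph, c in comp_counts.items()}
            community, markers = expected_rer_distribution(
                pool, composition, pool.n_min, B=B,
                seed=seed + 100_003 * sample_counter,
            )
            res = ks_deviation_test(rers, markers, community, sample_id=sid)
            results.append(res)
            sample_counter += 1

    padj = stats.false_discovery_control([r.p_value for r in results], method="bh")
    rows = []
    for r, pa in zip(results, padj):
        r.p_adjusted = float(pa)
        rows.append(
            {
                "sample_id": r.sample_id,
                "observed_rer": r.observed_rer,
                "ks_statistic": r.ks_statistic,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "deviation": r.deviation,
                "significant": r.p_adjusted < alpha,
                "low_confidence": r.low_confidence,
            }
        )
    return pd.DataFrame(rows).sort_values("sample_id", kind="mergesort").reset_index(drop=True)
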