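"""Pairwise dN/dS by Nei-Gojobori (1986) counting with Jukes-Cantor correction.

Site counts exclude mutations to stop codons from the per-position
denominator; multi-difference codons are resolved by averaging the
synonymous/nonsynonymous tallies over all equally-weighted substitution
orderings, skipping orderings that pass through a stop codon.  Distances are
corrected as d = -(3/4) ln(1 - (4/3) p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Data import CodonTable
from Bio.SeqIO import parse as seqio_parse

__all__ = [
    "DndsResult",
    "DndsError",
    "codon_site_counts",
    "pairwise_dnds",
    "community_dnds",
    "read_pair_fasta",
]

BASES = "ACGT"


class DndsError(ValueError):
    pass


@lru_cache(maxsize=8)
def _code(table_id: int = 1):
    table = CodonTable.unambiguous_dna_by_id[table_id]
    fwd = dict(table.forward_table)
    stops = set(table.stop_codons)
    return fwd, stops


def _is_countable(codon: str, stops) -> bool:
    return (
        len(codon) == 3
        and all(b in BASES for b in codon)
        and codon not in stops
    )


@lru_cache(maxsize=None)
def codon_site_counts(codon: str, table_id: int = 1) -> Tuple[float, float]:
    """(nonsynonymous, synonymous) site counts of one codon.

    Per position, the synonymous fraction is (# synonymous single-nucleotide
    mutations) / (# mutations not creating a stop); n_sites = 3 - s_sites.
    """
    fwd, stops = _code(table_id)
    if codon in stops:
        raise DndsError(f"stop codon {codon} is not countable")
    if not _is_countable(codon, stops):
        raise DndsError(f"ambiguous or gapped codon {codon!r}")
    aa = fwd[codon]
    s_sites = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in stops:
                continue
            valid += 1
            if fwd[mut] == aa:
                syn += 1
        if valid:
            s_sites += syn / valid
    return 3.0 - s_sites, s_sites


@lru_cache(maxsize=None)
def _codon_pair_differences(c1: str, c2: str, table_id: int = 1) -> Tuple[float, float]:
    """Pathway-averaged (nonsynonymous, synonymous) difference counts between
    two codons.

    All orderings of the differing positions are weighted equally; orderings
    passing through a stop codon are excluded.  If every ordering is blocked
    by stops, all orderings are used as a fallback (standard practice)."""
    fwd, stops = _code(table_id)
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: Tuple[int, ...], allow_stops: bool) -> Optional[Tuple[int, int]]:
        nd = sd = 0
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in stops and not allow_stops:
                return None
            if nxt in stops or cur in stops:
                nd += 1  # stop transitions counted as nonsynonymous in fallback
            elif fwd[nxt] == fwd[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return nd, sd

    import itertools

    orders = list(itertools.permutations(diff_pos))
    tallies = [t for t in (walk(o, False) for o in orders) if t is not None]
    if not tallies:
        tallies = [walk(o, True) for o in orders]
    nd = sum(t[0] for t in tallies) / len(tallies)
    sd = sum(t[1] for t in tallies) / len(tallies)
    return nd, sd


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        raise DndsError("proportion >= 3/4: distance saturated")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class DndsResult:
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    pn: float
    ps: float
    dn: Optional[float]
    ds: Optional[float]
    omega: Optional[float]
    n_codons: int  # countable codons
    status: str  # ok | dS_zero | saturated

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def pairwise_dnds(
    seq1: str,
    seq2: str,
    table_id: int = 1,
    min_codons: int = 10,
) -> DndsResult:
    """NG86 pairwise dN/dS between two aligned coding sequences.

    Codons containing gaps or ambiguity codes in either sequence, and aligned
    stop codons, are dropped pairwise.  Symmetric in its arguments.
    """
    s1 = seq1.upper()
    s2 = seq2.upper()
    if len(s1) != len(s2):
        raise DndsError("aligned sequences differ in length")
    if len(s1) % 3:
        raise DndsError("alignment length not divisible by 3")
    _, stops = _code(table_id)

    n_sites = s_sites = 0.0
    nd = sd = 0.0
    n_codons = 0
    for i in range(0, len(s1), 3):
        c1, c2 = s1[i : i + 3], s2[i : i + 3]
        if not (_is_countable(c1, stops) and _is_countable(c2, stops)):
            continue
        n_codons += 1
        n1, sy1 = codon_site_counts(c1, table_id)
        n2, sy2 = codon_site_counts(c2, table_id)
        n_sites += (n1 + n2) / 2.0
        s_sites += (sy1 + sy2) / 2.0
        # pathway counts are symmetric; canonicalize for the cache
        a, b = (c1, c2) if c1 <= c2 else (c2, c1)
        d_n, d_s = _codon_pair_differences(a, b, table_id)
        nd += d_n
        sd += d_s

    if n_codons < min_codons:
        raise DndsError(
            f"only {n_codons} countable codons (< {min_codons} required)"
        )
    pn = nd / n_sites if n_sites > 0 else 0.0
    ps = sd / s_sites if s_sites > 0 else 0.0

    status = "ok"
    dn: Optional[float] = None
    ds: Optional[float] = None
    omega: Optional[float] = None
    if pn >= 0.75 or ps >= 0.75:
        status = "saturated"
    else:
        dn = _jc_correct(pn)
        ds = _jc_correct(ps)
        if ds == 0.0:
            status = "dS_zero"
        else:
            omega = dn / ds
    return DndsResult(
        n_sites=n_sites, s_sites=s_sites, nd=nd, sd=sd, pn=pn, ps=ps,
        dn=dn, ds=ds, omega=omega, n_codons=n_codons, status=status,
    )


def community_dnds(results: Sequence[DndsResult], aggregate: str = "median") -> Dict[str, float]:
    """Aggregate pairwise results for one sample.

    Returns the median (or mean) omega over usable pairs, the interquartile
    range, the fraction of pairs with omega < 1 (purifying-selection
    indicator), and the tally of excluded (non-ok) pairs.
    """
    ok = [r.omega for r in results if r.ok]
    if not ok:
        raise DndsError("no pairs with a defined omega")
    arr = np.asarray(ok, dtype=float)
    center = float(np.median(arr)) if aggregate == "median" else float(arr.mean())
    q1, q3 = np.percentile(arr, [25, 75])
    return {
        "omega": center,
        "iqr": float(q3 - q1),
        "fraction_purifying": float((arr < 1.0).mean()),
        "n_pairs": int(arr.size),
        "n_excluded": int(len(results) - arr.size),
    }


def read_pair_fasta(path) -> Tuple[str, str]:
    """Read an aligned pair (exactly two records) from a FASTA file."""
    records = list(seqio_parse(path, "fasta"))
    if len(records) != 2:
        raise DndsError(f"expected exactly 2 records in {path}, got {len(records)}")
    return str(records[0].seq), str(records[1].seq)
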