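"""Synthetic study generator.

Produces complete in-memory or on-disk studies with the statistical structure
the pipeline assumes: a reference phylogeny with monophyletic phyla, marker
placements with habitat-specific rate deviations injected through the
attachment geometry, codon pairs evolved at a stated omega, annotation tables
with stated transposase fractions and COG log-odds effects, and lognormal
abundance vectors.  Everything is deterministic given the master seed, and
every emitted file parses through the corresponding reader.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from Bio.Data import CodonTable

from .placement import PlacementRecord
from .tree_model import ReferenceTree, read_newick, write_newick

__all__ = [
    "DEFAULT_MARKERS",
    "COG_CATEGORIES",
    "StudyConfig",
    "HabitatConfig",
    "SimulatedTree",
    "simulate_reference_tree",
    "simulate_placements",
    "placements_to_jplace",
    "simulate_codon_pairs",
    "simulate_annotation_table",
    "simulate_abundances",
    "simulate_study",
]

# 31 universal single-copy marker families (ribosomal proteins, tRNA
# synthetases, SecY, RNA polymerase alpha), by COG label
DEFAULT_MARKERS = (
    "COG0012", "COG0016", "COG0018", "COG0048", "COG0049", "COG0052",
    "COG0080", "COG0081", "COG0087", "COG0088", "COG0090", "COG0091",
    "COG0092", "COG0093", "COG0094", "COG0096", "COG0097", "COG0098",
    "COG0099", "COG0100", "COG0102", "COG0103", "COG0124", "COG0172",
    "COG0184", "COG0185", "COG0186", "COG0197", "COG0200", "COG0201",
    "COG0202",
)

COG_CATEGORIES = tuple("JKLDVTMNUOCGEFHIPQRS")


class SyntheticDataError(ValueError):
    pass


# -- reference tree --------------------------------------------------------


@dataclass
class SimulatedTree:
    tree: ReferenceTree
    taxonomy: Dict[str, str]
    tip_depths: Dict[str, float]  # generator bookkeeping, by construction
    phylum_medians: Dict[str, float]
    newick: str


def _join_random(subtrees: List[Tuple[str, Dict[str, float]]], rng, lo: float, hi: float):
    """Random sequence of pairwise joins with uniform branch lengths."""
    subtrees = list(subtrees)
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        nj, dj = subtrees.pop(int(j))
        ni, di = subtrees.pop(int(i))
        li, lj = rng.uniform(lo, hi, size=2)
        merged_newick = f"({ni}:{li:.10g},{nj}:{lj:.10g})"
        depths = {t: d + li for t, d in di.items()}
        depths.update({t: d + lj for t, d in dj.items()})
        subtrees.append((merged_newick, depths))
    return subtrees[0]


def simulate_reference_tree(
    n_taxa: int, n_phyla: int, seed: int,
    within_lengths: Tuple[float, float] = (0.02, 0.25),
    between_lengths: Tuple[float, float] = (0.1, 0.5),
) -> SimulatedTree:
    """Random rooted reference tree with each phylum a monophyletic clade.

    Tips are named ``p<i>_t<j>`` and assigned to phylum ``phylum_<i>``.  The
    generator records every tip's root-to-tip depth by construction, and the
    per-phylum medians, as ground truth for downstream checks.
    """
    if n_phyla < 1 or n_taxa < 2 * n_phyla:
        raise SyntheticDataError("need n_taxa >= 2 * n_phyla (>= 2 tips/phylum)")
    rng = np.random.default_rng(seed)
    sizes = np.full(n_phyla, n_taxa // n_phyla)
    sizes[: n_taxa % n_phyla] += 1

    taxonomy: Dict[str, str] = {}
    clades: List[Tuple[str, Dict[str, float]]] = []
    for p in range(n_phyla):
        tips = []
        for j in range(int(sizes[p])):
            name = f"p{p}_t{j}"
            taxonomy[name] = f"phylum_{p}"
            tips.append((name, {name: 0.0}))
        # give each tip a pendant length, then join within the phylum
        tips = [
            (f"{n}", d) for n, d in tips
        ]
        clades.append(_join_random(tips, rng, *within_lengths))
    newick_body, depths = _join_random(clades, rng, *between_lengths)
    newick = newick_body + ";"
    tree = read_newick(newick)
    tree.rooted = True

    medians: Dict[str, float] = {}
    for p in range(n_phyla):
        vals = [depths[t] for t, ph in taxonomy.items() if ph == f"phylum_{p}"]
        medians[f"phylum_{p}"] = float(np.median(vals))
    return SimulatedTree(tree, taxonomy, depths, medians, newick)


# -- placements ------------------------------------------------------------


def simulate_placements(
    sim_tree: SimulatedTree,
    composition: Dict[str, float],
    delta: float,
    n_markers: int,
    seed: int,
    sigma: float = 0.05,
    markers: Sequence[str] = DEFAULT_MARKERS,
    max_retries: int = 200,
) -> Tuple[List[PlacementRecord], pd.DataFrame]:
    """Markers placed so each query's root-to-tip length is
    ``(1 + delta + eps) * phylum_median``, with eps ~ truncated Normal(0, sigma).

    Returns the placement records and a ground-truth table with each query's
    intended rER (= delta + eps) and tip length.
    """
    if delta <= -1:
        raise SyntheticDataError("delta must be > -1")
    tree = sim_tree.tree
    taxonomy = sim_tree.taxonomy
    rng = np.random.default_rng(seed)
    depths = tree.depths()

    # per-phylum candidate edges: edges whose child lies inside the clade
    tip_by_label = {lab: v for v, lab in tree.labels.items()}
    phylum_nodes: Dict[str, set] = {}
    for taxon, ph in taxonomy.items():
        phylum_nodes.setdefault(ph, set()).add(tip_by_label[taxon])
    clade_edges: Dict[str, List[int]] = {}
    for ph, tips in phylum_nodes.items():
        # smallest clade containing the phylum's tips: climb from one tip
        node = next(iter(tips))
        while not tips <= _descendant_tips(tree, node):
            node = tree.parent[node]
        members = _descendant_nodes(tree, node)
        clade_edges[ph] = sorted(v for v in members if tree.parent[v] is not None)

    phyla = sorted(composition)
    probs = np.array([composition[p] for p in phyla], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise SyntheticDataError("composition must sum to 1")

    records: List[PlacementRecord] = []
    truth_rows = []
    for i in range(n_markers):
        ph = phyla[int(rng.choice(len(phyla), p=probs))]
        median = sim_tree.phylum_medians[ph]
        edges = clade_edges[ph]
        placed = False
        for _ in range(max_retries):
            eps = float(rng.normal(0.0, sigma)) if sigma > 0 else 0.0
            if 1.0 + delta + eps <= 1e-3:
                continue
            target = (1.0 + delta + eps) * median
            feasible = [
                v for v in edges if depths[v] - tree.lengths[v] <= target
            ]
            if not feasible:
                continue
            v = feasible[int(rng.integers(len(feasible)))]
            depth_prox = depths[v] - tree.lengths[v]
            max_off = min(tree.lengths[v], target - depth_prox)
            offset = float(rng.uniform(0.0, max_off))
            pendant = target - depth_prox - offset
            marker = markers[i % len(markers)]
            qid = f"{marker}|q{i:05d}"
            records.append(
                PlacementRecord(
                    query_id=qid,
                    marker_id=marker,
                    edge_num=tree.edge_nums[v],
                    offset=offset,
                    pendant=pendant,
                    weight=1.0,
                    phylum=ph,
                )
            )
            truth_rows.append(
                {
                    "query_id": qid,
                    "marker_id": marker,
                    "phylum": ph,
                    "intended_rer": delta + eps,
                    "tip_length": target,
                }
            )
            placed = True
            break
        if not placed:
            raise SyntheticDataError(
                f"could not place marker {i} in phylum {ph} after retries"
            )
    return records, pd.DataFrame(truth_rows)


def _descendant_tips(tree: ReferenceTree, node: int) -> set:
    out = set()
    stack = [node]
    while stack:
        v = stack.pop()
        if tree.is_tip(v):
            out.add(v)
        stack.extend(tree.children.get(v, []))
    return out


def _descendant_nodes(tree: ReferenceTree, node: int) -> set:
    out = set()
    stack = [node]
    while stack:
        v = stack.pop()
        out.add(v)
        stack.extend(tree.children.get(v, []))
    return out


def placements_to_jplace(
    tree: ReferenceTree, records: Sequence[PlacementRecord], sample_id: str = ""
) -> dict:
    """Valid jplace (v3) document for a set of single-candidate placements."""
    return {
        "version": 3,
        "tree": write_newick(tree, edge_numbers=True),
        "fields": [
            "edge_num", "likelihood", "like_weight_ratio",
            "distal_length", "pendant_length",
        ],
        "placements": [
            {
                "p": [[r.edge_num, 0.0, r.weight, r.offset, r.pendant]],
                "n": [r.query_id],
            }
            for r in records
        ],
        "metadata": {"invocation": "commrer synthetic_data", "sample": sample_id},
    }


# -- codon pairs -----------------------------------------------------------


def _sense_codons(table_id: int = 1) -> List[str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return sorted(table.forward_table)


def simulate_codon_pairs(
    omega: float,
    n_pairs: int,
    n_codons: int,
    seed: int,
    divergence: float = 0.4,
    table_id: int = 1,
) -> List[Tuple[str, str]]:
    """Pairs of coding sequences diverged from a common ancestor.

    Point mutations are proposed uniformly; synonymous proposals are always
    accepted, nonsynonymous ones with relative probability ``omega``;
    proposals creating stop codons are rejected.  Each lineage receives a
    Poisson(divergence/2 * n_codons) number of proposal events.
    """
    if omega < 0:
        raise SyntheticDataError("omega must be >= 0")
    table = CodonTable.unambiguous_dna_by_id[table_id]
    fwd = dict(table.forward_table)
    stops = set(table.stop_codons)
    sense = _sense_codons(table_id)
    rng = np.random.default_rng(seed)
    bases = "ACGT"

    def evolve(codons: List[str]) -> List[str]:
        out = list(codons)
        n_events = rng.poisson(0.5 * divergence * n_codons)
        for _ in range(n_events):
            ci = int(rng.integers(n_codons))
            pos = int(rng.integers(3))
            cur = out[ci]
            alt = bases[int(rng.integers(4))]
            if alt == cur[pos]:
                continue
            mut = cur[:pos] + alt + cur[pos + 1 :]
            if mut in stops:
                continue
            if fwd[mut] != fwd[cur] and rng.random() >= omega:
                continue
            out[ci] = mut
        return out

    pairs = []
    for _ in range(n_pairs):
        ancestor = [sense[int(i)] for i in rng.integers(len(sense), size=n_codons)]
        pairs.append(("".join(evolve(ancestor)), "".join(evolve(ancestor))))
    return pairs


def write_pairs_fasta(pairs: Sequence[Tuple[str, str]], path) -> None:
    """Write consecutive-record pairs (pair<i>_a / pair<i>_b)."""
    with open(path, "w") as fh:
        for i, (a, b) in enumerate(pairs):
            fh.write(f">pair{i:04d}_a\n{a}\n>pair{i:04d}_b\n{b}\n")


def read_pairs_fasta(path) -> List[Tuple[str, str]]:
    """Read consecutive-record pairs written by :func:`write_pairs_fasta`."""
    from Bio import SeqIO

    records = list(SeqIO.parse(path, "fasta"))
    if len(records) % 2:
        raise SyntheticDataError(f"odd number of records in {path}")
    return [
        (str(records[i].seq), str(records[i + 1].seq))
        for i in range(0, len(records), 2)
    ]


# -- annotation tables -----------------------------------------------------


def simulate_annotation_table(
    n_genes: int,
    tau: float,
    cog_effects: Optional[Dict[str, float]] = None,
    seed: int = 0,
    categories: Sequence[str] = COG_CATEGORIES,
) -> pd.DataFrame:
    """Annotation table with Bernoulli(tau) transposase flags and COG
    categories drawn from a softmax-adjusted base composition.

    ``cog_effects`` gives per-category log-odds shifts against the uniform
    base; filter-relevant columns are generated so that all rows pass the
    default hit thresholds.
    """
    if not 0.0 <= tau <= 1.0:
        raise SyntheticDataError("tau must be in [0, 1]")
    effects = dict(cog_effects or {})
    unknown = sorted(set(effects) - set(categories))
    if unknown:
        raise SyntheticDataError(f"effects for unknown categories: {unknown}")
    rng = np.random.default_rng(seed)
    logits = np.array([effects.get(c, 0.0) for c in categories], dtype=float)
    probs = np.exp(logits - logits.max())
    probs /= probs.sum()
    cats = rng.choice(len(categories), size=n_genes, p=probs)
    return pd.DataFrame(
        {
            "gene_id": [f"gene{i:06d}" for i in range(n_genes)],
            "match_length": rng.integers(100, 400, size=n_genes),
            "identity": np.round(rng.uniform(50.0, 100.0, size=n_genes), 2),
            "coverage": np.round(rng.uniform(50.0, 100.0, size=n_genes), 2),
            "score": np.round(rng.uniform(60.0, 500.0, size=n_genes), 1),
            "cog_category": [categories[int(i)] for i in cats],
            "is_transposase": rng.random(n_genes) < tau,
        }
    )


# -- abundances ------------------------------------------------------------


def simulate_abundances(
    s_true: int,
    regime: str = "lognormal",
    seed: int = 0,
    depth: int = 20_000,
    sigma: float = 1.0,
) -> Dict[str, int]:
    """Abundance vector over ``s_true`` taxa.

    regime "lognormal": lognormal relative abundances, multinomial sampling
    at ``depth``.  regime "census": every taxon observed with a count above
    the default rare threshold (complete observation; ACE = s_true).
    """
    if s_true < 1:
        raise SyntheticDataError("s_true must be >= 1")
    if depth < 1:
        raise SyntheticDataError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    taxa = [f"taxon{i:05d}" for i in range(s_true)]
    if regime == "census":
        counts = 11 + rng.poisson(20, size=s_true)
        return dict(zip(taxa, (int(c) for c in counts)))
    if regime != "lognormal":
        raise SyntheticDataError(f"unknown regime: {regime}")
    rel = rng.lognormal(0.0, sigma, size=s_true)
    rel /= rel.sum()
    counts = rng.multinomial(depth, rel)
    return {t: int(c) for t, c in zip(taxa, counts) if c > 0}


# -- whole-study bundles ---------------------------------------------------


@dataclass
class HabitatConfig:
    label: str
    n_samples: int = 6
    delta: float = 0.15
    omega: float = 0.3
    tau: float = 0.003
    s_true: int = 200
    ogt_f: float = 0.39
    extreme: bool = False
    cog_effects: Dict[str, float] = field(default_factory=dict)


@dataclass
class StudyConfig:
    seed: int = 0
    habitats: List[HabitatConfig] = field(default_factory=list)
    n_taxa: int = 60
    n_phyla: int = 6
    markers_per_sample: int = 60
    codon_pairs_per_sample: int = 12
    codon_length: int = 150
    codon_divergence: float = 0.4
    n_genes_per_sample: int = 2000
    abundance_depth: int = 8000
    read_length: float = 400.0
    total_bp: float = 2.0e7
    rer_sigma: float = 0.05

    @classmethod
    def default(cls, seed: int = 0) -> "StudyConfig":
        """6-habitat study mirroring the extreme/normal contrast: three
        fast-evolving, transposase-rich, low-diversity habitats and three
        slow, diverse ones."""
        extremes = dict(delta=0.30, omega=0.45, tau=0.010, s_true=150,
                        extreme=True, cog_effects={"L": math.log(2)})
        normals = dict(delta=0.13, omega=0.20, tau=0.0006, s_true=240,
                       extreme=False)
        return cls(
            seed=seed,
            habitats=[
                HabitatConfig("amd", ogt_f=0.39, **extremes),
                HabitatConfig("saline_lake", ogt_f=0.39, **extremes),
                HabitatConfig("hot_spring", ogt_f=0.43, **extremes),
                HabitatConfig("surface_ocean", ogt_f=0.38, **normals),
                HabitatConfig("freshwater", ogt_f=0.38, **normals),
                HabitatConfig("soil", ogt_f=0.39, **normals),
            ],
        )


def simulate_study(config: StudyConfig, out_dir) -> Path:
    """Write a complete on-disk study bundle.

    Emits the reference newick (with edge numbers), taxonomy TSV, per-sample
    jplace / query manifest / annotation / abundance / codon-pair / protein
    files, the study manifest, the serialized config, and ``truth.json`` with
    every generator parameter.  Deterministic: the same config (including
    seed) yields byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    sim_tree = simulate_reference_tree(config.n_taxa, config.n_phyla, seed=config.seed)
    (out / "reference.nwk").write_text(
        write_newick(sim_tree.tree, edge_numbers=True) + "\n"
    )
    with open(out / "taxonomy.tsv", "w") as fh:
        fh.write("taxon_id\tphylum\n")
        for taxon in sorted(sim_tree.taxonomy):
            fh.write(f"{taxon}\t{sim_tree.taxonomy[taxon]}\n")

    phyla = sorted(sim_tree.phylum_medians)
    manifest_rows = []
    truth: Dict[str, dict] = {"config": _config_dict(config), "samples": {}}
    sample_index = 0
    for hab in config.habitats:
        for j in range(hab.n_samples):
            sid = f"{hab.label}_s{j}"
            sseed = int(config.seed + 7919 * (sample_index + 1))
            srng = np.random.default_rng(sseed)
            comp = srng.dirichlet(np.full(len(phyla), 3.0))
            composition = {p: float(c) for p, c in zip(phyla, comp)}

            records, truth_table = simulate_placements(
                sim_tree, composition, hab.delta, config.markers_per_sample,
                seed=sseed, sigma=config.rer_sigma,
            )
            doc = placements_to_jplace(sim_tree.tree, records, sample_id=sid)
            (out / f"{sid}.jplace").write_text(json.dumps(doc, sort_keys=True))
            with open(out / f"{sid}_queries.tsv", "w") as fh:
                fh.write("query_id\tmarker_id\tphylum\n")
                for r in records:
                    fh.write(f"{r.query_id}\t{r.marker_id}\t{r.phylum}\n")

            pairs = simulate_codon_pairs(
                hab.omega, config.codon_pairs_per_sample, config.codon_length,
                seed=sseed + 1, divergence=config.codon_divergence,
            )
            write_pairs_fasta(pairs, out / f"{sid}_pairs.fasta")

            ann = simulate_annotation_table(
                config.n_genes_per_sample, hab.tau, hab.cog_effects, seed=sseed + 2,
            )
            ann.to_csv(out / f"{sid}_annotations.tsv", sep="\t", index=False)

            abund = simulate_abundances(
                hab.s_true, "lognormal", seed=sseed + 3, depth=config.abundance_depth,
            )
            with open(out / f"{sid}_abundance.tsv", "w") as fh:
                fh.write("taxon\tcount\n")
                for t in sorted(abund):
                    fh.write(f"{t}\t{abund[t]}\n")

            proteins = _protein_string(hab.ogt_f, 5000, srng)
            (out / f"{sid}_proteins.fasta").write_text(
                f">{sid}_proteome\n{proteins}\n"
            )

            manifest_rows.append(
                {
                    "sample_id": sid,
                    "habitat": hab.label,
                    "annotation": "extreme" if hab.extreme else "normal",
                    "jplace": f"{sid}.jplace",
                    "queries": f"{sid}_queries.tsv",
                    "annotations": f"{sid}_annotations.tsv",
                    "abundance": f"{sid}_abundance.tsv",
                    "pairs": f"{sid}_pairs.fasta",
                    "proteins": f"{sid}_proteins.fasta",
                    "read_length": config.read_length,
                    "total_bp": config.total_bp,
                    "pool_group": "",
                }
            )
            truth["samples"][sid] = {
                "habitat": hab.label,
                "extreme": hab.extreme,
                "delta": hab.delta,
                "omega": hab.omega,
                "tau": hab.tau,
                "s_true": hab.s_true,
                "ogt_f": hab.ogt_f,
                "seed": sseed,
                "composition": composition,
                "intended_community_rer": float(
                    np.median(truth_table["intended_rer"])
                ),
            }
            sample_index += 1

    pd.DataFrame(manifest_rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    with open(out / "study_config.yaml", "w") as fh:
        yaml.safe_dump(_config_dict(config), fh, sort_keys=True)
    return out


_OGT_SET = "IVYWREL"
_OTHER_RESIDUES = "ACDFGHKMNPQST"


def _protein_string(f: float, n: int, rng) -> str:
    k = int(round(f * n))
    residues = [_OGT_SET[int(i)] for i in rng.integers(len(_OGT_SET), size=k)]
    residues += [
        _OTHER_RESIDUES[int(i)] for i in rng.integers(len(_OTHER_RESIDUES), size=n - k)
    ]
    return "".join(residues)


def _config_dict(config: StudyConfig) -> dict:
    d = asdict(config)
    return d
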