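import json

import numpy as np
import pandas as pd
import pytest

from commrer import community_metrics as cm
from commrer import placement as pl
from commrer import selection_dnds as dn
from commrer import synthetic_data as sd
from commrer import tree_model as tm


# -- reference tree --------------------------------------------------------


def test_tree_monophyly_and_sizes():
    sim = sd.simulate_reference_tree(20, 4, seed=1)
    assert sim.tree.n_tips == 20
    by_phylum = {}
    for taxon, ph in sim.taxonomy.items():
        by_phylum.setdefault(ph, []).append(taxon)
    assert len(by_phylum) == 4
    for ph, taxa in by_phylum.items():
        assert len(taxa) >= 2
        # monophyly: the MRCA of the phylum's tips contains only them
        nodes = {v for v, lab in sim.tree.labels.items() if lab in taxa}
        node = next(iter(nodes))
        while not nodes <= sd._descendant_tips(sim.tree, node):
            node = sim.tree.parent[node]
        assert sd._descendant_tips(sim.tree, node) == nodes


def test_tree_determinism():
    a = sd.simulate_reference_tree(20, 4, seed=9)
    b = sd.simulate_reference_tree(20, 4, seed=9)
    assert a.newick == b.newick
    assert sd.simulate_reference_tree(20, 4, seed=10).newick != a.newick


def test_tree_medians_match_tree_model(sim_tree):
    medians = tm.phylum_reference_medians(sim_tree.tree, sim_tree.taxonomy)
    for ph, truth in sim_tree.phylum_medians.items():
        assert medians[ph] == pytest.approx(truth, abs=1e-9)


def test_tree_depths_match_tree_model(sim_tree):
    lengths = tm.root_to_tip_lengths(sim_tree.tree)
    for taxon, depth in sim_tree.tip_depths.items():
        assert lengths[taxon] == pytest.approx(depth, abs=1e-9)


def test_tree_infeasible_parameters():
    with pytest.raises(sd.SyntheticDataError):
        sd.simulate_reference_tree(5, 3, seed=0)


# -- placements ------------------------------------------------------------


def even_composition(sim):
    phyla = sorted(sim.phylum_medians)
    return {p: 1.0 / len(phyla) for p in phyla}


def test_placements_delta_zero_sigma_zero(sim_tree):
    records, truth = sd.simulate_placements(
        sim_tree, even_composition(sim_tree), delta=0.0, n_markers=50, seed=2,
        sigma=0.0,
    )
    assert np.allclose(truth["intended_rer"], 0.0)
    for rec in records:
        med = sim_tree.phylum_medians[rec.phylum]
        assert pl.query_tip_length(sim_tree.tree, rec) == pytest.approx(med, abs=1e-9)


def test_placements_delta_recovery(sim_tree):
    _, truth = sd.simulate_placements(
        sim_tree, even_composition(sim_tree), delta=0.3, n_markers=200, seed=3,
        sigma=0.05,
    )
    assert float(np.median(truth["intended_rer"])) == pytest.approx(0.3, abs=0.03)


def test_placements_jplace_roundtrip(sim_tree):
    records, truth = sd.simulate_placements(
        sim_tree, even_composition(sim_tree), delta=0.2, n_markers=60, seed=4,
    )
    doc = json.dumps(sd.placements_to_jplace(sim_tree.tree, records))
    ps = pl.read_jplace(doc, sim_tree.tree, sample_id="s")
    assert len(ps.records) == 60
    expected = dict(zip(truth["query_id"], truth["tip_length"]))
    for rec in ps.best_per_query():
        assert pl.query_tip_length(sim_tree.tree, rec) == pytest.approx(
            expected[rec.query_id], abs=1e-9
        )


def test_placements_delta_bound():
    simt = sd.simulate_reference_tree(12, 3, seed=0)
    with pytest.raises(sd.SyntheticDataError):
        sd.simulate_placements(simt, even_composition(simt), delta=-1.0,
                               n_markers=5, seed=0)


def test_placements_marker_ids_cycle(sim_tree):
    records, _ = sd.simulate_placements(
        sim_tree, even_composition(sim_tree), delta=0.1, n_markers=35, seed=5,
    )
    assert records[0].marker_id == sd.DEFAULT_MARKERS[0]
    assert records[31].marker_id == sd.DEFAULT_MARKERS[0]
    assert len(sd.DEFAULT_MARKERS) == 31


# -- codon pairs -----------------------------------------------------------


def test_codon_pairs_omega_zero_all_synonymous():
    pairs = sd.simulate_codon_pairs(0.0, 10, 120, seed=6)
    for a, b in pairs:
        res = dn.pairwise_dnds(a, b)
        assert res.nd == 0.0
        if res.status == "ok":
            assert res.omega == 0.0


def test_codon_pairs_deterministic():
    assert sd.simulate_codon_pairs(0.5, 5, 60, seed=7) == sd.simulate_codon_pairs(
        0.5, 5, 60, seed=7
    )


def test_codon_pairs_no_stops():
    from Bio.Data import CodonTable

    stops = set(CodonTable.unambiguous_dna_by_id[1].stop_codons)
    for a, b in sd.simulate_codon_pairs(1.0, 10, 100, seed=8):
        for seq in (a, b):
            assert not any(seq[i:i + 3] in stops for i in range(0, len(seq), 3))


def test_codon_pairs_zero_divergence_identical():
    pairs = sd.simulate_codon_pairs(0.5, 5, 60, seed=9, divergence=0.0)
    assert all(a == b for a, b in pairs)


def test_pairs_fasta_roundtrip(tmp_path):
    pairs = sd.simulate_codon_pairs(0.3, 4, 30, seed=10)
    p = tmp_path / "pairs.fasta"
    sd.write_pairs_fasta(pairs, p)
    assert sd.read_pairs_fasta(p) == pairs


# -- annotations -----------------------------------------------------------


def test_annotation_tau_zero():
    t = sd.simulate_annotation_table(500, 0.0, seed=11)
    assert not t["is_transposase"].any()


def test_annotation_passes_default_filter():
    t = sd.simulate_annotation_table(300, 0.01, seed=12)
    filtered, removed = cm.filter_hits(t)
    assert len(filtered) == 300
    assert sum(removed.values()) == 0


def test_annotation_effect_recovery():
    import math

    from commrer import enrichment_cluster as ec

    focal_t = sd.simulate_annotation_table(
        100_000, 0.0, {"L": math.log(2)}, seed=13
    )
    base_t = sd.simulate_annotation_table(100_000, 0.0, seed=14)
    focal = focal_t["cog_category"].value_counts().to_dict()
    background = base_t["cog_category"].value_counts().to_dict()
    results = {r.category: r for r in ec.habitat_enrichment_profile(focal, background)}
    assert results["L"].log_odds_ratio == pytest.approx(math.log(2), abs=0.1)


def test_annotation_unknown_category_rejected():
    with pytest.raises(sd.SyntheticDataError, match="unknown"):
        sd.simulate_annotation_table(10, 0.0, {"??": 1.0}, seed=0)


# -- abundances ------------------------------------------------------------


def test_census_regime_ace_equals_s_true():
    abund = sd.simulate_abundances(150, "census", seed=15)
    assert cm.ace_richness(list(abund.values())) == 150.0


def test_lognormal_depth_and_positivity():
    abund = sd.simulate_abundances(100, "lognormal", seed=16, depth=5000)
    assert sum(abund.values()) == 5000
    assert all(c > 0 for c in abund.values())


def test_abundance_errors():
    with pytest.raises(sd.SyntheticDataError):
        sd.simulate_abundances(0, "lognormal", seed=0)
    with pytest.raises(sd.SyntheticDataError):
        sd.simulate_abundances(10, "lognormal", seed=0, depth=0)
    with pytest.raises(sd.SyntheticDataError):
        sd.simulate_abundances(10, "weird", seed=0)


# -- study bundles ---------------------------------------------------------


def test_study_bundle_files_parse(study_bundle):
    tree = tm.read_newick((study_bundle / "reference.nwk").read_text().strip())
    taxonomy = tm.read_taxonomy(str(study_bundle / "taxonomy.tsv"))
    assert set(tree.labels.values()) == set(taxonomy)
    manifest = pd.read_csv(study_bundle / "manifest.tsv", sep="\t")
    assert len(manifest) == 18
    row = manifest.iloc[0]
    ps = pl.read_jplace(
        (study_bundle / row["jplace"]).read_text(), tree, sample_id=row["sample_id"]
    )
    assert len(ps.records) == 40
    truth = json.loads((study_bundle / "truth.json").read_text())
    assert set(truth["samples"]) == set(manifest["sample_id"])


def test_study_bundle_deterministic(tmp_path):
    cfg = sd.StudyConfig.default(seed=3)
    for h in cfg.habitats:
        h.n_samples = 1
    cfg.markers_per_sample = 10
    cfg.codon_pairs_per_sample = 2
    cfg.codon_length = 30
    cfg.n_genes_per_sample = 50
    a = sd.simulate_study(cfg, tmp_path / "a")
    b = sd.simulate_study(cfg, tmp_path / "b")
    files_a = sorted(p.name for p in a.iterdir())
    assert files_a == sorted(p.name for p in b.iterdir())
    for name in files_a:
        assert (a / name).read_bytes() == (b / name).read_bytes(), name
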