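"""PEST discovery: role seeding, neighborhood network, cassettes,
superfamilies, conservation profiling."""

import numpy as np
import pytest

from prophikit.config import PipelineConfig
from prophikit.core import GeneFeature
from prophikit.errors import ConfigurationError, ValidationError
from prophikit.homology import ProfileDatabase, Pssm
from prophikit.pest import (
    build_neighborhood_network,
    conservation_profile,
    extract_cassettes,
    group_superfamilies,
    seed_pest_homologs,
)

from oracles import neighborhood_component_oracle

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, n):
    return "".join(rng.choice(list(AA), size=n))


def mutate(rng, p, rate):
    chars = list(p)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = str(rng.choice(list(AA)))
    return "".join(chars)


# -- role seeding ------------------------------------------------------------


@pytest.fixture(scope="module")
def role_db():
    rng = np.random.default_rng(0)
    pt = random_protein(rng, 200)
    wxg = random_protein(rng, 100)
    imm = random_protein(rng, 120)
    db = ProfileDatabase(
        [
            Pssm("pt1", "polymorphic_toxin", [pt]),
            Pssm("wxg1", "wxg100", [wxg]),
            Pssm("imm1", "immunity", [imm]),
        ]
    )
    return db, pt, wxg, imm, rng


def test_training_sequence_pham_seeds_its_role(role_db):
    db, pt, wxg, imm, _ = role_db
    phams = {"ph1": [("g1", pt)], "ph2": [("g2", wxg)], "ph3": [("g3", imm)]}
    roles = seed_pest_homologs(phams, db)
    assert roles == {
        "ph1": "polymorphic_toxin",
        "ph2": "wxg100",
        "ph3": "immunity",
    }


def test_random_pham_stays_unseeded(role_db):
    db, *_, rng = role_db
    phams = {"ph1": [(f"g{i}", random_protein(rng, 150)) for i in range(3)]}
    assert seed_pest_homologs(phams, db) == {}


def test_dual_hit_takes_higher_scoring_role(role_db):
    db, pt, wxg, _, _ = role_db
    # chimera carrying the full PT domain but only half the WXG domain:
    # the PT score dominates
    chimera = pt + wxg[:50]
    roles = seed_pest_homologs({"ph": [("g", chimera)]}, db)
    assert roles == {"ph": "polymorphic_toxin"}


def test_empty_profile_db_is_configuration_error(role_db):
    _, pt, *_ = role_db
    arch_only = ProfileDatabase([Pssm("a", "phage_archetype", [pt])])
    with pytest.raises(ConfigurationError):
        seed_pest_homologs({"ph": [("g", pt)]}, arch_only)


# -- neighborhood network ----------------------------------------------------


def layout_genes(layouts):
    """layouts: contig -> list of pham labels; returns (genes, gene_to_pham)."""
    genes, mapping = [], {}
    for contig, phams in layouts.items():
        for rank, pham in enumerate(phams):
            gid = f"{contig}_{rank}"
            genes.append(GeneFeature(gid, contig, rank * 100, rank * 100 + 90, "+", "M", rank))
            mapping[gid] = pham
    return genes, mapping


def test_single_toxin_neighborhood():
    genes, mapping = layout_genes({"c": ["a", "b", "PT", "c", "d"]})
    net = build_neighborhood_network(genes, mapping, ["PT"], radius=2)
    assert net.nodes == {"PT", "a", "b", "c", "d"}
    assert len([e for e in net.edges if "PT" in e]) == 4


def test_shared_neighbor_joins_two_genomes():
    genes, mapping = layout_genes(
        {"c1": ["a", "PT1", "x"], "c2": ["x", "PT2", "b"]}
    )
    net = build_neighborhood_network(genes, mapping, ["PT1", "PT2"], radius=2)
    assert {"PT1", "PT2", "x", "a", "b"} <= net.nodes


def test_empty_seed_set_gives_empty_network():
    genes, mapping = layout_genes({"c": ["a", "b"]})
    net = build_neighborhood_network(genes, mapping, [], radius=2)
    assert net.nodes == set() and net.iterations_to_fixpoint == 0


def test_gene_without_pham_rejected():
    genes, mapping = layout_genes({"c": ["a", "PT"]})
    del mapping["c_0"]
    with pytest.raises(ValidationError):
        build_neighborhood_network(genes, mapping, ["PT"], radius=2)


@pytest.mark.parametrize("radius", [1, 2, 3])
def test_fixpoint_equals_component_oracle_on_random_layouts(radius):
    rng = np.random.default_rng(radius)
    for _ in range(34):
        n_contigs = int(rng.integers(1, 4))
        layouts = {}
        pham_pool = [f"p{i}" for i in range(int(rng.integers(5, 20)))]
        for c in range(n_contigs):
            n_genes = int(rng.integers(1, 25))
            layouts[f"c{c}"] = [
                pham_pool[int(rng.integers(len(pham_pool)))] for _ in range(n_genes)
            ]
        present = {p for genes in layouts.values() for p in genes}
        if not present:
            continue
        seeds = list(rng.choice(sorted(present), size=min(2, len(present)), replace=False))
        genes, mapping = layout_genes(layouts)
        net = build_neighborhood_network(genes, mapping, seeds, radius=radius)
        contig_order = {c: [f"{c}_{r}" for r in range(len(genes_))]
                        for c, genes_ in layouts.items()}
        oracle = neighborhood_component_oracle(contig_order, mapping, seeds, radius)
        assert net.nodes == oracle


def test_seeds_only_expansion_stops_after_first_ring():
    genes, mapping = layout_genes({"c": ["a", "b", "PT", "c", "d", "e", "f"]})
    ring = build_neighborhood_network(genes, mapping, ["PT"], radius=1, expansion="seeds_only")
    assert ring.nodes == {"PT", "b", "c"}
    full = build_neighborhood_network(genes, mapping, ["PT"], radius=1, expansion="full")
    assert full.nodes == {"a", "b", "PT", "c", "d", "e", "f"}


# -- cassette extraction -----------------------------------------------------


def role_genes(spec, contig="c", strand="+", offset=0):
    """spec: list of (gene_id, role or None); builds rank-ordered genes."""
    genes, roles = [], {}
    for rank, (gid, role) in enumerate(spec):
        genes.append(
            GeneFeature(gid, contig, offset + rank * 100, offset + rank * 100 + 90, strand, "M", rank)
        )
        if role:
            roles[gid] = role
    return genes, roles


def test_three_and_four_gene_architectures():
    genes, roles = role_genes(
        [("h1", None), ("w", "wxg100"), ("p", "polymorphic_toxin"), ("i", "immunity"), ("h2", None)]
    )
    cassettes = extract_cassettes(genes, roles, "G")
    assert len(cassettes) == 1
    assert cassettes[0].roles == ["WXG", "PT", "Imm"]
    assert cassettes[0].architecture == "three_gene"

    genes, roles = role_genes(
        [("w1", "wxg100"), ("w2", "wxg100"), ("p", "polymorphic_toxin"), ("i", "immunity")]
    )
    assert extract_cassettes(genes, roles, "G")[0].architecture == "four_gene"


def test_pt_without_immunity_is_incomplete():
    genes, roles = role_genes([("w", "wxg100"), ("p", "polymorphic_toxin"), ("h", None)])
    cassette = extract_cassettes(genes, roles, "G")[0]
    assert cassette.architecture == "incomplete"
    assert cassette.roles == ["WXG", "PT"]


def test_position_invariance():
    spec = [("w", "wxg100"), ("p", "polymorphic_toxin"), ("i", "immunity")]
    a = extract_cassettes(*role_genes(spec), "G")
    b = extract_cassettes(*role_genes(spec, offset=50_000), "G")
    assert [(c.roles, c.architecture) for c in a] == [(c.roles, c.architecture) for c in b]


def test_strand_consistency_on_reverse_complemented_contig():
    fwd_spec = [("w", "wxg100"), ("p", "polymorphic_toxin"), ("i", "immunity")]
    fwd = extract_cassettes(*role_genes(fwd_spec, strand="+"), "G")
    # the same cassette on a fully reverse-complemented contig: gene order
    # mirrored, strand '-'
    rev_spec = [("i", "immunity"), ("p", "polymorphic_toxin"), ("w", "wxg100")]
    rev = extract_cassettes(*role_genes(rev_spec, strand="-"), "G")
    assert fwd[0].roles == rev[0].roles == ["WXG", "PT", "Imm"]
    assert rev[0].architecture == "three_gene"


def test_cassette_requires_exactly_one_pt():
    from prophikit.pest import PESTCassette

    with pytest.raises(ValidationError):
        PESTCassette("G", "c", ["a", "b"], ["WXG", "Imm"], "incomplete")


# -- superfamilies -----------------------------------------------------------


def test_identical_nterm_divergent_cterm_grouped():
    rng = np.random.default_rng(5)
    nterm = random_protein(rng, 150)
    phams = {
        "pA": [("g1", nterm + random_protein(rng, 200))],
        "pB": [("g2", nterm + random_protein(rng, 250))],
    }
    labels = group_superfamilies(phams, PipelineConfig(pest_nterm_window_aa=150))
    assert labels["pA"] == labels["pB"] == "PEST1"


def test_three_archetypes_recovered_without_cross_assignment():
    rng = np.random.default_rng(6)
    archetypes = [random_protein(rng, 200) for _ in range(3)]
    phams, expected = {}, {}
    for i, arch in enumerate(archetypes):
        for k in range(4):
            pid = f"p{i}_{k}"
            phams[pid] = [(pid, mutate(rng, arch, 0.10) + random_protein(rng, 220))]
            expected[pid] = i
    labels = group_superfamilies(phams, PipelineConfig())
    by_label = {}
    for pid, lab in labels.items():
        by_label.setdefault(lab, set()).add(expected[pid])
    assert len(by_label) == 3
    assert all(len(archs) == 1 for archs in by_label.values())  # zero crossing


def test_single_pham_is_pest1_and_permutation_invariance():
    rng = np.random.default_rng(7)
    solo = {"pX": [("g", random_protein(rng, 300))]}
    assert group_superfamilies(solo, PipelineConfig()) == {"pX": "PEST1"}

    nterm = random_protein(rng, 180)
    items = {
        f"p{i}": [(f"g{i}", nterm + random_protein(rng, 100))] for i in range(4)
    }
    fwd = group_superfamilies(dict(sorted(items.items())), PipelineConfig())
    rev = group_superfamilies(dict(sorted(items.items(), reverse=True)), PipelineConfig())
    assert fwd == rev


# -- conservation profiling --------------------------------------------------


def test_identical_sequences_fully_conserved_single_segment():
    profile = conservation_profile(["MARSWXG" * 20] * 4, smooth_window=5)
    assert np.allclose(profile.values, 1.0)
    assert profile.segments == [("WXG", 0, 140)]


def test_half_split_column_value():
    profile = conservation_profile(["AA", "AC"], smooth_window=1)
    assert profile.values[0] == pytest.approx(1.0)
    assert profile.values[1] == pytest.approx(0.5)


def test_gaps_counted_in_denominator():
    profile = conservation_profile(["A-", "AC", "AC", "A-"], smooth_window=1)
    assert profile.values[1] == pytest.approx(0.5)


def test_ragged_alignment_rejected():
    with pytest.raises(ValidationError):
        conservation_profile(["MAR", "MARS"])


def test_planted_domain_boundaries_recovered_within_tolerance():
    rng = np.random.default_rng(8)
    head = random_protein(rng, 100)  # conserved WXG
    tail = random_protein(rng, 150)  # conserved TOX
    seqs = [
        mutate(rng, head, 0.05) + random_protein(rng, 50) + mutate(rng, tail, 0.05)
        for _ in range(8)
    ]
    profile = conservation_profile(seqs, smooth_window=15)
    segments = dict((name, (s, e)) for name, s, e in profile.segments)
    assert set(segments) == {"WXG", "linker", "TOX"}
    assert abs(segments["WXG"][1] - 100) <= 10
    assert abs(segments["TOX"][0] - 150) <= 10
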