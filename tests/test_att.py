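"""Attachment-site machinery: core repeats, reference mapping, consensus,
attP circularization and feature overlap."""

import numpy as np
import pytest

from prophikit.att import (
    AttCore,
    AttOccurrence,
    ConsensusAttB,
    LocatedOccurrence,
    annotate_overlap,
    consensus_attB,
    find_core_repeats,
    integrate_at_attB,
    map_att_to_reference,
    reconstruct_attP,
)
from prophikit.config import PipelineConfig
from prophikit.core import Contig, GenomeAssembly, RnaFeature
from prophikit.errors import ConsistencyError
from prophikit.simulate import random_dna


def lysogen(rng, core_len=45, phage_len=6000, flank=5000):
    """host-left + attL + phage + attR + host-right, with pinned flanking
    bases so the planted core is the maximal repeat."""
    core = random_dna(rng, core_len)
    phage = "C" + random_dna(rng, phage_len - 2) + "C"
    left = random_dna(rng, flank - 1) + "A"
    right = "A" + random_dna(rng, flank - 1)
    seq = left + core + phage + core + right
    start = len(left)
    end = start + 2 * core_len + phage_len
    return seq, core, (start, end)


def test_planted_core_recovered_exactly():
    rng = np.random.default_rng(0)
    seq, core, (start, end) = lysogen(rng)
    asm = GenomeAssembly("1", "A", [Contig("c", seq)])
    found = find_core_repeats(asm, "c", (start, end))
    assert found is not None
    assert found.sequence == core
    assert found.attL_interval == (start, start + len(core))
    assert found.attR_interval == (end - len(core), end)


def test_no_repeat_returns_none():
    rng = np.random.default_rng(1)
    seq = random_dna(rng, 3000)
    asm = GenomeAssembly("1", "A", [Contig("c", seq)])
    cfg = PipelineConfig(boundary_search_bp=200, min_core_len_bp=12)
    assert find_core_repeats(asm, "c", (1000, 2000), cfg) is None


def test_equal_length_candidates_take_leftmost_pair():
    rng = np.random.default_rng(2)
    core = random_dna(rng, 30)
    filler = random_dna(rng, 500)
    # two left copies and one right copy, with pinned mismatching flanks
    # so no chance extension beats the planted length: leftmost attL wins
    seq = (
        random_dna(rng, 200) + "A" + core + "A" + random_dna(rng, 98) + "G" + core + "G"
        + filler + "C" + core + "C" + random_dna(rng, 200)
    )
    asm = GenomeAssembly("1", "A", [Contig("c", seq)])
    cfg = PipelineConfig(boundary_search_bp=400, min_core_len_bp=10)
    left_boundary = 201
    right_boundary = 201 + 30 + 100 + 32 + 500 + 31
    found = find_core_repeats(asm, "c", (left_boundary, right_boundary), cfg)
    assert len(found.sequence) == 30
    assert found.attL_start == 201


def test_interval_outside_contig_raises():
    asm = GenomeAssembly("1", "A", [Contig("c", "ACGT" * 100)])
    with pytest.raises(IndexError):
        find_core_repeats(asm, "c", (0, 9999))


# -- mapping to a reference --------------------------------------------------


@pytest.fixture(scope="module")
def reference():
    rng = np.random.default_rng(3)
    return GenomeAssembly("ref", "R", [Contig("chrom", random_dna(rng, 40000))]), rng


def occurrence_from(ref_seq, core_pos, core_len, strain, flank=200, snps=0, rng=None):
    core = ref_seq[core_pos : core_pos + core_len]
    left = ref_seq[core_pos - flank : core_pos]
    right = ref_seq[core_pos + core_len : core_pos + core_len + flank]
    seq = left + core + right
    if snps:
        chars = list(seq)
        for i in rng.choice(flank - 1, size=snps, replace=False):
            chars[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[i]]
        seq = "".join(chars)
    return AttOccurrence(strain, core, seq, flank, flank + core_len)


def test_exact_and_snp_flank_occurrences_place_at_same_locus(reference):
    ref, rng = reference
    ref_seq = ref.contigs[0].sequence
    occ_exact = occurrence_from(ref_seq, 10000, 45, "S1")
    occ_snp = occurrence_from(ref_seq, 10000, 45, "S2", snps=5, rng=rng)
    located = map_att_to_reference([occ_exact, occ_snp], ref)
    assert all(rec.placed for rec in located)
    assert {(rec.ref_start, rec.ref_end) for rec in located} == {(10000, 10045)}


def test_duplicated_flank_is_ambiguous():
    rng = np.random.default_rng(4)
    segment = random_dna(rng, 600)
    ref_seq = random_dna(rng, 5000) + segment + random_dna(rng, 5000) + segment + random_dna(rng, 5000)
    ref = GenomeAssembly("ref", "R", [Contig("chrom", ref_seq)])
    occ = AttOccurrence("S1", segment[200:245], segment[:445], 200, 245)
    located = map_att_to_reference([occ], ref)
    assert located[0].ambiguous and not located[0].placed


# -- consensus ---------------------------------------------------------------


def _loc(strain, start, end):
    rec = LocatedOccurrence(AttOccurrence(strain, "X", "X", 0, 1))
    rec.ref_start, rec.ref_end = start, end
    return rec


def test_consensus_identical_intervals():
    sites = consensus_attB([_loc("a", 1000, 1045), _loc("b", 1000, 1045), _loc("c", 1000, 1045)])
    assert len(sites) == 1
    assert sites[0].reference_interval == (1000, 1045)
    assert sites[0].attB_id == "attB-1"


def test_consensus_is_interval_intersection():
    sites = consensus_attB(
        [_loc("a", 1000, 1045), _loc("b", 997, 1042), _loc("c", 1003, 1048)]
    )
    assert len(sites) == 1
    assert sites[0].reference_interval == (1003, 1042)
    # the consensus is contained in every member occurrence
    for _, (s, e) in sites[0].occurrences:
        assert s <= sites[0].start and sites[0].end <= e


def test_disjoint_groups_numbered_by_position():
    sites = consensus_attB([_loc("a", 9000, 9045), _loc("b", 1000, 1045)])
    assert [(s.attB_id, s.reference_interval) for s in sites] == [
        ("attB-1", (1000, 1045)),
        ("attB-2", (9000, 9045)),
    ]


def test_pathological_chain_splits_at_largest_gap():
    # a–b overlap, b–c overlap, but a∩c is empty: chain intersection empty
    with pytest.warns(UserWarning):
        sites = consensus_attB(
            [_loc("a", 1000, 1050), _loc("b", 1040, 1120), _loc("c", 1110, 1160)]
        )
    assert len(sites) == 2


# -- attP reconstruction and integration ------------------------------------


def test_attP_junction_contains_core_once_and_length_identity():
    rng = np.random.default_rng(5)
    core = random_dna(rng, 40)
    internal = random_dna(rng, 3000)
    prophage = core + internal + core
    junction = reconstruct_attP(prophage, core)
    assert len(junction.sequence) == len(prophage) - len(core)
    assert junction.sequence.count(core) == 1
    assert junction.sequence.startswith(core)


def test_attP_requires_core_at_both_ends():
    rng = np.random.default_rng(6)
    core = random_dna(rng, 40)
    with pytest.raises(ConsistencyError):
        reconstruct_attP(core + random_dna(rng, 1000), core)


def test_excision_integration_round_trip_on_random_fixtures():
    """Excise then re-integrate is the identity on 100 random lysogens."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        core = random_dna(rng, int(rng.integers(12, 60)))
        host = random_dna(rng, 800) + core + random_dna(rng, 800)
        attB_pos = 800
        internal = random_dna(rng, int(rng.integers(500, 2000)))
        lysogen_seq = (
            host[:attB_pos] + core + internal + core + host[attB_pos + len(core) :]
        )
        prophage = core + internal + core
        junction = reconstruct_attP(prophage, core)
        assert integrate_at_attB(host, attB_pos, junction) == lysogen_seq


# -- tRNA/tmRNA overlap ------------------------------------------------------


def make_site(start, end):
    return ConsensusAttB("attB-1", start, end, [("s", (start, end))])


def test_overlap_with_tRNA_reports_isotype():
    trna = RnaFeature("r1", "chrom", 990, 1070, "tRNA", "tRNA-Arg (TCT)")
    site = make_site(1000, 1045)
    assert annotate_overlap(site, [trna]) == "tRNA-Arg (TCT)"
    assert site.overlap_feature == "tRNA-Arg (TCT)"


def test_intergenic_site_has_no_overlap():
    trna = RnaFeature("r1", "chrom", 5000, 5080, "tRNA", "tRNA-Gly (GCC)")
    assert annotate_overlap(make_site(1000, 1045), [trna]) is None


def test_tmRNA_overlap_and_largest_overlap_tiebreak():
    tm = RnaFeature("r1", "chrom", 1000, 1300, "tmRNA", "")
    small = RnaFeature("r2", "chrom", 1310, 1400, "tRNA", "tRNA-Leu (TAA)")
    site = make_site(1280, 1320)
    assert annotate_overlap(site, [small, tm]) == "tmRNA"  # 20 bp > 10 bp
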