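"""Contig-end fragment detection and prophage splicing."""

import numpy as np
import pytest

from prophikit.config import PipelineConfig
from prophikit.core import Contig, GenomeAssembly, reverse_complement
from prophikit.errors import AnnotationError, GroupingError, ValidationError
from prophikit.homology import ProfileDatabase, Pssm
from prophikit.io import PhageDatabase
from prophikit.simulate import PlannedGene, make_toy_phage, random_dna
from prophikit.splice import (
    ProphageFragment,
    assign_cluster_from_reference,
    find_end_fragments,
    group_fragments_by_reference,
    make_profile_validator,
    splice_fragments,
    validate_spliced,
)


@pytest.fixture(scope="module")
def phage():
    plan = [PlannedGene("phage_archetype", length_aa=170) for _ in range(14)]
    return make_toy_phage(seed=11, length=12000, gene_plan=plan, phage_id="phiT")


@pytest.fixture(scope="module")
def phage_db(phage):
    return PhageDatabase({"phiT": phage.sequence}, {"phiT": "K"})


@pytest.fixture(scope="module")
def config():
    return PipelineConfig()


def split_assembly(phage_seq, cut, seed=5, flank=8000, reverse_second=False):
    """Host with the phage head ending contig 1 and the tail starting
    contig 2 (optionally stored reverse-complemented)."""
    rng = np.random.default_rng(seed)
    head, tail = phage_seq[:cut], phage_seq[cut:]
    c1 = random_dna(rng, flank) + head
    c2 = reverse_complement(tail) if reverse_second else tail
    c2 = c2 + random_dna(rng, flank) if not reverse_second else random_dna(rng, flank) + c2
    return GenomeAssembly("7", "S", [Contig("c1", c1), Contig("c2", c2)])


def test_split_prophage_yields_two_end_fragments(phage, phage_db, config):
    asm = split_assembly(phage.sequence, cut=5000)
    frags = find_end_fragments(asm, phage_db, config)
    assert len(frags) == 2
    by_contig = {f.contig_id: f for f in frags}
    assert by_contig["c1"].end_distance == 0
    assert by_contig["c2"].end_distance == 0
    assert by_contig["c1"].ref_interval == (0, 5000)
    assert by_contig["c2"].ref_interval == (5000, 12000)


def test_interior_match_outside_end_margin_excluded(phage, phage_db, config):
    rng = np.random.default_rng(6)
    contig = random_dna(rng, 10000) + phage.sequence[:4000] + random_dna(rng, 10000)
    asm = GenomeAssembly("7", "S", [Contig("c", contig)])
    assert find_end_fragments(asm, phage_db, config) == []


def test_no_similarity_gives_no_fragments(phage_db, config):
    rng = np.random.default_rng(7)
    asm = GenomeAssembly("7", "S", [Contig("c", random_dna(rng, 20000))])
    assert find_end_fragments(asm, phage_db, config) == []


def test_splice_reconstructs_planted_sequence_exactly(phage, phage_db, config):
    asm = split_assembly(phage.sequence, cut=5000)
    frags = find_end_fragments(asm, phage_db, config)
    sp = splice_fragments(frags, asm, phage_db, config)
    assert sp.sequence == phage.sequence
    assert sp.completeness == "complete_on_reference"
    assert sp.gaps == []


def test_splice_fixes_reverse_oriented_fragment(phage, phage_db, config):
    asm = split_assembly(phage.sequence, cut=5000, reverse_second=True)
    frags = find_end_fragments(asm, phage_db, config)
    orientations = {f.contig_id: f.orientation for f in frags}
    assert orientations["c2"] == "-"
    sp = splice_fragments(frags, asm, phage_db, config)
    assert sp.sequence == phage.sequence


def test_splice_order_invariance(phage, phage_db, config):
    asm = split_assembly(phage.sequence, cut=7000)
    frags = find_end_fragments(asm, phage_db, config)
    fwd = splice_fragments(frags, asm, phage_db, config).sequence
    rev = splice_fragments(frags[::-1], asm, phage_db, config).sequence
    assert fwd == rev


def test_single_fragment_is_partial(phage, phage_db, config):
    rng = np.random.default_rng(8)
    asm = GenomeAssembly(
        "7", "S", [Contig("c1", random_dna(rng, 6000) + phage.sequence[:5000])]
    )
    frags = find_end_fragments(asm, phage_db, config)
    assert len(frags) == 1
    sp = splice_fragments(frags, asm, phage_db, config)
    assert sp.completeness == "partial"
    assert sp.sequence == phage.sequence[:5000]


def test_mixed_references_require_grouping(phage, phage_db, config):
    f1 = ProphageFragment("c1", 0, 3000, "phiT", 0, 3000, "+", 0, 1.0)
    f2 = ProphageFragment("c2", 0, 3000, "phiX", 0, 3000, "+", 0, 1.0)
    asm = split_assembly(phage.sequence, cut=5000)
    with pytest.raises(GroupingError):
        splice_fragments([f1, f2], asm, phage_db, config)
    assert set(group_fragments_by_reference([f1, f2])) == {"phiT", "phiX"}


def test_cluster_label_propagates_and_missing_label_raises(phage, phage_db, config):
    asm = split_assembly(phage.sequence, cut=5000)
    frags = find_end_fragments(asm, phage_db, config)
    sp = splice_fragments(frags, asm, phage_db, config)
    assert assign_cluster_from_reference(sp, phage_db) == "K"
    unlabeled = PhageDatabase({"phiT": phage.sequence}, {})
    with pytest.raises(AnnotationError):
        assign_cluster_from_reference(sp, unlabeled)


@pytest.fixture(scope="module")
def profile_db(phage):
    profiles = [
        Pssm(f"a{i}", "phage_archetype", [prot[1:]])  # drop the leading Met
        for i, (_, _, _, prot, _) in enumerate(
            (g for g in phage.genes if g[4] == "phage_archetype")
        )
    ]
    return ProfileDatabase(profiles)


def test_validator_accepts_self_and_rejects_random(phage, phage_db, profile_db, config):
    asm = split_assembly(phage.sequence, cut=5000)
    frags = find_end_fragments(asm, phage_db, config)
    sp = splice_fragments(frags, asm, phage_db, config)
    validator = make_profile_validator(profile_db, config)
    assert validate_spliced(sp, validator, config=config) is True
    assert sp.validated

    rng = np.random.default_rng(9)
    sp_random = splice_fragments(frags, asm, phage_db, config)
    sp_random.sequence = random_dna(rng, len(phage.sequence), gc=0.62)
    assert validate_spliced(sp_random, validator, config=config) is False


def test_validator_exception_propagates(phage, phage_db, config):
    asm = split_assembly(phage.sequence, cut=5000)
    frags = find_end_fragments(asm, phage_db, config)
    sp = splice_fragments(frags, asm, phage_db, config)

    def broken(sequence, genes):
        raise RuntimeError("boom")

    with pytest.raises(ValidationError):
        validate_spliced(sp, broken, config=config)
    assert sp.validated is False


def test_exact_split_recovery_over_many_random_cuts(phage, phage_db, config):
    """Random internal split positions always reconstruct exactly."""
    rng = np.random.default_rng(10)
    for trial in range(50):
        cut = int(rng.integers(2500, len(phage.sequence) - 2500))
        asm = split_assembly(phage.sequence, cut=cut, seed=100 + trial, flank=4000)
        frags = find_end_fragments(asm, phage_db, config)
        sp = splice_fragments(frags, asm, phage_db, config)
        assert sp.sequence == phage.sequence, f"cut={cut}"
        assert sp.completeness == "complete_on_reference"
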