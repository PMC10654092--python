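"""Sliding-window scanner, region classification, QC filter and dedup."""

import itertools

import numpy as np
import pytest

from prophikit.config import PipelineConfig
from prophikit.core import Contig, GenomeAssembly, GeneFeature, ProphageCall
from prophikit.errors import ValidationError
from prophikit.homology import ProfileHit
from prophikit.io import PhageDatabase
from prophikit.regions import (
    classify_region,
    dedupe_prophages,
    filter_prophage_calls,
    flag_defective,
    scan_regions,
)
from prophikit.simulate import random_dna

from oracles import window_regions_oracle


def make_genes(n, contig="c"):
    return [
        GeneFeature(f"g{r}", contig, r * 1000, r * 1000 + 900, "+", "M", r)
        for r in range(n)
    ]


def hit(gene_id, category="phage_archetype", significant=True):
    return ProfileHit(gene_id, "p1", category, 50.0 if significant else 1.0, significant)


def test_no_hits_no_regions():
    assert scan_regions(make_genes(30), [], 15) == []


def test_single_hit_window_union_extent():
    genes = make_genes(100)
    regions = scan_regions(genes, [hit("g20")], 15)
    assert len(regions) == 1
    assert regions[0].gene_rank_span == (6, 34)
    assert window_regions_oracle(100, {20}, 15) == [(6, 34)]
    assert regions[0].bp_interval == (6 * 1000, 34 * 1000 + 900)


def test_merge_and_disjoint_hits():
    genes = make_genes(100)
    two = scan_regions(genes, [hit("g10"), hit("g60")], 15)
    assert [r.gene_rank_span for r in two] == [(0, 24), (46, 74)]
    one = scan_regions(genes, [hit("g10"), hit("g20")], 15)
    assert [r.gene_rank_span for r in one] == [(0, 34)]


def test_unknown_gene_in_hits_rejected():
    with pytest.raises(ValidationError):
        scan_regions(make_genes(5), [hit("nope")], 15)


@pytest.mark.parametrize("window", [1, 5, 15])
def test_scan_matches_bruteforce_on_random_layouts(window):
    rng = np.random.default_rng(window)
    for _ in range(150):
        n = int(rng.integers(1, 60))
        n_hits = int(rng.integers(0, min(n, 6) + 1))
        ranks = set(map(int, rng.choice(n, size=n_hits, replace=False)))
        genes = make_genes(n)
        regions = scan_regions(genes, [hit(f"g{r}") for r in sorted(ranks)], window)
        assert [r.gene_rank_span for r in regions] == window_regions_oracle(
            n, ranks, window
        )


def test_hit_bounded_extent_shrinks_to_hits():
    genes = make_genes(100)
    regions = scan_regions(genes, [hit("g20"), hit("g25")], 15, extent="hit_bounded")
    assert [r.gene_rank_span for r in regions] == [(20, 25)]


@pytest.mark.parametrize(
    "integrase,capsid,other", list(itertools.product([0, 1], repeat=3))
)
def test_classification_truth_table(integrase, capsid, other):
    """All 8 presence combinations of integrase x capsid x other phage gene."""
    genes = make_genes(20)
    hits = []
    if integrase:
        hits.append(hit("g5", "integrase"))
    if capsid:
        hits.append(hit("g6", "major_capsid"))
    if other:
        hits.append(hit("g7", "phage_archetype"))
    regions = scan_regions(genes, hits, 15)
    if not hits:
        assert regions == []
        return
    classes = classify_region(regions[0], [])
    assert ("integrated_element" in classes) == bool(integrase)
    assert ("phage_related" in classes) == bool(capsid or other)
    assert ("candidate_PICI" in classes) == bool(integrase and capsid)


def test_integrated_element_excludes_prophage_overlap():
    genes = make_genes(20)
    regions = scan_regions(genes, [hit("g5", "integrase")], 15)
    call = ProphageCall("prophi1.A-1", "1.A", "c", 4000, 8000, "A" * 4000)
    assert "integrated_element" not in classify_region(regions[0], [call])
    omitted = ProphageCall(
        "prophi1.A-2", "1.A", "c", 4000, 8000, "A" * 4000, status="omitted"
    )
    assert "integrated_element" in classify_region(regions[0], [omitted])


# -- defective flagging ------------------------------------------------------


@pytest.fixture(scope="module")
def remnant_setup():
    rng = np.random.default_rng(0)
    phage = random_dna(rng, 20000)
    db = PhageDatabase({"phi": phage}, {"phi": "A"})
    remnant = phage[6000:14000]  # exact 8 kb remnant
    return rng, phage, db, remnant


def region_over(contig_seq, start, end):
    genes = [
        GeneFeature("g0", "c", start, start + 60, "+", "M", 0),
        GeneFeature("g1", "c", end - 60, end, "+", "M", 1),
    ]
    regions = scan_regions(genes, [hit("g0"), hit("g1")], 15)
    return regions[0]


def test_exact_remnant_flagged(remnant_setup):
    rng, phage, db, remnant = remnant_setup
    contig = random_dna(np.random.default_rng(1), 5000) + remnant + random_dna(
        np.random.default_rng(2), 5000
    )
    asm = GenomeAssembly("1", "A", [Contig("c", contig)])
    region = region_over(contig, 4000, 15000)
    flagged, evidence = flag_defective(region, asm, db)
    assert flagged and evidence
    assert "defective_prophage" in region.classes


def test_region_without_phage_sequence_not_flagged(remnant_setup):
    _, _, db, _ = remnant_setup
    contig = random_dna(np.random.default_rng(3), 12000)
    asm = GenomeAssembly("1", "A", [Contig("c", contig)])
    region = region_over(contig, 2000, 10000)
    flagged, evidence = flag_defective(region, asm, db)
    assert not flagged and evidence == []


def test_mutated_remnant_threshold_dependence(remnant_setup):
    """A ~70%-identity remnant fails at 0.80 identity and is recovered at
    0.60 (with an extension budget wide enough to cross mutation runs)."""
    from prophikit.simulate import mutate_dna

    rng = np.random.default_rng(4)
    _, phage, db, remnant = remnant_setup
    mutated = mutate_dna(rng, remnant, 0.30)  # ~70% identity
    contig = random_dna(np.random.default_rng(5), 5000) + mutated + random_dna(
        np.random.default_rng(6), 5000
    )
    asm = GenomeAssembly("1", "A", [Contig("c", contig)])
    strict = PipelineConfig(min_alignment_identity=0.80, xdrop=60)
    lenient = PipelineConfig(min_alignment_identity=0.60, xdrop=60)
    region = region_over(contig, 4000, 15000)
    assert flag_defective(region, asm, db, strict)[0] is False
    region2 = region_over(contig, 4000, 15000)
    assert flag_defective(region2, asm, db, lenient)[0] is True


def test_mask_intervals_suppress_prophage_evidence(remnant_setup):
    _, phage, db, remnant = remnant_setup
    contig = random_dna(np.random.default_rng(7), 5000) + remnant + random_dna(
        np.random.default_rng(8), 5000
    )
    asm = GenomeAssembly("1", "A", [Contig("c", contig)])
    region = region_over(contig, 4000, 15000)
    flagged, _ = flag_defective(region, asm, db, mask_intervals=[(5000, 13000)])
    assert flagged is False


# -- prophage QC filter ------------------------------------------------------


def build_call(contig_id, start, end, asm, core=None, designation="prophi1.A-1"):
    return ProphageCall(
        designation, "1.A", contig_id, start, end,
        asm.contig(contig_id).sequence[start:end], core_att=core,
    )


def qc_fixture():
    """One contig with a mid-contig call, a call ending at the contig end,
    and a call over mostly unannotated (bacterial) genes."""
    rng = np.random.default_rng(9)
    contig = random_dna(rng, 60000)
    asm = GenomeAssembly("1", "A", [Contig("c", contig)])
    genes, hits = [], []
    for r in range(20):  # phage genes 5k-25k (region of the good call)
        g = GeneFeature(f"p{r}", "c", 5000 + r * 1000, 5000 + r * 1000 + 900, "+", "M", r)
        genes.append(g)
        hits.append(hit(g.gene_id))
    # contaminated region 30k-50k: 4 phage genes among 16 host genes
    for r in range(20):
        g = GeneFeature(f"q{r}", "c", 30000 + r * 1000, 30000 + r * 1000 + 900, "+", "M", 20 + r)
        genes.append(g)
        if r % 5 == 0:
            hits.append(hit(g.gene_id))
    # truncated region at the right contig end
    for r in range(6):
        g = GeneFeature(f"t{r}", "c", 54000 + r * 1000, 54000 + r * 1000 + 900, "+", "M", 40 + r)
        genes.append(g)
        hits.append(hit(g.gene_id))
    return asm, genes, hits


def test_filter_keeps_good_omits_truncated_and_contaminated():
    from prophikit.att import AttCore

    asm, genes, hits = qc_fixture()
    core = AttCore("ACGTACGTACGTACGTACGTA", 4979, 5000, 25900, 25921)
    good = build_call("c", 4979, 25921, asm, core=core, designation="prophi1.A-1")
    contaminated = build_call("c", 30000, 49900, asm, designation="prophi1.A-2")
    truncated = build_call("c", 54000, 59900, asm, designation="prophi1.A-3")
    kept, omitted = filter_prophage_calls(
        [good, contaminated, truncated], asm, genes, hits, PipelineConfig()
    )
    assert [c.designation for c in kept] == ["prophi1.A-1"]
    reasons = {c.designation: c.omission_reason for c in omitted}
    assert reasons["prophi1.A-2"] == "excess_bacterial_sequence"
    assert reasons["prophi1.A-3"] == "truncated_by_contig_end"
    assert all(c.status == "omitted" for c in omitted)


def test_call_at_end_with_att_core_is_kept():
    from prophikit.att import AttCore

    asm, genes, hits = qc_fixture()
    core = AttCore("ACGTACGTACGTACGTACGTA", 54000, 54021, 59800, 59821)
    call = build_call("c", 54000, 59821, asm, core=core)
    kept, omitted = filter_prophage_calls([call], asm, genes, hits, PipelineConfig())
    assert kept and not omitted


# -- deduplication -----------------------------------------------------------


def _call_with_seq(designation, seq):
    return ProphageCall(designation, "1.A", "c", 0, len(seq), seq)


def test_dedupe_identical_and_revcomp_and_substitution():
    from prophikit.core import reverse_complement

    rng = np.random.default_rng(10)
    seq = random_dna(rng, 500)
    triple = [
        _call_with_seq("prophi1.A-1", seq),
        _call_with_seq("prophi1.B-1", seq),
        _call_with_seq("prophi1.C-1", seq),
    ]
    unique, table = dedupe_prophages(triple)
    assert len(unique) == 1 and table[0][1] == 3
    assert unique[0].designation == "prophi1.A-1"  # smallest designation

    pair = [
        _call_with_seq("prophi1.A-1", seq),
        _call_with_seq("prophi1.B-1", reverse_complement(seq)),
    ]
    assert len(dedupe_prophages(pair)[0]) == 1

    mutated = seq[:100] + ("A" if seq[100] != "A" else "C") + seq[101:]
    diff = [_call_with_seq("prophi1.A-1", seq), _call_with_seq("prophi1.B-1", mutated)]
    assert len(dedupe_prophages(diff)[0]) == 2
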