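"""Deterministic synthetic corpora with planted ground truth.

The generator emulates the inputs the discovery pipeline is built for:
draft assemblies of related bacterial strains sharing a chromosome
backbone, carrying planted intact prophages integrated at shared attB
loci (core duplicated as attL/attR), prophages split across contig ends,
candidate PICIs (integrase + capsid, no virion module), PEST cassettes
(three- and four-gene, from three N-terminal toxin archetypes),
defective prophage remnants, and QC decoys (prophages truncated by a
contig end; calls diluted with bacterial genes).  Every planted element
is described by a machine-readable :class:`TruthRecord`.

Design notes: background DNA is i.i.d. with mycobacterial-like GC
(default 0.66); proteins are uniform-random over the 20 amino acids and
encoded through a fixed one-codon-per-residue table chosen so that
reverse-strand open reading frames are regularly interrupted (the Leu
and Ser codons read as stops on the opposite strand).  The generator
shares no detection logic with the discovery modules, so recovery tests
are meaningful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .config import PipelineConfig
from .core import AA_ALPHABET, Contig, GeneFeature, GenomeAssembly, RnaFeature, rank_genes
from .errors import ValidationError
from .homology import ProfileDatabase, Pssm
from .io import PhageDatabase, write_assembly, write_fasta, write_gene_table

# one codon per amino acid, chosen so every reverse-strand reading frame
# hits stop codons regularly (TTA/CTA/TCA on the forward strand read as
# stops in reverse): TTA/TCA give codon-aligned reverse stops, the many
# ...T|A.. and ...T|GA/AG junctions give them in the shifted frames.
# Keeps spurious reverse-frame ORFs in encoded genes short.
CODON_OF = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "TTA",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "AGA",
    "S": "TCA", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

_DNA = np.array(list("ACGT"))
_AA = np.array(list(AA_ALPHABET))


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.66) -> str:
    at = (1.0 - gc) / 2.0
    probs = [at, gc / 2.0, gc / 2.0, at]
    return "".join(rng.choice(_DNA, size=length, p=probs))


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


def mutate_protein(rng: np.random.Generator, protein: str, rate: float) -> str:
    if rate <= 0:
        return protein
    chars = list(protein)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = str(rng.choice(_AA))
    return "".join(chars)


def mutate_dna(rng: np.random.Generator, dna: str, rate: float) -> str:
    if rate <= 0:
        return dna
    chars = list(dna)
    for i in range(len(chars)):
        if chars[i] != "N" and rng.random() < rate:
            alternatives = [b for b in "ACGT" if b != chars[i]]
            chars[i] = str(rng.choice(alternatives))
    return "".join(chars)


def encode_gene(protein: str) -> str:
    """ATG + fixed codons + TAA; translation restores M + protein."""
    return "ATG" + "".join(CODON_OF[aa] for aa in protein) + "TAA"


# ---------------------------------------------------------------------------
# Toy phage genomes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlannedGene:
    """One gene of a plan: explicit protein (or a length to draw) plus a
    profile category ('none' = background gene)."""

    category: str
    protein: Optional[str] = None
    length_aa: int = 150


@dataclass
class ToyPhage:
    phage_id: str
    sequence: str
    genes: list[tuple[int, int, str, str, str]]  # (start, end, strand, protein, category)
    spacers: list[tuple[int, int]]

    @property
    def length(self) -> int:
        return len(self.sequence)


def make_toy_phage(
    seed: int,
    length: int,
    gene_plan: Sequence[PlannedGene],
    phage_id: str = "phage",
    gc: float = 0.66,
) -> ToyPhage:
    """Deterministic annotated phage genome matching a gene plan.

    Genes are laid out left to right on the forward strand with random
    intergenic spacers filling the remaining length; raises when the plan
    does not fit.
    """
    rng = np.random.default_rng(seed)
    proteins = [
        g.protein if g.protein is not None else random_protein(rng, g.length_aa)
        for g in gene_plan
    ]
    gene_dna = [encode_gene(p) for p in proteins]
    total_genes = sum(len(d) for d in gene_dna)
    n_spacers = len(gene_plan) + 1
    slack = length - total_genes
    if slack < n_spacers * 20:
        raise ValidationError(
            f"gene plan needs {total_genes + n_spacers * 20} bp, only {length} given"
        )
    # random spacer lengths summing exactly to the slack
    cuts = np.sort(rng.choice(np.arange(1, slack - 20 * n_spacers), size=n_spacers - 1, replace=False))
    spacer_lens = np.diff(np.concatenate([[0], cuts, [slack - 20 * n_spacers]])) + 20

    parts: list[str] = []
    genes: list[tuple[int, int, str, str, str]] = []
    spacers: list[tuple[int, int]] = []
    pos = 0
    for i, dna in enumerate(gene_dna):
        sp = random_dna(rng, int(spacer_lens[i]), gc)
        spacers.append((pos, pos + len(sp)))
        parts.append(sp)
        pos += len(sp)
        # record the encoded protein with its leading Met, matching translation
        genes.append((pos, pos + len(dna), "+", "M" + proteins[i], gene_plan[i].category))
        parts.append(dna)
        pos += len(dna)
    sp = random_dna(rng, int(spacer_lens[-1]), gc)
    spacers.append((pos, pos + len(sp)))
    parts.append(sp)
    sequence = "".join(parts)
    assert len(sequence) == length
    return ToyPhage(phage_id, sequence, genes, spacers)


def plant_prophage(
    host_sequence: str, phage_sequence: str, att_core: str, locus: int
) -> tuple[str, dict]:
    """Integrate a phage at a host attB: the core at *locus* becomes
    attL + phage + attR (core duplicated).

    Returns the modified host sequence and a truth dict with the prophage
    interval (attL start to attR end) and core coordinates.
    """
    k = len(att_core)
    if host_sequence[locus : locus + k] != att_core:
        raise ValidationError(f"att core not present at locus {locus}")
    new_seq = (
        host_sequence[:locus]
        + att_core
        + phage_sequence
        + att_core
        + host_sequence[locus + k :]
    )
    truth = {
        "start": locus,
        "end": locus + 2 * k + len(phage_sequence),
        "attL": (locus, locus + k),
        "attR": (locus + k + len(phage_sequence), locus + 2 * k + len(phage_sequence)),
        "core": att_core,
    }
    return new_seq, truth


# ---------------------------------------------------------------------------
# Truth records and corpus configuration
# ---------------------------------------------------------------------------


@dataclass
class TruthRecord:
    """Ground truth for one planted element (coordinates post-fragmentation)."""

    element_type: str  # prophage | split_prophage | pici | pest_cassette |
    #                    attB_locus | defective_remnant | decoy_truncated |
    #                    decoy_contaminated
    strain_id: str
    contig_id: str
    start: int
    end: int
    sequence: str
    attrs: dict = field(default_factory=dict)


@dataclass
class CorpusConfig:
    n_assemblies: int = 20
    n_intact_prophages: int = 30
    n_split_prophages: int = 10
    n_picis: int = 8
    n_pest_cassettes: int = 25
    n_att_loci: int = 5
    n_defective_remnants: int = 6
    n_truncated_decoys: int = 3
    n_contaminated_decoys: int = 3
    gc: float = 0.66
    n_host_genes: int = 60
    n_phage_types: int = 6
    phage_length: int = 15000
    #: per-instance substitution rate on PEST cassette proteins (the
    #: mutation load separating superfamily members)
    pest_mutation_rate: float = 0.08
    #: divergence of each phage type's archetypal genes from the shared
    #: profile pool (keeps types in distinct phams while profiles still hit)
    archetype_divergence: float = 0.65
    #: optional whole-genome per-base substitution rate (0 = exact corpus)
    mutation_rate: float = 0.0

    @classmethod
    def scaled(cls, n_assemblies: int, **overrides) -> "CorpusConfig":
        """Element counts scaled proportionally from the 20-assembly
        default corpus (att loci and phage types stay fixed)."""
        f = n_assemblies / 20.0
        scale = lambda x: max(1, round(x * f))
        return cls(
            n_assemblies=n_assemblies,
            n_intact_prophages=scale(30),
            n_split_prophages=scale(10),
            n_picis=scale(8),
            n_pest_cassettes=scale(25),
            n_defective_remnants=scale(6),
            n_truncated_decoys=scale(3),
            n_contaminated_decoys=scale(3),
            **overrides,
        )

    def __post_init__(self) -> None:
        # every strain integrates prophages at distinct att loci, so the
        # per-strain load cannot exceed the number of loci
        per_strain = -(-self.n_intact_prophages // self.n_assemblies)  # ceil
        per_strain += 1 if self.n_split_prophages > 0 else 0
        if per_strain > self.n_att_loci:
            raise ValidationError(
                f"{self.n_intact_prophages} intact + {self.n_split_prophages} "
                f"split prophages over {self.n_assemblies} assemblies exceed "
                f"the {self.n_att_loci} att loci available per strain"
            )


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------


@dataclass
class _StrainDraft:
    """A strain genome under construction: one linear sequence plus
    absolutely positioned features and pending truth."""

    strain_id: str
    sequence: str
    genes: list[tuple[int, int, str, str, str]]  # start, end, strand, protein, tag
    rna: list[tuple[int, int, str, str]]  # start, end, kind, isotype
    truth: list[TruthRecord]
    forced_breaks: list[int]


@dataclass
class SyntheticCorpus:
    """In-memory corpus: assemblies + annotations + databases + truth."""

    assemblies: list[GenomeAssembly]
    genes: dict[str, list[GeneFeature]]
    rna_features: dict[str, list[RnaFeature]]
    phage_db: PhageDatabase
    profile_db: ProfileDatabase
    truth: list[TruthRecord]
    reference: GenomeAssembly
    reference_rna: list[RnaFeature]
    att_cores: list[str]
    taxon_id: str
    config: CorpusConfig
    seed: int

    def truth_of(self, element_type: str) -> list[TruthRecord]:
        return [t for t in self.truth if t.element_type == element_type]

    def write(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        (outdir / "assemblies").mkdir(parents=True, exist_ok=True)
        (outdir / "genes").mkdir(exist_ok=True)
        (outdir / "rna").mkdir(exist_ok=True)
        manifest_rows = []
        for asm in self.assemblies:
            write_assembly(outdir / "assemblies" / f"{asm.strain_id}.fasta", asm)
            write_gene_table(outdir / "genes" / f"{asm.strain_id}.tsv", self.genes[asm.strain_id])
            with open(outdir / "rna" / f"{asm.strain_id}.tsv", "w") as fh:
                fh.write("feature_id\tcontig\tstart\tend\tkind\tisotype\n")
                for r in self.rna_features[asm.strain_id]:
                    fh.write(
                        f"{r.feature_id}\t{r.contig_id}\t{r.start}\t{r.end}\t{r.kind}\t{r.isotype}\n"
                    )
            manifest_rows.append(
                (asm.strain_id, asm.taxon_id, asm.species_label, asm.contig_count)
            )
        with open(outdir / "assemblies.tsv", "w") as fh:
            fh.write("strain_id\ttaxon_id\tspecies\tn_contigs\n")
            for row in manifest_rows:
                fh.write("\t".join(str(x) for x in row) + "\n")
        self.phage_db.to_files(outdir / "phage_db.fasta", outdir / "phage_clusters.tsv")
        self.profile_db.to_directory(outdir / "profiles")
        write_assembly(outdir / "reference.fasta", self.reference)
        with open(outdir / "reference_rna.tsv", "w") as fh:
            fh.write("feature_id\tcontig\tstart\tend\tkind\tisotype\n")
            for r in self.reference_rna:
                fh.write(
                    f"{r.feature_id}\t{r.contig_id}\t{r.start}\t{r.end}\t{r.kind}\t{r.isotype}\n"
                )
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("element_type\tstrain_id\tcontig_id\tstart\tend\tsequence\tattrs_json\n")
            for t in self.truth:
                fh.write(
                    f"{t.element_type}\t{t.strain_id}\t{t.contig_id}\t{t.start}\t"
                    f"{t.end}\t{t.sequence}\t{json.dumps(t.attrs, sort_keys=True)}\n"
                )
        with open(outdir / "corpus_config.json", "w") as fh:
            json.dump({"seed": self.seed, "taxon_id": self.taxon_id, **asdict(self.config)}, fh, indent=1, sort_keys=True)


def _build_phage_types(
    rng: np.random.Generator, cfg: CorpusConfig
) -> tuple[list[ToyPhage], dict[str, str], list[Pssm]]:
    """Phage reference genomes, their cluster labels, and the profile pool.

    Types 0 and 1 share half their genes exactly (one cluster); all other
    types are unrelated (each its own cluster).  Every type carries an
    integrase, a major capsid gene, 12 diverged copies of the shared
    archetypal-gene pool and 4 background genes placed interior, so both
    the first and last genes carry profile signal.
    """
    pool = [random_protein(rng, 180) for _ in range(12)]
    integrase_arch = random_protein(rng, 330)
    capsid_arch = random_protein(rng, 300)
    transposase_arch = random_protein(rng, 280)

    profiles = [
        Pssm(f"arch{i + 1}", "phage_archetype", [p]) for i, p in enumerate(pool)
    ]
    profiles.append(Pssm("int1", "integrase", [integrase_arch]))
    profiles.append(Pssm("mcp1", "major_capsid", [capsid_arch]))
    profiles.append(Pssm("tnp1", "transposase", [transposase_arch]))

    phages: list[ToyPhage] = []
    clusters: dict[str, str] = {}
    type_plans: list[list[PlannedGene]] = []
    for t in range(cfg.n_phage_types):
        if t == 1:
            # half the genes copied verbatim from type 0 (alternating
            # positions, so identical stretches stay short), half fresh
            base = type_plans[0]
            plan = []
            for i, g in enumerate(base):
                if i % 2 == 0 or g.category in ("integrase",):
                    plan.append(g)
                else:
                    category = g.category
                    if category == "phage_archetype":
                        protein = mutate_protein(
                            rng, pool[len(plan) % len(pool)], cfg.archetype_divergence
                        )
                    elif category == "major_capsid":
                        protein = mutate_protein(rng, capsid_arch, 0.3)
                    else:
                        protein = random_protein(rng, 150)
                    plan.append(PlannedGene(category, protein))
        else:
            none_at = {5, 8, 11, 14}
            plan = [
                PlannedGene("integrase", mutate_protein(rng, integrase_arch, 0.25)),
                PlannedGene("major_capsid", mutate_protein(rng, capsid_arch, 0.25)),
            ]
            arch_i = 0
            while len(plan) < 18:
                if len(plan) in none_at:
                    plan.append(PlannedGene("none", random_protein(rng, 150)))
                else:
                    plan.append(
                        PlannedGene(
                            "phage_archetype",
                            mutate_protein(rng, pool[arch_i % len(pool)], cfg.archetype_divergence),
                        )
                    )
                    arch_i += 1
        type_plans.append(plan)
        phage = make_toy_phage(
            int(rng.integers(2**31)), cfg.phage_length, plan,
            phage_id=f"refphage_{t + 1}", gc=cfg.gc,
        )
        # pin the terminal bases so an integrated copy's att direct repeat
        # never extends by chance into the phage (the host side pins 'A',
        # see the backbone builder) and the planted core stays maximal
        phage.sequence = "C" + phage.sequence[1:-1] + "C"
        phages.append(phage)
        clusters[phage.phage_id] = "A" if t <= 1 else chr(ord("A") + t - 1)
    return phages, clusters, profiles


def _build_pest_archetypes(rng: np.random.Generator) -> tuple[list[str], str, str, list[Pssm]]:
    pt_archs = [random_protein(rng, 200) for _ in range(3)]
    wxg_arch = random_protein(rng, 100)
    imm_arch = random_protein(rng, 120)
    profiles = [
        Pssm(f"pt{i + 1}", "polymorphic_toxin", [p]) for i, p in enumerate(pt_archs)
    ]
    profiles.append(Pssm("wxg1", "wxg100", [wxg_arch]))
    profiles.append(Pssm("imm1", "immunity", [imm_arch]))
    return pt_archs, wxg_arch, imm_arch, profiles


def _element_block(
    rng: np.random.Generator,
    proteins_cats: Sequence[tuple[str, str, str]],  # (protein, category, strand)
    gc: float,
    spacer: tuple[int, int] = (60, 160),
) -> tuple[str, list[tuple[int, int, str, str, str]]]:
    """DNA block of genes separated by random spacers; '-' genes are
    reverse-complemented in the DNA but annotated with their protein."""
    from .core import reverse_complement

    parts: list[str] = []
    genes: list[tuple[int, int, str, str, str]] = []
    pos = 0
    for protein, category, strand in proteins_cats:
        sp = random_dna(rng, int(rng.integers(*spacer)), gc)
        parts.append(sp)
        pos += len(sp)
        dna = encode_gene(protein)
        if strand == "-":
            dna = reverse_complement(dna)
        genes.append((pos, pos + len(dna), strand, "M" + protein, category))
        parts.append(dna)
        pos += len(dna)
    sp = random_dna(rng, int(rng.integers(*spacer)), gc)
    parts.append(sp)
    return "".join(parts), genes


def fragment_assembly(
    draft: _StrainDraft,
    taxon_id: str,
    n_contigs: int,
    rng: np.random.Generator,
    species_label: str = "",
) -> tuple[GenomeAssembly, list[GeneFeature], list[RnaFeature], list[TruthRecord]]:
    """Cut a strain draft into contigs and re-express all coordinates.

    Forced breakpoints (inside split prophages) become contig boundaries;
    remaining breakpoints are drawn from positions at least 6 kb away from
    every planted element and outside genes.  Split-prophage truth is
    rewritten with per-contig fragment intervals.
    """
    length = len(draft.sequence)
    forced = sorted(draft.forced_breaks)
    n_random = n_contigs - 1 - len(forced)
    if n_random < 0:
        raise ValidationError("more forced splits than contigs-1")
    phage_like = {
        "prophage", "split_prophage", "defective_remnant",
        "decoy_truncated", "decoy_contaminated",
    }
    protected: list[tuple[int, int]] = [
        (t.start - (6000 if t.element_type in phage_like else 1000),
         t.end + (6000 if t.element_type in phage_like else 1000))
        for t in draft.truth
    ]
    protected += [(s - 200, e + 200) for (s, e, _, _, _) in draft.genes]
    protected += [(b - 6000, b + 6000) for b in forced]

    def clear(pos: int) -> bool:
        return not any(s <= pos < e for s, e in protected)

    candidates = [p for p in range(3000, length - 3000, 997) if clear(p)]
    if len(candidates) < n_random:
        raise ValidationError("not enough breakpoint-safe positions")
    chosen = sorted(
        int(c) for c in rng.choice(np.array(candidates), size=n_random, replace=False)
    )
    breaks = sorted(set(forced + chosen))
    bounds = [0] + breaks + [length]

    contig_ids = [f"{draft.strain_id}_c{i + 1}" for i in range(len(bounds) - 1)]
    contigs = [
        Contig(contig_ids[i], draft.sequence[bounds[i] : bounds[i + 1]])
        for i in range(len(bounds) - 1)
    ]

    def locate(pos: int) -> int:
        """Index of the contig containing genomic position `pos`."""
        for i in range(len(bounds) - 1):
            if bounds[i] <= pos < bounds[i + 1]:
                return i
        return len(bounds) - 2

    genes: list[GeneFeature] = []
    for n, (s, e, strand, protein, _tag) in enumerate(draft.genes):
        ci = locate(s)
        genes.append(
            GeneFeature(
                f"{draft.strain_id}_g{n + 1:04d}", contig_ids[ci],
                s - bounds[ci], e - bounds[ci], strand, protein, 0,
            )
        )
    ranked: list[GeneFeature] = []
    for cid in contig_ids:
        ranked.extend(rank_genes([g for g in genes if g.contig_id == cid]))

    rna: list[RnaFeature] = []
    for n, (s, e, kind, isotype) in enumerate(draft.rna):
        ci = locate(s)
        rna.append(
            RnaFeature(
                f"{draft.strain_id}_r{n + 1}", contig_ids[ci],
                s - bounds[ci], e - bounds[ci], kind, isotype,
            )
        )

    truth: list[TruthRecord] = []
    for t in draft.truth:
        if t.element_type == "split_prophage":
            fragments = []
            ci_first, ci_last = locate(t.start), locate(t.end - 1)
            for ci in range(ci_first, ci_last + 1):
                fs = max(t.start, bounds[ci]) - bounds[ci]
                fe = min(t.end, bounds[ci + 1]) - bounds[ci]
                fragments.append([contig_ids[ci], fs, fe])
            t.attrs["fragments"] = fragments
            t.contig_id = "+".join(f[0] for f in fragments)
            t.start, t.end = fragments[0][1], fragments[-1][2]
        else:
            ci = locate(t.start)
            t.contig_id = contig_ids[ci]
            t.start -= bounds[ci]
            t.end -= bounds[ci]
        t.strain_id = draft.strain_id
        truth.append(t)

    assembly = GenomeAssembly(taxon_id, draft.strain_id, contigs, species_label)
    return assembly, ranked, rna, truth


def generate_corpus(
    config: Optional[CorpusConfig] = None, seed: int = 0, taxon_id: str = "9999"
) -> SyntheticCorpus:
    """Build the default study corpus: related draft assemblies with
    planted prophages, split prophages, PICIs, PEST cassettes, shared attB
    loci, defective remnants and QC decoys, all byte-deterministic in
    *seed*."""
    cfg = config or CorpusConfig()
    rng = np.random.default_rng(seed)

    phages, phage_clusters, phage_profiles = _build_phage_types(rng, cfg)
    pt_archs, wxg_arch, imm_arch, pest_profiles = _build_pest_archetypes(rng)
    profile_db = ProfileDatabase(phage_profiles + pest_profiles)
    phage_db = PhageDatabase(
        {p.phage_id: p.sequence for p in phages}, phage_clusters
    )

    # -- shared chromosome backbone ---------------------------------------
    host_proteins = [random_protein(rng, int(rng.integers(130, 240)))
                     for _ in range(cfg.n_host_genes)]
    att_cores = [random_dna(rng, int(rng.integers(40, 50)), cfg.gc)
                 for _ in range(cfg.n_att_loci)]
    backbone_parts: list[str] = []
    backbone_genes: list[tuple[int, int, str, str, str]] = []
    backbone_rna: list[tuple[int, int, str, str]] = []
    gap_slots: list[tuple[int, int]] = []  # (gap index, insertion position)
    att_positions: dict[int, int] = {}  # att locus index -> backbone pos
    # att gaps spaced 11 host genes apart so neighboring planted elements
    # never sit within a caller hit-run gap of each other
    att_gaps = (5, 16, 27, 38, 49)
    att_gap_of = {g: i for i, g in enumerate(att_gaps)}
    trna_overlap = {1: ("tRNA", "tRNA-Arg (TCT)"), 3: ("tmRNA", "")}
    pos = 0
    for i in range(cfg.n_host_genes + 1):
        gap_len = int(rng.integers(700, 1300))
        gap = random_dna(rng, gap_len, cfg.gc)
        if i in att_gap_of:
            locus = att_gap_of[i]
            core = att_cores[locus]
            mid = gap_len // 2
            # 'A' pins either side of the core: with phage termini pinned
            # to 'C', the attL/attR direct repeat of a lysogen is exactly
            # the planted core (no chance 1-bp extensions)
            gap = gap[: mid - 1] + "A" + core + "A" + gap[mid + len(core) + 1 :]
            att_positions[locus] = pos + mid
            if locus in trna_overlap:
                kind, isotype = trna_overlap[locus]
                # RNA gene covering the core and some flank
                backbone_rna.append((pos + mid - 15, pos + mid + len(core) + 15, kind, isotype))
        else:
            gap_slots.append((i, pos + gap_len // 2))
        backbone_parts.append(gap)
        pos += gap_len
        if i < cfg.n_host_genes:
            dna = encode_gene(host_proteins[i])
            strand = "+" if i % 3 else "-"
            if strand == "-":
                from .core import reverse_complement

                dna = reverse_complement(dna)
            backbone_genes.append((pos, pos + len(dna), strand, "M" + host_proteins[i], "host"))
            backbone_parts.append(dna)
            pos += len(dna)
    backbone = "".join(backbone_parts)
    # slots at least 5 host genes from every att gap: reserved for
    # phage-like insertions (PICIs, remnants, decoys), which must not sit
    # close enough to a prophage to fuse with its gene-hit run
    far_slots_all = [
        p for g, p in gap_slots if min(abs(g - a) for a in att_gaps) >= 5
    ]
    near_slots_all = [
        p for g, p in gap_slots if min(abs(g - a) for a in att_gaps) < 5
    ]
    # a decoy tRNA that overlaps nothing, to exercise the no-overlap path
    backbone_rna.append((near_slots_all[0] + 220, near_slots_all[0] + 295, "tRNA", "tRNA-Gly (GCC)"))

    reference = GenomeAssembly(taxon_id, "REF", [Contig("ref_chrom", backbone)], "reference")
    reference_rna = [
        RnaFeature(f"ref_r{i + 1}", "ref_chrom", s, e, kind, isotype)
        for i, (s, e, kind, isotype) in enumerate(backbone_rna)
    ]

    # -- assignment of elements to strains --------------------------------
    n = cfg.n_assemblies
    strain_ids = [f"S{i + 1:02d}" for i in range(n)]
    intact_of: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n)}  # (phage_type, att_locus)
    used_loci: dict[int, set[int]] = {i: set() for i in range(n)}
    for k in range(cfg.n_intact_prophages):
        s = k % n
        # spread occupancy over every att locus so each collects occurrences
        preferred = (s + 2 * (k // n)) % cfg.n_att_loci
        locus = next(
            (preferred + d) % cfg.n_att_loci
            for d in range(cfg.n_att_loci)
            if (preferred + d) % cfg.n_att_loci not in used_loci[s]
        )
        used_loci[s].add(locus)
        intact_of[s].append((k % cfg.n_phage_types, locus))
    split_of: dict[int, tuple[int, int]] = {}
    for k in range(cfg.n_split_prophages):
        s = (n - 1 - k) % n
        free = [l for l in range(cfg.n_att_loci) if l not in used_loci[s]]
        locus = free[0]
        used_loci[s].add(locus)
        split_of[s] = ((k + 2) % cfg.n_phage_types, locus)
    pici_strains = [k % n for k in range(3, 3 + cfg.n_picis * 2, 2)]
    remnant_strains = [k % n for k in range(1, 1 + cfg.n_defective_remnants * 3, 3)]
    trunc_strains = [(5 + 7 * k) % n for k in range(cfg.n_truncated_decoys)]
    contam_strains = [(2 + 7 * k) % n for k in range(cfg.n_contaminated_decoys)]
    cassette_strains = [k % n for k in range(cfg.n_pest_cassettes)]

    # -- build each strain --------------------------------------------------
    assemblies: list[GenomeAssembly] = []
    genes: dict[str, list[GeneFeature]] = {}
    rna_features: dict[str, list[RnaFeature]] = {}
    truth: list[TruthRecord] = []

    for locus in range(cfg.n_att_loci):
        truth.append(
            TruthRecord(
                "attB_locus", "REF", "ref_chrom",
                att_positions[locus], att_positions[locus] + len(att_cores[locus]),
                att_cores[locus],
                {"attB_index": locus + 1,
                 "n_expected_occurrences": 0},  # filled below
            )
        )

    cassette_counter = 0
    for s in range(n):
        strain_id = strain_ids[s]
        srng = np.random.default_rng(int(rng.integers(2**31)))
        # events: (backbone position, consumed bp, inserted seq, rel genes,
        #          rel rna, truth records rel to insertion, forced breaks rel)
        events = []

        def add_gap_event(seq: str, rel_genes, rel_truth, forced_rel=(), slot=None):
            position = slot if slot is not None else free_slots.pop(0)
            events.append((position, 0, seq, rel_genes, [], rel_truth, list(forced_rel)))

        # reserved far-from-att slots for phage-like elements; cassettes
        # draw from the remaining gaps in a per-strain shuffled order
        reserved = {
            "pici": far_slots_all[1],
            "remnant": far_slots_all[3],
            "trunc": far_slots_all[5],
            "contam": far_slots_all[7],
        }
        cassette_pool = sorted(
            set(near_slots_all + far_slots_all) - set(reserved.values())
        )
        slot_order = srng.permutation(len(cassette_pool))
        free_slots = [cassette_pool[i] for i in slot_order]

        # intact prophages at att loci
        for phage_type, locus in intact_of[s]:
            phage = phages[phage_type]
            core = att_cores[locus]
            seq = core + phage.sequence + core
            rel_genes = [
                (len(core) + gs, len(core) + ge, strand, prot, cat)
                for gs, ge, strand, prot, cat in phage.genes
            ]
            rel_truth = [
                TruthRecord(
                    "prophage", strain_id, "", 0, len(seq), seq,
                    {"phage_id": phage.phage_id,
                     "cluster": phage_clusters[phage.phage_id],
                     "core": core, "attB_index": locus + 1,
                     "integrase_class": "Int-Y" if phage_type < 3 else "Int-S"},
                )
            ]
            events.append(
                (att_positions[locus], len(core), seq, rel_genes, [], rel_truth, [])
            )
        # split prophage
        if s in split_of:
            phage_type, locus = split_of[s]
            phage = phages[phage_type]
            core = att_cores[locus]
            seq = core + phage.sequence + core
            rel_genes = [
                (len(core) + gs, len(core) + ge, strand, prot, cat)
                for gs, ge, strand, prot, cat in phage.genes
            ]
            mid = phage.length // 2
            spacer = min(phage.spacers, key=lambda sp: abs((sp[0] + sp[1]) // 2 - mid))
            break_rel = len(core) + (spacer[0] + spacer[1]) // 2
            rel_truth = [
                TruthRecord(
                    "split_prophage", strain_id, "", 0, len(seq), phage.sequence,
                    {"phage_id": phage.phage_id,
                     "cluster": phage_clusters[phage.phage_id],
                     "core": core, "attB_index": locus + 1},
                )
            ]
            events.append(
                (att_positions[locus], len(core), seq, rel_genes, [], rel_truth, [break_rel])
            )
        # PICIs: integrase + capsid + 4 background genes
        for p_idx, ps in enumerate(pici_strains):
            if ps != s:
                continue
            prng = np.random.default_rng(9000 + p_idx % 2)  # two PICI types
            block, rel_genes = _element_block(
                prng,
                [(mutate_protein(prng, profile_db.by_category("integrase")[0].sequences[0], 0.25), "integrase", "+"),
                 (mutate_protein(prng, profile_db.by_category("major_capsid")[0].sequences[0], 0.25), "major_capsid", "+")]
                + [(random_protein(prng, 140), "none", "+") for _ in range(4)],
                cfg.gc,
            )
            add_gap_event(
                block, rel_genes,
                [TruthRecord("pici", strain_id, "", 0, len(block), block,
                             {"pici_type": p_idx % 2 + 1})],
                slot=reserved["pici"],
            )
        # defective remnants: a phage slice with 3 archetype genes
        for r_idx, rs in enumerate(remnant_strains):
            if rs != s:
                continue
            src = phages[r_idx % cfg.n_phage_types]
            arch_genes = [g for g in src.genes if g[4] == "phage_archetype"][2:5]
            lo = max(0, arch_genes[0][0] - 80)
            hi = min(src.length, arch_genes[-1][1] + 80)
            block = src.sequence[lo:hi]
            rel_genes = [
                (gs - lo, ge - lo, strand, prot, cat)
                for gs, ge, strand, prot, cat in arch_genes
            ]
            add_gap_event(
                block, rel_genes,
                [TruthRecord("defective_remnant", strain_id, "", 0, len(block), block,
                             {"source_phage": src.phage_id})],
                slot=reserved["remnant"],
            )
        # truncated decoys: phage prefix ending at a forced contig break
        for t_idx, ts in enumerate(trunc_strains):
            if ts != s:
                continue
            src = phages[(t_idx + 1) % cfg.n_phage_types]
            cut_gene = src.genes[12]
            hi = cut_gene[1] + 50
            block = src.sequence[:hi]
            rel_genes = [
                (gs, ge, strand, prot, cat)
                for gs, ge, strand, prot, cat in src.genes
                if ge <= hi
            ]
            add_gap_event(
                block, rel_genes,
                [TruthRecord("decoy_truncated", strain_id, "", 0, len(block), block,
                             {"source_phage": src.phage_id})],
                forced_rel=[len(block)],
                slot=reserved["trunc"],
            )
        # contaminated decoys: phage genes diluted with background genes
        for c_idx, cs in enumerate(contam_strains):
            if cs != s:
                continue
            drng = np.random.default_rng(7000 + c_idx)
            src = phages[(c_idx + 3) % cfg.n_phage_types]
            arch = [g for g in src.genes if g[4] == "phage_archetype"][:6]
            plan = []
            for g in arch:
                plan.append((g[3][1:], "phage_archetype", "+"))
                for _ in range(3):
                    plan.append((random_protein(drng, 140), "contam", "+"))
            block, rel_genes = _element_block(drng, plan, cfg.gc)
            add_gap_event(
                block, rel_genes,
                [TruthRecord("decoy_contaminated", strain_id, "", 0, len(block), block,
                             {"source_phage": src.phage_id})],
                slot=reserved["contam"],
            )
        # PEST cassettes
        for k_idx, ks in enumerate(cassette_strains):
            if ks != s:
                continue
            crng = np.random.default_rng(int(rng.integers(2**31)))
            archetype = k_idx % 3
            four_gene = k_idx % 5 == 4  # every fifth cassette is four-gene
            strand = "-" if k_idx % 3 == 2 else "+"
            pt = (
                mutate_protein(crng, pt_archs[archetype], cfg.pest_mutation_rate)
                + random_protein(crng, 250)
            )
            wxg1 = mutate_protein(crng, wxg_arch, cfg.pest_mutation_rate)
            imm = mutate_protein(crng, imm_arch, cfg.pest_mutation_rate)
            members = [(wxg1, "wxg100", strand)]
            roles = ["WXG"]
            if four_gene:
                members.append(
                    (mutate_protein(crng, wxg_arch, cfg.pest_mutation_rate), "wxg100", strand)
                )
                roles.append("WXG")
            members += [(pt, "polymorphic_toxin", strand), (imm, "immunity", strand)]
            roles += ["PT", "Imm"]
            if strand == "-":
                members = members[::-1]
            block, rel_genes = _element_block(crng, members, cfg.gc)
            cassette_counter += 1
            add_gap_event(
                block, rel_genes,
                [TruthRecord(
                    "pest_cassette", strain_id, "", 0, len(block), block,
                    {"architecture": "four_gene" if four_gene else "three_gene",
                     "roles": roles, "archetype": archetype + 1,
                     "strand": strand,
                     "cassette_id": f"cas{cassette_counter:03d}"},
                )],
            )

        # -- apply events to the backbone ----------------------------------
        events.sort(key=lambda e: e[0])
        parts = []
        abs_genes: list[tuple[int, int, str, str, str]] = []
        abs_rna: list[tuple[int, int, str, str]] = []
        abs_truth: list[TruthRecord] = []
        forced_breaks: list[int] = []
        cursor = 0
        out_len = 0
        shift_events: list[tuple[int, int]] = []  # (backbone pos, delta)
        for b_pos, consumed, seq, rel_genes, rel_rna, rel_truth, forced_rel in events:
            parts.append(backbone[cursor:b_pos])
            out_len += b_pos - cursor
            start = out_len
            parts.append(seq)
            out_len += len(seq)
            cursor = b_pos + consumed
            shift_events.append((b_pos, len(seq) - consumed))
            for gs, ge, strand, prot, cat in rel_genes:
                abs_genes.append((start + gs, start + ge, strand, prot, cat))
            for rs_, re_, kind, isotype in rel_rna:
                abs_rna.append((start + rs_, start + re_, kind, isotype))
            for t in rel_truth:
                t2 = TruthRecord(
                    t.element_type, t.strain_id, t.contig_id,
                    start + t.start, start + t.end, t.sequence, dict(t.attrs),
                )
                abs_truth.append(t2)
            for br in forced_rel:
                forced_breaks.append(start + br)
        parts.append(backbone[cursor:])
        sequence = "".join(parts)

        def shifted(p: int) -> int:
            return p + sum(d for bp, d in shift_events if bp <= p)

        for gs, ge, strand, prot, cat in backbone_genes:
            abs_genes.append((shifted(gs), shifted(gs) + (ge - gs), strand, prot, cat))
        for rs_, re_, kind, isotype in backbone_rna:
            abs_rna.append((shifted(rs_), shifted(rs_) + (re_ - rs_), kind, isotype))
        abs_genes.sort()

        if cfg.mutation_rate > 0:
            sequence = mutate_dna(srng, sequence, cfg.mutation_rate)

        draft = _StrainDraft(
            strain_id, sequence, abs_genes, abs_rna, abs_truth, forced_breaks
        )
        n_contigs = 4 + (s % 4) + len(forced_breaks)
        species = f"clade_{s % 4 + 1}"
        assembly, ranked_genes, rna, strain_truth = fragment_assembly(
            draft, taxon_id, n_contigs, srng, species
        )
        assemblies.append(assembly)
        genes[strain_id] = ranked_genes
        rna_features[strain_id] = rna
        truth.extend(strain_truth)

    # tally expected att occurrences
    for t in truth:
        if t.element_type == "attB_locus":
            idx = t.attrs["attB_index"]
            t.attrs["n_expected_occurrences"] = sum(
                1
                for u in truth
                if u.element_type == "prophage" and u.attrs.get("attB_index") == idx
            )

    return SyntheticCorpus(
        assemblies=assemblies,
        genes=genes,
        rna_features=rna_features,
        phage_db=phage_db,
        profile_db=profile_db,
        truth=truth,
        reference=reference,
        reference_rna=reference_rna,
        att_cores=att_cores,
        taxon_id=taxon_id,
        config=cfg,
        seed=seed,
    )
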