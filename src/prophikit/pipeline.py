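"""Pipeline orchestration: prophage calling, QC, splicing, region
scanning, attachment-site consensus, pham/PEST analysis, and reporting.

``run_pipeline`` wires the stages end to end over a set of assemblies:

1. profile annotation of every gene;
2. prophage calling (pluggable; the built-in caller grows calls from
   phage-gene hit runs and refines boundaries to att core repeats);
3. QC filtering (truncated / contaminated calls omitted) and splicing
   recovery of prophages spanning contig ends;
4. sliding-window region scan, classification and defective flagging;
5. strand-normalized deduplication of prophages corpus-wide;
6. att occurrence mapping to a reference chromosome and consensus attB
   derivation with tRNA/tmRNA overlap annotation;
7. pham construction, PEST seeding, neighborhood network, cassette
   extraction and superfamily grouping;
8. tabular summaries (per-genome prophage counts, per-group means,
   unique prophages, regions per class, attB catalog, cassette table).

Everything is deterministic for fixed inputs and configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence, Union

import pandas as pd

from . import __version__
from .att import (
    AttCore,
    AttOccurrence,
    ConsensusAttB,
    annotate_overlap,
    consensus_attB,
    find_core_repeats,
    map_att_to_reference,
)
from .config import PipelineConfig, DEFAULT_CONFIG
from .core import (
    GeneFeature,
    GenomeAssembly,
    ProphageCall,
    RnaFeature,
    make_designation,
)
from .errors import ProphikitError, ValidationError
from .homology import (
    PHAGE_GENE_CATEGORIES,
    KmerIndex,
    ProfileDatabase,
    ProfileHit,
    annotate_genes,
    find_local_alignments,
)
from .io import PhageDatabase
from .pest import (
    build_neighborhood_network,
    extract_cassettes,
    group_superfamilies,
    seed_pest_homologs,
)
from .phams import (
    assign_clusters,
    build_phams,
    build_proteome_network,
    pham_membership,
)
from .regions import (
    REGION_SCAN_CATEGORIES,
    GenomicRegion,
    classify_region,
    dedupe_prophages,
    filter_prophage_calls,
    flag_defective,
    scan_regions,
)
from .splice import (
    SplicedProphage,
    assign_cluster_from_reference,
    find_end_fragments,
    group_fragments_by_reference,
    make_profile_validator,
    splice_fragments,
    validate_spliced,
)


@dataclass
class PipelineInputs:
    """Everything one run needs: assemblies with annotations plus the
    reference databases."""

    assemblies: list[GenomeAssembly]
    genes: dict[str, list[GeneFeature]]  # keyed by strain_id
    phage_db: PhageDatabase
    profile_db: ProfileDatabase
    rna_features: dict[str, list[RnaFeature]] = field(default_factory=dict)
    reference: Optional[GenomeAssembly] = None
    reference_rna: list[RnaFeature] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Prophage callers
# ---------------------------------------------------------------------------

ProphageCaller = Callable[
    [GenomeAssembly, Sequence[GeneFeature], Sequence[ProfileHit], PipelineConfig],
    list[ProphageCall],
]


def region_scan_caller(
    assembly: GenomeAssembly,
    genes: Sequence[GeneFeature],
    hits: Sequence[ProfileHit],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[ProphageCall]:
    """Built-in heuristic prophage caller.

    Candidate calls are maximal runs of genes with phage-gene profile hits
    (archetypal phage genes, major capsid) in which consecutive hits are
    at most ``call_max_hit_gap_genes`` apart; runs with fewer than
    ``min_phage_genes_for_call`` hit genes are dropped.  Each candidate
    interval is then refined to the longest flanking att direct repeat of
    at least ``att_call_min_core_bp`` — when found, the call spans attL
    through attR exactly.  Calls are designated by genomic position.
    """
    phage_hit_genes = {
        h.gene_id for h in hits if h.significant and h.category in PHAGE_GENE_CATEGORIES
    }
    # integrase/transposase hits extend a candidate's span (the integrase
    # sits next to attL) but do not count toward the phage-gene minimum
    span_hit_genes = phage_hit_genes | {
        h.gene_id
        for h in hits
        if h.significant and h.category in REGION_SCAN_CATEGORIES
    }
    raw: list[tuple[str, int, int, Optional[AttCore]]] = []
    for contig in assembly.contigs:
        contig_genes = sorted(
            (g for g in genes if g.contig_id == contig.contig_id),
            key=lambda g: g.rank,
        )
        hit_genes = [g for g in contig_genes if g.gene_id in span_hit_genes]
        if not hit_genes:
            continue
        runs: list[list[GeneFeature]] = [[hit_genes[0]]]
        for g in hit_genes[1:]:
            if g.rank - runs[-1][-1].rank <= config.call_max_hit_gap_genes:
                runs[-1].append(g)
            else:
                runs.append([g])
        for run in runs:
            if sum(1 for g in run if g.gene_id in phage_hit_genes) < config.min_phage_genes_for_call:
                continue
            start, end = run[0].start, run[-1].end
            core = find_core_repeats(
                assembly, contig.contig_id, (start, end), config
            )
            if core is not None and core.length >= config.att_call_min_core_bp:
                start, end = core.attL_start, core.attR_end
            else:
                core = None
            raw.append((contig.contig_id, start, end, core))

    order = {c.contig_id: i for i, c in enumerate(assembly.contigs)}
    raw.sort(key=lambda r: (order[r[0]], r[1]))
    calls = []
    for index, (contig_id, start, end, core) in enumerate(raw, start=1):
        sequence = assembly.contig(contig_id).sequence[start:end]
        calls.append(
            ProphageCall(
                designation=make_designation(assembly.taxon_id, assembly.strain_id, index),
                genome_id=assembly.genome_id,
                contig_id=contig_id,
                start=start,
                end=end,
                sequence=sequence,
                status="intact",
                core_att=core,
            )
        )
    return calls


def truth_backed_caller(truth_records) -> ProphageCaller:
    """A caller replaying known prophage intervals (fixture debugging and
    adapter testing); production discovery uses the region-scan caller."""

    def caller(assembly, genes, hits, config):
        raw = [
            t
            for t in truth_records
            if t.element_type == "prophage" and t.strain_id == assembly.strain_id
        ]
        order = {c.contig_id: i for i, c in enumerate(assembly.contigs)}
        raw.sort(key=lambda t: (order[t.contig_id], t.start))
        return [
            ProphageCall(
                designation=make_designation(assembly.taxon_id, assembly.strain_id, i + 1),
                genome_id=assembly.genome_id,
                contig_id=t.contig_id,
                start=t.start,
                end=t.end,
                sequence=assembly.contig(t.contig_id).sequence[t.start : t.end],
            )
            for i, t in enumerate(raw)
        ]

    return caller


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------


@dataclass
class GenomeReport:
    assembly: GenomeAssembly
    hits: list[ProfileHit]
    calls: list[ProphageCall]  # kept + omitted, designation order
    kept: list[ProphageCall]
    omitted: list[ProphageCall]
    spliced: list[SplicedProphage]
    regions: list[GenomicRegion]
    error: Optional[str] = None


@dataclass
class ReportBundle:
    genomes: dict[str, GenomeReport]
    unique_prophages: list[ProphageCall]
    multiplicity: list[tuple[str, int, list[str]]]
    attB_sites: list[ConsensusAttB]
    unplaced_occurrences: list[str]
    phams: list
    cluster_assignment: Optional[object]
    proteome_network: list[tuple[str, str, float]]
    pest_network: object
    cassettes: list
    superfamilies: dict[str, str]
    pham_roles: dict[str, str]
    config: PipelineConfig

    # -- tables -----------------------------------------------------------
    def prophage_table(self) -> pd.DataFrame:
        rows = []
        for genome_id in sorted(self.genomes):
            rep = self.genomes[genome_id]
            for c in rep.calls:
                rows.append(
                    {
                        "designation": c.designation,
                        "genome_id": c.genome_id,
                        "contig": c.contig_id,
                        "start_1based": c.start + 1,
                        "end": c.end,
                        "length": c.end - c.start,
                        "status": c.status,
                        "cluster": c.cluster_label or "",
                        "att_core": getattr(c.core_att, "sequence", "") if c.core_att else "",
                        "omission_reason": c.omission_reason or "",
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "designation", "genome_id", "contig", "start_1based", "end",
                "length", "status", "cluster", "att_core", "omission_reason",
            ],
        )

    def region_table(self) -> pd.DataFrame:
        rows = []
        for genome_id in sorted(self.genomes):
            for region in self.genomes[genome_id].regions:
                rows.append(
                    {
                        "genome_id": genome_id,
                        "contig": region.contig_id,
                        "start_1based": region.start + 1,
                        "end": region.end,
                        "gene_span": f"{region.rank_start}-{region.rank_end}",
                        "classes": ",".join(sorted(region.classes)),
                        "n_hits": len(region.hits),
                        "n_nt_evidence": len(region.nt_evidence),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["genome_id", "contig", "start_1based", "end", "gene_span",
                     "classes", "n_hits", "n_nt_evidence"],
        )

    def attB_table(self) -> pd.DataFrame:
        rows = [
            {
                "attB_id": s.attB_id,
                "start_1based": s.start + 1,
                "end": s.end,
                "n_occurrences": len(s.occurrences),
                "integrase_class": s.integrase_class,
                "overlap_feature": s.overlap_feature or "",
            }
            for s in self.attB_sites
        ]
        return pd.DataFrame(
            rows,
            columns=["attB_id", "start_1based", "end", "n_occurrences",
                     "integrase_class", "overlap_feature"],
        )

    def cassette_table(self) -> pd.DataFrame:
        rows = [
            {
                "genome_id": c.genome_id,
                "contig": c.contig_id,
                "genes": ",".join(c.gene_ids),
                "roles": "-".join(c.roles),
                "architecture": c.architecture,
                "superfamily": c.superfamily,
            }
            for c in self.cassettes
        ]
        return pd.DataFrame(
            rows,
            columns=["genome_id", "contig", "genes", "roles", "architecture",
                     "superfamily"],
        )

    def write(self, outdir: Union[str, Path], rng_seed: Optional[int] = None) -> None:
        """Write the TSV report bundle plus a checksummed run manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tables = {
            "prophages.tsv": self.prophage_table(),
            "regions.tsv": self.region_table(),
            "attB_catalog.tsv": self.attB_table(),
            "cassettes.tsv": self.cassette_table(),
        }
        for name, table in tables.items():
            table.to_csv(outdir / name, sep="\t", index=False)
        with open(outdir / "pest_network.tsv", "w") as fh:
            fh.write("pham_a\tpham_b\tadjacency_count\n")
            for a, b, count in self.pest_network.edge_list():
                fh.write(f"{a}\t{b}\t{count}\n")
        with open(outdir / "unique_prophages.tsv", "w") as fh:
            fh.write("representative\tmultiplicity\tmembers\n")
            for rep, mult, members in self.multiplicity:
                fh.write(f"{rep}\t{mult}\t{','.join(members)}\n")
        manifest = {
            "tool": "prophikit",
            "version": __version__,
            "rng_seed": self.config.rng_seed if rng_seed is None else rng_seed,
            "config": self.config.to_dict(),
            "outputs": {},
        }
        for path in sorted(outdir.glob("*.tsv")):
            manifest["outputs"][path.name] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# The pipeline
# ---------------------------------------------------------------------------


def run_pipeline(
    inputs: PipelineInputs,
    config: PipelineConfig = DEFAULT_CONFIG,
    caller: Optional[ProphageCaller] = None,
) -> ReportBundle:
    """Run discovery end to end; per-genome failures are recorded in the
    genome's report while the remaining genomes complete."""
    caller = caller or region_scan_caller
    validator = make_profile_validator(inputs.profile_db, config)
    genomes: dict[str, GenomeReport] = {}
    score_cache: dict[tuple[str, str], float] = {}
    db_index = KmerIndex(dict(inputs.phage_db.items()), config.seed_kmer)

    for assembly in inputs.assemblies:
        genes = inputs.genes.get(assembly.strain_id, [])
        try:
            hits = annotate_genes(
                genes, inputs.profile_db, config.profile_score_threshold, score_cache
            )
            calls = caller(assembly, genes, hits, config)
            kept, omitted = filter_prophage_calls(calls, assembly, genes, hits, config)

            # splicing: prophages spanning contig ends
            spliced: list[SplicedProphage] = []
            if assembly.contig_count > 1:
                fragments = find_end_fragments(
                    assembly, inputs.phage_db, config, index=db_index
                )
                for ref_id in sorted(group_fragments_by_reference(fragments)):
                    group = group_fragments_by_reference(fragments)[ref_id]
                    if len(group) < 2 or len({f.contig_id for f in group}) < 2:
                        continue  # a lone end fragment is not a split prophage
                    sp = splice_fragments(group, assembly, inputs.phage_db, config)
                    assign_cluster_from_reference(sp, inputs.phage_db)
                    validate_spliced(sp, validator, config=config)
                    spliced.append(sp)

            # represent spliced reconstructions as prophage calls too
            next_index = len(calls) + 1
            for sp in spliced:
                call = ProphageCall(
                    designation=make_designation(
                        assembly.taxon_id, assembly.strain_id, next_index
                    ),
                    genome_id=assembly.genome_id,
                    contig_id="+".join(
                        dict.fromkeys(f.contig_id for f in sp.fragments)
                    ),
                    start=0,
                    end=len(sp.sequence),
                    sequence=sp.sequence,
                    status="spliced_partial",
                    cluster_label=sp.cluster_label,
                )
                calls.append(call)
                if sp.validated:
                    kept.append(call)
                next_index += 1

            # provisional cluster for intact kept calls: best nucleotide
            # match in the reference phage database
            for call in kept:
                if call.status != "intact" or call.cluster_label is not None:
                    continue
                alns = find_local_alignments(
                    call.sequence,
                    db_index,
                    min_len=config.min_fragment_len_bp,
                    min_identity=config.min_alignment_identity,
                    k=config.seed_kmer,
                    xdrop=config.xdrop,
                )
                if alns:
                    best = max(alns, key=lambda a: (a.score, a.subject_id))
                    call.cluster_label = inputs.phage_db.cluster_of(best.subject_id)

            # region scan over every contig
            region_hits = [
                h for h in hits if h.category in REGION_SCAN_CATEGORIES
            ]
            regions: list[GenomicRegion] = []
            for contig in assembly.contigs:
                contig_genes = sorted(
                    (g for g in genes if g.contig_id == contig.contig_id),
                    key=lambda g: g.rank,
                )
                gene_ids = {g.gene_id for g in contig_genes}
                contig_hits = [h for h in region_hits if h.gene_id in gene_ids]
                kept_intervals = [
                    (c.start, c.end)
                    for c in kept
                    if c.contig_id == contig.contig_id and c.status == "intact"
                ]
                for region in scan_regions(
                    contig_genes, contig_hits, config.window_size_genes,
                    config.region_extent,
                ):
                    classify_region(region, kept)
                    if region.classes & {"phage_related", "integrated_element"}:
                        # accepted prophage sequence is masked: only
                        # phage similarity outside a kept call marks a
                        # region as a likely defective prophage
                        flag_defective(
                            region, assembly, inputs.phage_db, config,
                            mask_intervals=kept_intervals, index=db_index,
                        )
                    regions.append(region)

            genomes[assembly.genome_id] = GenomeReport(
                assembly, hits, calls, kept, omitted, spliced, regions
            )
        except Exception as exc:  # a failing genome must not sink the run
            genomes[assembly.genome_id] = GenomeReport(
                assembly, [], [], [], [], [], [], error=f"{type(exc).__name__}: {exc}"
            )

    # -- corpus-level stages -----------------------------------------------
    all_kept = [c for rep in genomes.values() for c in rep.kept]
    unique, multiplicity = dedupe_prophages(all_kept)

    attB_sites: list[ConsensusAttB] = []
    unplaced: list[str] = []
    if inputs.reference is not None:
        occurrences = []
        for rep in sorted(genomes.values(), key=lambda r: r.assembly.strain_id):
            for call in rep.kept:
                core = call.core_att
                if core is None or call.status != "intact":
                    continue
                contig = rep.assembly.contig(call.contig_id)
                flank = config.att_flank_bp
                left = contig.sequence[max(0, core.attL_start - flank) : core.attL_start]
                right = contig.sequence[core.attR_end : core.attR_end + flank]
                occurrences.append(
                    AttOccurrence(
                        strain_id=rep.assembly.strain_id,
                        core=core.sequence,
                        sequence=left + core.sequence + right,
                        core_start=len(left),
                        core_end=len(left) + core.length,
                        integrase_class=_integrase_class_of(call),
                    )
                )
        located = map_att_to_reference(occurrences, inputs.reference, config)
        unplaced = sorted(
            rec.occurrence.strain_id for rec in located if not rec.placed
        )
        attB_sites = consensus_attB(located, config)
        for site in attB_sites:
            annotate_overlap(site, inputs.reference_rna)

    # -- pham space and PEST -----------------------------------------------
    all_genes: list[GeneFeature] = []
    gene_to_genome: dict[str, str] = {}
    for rep in sorted(genomes.values(), key=lambda r: r.assembly.strain_id):
        for g in inputs.genes.get(rep.assembly.strain_id, []):
            all_genes.append(g)
            gene_to_genome[g.gene_id] = rep.assembly.genome_id
    phams = build_phams(
        [(g.gene_id, g.protein) for g in all_genes],
        config.protein_cluster_identity,
        config.protein_cluster_coverage,
    )
    membership = pham_membership(phams)
    pham_proteins = {p.pham_id: [] for p in phams}
    protein_of = {g.gene_id: g.protein for g in all_genes}
    for p in phams:
        for gene_id in sorted(p.members):
            pham_proteins[p.pham_id].append((gene_id, protein_of[gene_id]))

    pham_roles = seed_pest_homologs(pham_proteins, inputs.profile_db, config)
    seed_pt = sorted(
        pid for pid, role in pham_roles.items() if role == "polymorphic_toxin"
    )
    pest_network = build_neighborhood_network(
        all_genes, membership, seed_pt,
        config.neighborhood_radius_orfs, config.pest_expansion,
    )
    gene_roles = {
        g.gene_id: pham_roles[membership[g.gene_id]]
        for g in all_genes
        if membership[g.gene_id] in pham_roles
    }
    cassettes = []
    for rep in sorted(genomes.values(), key=lambda r: r.assembly.strain_id):
        strain_genes = inputs.genes.get(rep.assembly.strain_id, [])
        cassettes.extend(
            extract_cassettes(strain_genes, gene_roles, rep.assembly.genome_id)
        )
    pt_pham_ids = {
        membership[g] for c in cassettes for g, role in zip(c.gene_ids, c.roles)
        if role == "PT"
    } | set(seed_pt)
    superfamilies = group_superfamilies(
        {pid: pham_proteins[pid] for pid in sorted(pt_pham_ids)}, config
    )
    for c in cassettes:
        pt_gene = c.gene_ids[c.roles.index("PT")]
        c.superfamily = superfamilies.get(membership[pt_gene], "unassigned")

    # genome-level relatedness of the unique prophages (shared gene content):
    # cluster membership at cluster_threshold, looser relatedness network at
    # network_threshold
    genes_by_location: dict[tuple[str, str], list[GeneFeature]] = {}
    for g in all_genes:
        genome = gene_to_genome[g.gene_id]
        genes_by_location.setdefault((genome, g.contig_id), []).append(g)
    prophage_phams: dict[str, frozenset] = {}
    for call in unique:
        if call.status != "intact":
            continue
        inside = [
            membership[g.gene_id]
            for g in genes_by_location.get((call.genome_id, call.contig_id), [])
            if g.start >= call.start and g.end <= call.end
        ]
        if inside:
            prophage_phams[call.designation] = frozenset(inside)
    cluster_assignment = (
        assign_clusters(prophage_phams, config.cluster_threshold, config.gene_content_metric)
        if prophage_phams
        else None
    )
    proteome_network = (
        build_proteome_network(prophage_phams, config.network_threshold, config.gene_content_metric)
        if prophage_phams
        else []
    )

    return ReportBundle(
        genomes=genomes,
        unique_prophages=unique,
        multiplicity=multiplicity,
        attB_sites=attB_sites,
        unplaced_occurrences=unplaced,
        phams=phams,
        cluster_assignment=cluster_assignment,
        proteome_network=proteome_network,
        pest_network=pest_network,
        cassettes=cassettes,
        superfamilies=superfamilies,
        pham_roles=pham_roles,
        config=config,
    )


def _integrase_class_of(call: ProphageCall) -> str:
    return getattr(call, "integrase_class", "unknown")


# ---------------------------------------------------------------------------
# Summaries (Tables 1-3 structure: counts and means per group)
# ---------------------------------------------------------------------------


def summarize(
    bundle: ReportBundle, groups: Optional[Mapping[str, str]] = None
) -> pd.DataFrame:
    """Per-group prophage statistics with a Total row.

    *groups* maps genome_id to a group label (defaults to each assembly's
    species label); columns report genomes analyzed, genomes with at
    least one prophage, total prophages, the mean per genome, and the
    number of unique prophage sequences contributed by the group.
    """
    if groups is None:
        groups = {
            gid: rep.assembly.species_label or "all"
            for gid, rep in bundle.genomes.items()
        }
    for gid in bundle.genomes:
        if gid not in groups:
            raise ValidationError(f"no group label for genome {gid}")
    unique_by_genome: dict[str, set[str]] = {}
    for rep_call in bundle.unique_prophages:
        unique_by_genome.setdefault(rep_call.genome_id, set()).add(rep_call.designation)

    rows = []
    for label in sorted(set(groups.values())):
        members = sorted(g for g, lab in groups.items() if lab == label)
        counts = [len(bundle.genomes[g].kept) for g in members]
        rows.append(
            {
                "group": label,
                "n_genomes": len(members),
                "genomes_with_prophage": sum(1 for c in counts if c > 0),
                "total_prophages": sum(counts),
                "mean_prophages": (sum(counts) / len(members)) if members else 0.0,
                "unique_prophages": sum(
                    len(unique_by_genome.get(g, ())) for g in members
                ),
            }
        )
    total = {
        "group": "Total",
        "n_genomes": sum(r["n_genomes"] for r in rows),
        "genomes_with_prophage": sum(r["genomes_with_prophage"] for r in rows),
        "total_prophages": sum(r["total_prophages"] for r in rows),
        "mean_prophages": (
            sum(r["total_prophages"] for r in rows)
            / max(1, sum(r["n_genomes"] for r in rows))
        ),
        "unique_prophages": len(bundle.unique_prophages),
    }
    rows.append(total)
    return pd.DataFrame(
        rows,
        columns=["group", "n_genomes", "genomes_with_prophage", "total_prophages",
                 "mean_prophages", "unique_prophages"],
    )
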