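"""Pipeline configuration.

Every named threshold used anywhere in the toolkit lives here, so a run is
fully described by one :class:`PipelineConfig` plus a seed.  Defaults follow
the published analysis where a value is printed (window of 15 genes, 35%
shared gene content for cluster membership, 25% for the relatedness network,
50%/50% identity/coverage for protein-family construction, a 2-ORF
neighborhood radius around polymorphic-toxin genes, and the 100-contig
assembly-admission rule); the remaining cutoffs are explicit, documented
stand-ins for criteria the upstream tools keep internal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .errors import ValidationError


@dataclass
class PipelineConfig:
    # -- corpus admission -------------------------------------------------
    max_contigs: int = 100

    # -- region scanning --------------------------------------------------
    window_size_genes: int = 15
    #: region extent strategy: "window_union" (union of qualifying windows)
    #: or "hit_bounded" (first to last hit gene).
    region_extent: str = "window_union"

    # -- pham / cluster thresholds ---------------------------------------
    cluster_threshold: float = 0.35
    network_threshold: float = 0.25
    protein_cluster_identity: float = 0.50
    protein_cluster_coverage: float = 0.50
    #: shared-gene-content strategy: "mean" of the two directional
    #: fractions, or "min_denominator" (|A∩B| / max(|A|,|B|)).
    gene_content_metric: str = "mean"

    # -- PEST neighborhood network ----------------------------------------
    neighborhood_radius_orfs: int = 2
    #: anchor expansion: "full" (all member genes of discovered phams become
    #: anchors) or "seeds_only" (only the original toxin genes anchor).
    pest_expansion: str = "full"
    #: N-terminal window (aa) used to build per-pham secretion-domain
    #: profiles for superfamily grouping.
    pest_nterm_window_aa: int = 200
    #: profile-profile score threshold per overlapped column (log-odds
    #: dot-product units; related columns score ~1, unrelated ~0).
    pest_pp_threshold_bits_per_col: float = 0.20
    pest_pp_min_overlap_cols: int = 50

    # -- nucleotide homology (contig-end fragments, defective evidence) ---
    min_fragment_len_bp: int = 2000
    end_margin_bp: int = 5000
    min_alignment_identity: float = 0.80
    #: minimum alignment length for "defective prophage" nucleotide evidence
    defective_min_len_bp: int = 1000
    seed_kmer: int = 15
    xdrop: int = 20

    # -- profile matching --------------------------------------------------
    #: bit-score cutoff for a significant profile hit.  Log-odds are taken
    #: against a uniform amino-acid background, so 0 would mean "better than
    #: background"; scanning a corpus evaluates on the order of 1e5 profile
    #: placements, whose null maximum reaches ~10 bits, so the default sits
    #: a Bonferroni-style margin above that while remaining far below the
    #: weakest homologs of interest (>=50 bits at ~40% identity).
    profile_score_threshold: float = 20.0

    # -- attachment sites --------------------------------------------------
    min_core_len_bp: int = 10
    boundary_search_bp: int = 3000
    att_flank_bp: int = 200
    #: minimum core length the prophage caller accepts when refining call
    #: boundaries to an att repeat; chance repeats between two multi-kb
    #: boundary windows reach ~12-14 bp, so refinement demands more.
    att_call_min_core_bp: int = 20
    #: consensus strategy: "intersection" (conserved coordinate positions)
    #: or "majority" (positions covered by more than half the occurrences).
    att_consensus: str = "intersection"

    # -- prophage-call QC --------------------------------------------------
    #: a call boundary without an att core this close to a contig end marks
    #: the call truncated; generous because gene-bounded call boundaries
    #: stop at the last complete gene, up to an intergenic gap short of the
    #: break itself.
    truncation_margin_bp: int = 2500
    bacterial_contamination_threshold: float = 0.33
    #: minimum number of genes with phage-gene profile hits for the built-in
    #: region-scan-backed caller to emit a prophage call.
    min_phage_genes_for_call: int = 5
    #: the caller splits a region's phage-gene hits into separate candidate
    #: calls wherever consecutive hits are more than this many genes apart
    #: (two prophages closer than a window length would otherwise fuse).
    call_max_hit_gap_genes: int = 4
    #: built-in spliced-prophage validator: minimum fraction of called genes
    #: with a significant phage-archetype hit.
    validator_min_phage_fraction: float = 0.5
    #: minimum ORF length (aa) for the naive fixture gene caller; high
    #: enough that frameshifted stop-free stretches inside real genes
    #: rarely surface as spurious calls.
    min_orf_aa: int = 120
    #: reference coverage above which a spliced reconstruction is complete.
    splice_complete_coverage: float = 0.95

    # -- conservation profiling -------------------------------------------
    conservation_smooth_window: int = 15

    rng_seed: int = 0

    def __post_init__(self) -> None:
        fractions = {
            "cluster_threshold": self.cluster_threshold,
            "network_threshold": self.network_threshold,
            "protein_cluster_identity": self.protein_cluster_identity,
            "protein_cluster_coverage": self.protein_cluster_coverage,
            "min_alignment_identity": self.min_alignment_identity,
            "bacterial_contamination_threshold": self.bacterial_contamination_threshold,
            "validator_min_phage_fraction": self.validator_min_phage_fraction,
            "splice_complete_coverage": self.splice_complete_coverage,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {value}")
        lengths = {
            "max_contigs": self.max_contigs,
            "window_size_genes": self.window_size_genes,
            "neighborhood_radius_orfs": self.neighborhood_radius_orfs,
            "min_fragment_len_bp": self.min_fragment_len_bp,
            "end_margin_bp": self.end_margin_bp,
            "defective_min_len_bp": self.defective_min_len_bp,
            "min_core_len_bp": self.min_core_len_bp,
            "boundary_search_bp": self.boundary_search_bp,
            "seed_kmer": self.seed_kmer,
            "min_orf_aa": self.min_orf_aa,
        }
        for name, value in lengths.items():
            if value <= 0:
                raise ValidationError(f"{name} must be positive, got {value}")
        if self.region_extent not in ("window_union", "hit_bounded"):
            raise ValidationError(f"unknown region_extent {self.region_extent!r}")
        if self.gene_content_metric not in ("mean", "min_denominator"):
            raise ValidationError(
                f"unknown gene_content_metric {self.gene_content_metric!r}"
            )
        if self.pest_expansion not in ("full", "seeds_only"):
            raise ValidationError(f"unknown pest_expansion {self.pest_expansion!r}")
        if self.att_consensus not in ("intersection", "majority"):
            raise ValidationError(f"unknown att_consensus {self.att_consensus!r}")

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULT_CONFIG = PipelineConfig()
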