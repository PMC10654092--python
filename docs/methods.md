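# Methods

This note documents the models and procedures prophikit implements, the
parameters that matter, the synthetic data the tests run on, and the
choices made where the design was genuinely open.  Coordinates are
0-based half-open internally and 1-based inclusive in emitted reports
(GFF3 convention).

## Similarity search

**Nucleotide local alignment** (`homology.find_local_alignments`) is an
exact-k-mer seed-and-extend search: 15-mer seeds (seeds containing N are
skipped; N never matches during extension), seeds merged into maximal
runs per (subject, diagonal), then ungapped extension with an X-drop of
20 under +1 match / −2 mismatch scoring.  Identity is matches divided by
alignment length.  Both strands of the query are searched, and a
prebuilt `KmerIndex` can be shared across queries.  The design target is
exact or near-exact copies — the regime of contig-end fragments and
defective remnants against a curated phage database; for diverged real
data a gapped external aligner can be adapted behind the same
`LocalAlignment` record.  The ungapped X-drop means alignments across a
dense mutation cluster can be cut short; the X-drop budget is
configurable (`xdrop`) for lenient searches.

**Protein profiles** (`homology.Pssm`) are ungapped position-specific
score matrices over the 20 amino acids: +1 pseudocounts, uniform 1/20
background, log2-odds columns.  A protein's score is the best column sum
over all placements with the shorter of profile and protein fully
contained in the longer.  Profiles are a deterministic, dependency-free
stand-in for profile HMMs; a real HMM engine can be plugged in behind
the `ProfileHit` contract.

*Significance* (`profile_score_threshold`, default 20 bits).  Zero bits
would mean "better than background", but scanning a corpus evaluates on
the order of 10^5 (protein, profile, placement) triples, and the
maximum of that many null scores reaches roughly +10 bits (each
placement's null score for a 150–300 column profile has mean ≈ −3 to −6
bits and sd ≈ 3 bits).  20 bits adds a Bonferroni-style margin over the
null maximum while remaining far below genuinely homologous scores
(≈ +0.3 bits per column at 40% identity: ≥ 50 bits for the shortest
profiles in use).

## Prophage calling and QC

The built-in caller (`pipeline.region_scan_caller`) grows candidate
calls from runs of genes with significant phage-gene hits (archetypal
phage genes and major capsid; integrase/transposase hits extend the run
but do not count toward the minimum).  Parameters:

* `call_max_hit_gap_genes` (4) — a run breaks where consecutive hit
  genes are more than 4 genes apart.  Needed because the 15-gene window
  scanner merges any two phage elements closer than a window length into
  one region; real neighboring prophages at a typical backbone spacing
  would otherwise fuse into one call.
* `min_phage_genes_for_call` (5) — PICIs and small remnants carry 1–4
  phage-gene hits and must not be called as prophages.
* `boundary_search_bp` (3000) and `att_call_min_core_bp` (20) — the
  candidate interval is refined to the longest exact direct repeat with
  one copy in each boundary window.  The left boundary of a hit run can
  sit ~2.5 kb right of attL (integrase plus generous intergenic gaps),
  hence the 3 kb window; chance exact repeats between two 6 kb windows
  reach ~14 bp (≈ log-base-1/Σp² of the window-pair product), hence the
  20 bp floor for accepting a repeat as att evidence.  The general
  `find_core_repeats` operation keeps its own lower floor
  (`min_core_len_bp`, 10) so short serine-integrase cores can be chased
  deliberately.

QC (`regions.filter_prophage_calls`) omits a call as *truncated* when a
boundary without an att core lies within `truncation_margin_bp`
(2500 bp) of a contig end — generous because gene-bounded call
boundaries stop at the last complete annotated gene, up to an
intergenic gap plus one unannotated gene short of the break itself —
and as *contaminated* when fewer than
`bacterial_contamination_threshold` (33%) of the genes inside the call
carry phage-gene hits.  Omitted calls are retained with
`status="omitted"` and a reason so reports can account for them.

The spliced-prophage validator accepts a reconstruction when at least
half its genes carry a significant phage-archetype hit; without an
annotation it calls ORFs naively (ATG-to-stop, both strands,
`min_orf_aa` 120 — high enough that frameshifted stop-free stretches
inside real genes rarely surface).

## Region scanning and classification

A window of `window_size_genes` (15) slides one gene at a time along
each contig (windows never span contigs); windows with ≥1 significant
hit qualify, and the union of qualifying windows is merged into maximal
regions — so a lone hit spans up to 29 genes, clipped at contig ends.
The alternative hit-bounded extent is config-selectable
(`region_extent`).  The scanner listens only to the phage-gene +
integrase/transposase profile categories; effector/toxin profiles drive
the cassette analysis, not region discovery.  Classification is
non-exclusive: integrated element (integrase or transposase, and not
overlapping an accepted prophage call by ≥1 bp — prophages are counted
separately), phage-related (≥1 phage gene; integrase/transposase-only
regions are mobility elements, not phage-related), candidate PICI
(integrase AND major capsid).  Defective-prophage flagging aligns the
region sequence (with accepted prophage intervals N-masked, so a
prophage does not count as its own defective evidence) against the
intact-phage database at ≥1 kb and ≥80% identity.

## Attachment sites

Occurrences of a prophage's core (plus `att_flank_bp` = 200 bp of host
flank on each side, i.e. the reconstituted attB) are placed on a closed
reference chromosome by local alignment; ties between equally good loci
flag the occurrence ambiguous.  Consensus attB sites are the
overlap-connected components of placed occurrences, each collapsed to
the **intersection** of its member intervals — the coordinate positions
conserved across every strain; a majority-coverage mode is available
(`att_consensus`).  Sites are numbered attB-1, attB-2, … by reference
position (synthetic numbering, not any historical catalog).  attP is
reconstructed by circularizing the prophage at the core: the output is
the excised circle linearized at the junction, length = prophage −
core, carrying the core exactly once; in-silico re-integration at the
original attB restores the lysogen byte-exactly, and this round trip is
asserted on random fixtures.  Each site's integrase class is the
majority class of contributing occurrences, with conflicts flagged.

## Phams, clusters, and the relatedness network

Two proteins are directly related when global identity
(1 − edit distance / longer length, via edlib) is ≥50% and the shorter
covers ≥50% of the longer; phams are the transitive closure.  Exact
duplicate sequences are collapsed before the all-pairs pass and a
length-ratio prefilter skips pairs that cannot meet coverage.  Shared
gene content between two genomes is the mean of the two directional
shared-pham fractions (|A∩B|/|A| and |A∩B|/|B|) over **distinct** phams
(paralogs count once); a min-denominator variant is selectable.
Clusters are connected components at ≥35%, labeled A, B, C, … by
decreasing size (ties by smallest member id); singletons are genomes
alone in their component.  The relatedness network repeats the
computation at ≥25% and is therefore always a supergraph of the cluster
graph.  Subcluster assignment is out of scope.

## PEST discovery

Role seeding assigns each pham at most one of PT / WXG / Imm — the
best-scoring significant profile hit wins, ties broken in that order.
The neighborhood network starts from PT-seeded phams: every gene of an
anchor pham contributes the phams of genes within
`neighborhood_radius_orfs` (2) ORFs up/downstream on its contig (rank
distance; strand ignored; contig ends truncate silently), newly reached
phams anchor the next round, and iteration stops at a fixpoint — which
equals the connected component of the radius-adjacency pham graph
around the seeds.  Both readings of the anchor-expansion ambiguity are
implemented (`pest_expansion`: `full` expands every member gene of a
discovered pham genome-wide, the default; `seeds_only` stops after one
ring).

Cassettes are read off the maximal run of rank-adjacent, same-strand,
role-bearing genes around each PT, in the strand's reading direction:
`WXG,PT,Imm` → three-gene, `WXG,WXG,PT,Imm` → four-gene, anything else
with a PT → incomplete.

Superfamilies: each PT pham gets a profile over its members' N-terminal
`pest_nterm_window_aa` (200) residues — the conserved secretion domain;
the variable C-terminal toxin domain is excluded.  Pham pairs connect
when the best ungapped offset of their **mean-centered** column
log-odds dot product exceeds `pest_pp_threshold_bits_per_col` (0.2) per
overlapped column with ≥50 columns of overlap.  Centering matters: the
raw dot product of two columns' background penalties is systematically
positive (≈ +0.1 per column for sharp profiles), enough to bridge
unrelated profiles over a 200-column window; after centering, unrelated
columns score ≈ 0 and same-residue columns ≈ +1.  Connected components
become PEST1, PEST2, PEST3 by decreasing size; further components are
`unassigned-k`.  The labels are size-ordered synthetic names.

Conservation profiles over aligned PT proteins use modal-residue
frequency per column (gaps excluded from the numerator, counted in the
denominator), smoothed by a centered 15-column moving average, and
segmented by thresholding at the track mean: leading high segment =
WXG, trailing = TOX, middle = linker.

## The synthetic corpus

`simulate.generate_corpus` builds the default study conditions: 20
draft assemblies sharing a ~94 kb chromosome backbone (60 host genes,
i.i.d. background DNA at GC 0.66, mycobacterial-like), 5 attB loci
(40–50 bp random cores, spaced 11 host genes apart; two overlap planted
tRNA/tmRNA genes), 30 intact prophages integrated at the loci with
attL/attR core duplication, 10 prophages split across contig ends at a
forced breakpoint, 8 candidate PICIs (integrase + capsid + background
genes), 25 PEST cassettes (three- and four-gene, from 3 N-terminal
toxin archetypes at 8% per-instance substitution — the mutation load
the superfamily grouping must absorb), 6 defective remnants (exact
multi-gene phage slices), and 3 + 3 truncated/contaminated QC decoys.
Six reference phage genomes (15 kb, 18 genes) populate the database;
two of them share half their genes (one cluster), the rest are
unrelated.  Proteins are uniform-random over the 20 amino acids and
encoded through a fixed one-codon-per-residue table chosen so that all
reading frames other than the coding one hit stop codons regularly;
otherwise a naive ORF caller drowns in frameshifted stop-free ORFs that
no real genome would show at this rate.

Two generator details exist to make the planted truth well-posed rather
than to make detection easier.  First, the bases immediately flanking
each att core are pinned ('A' on the host side, 'C' at the phage
termini): without this, a 1-in-4 chance base match extends the
attL/attR maximal repeat past the planted core at roughly half the
loci, and "the longest direct repeat" no longer equals the planted
truth.  Second, phage-like elements (remnants, decoys, PICIs) are
planted at least 5 host genes from any att locus so that a prophage and
an unrelated element never fall within one caller hit-run of each
other; cassettes, which carry no phage-gene hits, may land anywhere.

What the corpus does **not** emulate: gene-level evolution (the default
corpus is substitution-free outside cassette proteins; a whole-genome
`mutation_rate` mode exists and recovery degrades monotonically with
it, but annotation proteins are not re-derived from mutated DNA),
recombination and mosaicism, codon/GC structure beyond a global GC
target, insertion-sequence noise, assembly artifacts other than clean
breaks, and real integrase-family sequence diversity.  Passing at 100%
on this corpus therefore demonstrates the bookkeeping, coordinate
arithmetic and graph algorithms are exact, and that the detectors are
correct in the near-exact regime they target — not that the built-in
aligner or PSSMs match BLAST/HMMER sensitivity on diverged real
genomes, which is what the pluggable adapter seams are for.

The generator and the detectors share no detection logic (the generator
plants by construction; the detectors search), so recovery tests are
meaningful.

## Numerical and procedural choices

* Determinism everywhere: all randomness flows from explicit seeds;
  iteration orders are sorted; two runs from one seed produce
  byte-identical report bundles (asserted by checksum).
* Tie-breaks: att repeats — leftmost attL then leftmost attR; pham ids —
  input order of first member; representative — longest member, then
  earliest; cluster labels — component size then smallest member id;
  splice overlap trimming keeps the earlier-on-reference fragment's
  copy; fragment→reference assignment keeps the single best
  identity×length alignment.
* Degenerate inputs: empty protein sets give empty pham lists (not
  errors); a single splice fragment is returned as a partial
  reconstruction; a consensus group with an empty intersection is split
  at its largest coverage gap with a warning; per-genome pipeline
  failures are recorded on that genome's report while the rest of the
  run completes.
* Problem sizes in the tests (500 window layouts, 200 proteins for the
  pham oracle, 100 neighborhood layouts, 100 att round trips, the
  20-assembly corpus) were chosen so each check exercises its
  combinatorial space while the whole suite stays interactive to run.

## Known limitations

* The built-in aligner is ungapped; indel-containing homologs fragment
  into multiple alignments or are missed.
* PSSMs ignore residue substitution similarity (no BLOSUM weighting);
  diverged homologs below ~30% identity need a real profile-HMM engine.
* Splicing chains fragments greedily by reference coordinates; complex
  rearrangements between fragment and reference are not modeled.
* attB numbering is positional per run, not stable across corpora.
* Cluster labels are size-ordered synthetic letters, not any published
  catalog's letters.
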