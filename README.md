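# prophikit

Prophage, phage-satellite and phage-encoded toxin-cassette discovery in
draft bacterial assemblies.

Temperate phages integrate into their host chromosome by site-specific
recombination between a bacterial attachment site (*attB*) and a phage
site (*attP*) that share a common **core** sequence; the integrated
prophage is flanked by the duplicated core as *attL*/*attR* direct
repeats.  Draft assemblies complicate every step of finding these
elements: prophages get split across unjoined contigs, defective
remnants and satellite elements (PICIs) mimic them, and calls can be
truncated by contig ends or diluted with bacterial sequence.  prophikit
is a toolkit for this whole problem, aimed at researchers mining large
collections of *Mycobacterium*-like draft genomes:

* **Contig-end splicing** — phage-like fragments within a margin of
  contig ends are located against a database of cluster-labeled
  reference phage genomes, ordered along their best reference,
  concatenated into a single prophage sequence, assigned the reference's
  cluster, and validated.
* **Sliding-window region scan** — a 15-gene window over each contig
  records regions with significant profile hits and classifies them:
  *integrated element* (integrase/transposase, excluding prophages),
  *phage-related* (≥1 phage gene), *candidate PICI* (integration
  machinery + major capsid gene), and *likely defective prophage*
  (nucleotide similarity to intact phages).
* **Attachment-site machinery** — the att core is found as the longest
  exact direct repeat flanking a prophage; occurrences from many strains
  are mapped onto a reference chromosome and collapsed into consensus
  *attB* sites (the conserved coordinate positions of each overlapping
  set); *attP* is reconstructed by circularizing the prophage at the
  core; sites are annotated with overlapping tRNA/tmRNA genes.
* **Phamilies and genome relatedness** — proteins are clustered into
  phamilies ("phams") by transitive closure at 50% identity / 50%
  coverage; genomes sharing ≥35% gene content form clusters (labels A,
  B, C, …; singletons have no close relatives), and a looser relatedness
  network is drawn at 25%.
* **PEST cassette mining** — phage-encoded ESX-secreted toxin systems
  (WXG100 effector + polymorphic toxin + immunity protein) are found by
  seeding phams on toxin homology, growing a gene-neighborhood network
  (2 ORFs up/downstream, iterated to a fixpoint), reading cassettes off
  same-strand runs (three-gene WXG–PT–Imm and four-gene WXG–WXG–PT–Imm),
  and grouping toxins into superfamilies by profile–profile alignment of
  their N-terminal secretion domains.
* **Synthetic corpora with planted truth** — a deterministic generator
  builds draft assemblies of related strains with planted prophages
  (including splits across contig ends), shared attB loci, PICIs, PEST
  cassettes, defective remnants and QC decoys, each with a
  machine-readable truth record, so every detector is tested against
  known ground truth.

## Worked example

```bash
prophikit simulate --seed 3 --out corpus/ --assemblies 6
prophikit all corpus/ --out run/ --seed 3
```

prints

```
wrote corpus (6 assemblies) to corpus
12 prophages kept (12 unique), 5 consensus attB sites, 8 PEST cassettes -> run
```

meaning: across the 6 simulated strains, 12 prophage calls survived QC
(none were duplicates of one another), their att cores collapsed onto 5
consensus attB loci on the reference chromosome, and 8 WXG–PT–Imm
cassettes were extracted.  `run/` then contains `prophages.tsv` (one row
per call with 1-based coordinates, status, cluster, att core and any
omission reason), `regions.tsv` (classified phage-like regions),
`attB_catalog.tsv`, `cassettes.tsv`, `pest_network.tsv`,
`unique_prophages.tsv` and a checksummed `manifest.json`.  The attB
catalog from the same corpus:

```
attB_id  start_1based  end    n_occurrences  integrase_class  overlap_feature
attB-1   7795          7842   2              unknown
attB-2   24822         24867  1              unknown          tRNA-Arg (TCT)
attB-3   43193         43236  2              unknown
attB-4   60683         60725  2              unknown          tmRNA
attB-5   78575         78622  2              unknown
```

— five consensus sites numbered by reference position, two of them
inside tRNA/tmRNA genes, the classic targets of tyrosine integrases.

The same machinery is available as a library:

```python
from prophikit import generate_corpus, run_pipeline, PipelineConfig
from prophikit.pipeline import PipelineInputs

corpus = generate_corpus(seed=3)
bundle = run_pipeline(PipelineInputs(
    corpus.assemblies, corpus.genes, corpus.phage_db, corpus.profile_db,
    corpus.rna_features, corpus.reference, corpus.reference_rna,
))
print(bundle.attB_table())
```

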