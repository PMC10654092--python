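"""Built-in similarity search: nucleotide local alignment and protein
profile matching.

Both implementations are deterministic stand-ins honoring pluggable
contracts: :func:`find_local_alignments` plays the role of a BLASTn search
against a reference phage database (exact 15-mer seeds, diagonal run
merging, ungapped X-drop extension — adequate for exact or near-exact
copies; an external gapped aligner can be adapted to emit the same
:class:`LocalAlignment` records), and :class:`Pssm` is an ungapped
position-specific score matrix standing in for an HMM profile (+1
pseudocounts, uniform background, bit-score units) behind the same
:class:`ProfileHit` contract a real HMM engine would fill.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .core import AA_ALPHABET, GeneFeature, reverse_complement
from .errors import ConfigurationError, ValidationError

# -- nucleotide local alignment ---------------------------------------------

_MATCH = 1
_MISMATCH = -2

PROFILE_CATEGORIES = (
    "phage_archetype",
    "integrase",
    "transposase",
    "major_capsid",
    "polymorphic_toxin",
    "wxg100",
    "immunity",
)

#: categories counting as "phage genes" for phage-related region calls and
#: gene-content QC (integrases/transposases are mobility genes, not phage
#: genes; see the region classifier).
PHAGE_GENE_CATEGORIES = frozenset({"phage_archetype", "major_capsid"})


@dataclass(frozen=True)
class LocalAlignment:
    """An ungapped local alignment between a query and a subject sequence.

    ``strand == "-"`` means the subject interval matches the reverse
    complement of the query interval; both intervals are on their
    sequence's forward coordinates.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    identity: float
    aln_length: int

    def __post_init__(self) -> None:
        if self.q_end - self.q_start != self.aln_length:
            raise ValidationError("ungapped alignment: |q interval| != aln_length")
        if not 0.0 <= self.identity <= 1.0:
            raise ValidationError(f"identity {self.identity} outside [0,1]")

    @property
    def q_interval(self) -> tuple[int, int]:
        return (self.q_start, self.q_end)

    @property
    def s_interval(self) -> tuple[int, int]:
        return (self.s_start, self.s_end)

    @property
    def score(self) -> float:
        """Identity-weighted length, used to rank candidate references."""
        return self.identity * self.aln_length


def _merge_diagonal_runs(positions: list[int], k: int) -> list[tuple[int, int]]:
    """Merge sorted seed start offsets on one diagonal into maximal runs."""
    runs: list[tuple[int, int]] = []
    start = prev = positions[0]
    for p in positions[1:]:
        if p <= prev + k:  # overlapping or adjacent seeds extend the run
            prev = p
        else:
            runs.append((start, prev + k))
            start = prev = p
    runs.append((start, prev + k))
    return runs


def _xdrop_extend(
    q: str, s: str, qs: int, qe: int, ss: int, se: int, xdrop: int
) -> tuple[int, int, int, int, int]:
    """Ungapped X-drop extension of an exact run; returns interval + matches."""
    matches = qe - qs  # the seed run is exact
    # left
    score = best = 0
    best_off = 0
    off = 0
    while qs - off - 1 >= 0 and ss - off - 1 >= 0:
        off += 1
        a, b = q[qs - off], s[ss - off]
        score += _MATCH if (a == b and a != "N") else _MISMATCH
        if score > best:
            best, best_off = score, off
        elif score < best - xdrop:
            break
    left = best_off
    lmatch = sum(
        1
        for i in range(1, left + 1)
        if q[qs - i] == s[ss - i] and q[qs - i] != "N"
    )
    # right
    score = best = 0
    best_off = 0
    off = 0
    nq, ns = len(q), len(s)
    while qe + off < nq and se + off < ns:
        a, b = q[qe + off], s[se + off]
        off += 1
        score += _MATCH if (a == b and a != "N") else _MISMATCH
        if score > best:
            best, best_off = score, off
        elif score < best - xdrop:
            break
    right = best_off
    rmatch = sum(
        1
        for i in range(right)
        if q[qe + i] == s[se + i] and q[qe + i] != "N"
    )
    return qs - left, qe + right, ss - left, se + right, matches + lmatch + rmatch


class KmerIndex:
    """Exact k-mer index over a subject collection, reusable across many
    queries (building it dominates the cost of small searches)."""

    def __init__(self, subjects: Union[Mapping[str, str], Sequence[tuple[str, str]]], k: int = 15):
        items = subjects.items() if isinstance(subjects, Mapping) else list(subjects)
        self.k = k
        self.subjects = {sid: seq.upper() for sid, seq in items}
        self.index: dict[str, list[tuple[str, int]]] = {}
        for sid in sorted(self.subjects):
            seq = self.subjects[sid]
            for j in range(len(seq) - k + 1):
                kmer = seq[j : j + k]
                if "N" not in kmer:
                    self.index.setdefault(kmer, []).append((sid, j))


def find_local_alignments(
    query: str,
    subjects: Union[Mapping[str, str], Sequence[tuple[str, str]], KmerIndex],
    min_len: int = 1000,
    min_identity: float = 0.80,
    k: int = 15,
    xdrop: int = 20,
    query_id: str = "query",
) -> list[LocalAlignment]:
    """Seed-and-extend local search of *query* against every subject.

    Exact k-mer seeds (N-containing seeds skipped), runs merged per
    diagonal, ungapped X-drop extension; both strands of the query are
    searched.  *subjects* may be a prebuilt :class:`KmerIndex` to amortize
    indexing over many queries.  Reported alignments satisfy
    ``aln_length >= min_len`` and ``identity >= min_identity`` and are
    sorted by ``(subject_id, s_start, strand, q_start)``.
    """
    if not query:
        raise ValidationError("empty query sequence")
    if min_len < k:
        raise ValidationError(f"min_len {min_len} below seed size {k}")
    query = query.upper()
    index = subjects if isinstance(subjects, KmerIndex) else KmerIndex(subjects, k)
    if index.k != k:
        raise ValidationError(f"index built with k={index.k}, search asked k={k}")

    results: list[LocalAlignment] = []
    nq = len(query)
    for strand in ("+", "-"):
        q = query if strand == "+" else reverse_complement(query)
        diagonals: dict[tuple[str, int], list[int]] = {}
        for i in range(nq - k + 1):
            kmer = q[i : i + k]
            if "N" in kmer:
                continue
            for sid, j in index.index.get(kmer, ()):
                diagonals.setdefault((sid, j - i), []).append(i)
        seen: set[tuple[str, int, int, int, int]] = set()
        for sid, diag in sorted(diagonals):
            subject = index.subjects[sid]
            covered_to = -1
            for qs, qe in _merge_diagonal_runs(sorted(set(diagonals[(sid, diag)])), k):
                if qe <= covered_to:
                    continue
                xqs, xqe, xss, xse, matches = _xdrop_extend(
                    q, subject, qs, qe, qs + diag, qe + diag, xdrop
                )
                covered_to = xqe
                aln_len = xqe - xqs
                if aln_len < min_len:
                    continue
                identity = matches / aln_len
                if identity < min_identity:
                    continue
                if strand == "+":
                    oqs, oqe = xqs, xqe
                else:
                    oqs, oqe = nq - xqe, nq - xqs
                key = (sid, oqs, oqe, xss, xse)
                if key in seen:
                    continue
                seen.add(key)
                results.append(
                    LocalAlignment(
                        query_id, sid, oqs, oqe, xss, xse,
                        strand, identity, aln_len,
                    )
                )
    results.sort(key=lambda a: (a.subject_id, a.s_start, a.strand, a.q_start))
    return results


# -- protein profile matching -----------------------------------------------

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}


@dataclass(frozen=True)
class ProfileHit:
    """Best placement of a profile on one protein, with significance call."""

    gene_id: str
    profile_id: str
    category: str
    score: float
    significant: bool


class Pssm:
    """Ungapped position-specific score matrix over the 20 amino acids.

    Columns carry log2-odds of observed (+1 pseudocount) vs a uniform
    background; the score of a protein is the best column-sum over all
    ungapped placements where the shorter of profile and protein is fully
    contained in the longer.  The training sequences are retained so the
    profile can be round-tripped through its aligned-FASTA representation.
    """

    def __init__(self, profile_id: str, category: str, sequences: Sequence[str]):
        if not sequences:
            raise ValidationError(f"profile {profile_id}: no training sequences")
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise ValidationError(
                f"profile {profile_id}: training sequences must be aligned "
                f"to equal length, got lengths {sorted(lengths)}"
            )
        self.profile_id = profile_id
        self.category = category
        self.sequences = [s.upper() for s in sequences]
        self.length = lengths.pop()
        counts = np.zeros((self.length, 20))
        for seq in self.sequences:
            for col, aa in enumerate(seq):
                if aa == "-":
                    continue
                if aa not in _AA_INDEX:
                    raise ValidationError(
                        f"profile {profile_id}: residue {aa!r} outside the "
                        f"amino-acid alphabet"
                    )
                counts[col, _AA_INDEX[aa]] += 1
        freqs = (counts + 1.0) / (counts.sum(axis=1, keepdims=True) + 20.0)
        self.matrix = np.log2(freqs * 20.0)

    def score(self, protein: str) -> float:
        """Best ungapped placement score in bits."""
        if not protein:
            raise ValidationError("empty protein")
        protein = protein.upper()
        try:
            encoded = np.array([_AA_INDEX[aa] for aa in protein])
        except KeyError as exc:
            raise ValidationError(
                f"residue {exc.args[0]!r} outside the amino-acid alphabet"
            )
        lp, lm = len(protein), self.length
        if lp >= lm:
            windows = np.lib.stride_tricks.sliding_window_view(encoded, lm)
            scores = self.matrix[np.arange(lm), windows].sum(axis=1)
        else:
            per_col = self.matrix[:, encoded]  # (lm, lp)
            scores = np.array(
                [per_col.diagonal(-off).sum() for off in range(lm - lp + 1)]
            )
        return float(scores.max())

    @property
    def max_score(self) -> float:
        """The maximum attainable score (best residue in every column)."""
        return float(self.matrix.max(axis=1).sum())


def score_profile(
    protein: str, profile: Pssm, threshold: float, gene_id: str = ""
) -> ProfileHit:
    """Score one protein against one profile and call significance."""
    score = profile.score(protein)
    return ProfileHit(
        gene_id, profile.profile_id, profile.category, score, score >= threshold
    )


class ProfileDatabase:
    """A set of category-labeled profiles (the HMM-database stand-in).

    On disk: a directory of aligned FASTA files named
    ``<category>__<profile_id>.fasta``.
    """

    def __init__(self, profiles: Sequence[Pssm]):
        self.profiles = list(profiles)
        ids = [p.profile_id for p in self.profiles]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate profile_id in profile database")

    def __len__(self) -> int:
        return len(self.profiles)

    def by_category(self, category: str) -> list[Pssm]:
        return [p for p in self.profiles if p.category == category]

    @classmethod
    def from_directory(cls, directory: Union[str, Path]) -> "ProfileDatabase":
        directory = Path(directory)
        profiles = []
        for path in sorted(directory.glob("*.fasta")):
            stem = path.stem
            if "__" not in stem:
                raise ConfigurationError(
                    f"profile file {path.name} not named <category>__<id>.fasta"
                )
            category, profile_id = stem.split("__", 1)
            seqs = []
            current: list[str] = []
            with open(path) as fh:
                for line in fh:
                    line = line.strip()
                    if line.startswith(">"):
                        if current:
                            seqs.append("".join(current))
                            current = []
                    elif line:
                        current.append(line)
            if current:
                seqs.append("".join(current))
            profiles.append(Pssm(profile_id, category, seqs))
        if not profiles:
            raise ConfigurationError(f"no profiles found in {directory}")
        return cls(profiles)

    def to_directory(self, directory: Union[str, Path]) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for p in self.profiles:
            path = directory / f"{p.category}__{p.profile_id}.fasta"
            with open(path, "w") as fh:
                for i, seq in enumerate(p.sequences):
                    fh.write(f">{p.profile_id}_{i + 1}\n")
                    for j in range(0, len(seq), 60):
                        fh.write(seq[j : j + 60] + "\n")


def annotate_genes(
    genes: Iterable[GeneFeature],
    profile_db: ProfileDatabase,
    threshold: float,
    cache: Optional[dict[tuple[str, str], float]] = None,
) -> list[ProfileHit]:
    """All significant profile hits for a gene set, sorted deterministically.

    Pass a shared *cache* dict when annotating many genomes — identical
    proteins recur across strains and are scored once.
    """
    hits = []
    if cache is None:
        cache = {}
    for gene in genes:
        for profile in profile_db.profiles:
            key = (gene.protein, profile.profile_id)
            if key not in cache:
                cache[key] = profile.score(gene.protein)
            score = cache[key]
            if score >= threshold:
                hits.append(
                    ProfileHit(gene.gene_id, profile.profile_id, profile.category,
                               score, True)
                )
    hits.sort(key=lambda h: (h.gene_id, h.category, h.profile_id))
    return hits
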