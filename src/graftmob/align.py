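"""Internal read alignment.

Two aligners back the genome-of-origin classification:

* :func:`align_reads` — bounded-edit-distance semi-global mapping (the
  first- and second-pass mapper; edit caps k=2 and k=1 in the pipeline).
  "Edit distance" is unit-cost Levenshtein with the read fully consumed and
  the reference local. The search is seed-and-verify: exact k-mer probes at
  a pigeonhole-safe stride nominate candidate diagonals, which are verified
  exhaustively with banded dynamic programming (edlib, mode ``HW``). Every
  placement within the edit cap shares an exact probe k-mer, so the minimal
  distance reported equals a full semi-global scan.

* :func:`local_search` — a BLASTN-like local-alignment cross-check used to
  arbitrate genome of origin for unmapped reads. A hit requires the best
  local alignment to cover >= ``min_aligned_fraction`` of the read at
  >= ``min_identity`` percent identity (defaults 0.5 and 80), with BLASTN
  scoring (match +2, mismatch -3, gap open -5, gap extend -2) and word
  size 11 seeding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np
from Bio import Align

from .io import GeneModel, GenotypeReference, ReadRecord, revcomp

_STRAND_RANK = {"+": 0, "-": 1}


@dataclass(frozen=True, slots=True)
class AlignmentHit:
    """Best semi-global placement of one read (0-based half-open interval)."""

    read_id: str
    genotype_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    edit_distance: int
    gene_id: str | None

    def sort_key(self) -> tuple:
        return (
            self.edit_distance,
            self.chromosome,
            self.start,
            _STRAND_RANK[self.strand],
        )


@dataclass(frozen=True, slots=True)
class LocalSearchHit:
    """A BLAST-like local hit of a read against one genotype reference."""

    read_id: str
    genotype_id: str
    score: float
    aligned_fraction: float
    identity: float


class _GeneLocator:
    """Per-chromosome interval lookup: aligned interval -> overlapping gene.

    Returns the overlapping gene with the smallest (start, gene_id);
    deterministic for overlapping annotations.
    """

    def __init__(self, reference: GenotypeReference) -> None:
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
        per_chrom: dict[str, list[GeneModel]] = {}
        for g in reference.genes:
            per_chrom.setdefault(g.chromosome, []).append(g)
        for chrom, genes in per_chrom.items():
            genes.sort(key=lambda g: (g.start, g.gene_id))
            starts = np.array([g.start for g in genes], dtype=np.int64)
            ends = np.array([g.end for g in genes], dtype=np.int64)
            # running max of ends lets the scan stop early for overlapping genes
            self._by_chrom[chrom] = (
                starts,
                np.maximum.accumulate(ends),
                [g.gene_id for g in genes],
            )
        self._genes = per_chrom

    def locate(self, chrom: str, start: int, end: int) -> str | None:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, max_ends, _ = entry
        i = int(np.searchsorted(starts, end, side="left")) - 1
        genes = self._genes[chrom]
        found: str | None = None
        while i >= 0 and max_ends[i] > start:
            if genes[i].end > start:
                found = genes[i].gene_id  # genes sorted: last kept = smallest start
            i -= 1
        return found


class AlignmentIndex:
    """Exact k-mer position table over a genotype reference.

    Forward-strand k-mers are stored; reverse-strand placements are found by
    probing the read's reverse complement, so both strands are covered.
    """

    def __init__(self, genotype_id: str, k: int) -> None:
        self.genotype_id = genotype_id
        self.k = k
        self._table: dict[str, object] = {}  # kmer -> (chrom_idx, pos) or list thereof
        self.chromosomes: list[str] = []

    def add_reference(self, reference: GenotypeReference) -> None:
        k = self.k
        table = self._table
        for chrom, seq in reference.sequences.items():
            ci = len(self.chromosomes)
            self.chromosomes.append(chrom)
            n = len(seq)
            for pos in range(n - k + 1):
                kmer = seq[pos : pos + k]
                entry = table.get(kmer)
                if entry is None:
                    table[kmer] = (ci, pos)
                elif isinstance(entry, tuple):
                    table[kmer] = [entry, (ci, pos)]
                else:
                    entry.append((ci, pos))

    def lookup(self, kmer: str) -> list[tuple[int, int]]:
        entry = self._table.get(kmer)
        if entry is None:
            return []
        if isinstance(entry, tuple):
            return [entry]
        return entry

    @property
    def n_kmers(self) -> int:
        return len(self._table)

    def n_positions(self) -> int:
        return sum(1 if isinstance(v, tuple) else len(v) for v in self._table.values())

    def serialize(self) -> list[tuple[str, tuple[int, int]]]:
        """Deterministic flat representation (sorted), for equality checks."""
        out: list[tuple[str, tuple[int, int]]] = []
        for kmer in sorted(self._table):
            for entry in sorted(self.lookup(kmer)):
                out.append((kmer, entry))
        return out


def build_index(reference: GenotypeReference, k: int = 21) -> AlignmentIndex:
    """Build the exact k-mer seed index for a reference (default k=21)."""
    if not 1 <= k:
        raise ValueError("k must be positive")
    min_len = min((len(s) for s in reference.sequences.values()), default=0)
    if min_len < k:
        raise ValueError(
            f"k={k} exceeds shortest reference sequence length {min_len}"
        )
    index = AlignmentIndex(reference.genotype_id, k)
    index.add_reference(reference)
    return index


def _probe_offsets(read_len: int, k: int, max_ed: int) -> list[int]:
    """Probe start offsets with the pigeonhole guarantee.

    Any placement with <= max_ed edits leaves an error-free block of
    read_len // (max_ed + 1) bases, which contains block_len - k + 1
    consecutive exact k-mer starts; a stride no larger than that run hits
    at least one of them.
    """
    block = read_len // (max_ed + 1)
    run = block - k + 1
    if run < 1:
        return []  # pigeonhole not available at this read length
    step = max(1, run)
    offsets = list(range(0, read_len - k + 1, step))
    last = read_len - k
    if offsets[-1] != last:
        offsets.append(last)
    return offsets


def _verify_candidates(
    query: str,
    strand: str,
    diagonals: dict[int, set[int]],
    reference: GenotypeReference,
    chromosomes: list[str],
    max_ed: int,
) -> list[tuple[int, str, int, int, str]]:
    """Banded verification of seeded diagonals; returns (ed, chrom, start, end, strand)."""
    L = len(query)
    results: list[tuple[int, str, int, int, str]] = []
    for ci, diags in diagonals.items():
        chrom = chromosomes[ci]
        seq = reference.sequences[chrom]
        # merge diagonals within max_ed into shared verification windows
        sorted_diags = sorted(diags)
        groups: list[list[int]] = [[sorted_diags[0]]]
        for d in sorted_diags[1:]:
            if d - groups[-1][-1] <= max_ed:
                groups[-1].append(d)
            else:
                groups.append([d])
        for grp in groups:
            wstart = max(0, grp[0] - max_ed)
            wend = min(len(seq), grp[-1] + L + max_ed)
            window = seq[wstart:wend]
            res = edlib.align(query, window, mode="HW", task="locations", k=max_ed)
            if res["editDistance"] < 0:
                continue
            ed = res["editDistance"]
            loc = min(res["locations"], key=lambda t: (t[0], t[1]))
            results.append((ed, chrom, wstart + loc[0], wstart + loc[1] + 1, strand))
    return results


def _full_scan(
    query: str,
    strand: str,
    reference: GenotypeReference,
    max_ed: int,
) -> list[tuple[int, str, int, int, str]]:
    results = []
    for chrom in sorted(reference.sequences):
        seq = reference.sequences[chrom]
        res = edlib.align(query, seq, mode="HW", task="locations", k=max_ed)
        if res["editDistance"] < 0:
            continue
        ed = res["editDistance"]
        loc = min(res["locations"], key=lambda t: (t[0], t[1]))
        results.append((ed, chrom, loc[0], loc[1] + 1, strand))
    return results


def align_reads(
    reads: Sequence[ReadRecord],
    index: AlignmentIndex,
    reference: GenotypeReference,
    max_edit_distance: int = 2,
) -> tuple[list[AlignmentHit], list[str]]:
    """Map reads to a reference at a bounded edit distance.

    A read is mapped iff some location on either strand aligns the full read
    semi-globally with Levenshtein distance <= *max_edit_distance*; the
    single best hit is reported (ties broken by lowest (chromosome, start),
    then + strand first). Returns ``(hits, unmapped_read_ids)``; the two
    partition the input.
    """
    if max_edit_distance < 0:
        raise ValueError("max_edit_distance must be >= 0")
    locator = _GeneLocator(reference)
    k = index.k
    chromosomes = index.chromosomes
    hits: list[AlignmentHit] = []
    unmapped: list[str] = []
    lookup = index.lookup
    seqs = reference.sequences

    for read in reads:
        seq = read.sequence
        L = len(seq)
        rc = revcomp(seq)
        best: tuple | None = None

        # exact fast path: all distance-0 placements carry the first k-mer
        if L >= k:
            exact: list[tuple[int, str, int, int, str]] = []
            for query, strand in ((seq, "+"), (rc, "-")):
                probe = query[:k]
                for ci, pos in lookup(probe):
                    chrom = chromosomes[ci]
                    if seqs[chrom][pos : pos + L] == query:
                        exact.append((0, chrom, pos, pos + L, strand))
            if exact:
                best = min(exact, key=lambda t: (t[1], t[2], _STRAND_RANK[t[4]]))

        if best is None:
            offsets = _probe_offsets(L, k, max_edit_distance) if L >= k else []
            candidates: list[tuple[int, str, int, int, str]] = []
            if offsets:
                for query, strand in ((seq, "+"), (rc, "-")):
                    diagonals: dict[int, set[int]] = {}
                    for off in offsets:
                        for ci, pos in lookup(query[off : off + k]):
                            diagonals.setdefault(ci, set()).add(pos - off)
                    if diagonals:
                        candidates.extend(
                            _verify_candidates(
                                query, strand, diagonals, reference,
                                chromosomes, max_edit_distance,
                            )
                        )
            else:
                # read too short for the pigeonhole guarantee: exhaustive scan
                for query, strand in ((seq, "+"), (rc, "-")):
                    candidates.extend(
                        _full_scan(query, strand, reference, max_edit_distance)
                    )
            if candidates:
                best = min(
                    candidates,
                    key=lambda t: (t[0], t[1], t[2], _STRAND_RANK[t[4]]),
                )

        if best is None:
            unmapped.append(read.read_id)
        else:
            ed, chrom, start, end, strand = best
            hits.append(
                AlignmentHit(
                    read_id=read.read_id,
                    genotype_id=reference.genotype_id,
                    chromosome=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    edit_distance=ed,
                    gene_id=locator.locate(chrom, start, end),
                )
            )
    return hits, unmapped


# ---------------------------------------------------------------------------
# Local-alignment cross-check (BLASTN stand-in)

DEFAULT_WORD_SIZE = 11
DEFAULT_MIN_ALIGNED_FRACTION = 0.5
DEFAULT_MIN_IDENTITY = 80.0
_MAX_WINDOWS = 30


def _make_local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


class LocalAligner:
    """Seeded local-alignment search against one genotype reference.

    Word hits (default word size 11) nominate diagonals; the best-supported
    windows are aligned locally with BLASTN scoring and the best alignment
    is tested against the coverage and identity thresholds.
    """

    def __init__(
        self,
        reference: GenotypeReference,
        word_size: int = DEFAULT_WORD_SIZE,
        min_aligned_fraction: float = DEFAULT_MIN_ALIGNED_FRACTION,
        min_identity: float = DEFAULT_MIN_IDENTITY,
    ) -> None:
        self.reference = reference
        self.word_size = word_size
        self.min_aligned_fraction = min_aligned_fraction
        self.min_identity = min_identity
        self._aligner = _make_local_aligner()
        self._words: dict[str, object] = {}
        self._chroms: list[str] = []
        w = word_size
        for chrom in sorted(reference.sequences):
            seq = reference.sequences[chrom]
            ci = len(self._chroms)
            self._chroms.append(chrom)
            table = self._words
            for pos in range(len(seq) - w + 1):
                word = seq[pos : pos + w]
                entry = table.get(word)
                if entry is None:
                    table[word] = (ci, pos)
                elif isinstance(entry, tuple):
                    table[word] = [entry, (ci, pos)]
                else:
                    entry.append((ci, pos))

    def _word_hits(self, word: str) -> list[tuple[int, int]]:
        entry = self._words.get(word)
        if entry is None:
            return []
        return [entry] if isinstance(entry, tuple) else entry

    def search(self, read: ReadRecord) -> LocalSearchHit | None:
        w = self.word_size
        L = len(read.sequence)
        if L < w:
            return None
        margin = max(20, L // 3)
        # phase 1: score-only over seeded windows, both strands
        best_score = 0.0
        best_window: str | None = None
        best_query: str | None = None
        for query in (read.sequence, revcomp(read.sequence)):
            # seed: count word hits per (chromosome, binned diagonal)
            support: dict[tuple[int, int], int] = {}
            step = max(1, w // 2)
            for off in range(0, L - w + 1, step):
                for ci, pos in self._word_hits(query[off : off + w]):
                    key = (ci, (pos - off) // margin)
                    support[key] = support.get(key, 0) + 1
            if not support:
                continue
            ranked = sorted(support.items(), key=lambda kv: (-kv[1], kv[0]))
            for (ci, dbin), _count in ranked[:_MAX_WINDOWS]:
                chrom = self._chroms[ci]
                seq = self.reference.sequences[chrom]
                wstart = max(0, dbin * margin - margin)
                wend = min(len(seq), (dbin + 1) * margin + L + margin)
                window = seq[wstart:wend]
                score = float(self._aligner.score(window, query))
                if score > best_score:
                    best_score, best_window, best_query = score, window, query
        if best_window is None or best_score <= 0:
            return None
        # phase 2: one full alignment of the best window for coverage/identity
        try:
            aln = self._aligner.align(best_window, best_query)[0]
        except IndexError:
            return None
        counts = aln.counts()
        columns = counts.identities + counts.mismatches + counts.gaps
        if columns == 0:
            return None
        identity = 100.0 * counts.identities / columns
        qranges = aln.aligned[1]
        cov = int(qranges[-1][1] - qranges[0][0]) / L
        if cov >= self.min_aligned_fraction and identity >= self.min_identity:
            return LocalSearchHit(
                read_id=read.read_id,
                genotype_id=self.reference.genotype_id,
                score=best_score,
                aligned_fraction=cov,
                identity=identity,
            )
        return None


def _cached_local_aligner(reference: GenotypeReference, **kwargs) -> LocalAligner:
    cache = getattr(reference, "_local_aligner_cache", None)
    key = tuple(sorted(kwargs.items()))
    if cache is None:
        cache = {}
        object.__setattr__(reference, "_local_aligner_cache", cache)
    if key not in cache:
        cache[key] = LocalAligner(reference, **kwargs)
    return cache[key]


def local_search(
    read: ReadRecord,
    reference_a: GenotypeReference,
    reference_b: GenotypeReference,
    word_size: int = DEFAULT_WORD_SIZE,
    min_aligned_fraction: float = DEFAULT_MIN_ALIGNED_FRACTION,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> tuple[LocalSearchHit | None, LocalSearchHit | None]:
    """Cross-check one read against two genotype references.

    Returns a hit per reference, or None where the best local alignment
    fails the coverage/identity criterion. Seed indexes are cached on the
    reference objects, so repeated calls are cheap.
    """
    kwargs = dict(
        word_size=word_size,
        min_aligned_fraction=min_aligned_fraction,
        min_identity=min_identity,
    )
    hit_a = _cached_local_aligner(reference_a, **kwargs).search(read)
    hit_b = _cached_local_aligner(reference_b, **kwargs).search(read)
    return hit_a, hit_b
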