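"""Bounded-edit-distance aligner vs an independent dynamic-programming oracle,
plus the local-alignment cross-check."""

import numpy as np
import pytest

from graftmob.align import (
    LocalAligner,
    align_reads,
    build_index,
    local_search,
)
from graftmob.io import GenotypeReference, revcomp

from .conftest import make_read, mutate, random_sequence


def semiglobal_distance(query: str, ref: str) -> int:
    """Brute-force semi-global Levenshtein: query fully consumed, reference
    local. Row-wise DP with a prefix-min pass for the horizontal moves —
    independent of the aligner under test."""
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    r = np.frombuffer(ref.encode(), dtype=np.uint8)
    n = len(r)
    ar = np.arange(n + 1)
    prev = np.zeros(n + 1, dtype=np.int32)
    for i in range(1, len(q) + 1):
        cost = (q[i - 1] != r).astype(np.int32)
        cand = np.empty(n + 1, dtype=np.int32)
        cand[0] = i
        cand[1:] = np.minimum(prev[1:] + 1, prev[:-1] + cost)
        prev = np.minimum.accumulate(cand - ar) + ar
    return int(prev.min())


def oracle_min_distance(query: str, reference: GenotypeReference) -> int:
    return min(
        min(semiglobal_distance(q, seq) for seq in reference.sequences.values())
        for q in (query, revcomp(query))
    )


class TestIndex:
    def test_forward_kmer_count(self):
        ref = GenotypeReference("g", {"c1": "ACGTACGTACGTACGTACGTACGTA"})  # 25 nt
        idx = build_index(ref, k=21)
        assert idx.n_positions() == 5  # 25 - 21 + 1

    def test_identical_references_identical_index(self, rng):
        seq = random_sequence(rng, 300)
        a = build_index(GenotypeReference("g", {"c1": seq}), 21)
        b = build_index(GenotypeReference("g", {"c1": seq}), 21)
        assert a.serialize() == b.serialize()

    def test_k_longer_than_sequence_raises(self):
        ref = GenotypeReference("g", {"c1": "ACGTACGT"})
        with pytest.raises(ValueError):
            build_index(ref, 21)


class TestAlignReads:
    def test_exact_substring_maps_at_zero(self, small_reference):
        read = make_read(small_reference.sequences["c1"][600:750])
        hits, unmapped = align_reads([read], build_index(small_reference), small_reference, 2)
        assert not unmapped
        (h,) = hits
        assert (h.start, h.end, h.edit_distance, h.strand) == (600, 750, 0, "+")
        assert h.gene_id == "gA"

    def test_three_substitutions_unmapped_at_two(self, small_reference, rng):
        seq = mutate(rng, small_reference.sequences["c1"][100:250], n_sub=3)
        # ensure the mutations did not cancel: oracle distance is 3
        assert oracle_min_distance(seq, small_reference) == 3
        hits, unmapped = align_reads(
            [make_read(seq)], build_index(small_reference), small_reference, 2
        )
        assert not hits and unmapped == ["r0"]

    def test_reverse_strand_hit(self, small_reference):
        read = make_read(revcomp(small_reference.sequences["c1"][2600:2750]))
        (h,), _ = align_reads([read], build_index(small_reference), small_reference, 2)
        assert (h.start, h.strand, h.gene_id) == (2600, "-", "gB")

    def _random_instances(self, rng, n_cases, ref_len=5000, multi_chrom=False):
        seqs = {"c1": random_sequence(rng, ref_len)}
        if multi_chrom:
            seqs["c2"] = random_sequence(rng, ref_len // 2)
        ref = GenotypeReference("g", seqs)
        reads = []
        chrom_names = list(seqs)
        for i in range(n_cases):
            kind = i % 5
            chrom = seqs[chrom_names[i % len(chrom_names)]]
            L = int(rng.integers(60, 151))
            start = int(rng.integers(0, len(chrom) - L))
            base = chrom[start : start + L]
            if kind == 0:
                seq = base
            elif kind == 1:
                seq = mutate(rng, base, n_sub=int(rng.integers(1, 4)))
            elif kind == 2:
                seq = mutate(rng, base, n_sub=int(rng.integers(0, 2)),
                             n_indel=int(rng.integers(1, 3)))
            elif kind == 3:
                seq = revcomp(mutate(rng, base, n_sub=int(rng.integers(0, 3))))
            else:
                seq = random_sequence(rng, L)
            reads.append(make_read(seq, f"r{i}"))
        return ref, reads

    def test_matches_dp_oracle_on_random_instances(self, rng):
        """Reported minimal edit distances equal the brute-force scan."""
        ref, reads = self._random_instances(rng, 150, multi_chrom=True)
        idx = build_index(ref)
        for k in (1, 2):
            hits, unmapped = align_reads(reads, idx, ref, k)
            by_id = {h.read_id: h for h in hits}
            assert len(hits) + len(unmapped) == len(reads)
            for read in reads:
                expected = oracle_min_distance(read.sequence, ref)
                if expected <= k:
                    assert by_id[read.read_id].edit_distance == expected, read.read_id
                else:
                    assert read.read_id in unmapped

    def test_mapped_set_monotone_in_edit_cap(self, rng):
        ref, reads = self._random_instances(rng, 100)
        idx = build_index(ref)
        mapped = {}
        for k in (0, 1, 2):
            hits, _ = align_reads(reads, idx, ref, k)
            mapped[k] = {h.read_id for h in hits}
        assert mapped[0] <= mapped[1] <= mapped[2]

    def test_strand_symmetry(self, rng):
        """Reverse-complementing every read leaves the partition unchanged."""
        ref, reads = self._random_instances(rng, 60)
        idx = build_index(ref)
        flipped = [make_read(revcomp(r.sequence), r.read_id) for r in reads]
        hits_f, un_f = align_reads(reads, idx, ref, 2)
        hits_r, un_r = align_reads(flipped, idx, ref, 2)
        assert {h.read_id for h in hits_f} == {h.read_id for h in hits_r}
        assert set(un_f) == set(un_r)
        for a, b in zip(sorted(hits_f, key=lambda h: h.read_id),
                        sorted(hits_r, key=lambda h: h.read_id)):
            assert a.edit_distance == b.edit_distance


class TestLocalSearch:
    def test_verbatim_read_hits_only_its_source(self, rng):
        a = GenotypeReference("ga", {"c1": random_sequence(rng, 8000)})
        b = GenotypeReference("gb", {"c1": random_sequence(rng, 8000)})
        read = make_read(a.sequences["c1"][3000:3150])
        hit_a, hit_b = local_search(read, a, b)
        assert hit_a is not None and hit_a.identity == 100.0
        assert hit_a.aligned_fraction == 1.0
        assert hit_b is None

    def test_conserved_region_hits_both(self, rng):
        shared = random_sequence(rng, 1000)
        a = GenotypeReference("ga", {"c1": random_sequence(rng, 3000) + shared})
        b = GenotypeReference("gb", {"c1": shared + random_sequence(rng, 3000)})
        read = make_read(shared[400:550])
        hit_a, hit_b = local_search(read, a, b)
        assert hit_a is not None and hit_b is not None
        assert hit_a.score == hit_b.score

    def test_random_reads_rarely_hit(self, rng):
        """Empirical false-hit rate for random reads is far below 1e-3."""
        ref = GenotypeReference("g", {"c1": random_sequence(rng, 100_000)})
        aligner = LocalAligner(ref)
        hits = sum(
            aligner.search(make_read(random_sequence(rng, 150), f"r{i}")) is not None
            for i in range(2000)
        )
        assert hits == 0

    def test_diverged_ortholog_hits_with_lower_identity(self, rng):
        src = random_sequence(rng, 5000)
        a = GenotypeReference("ga", {"c1": src})
        read_seq = mutate(rng, src[1000:1150], n_sub=8)  # ~5% diverged
        hit = LocalAligner(a).search(make_read(read_seq))
        assert hit is not None
        assert 90.0 < hit.identity < 100.0
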