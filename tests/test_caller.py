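"""Read-set algebra, replicate consensus, and the source-expression filter."""

import numpy as np
import pandas as pd
import pytest

from graftmob.caller import (
    ClassifiedReadSets,
    MobileCall,
    PipelineParams,
    call_mobile_genes,
    classify_sample_reads,
    direction_for_tissue,
)
from graftmob.io import GeneModel, GenotypeReference, ValidationError, revcomp

from .conftest import make_read, mutate, random_sequence


def _two_genotypes(rng, shared_block: bool = False):
    """A native/foreign reference pair diverged ~5%, one gene each."""
    native_seq = random_sequence(rng, 6000)
    foreign_seq = mutate(rng, native_seq, n_sub=300)
    if shared_block:
        foreign_seq = foreign_seq[:3000] + native_seq[3000:4000] + foreign_seq[4000:]
    native = GenotypeReference(
        "nat", {"c1": native_seq}, [GeneModel("NG1", "c1", 500, 2000, "+", 1500)]
    )
    foreign = GenotypeReference(
        "for", {"c1": foreign_seq}, [GeneModel("FG1", "c1", 500, 2000, "+", 1500)]
    )
    return native, foreign


def _support_sets(per_rep_support: list[dict[str, int]], tissue="RR") -> list[ClassifiedReadSets]:
    direction = direction_for_tissue(tissue)
    return [
        ClassifiedReadSets(
            sample_id=f"s{i}", direction=direction, mapped_native=[], unmapped=[],
            candidate_mobile=[], false_positive=[], discarded=[], retained=[],
            gene_support=sup,
        )
        for i, sup in enumerate(per_rep_support)
    ]


def _source(genes: dict[str, list[int]]) -> pd.DataFrame:
    return pd.DataFrame(genes, index=["rep1", "rep2", "rep3"]).T


class TestClassifySampleReads:
    def test_all_native_sample_has_no_candidates(self, rng):
        native, foreign = _two_genotypes(rng)
        reads = [
            make_read(native.sequences["c1"][i * 40 : i * 40 + 150], f"r{i}")
            for i in range(80)
        ]
        sets = classify_sample_reads(reads, native, foreign, PipelineParams(), tissue="RR")
        assert len(sets.mapped_native) == 80
        assert not sets.candidate_mobile and not sets.false_positive
        assert sets.gene_support == {}

    def test_spiked_foreign_reads_recover_their_gene(self, rng):
        native, foreign = _two_genotypes(rng)
        reads = [
            make_read(native.sequences["c1"][i * 50 : i * 50 + 150], f"n{i}")
            for i in range(40)
        ]
        # 100 foreign reads from the foreign gene
        gseq = foreign.gene_sequence("FG1")
        spikes = [
            make_read(gseq[(i * 13) % (len(gseq) - 150) :][:150], f"f{i}")
            for i in range(100)
        ]
        sets = classify_sample_reads(
            reads + spikes, native, foreign, PipelineParams(), tissue="RR"
        )
        assert set(sets.gene_support) == {"FG1"}
        assert sets.gene_support["FG1"] >= 95  # nearly all spikes retained
        assert set(sets.candidate_mobile) >= {h.read_id for h in sets.retained}

    def test_ambiguous_read_from_shared_segment_is_false_positive(self, rng):
        """A read from a segment identical in both genotypes, pushed past the
        first-pass cap by 3 errors, matches both references equally well and
        is conservatively assigned to the native genome."""
        native, foreign = _two_genotypes(rng, shared_block=True)
        seq = mutate(rng, native.sequences["c1"][3300:3450], n_sub=3)
        from .test_align import oracle_min_distance
        assert oracle_min_distance(seq, native) == 3
        sets = classify_sample_reads(
            [make_read(seq)], native, foreign, PipelineParams(), tissue="RR"
        )
        assert sets.false_positive == ["r0"]
        assert not sets.candidate_mobile

    def test_partition_identity(self, tiny_result):
        """mapped + candidate + false-positive + discarded = QC-passed reads,
        for every sample of the simulated experiment."""
        for sid, sets in tiny_result.classified.items():
            total = len(sets.mapped_native) + len(sets.candidate_mobile) + len(
                sets.false_positive
            ) + len(sets.discarded)
            assert total == len(sets.mapped_native) + len(sets.unmapped), sid
            assert not set(sets.candidate_mobile) & set(sets.false_positive)
            assert {h.read_id for h in sets.retained} <= set(sets.candidate_mobile)

    def test_unknown_tissue_rejected(self, rng):
        native, foreign = _two_genotypes(rng)
        with pytest.raises(ValidationError):
            classify_sample_reads([], native, foreign, PipelineParams(), tissue="XX")


class TestCallMobileGenes:
    PARAMS = PipelineParams()

    def _call(self, per_rep, source, **kw):
        return call_mobile_genes(
            _support_sets(per_rep), source, self.PARAMS,
            tissue=kw.get("tissue", "RR"), condition="CK", source_genotype="scion",
        )

    def test_two_of_three_replicates_called(self):
        calls = self._call(
            [{"g1": 5}, {"g1": 3}, {}], _source({"g1": [10, 10, 10]})
        )
        assert [c.gene_id for c in calls] == ["g1"]
        assert calls[0].replicate_support == 2
        assert calls[0].counts == (5, 3, 0)

    def test_single_replicate_not_called(self):
        calls = self._call([{}, {}, {"g1": 50}], _source({"g1": [10, 10, 10]}))
        assert calls == []

    def test_source_silent_gene_excluded(self):
        calls = self._call(
            [{"g1": 5}, {"g1": 5}, {"g1": 5}], _source({"g1": [0, 0, 0]})
        )
        assert calls == []

    def test_source_expression_needs_two_replicates(self):
        calls = self._call(
            [{"g1": 5}, {"g1": 5}, {"g1": 5}], _source({"g1": [9, 4, 0]})
        )
        assert calls == []
        calls = self._call(
            [{"g1": 5}, {"g1": 5}, {"g1": 5}], _source({"g1": [9, 5, 0]})
        )
        assert len(calls) == 1

    def test_below_read_floor_does_not_support(self):
        calls = self._call(
            [{"g1": 1}, {"g1": 1}, {"g1": 1}], _source({"g1": [10, 10, 10]})
        )
        assert calls == []

    def test_missing_source_table_is_an_error(self):
        with pytest.raises(ValidationError):
            call_mobile_genes(
                _support_sets([{}]), None, self.PARAMS,
                tissue="RR", condition="CK", source_genotype="scion",
            )

    def test_threshold_monotonicity(self, rng):
        """Raising min_reads_per_gene or min_replicates never adds a call."""
        genes = [f"g{i}" for i in range(20)]
        per_rep = [
            {g: int(rng.integers(0, 6)) for g in genes} for _ in range(3)
        ]
        source = _source({g: [10, 10, 10] for g in genes})

        def called(min_reads, min_reps):
            params = PipelineParams(
                min_reads_per_gene=min_reads, min_replicates=min_reps
            )
            return {
                c.gene_id
                for c in call_mobile_genes(
                    _support_sets(per_rep), source, params,
                    tissue="RR", condition="CK", source_genotype="scion",
                )
            }

        for mr in (1, 2, 3):
            for reps in (1, 2):
                assert called(mr + 1, reps) <= called(mr, reps)
                assert called(mr, reps + 1) <= called(mr, reps)

    def test_direction_tissue_consistency_enforced(self):
        with pytest.raises(ValidationError):
            MobileCall("g1", "scion", "down", "HL", "CK", 2, (5, 5, 0))


class TestRecoveryOnSimulatedData:
    def test_ground_truth_recovered(self, tiny_sim, tiny_result):
        """Calls on the shared small simulation recover the spiked genes with
        perfect precision and high sensitivity."""
        from graftmob.pipeline import recovery_metrics

        m = recovery_metrics(tiny_result.calls, tiny_sim)
        assert m["precision"] == 1.0
        assert m["sensitivity"] >= 0.9
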