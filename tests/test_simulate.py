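"""Simulator properties: divergence statistics, profile normalization,
ground-truth consistency, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import edlib

from graftmob.io import read_fastq
from graftmob.simulate import (
    ParameterError,
    SimulationParams,
    build_base_reference,
    diverge_genome,
    generate_dataset,
    sample_expression,
    _partition_counts,
)


class TestDivergeGenome:
    def test_zero_divergence_is_identity(self, small_reference):
        div, variants = diverge_genome(small_reference, 0.0, 0.0, seed=5)
        assert div.sequences == small_reference.sequences
        assert variants.empty

    def test_substitution_count_matches_binomial(self):
        """Substitutions on a 100 kb genome at rate 0.05 stay within 3 sd of
        the binomial expectation."""
        params = SimulationParams(
            seed=3, n_genes_per_genotype=70, gene_length_range=(1300, 1500)
        )
        base = build_base_reference(params)
        n = base.total_length()
        assert n > 90_000
        _, variants = diverge_genome(base, 0.05, 0.0, seed=7)
        n_sub = int((variants["type"] == "sub").sum())
        mean, sd = 0.05 * n, np.sqrt(n * 0.05 * 0.95)
        assert abs(n_sub - mean) < 3 * sd

    def test_same_seed_reproduces(self, small_reference):
        a, va = diverge_genome(small_reference, 0.05, 0.002, seed=9)
        b, vb = diverge_genome(small_reference, 0.05, 0.002, seed=9)
        assert a.sequences == b.sequences
        pd.testing.assert_frame_equal(va, vb)

    def test_gene_models_lift_over(self, small_reference):
        div, _ = diverge_genome(small_reference, 0.03, 0.005, seed=2)
        assert len(div.genes) == len(small_reference.genes)
        for old, new in zip(small_reference.genes, div.genes):
            assert abs(new.length - old.length) <= 0.02 * old.length
            # lifted gene sequence stays close to its ortholog
            d = edlib.align(
                small_reference.gene_sequence(old), div.gene_sequence(new)
            )["editDistance"]
            assert d < 0.08 * old.length

    def test_excessive_divergence_rejected(self, small_reference):
        with pytest.raises(ParameterError):
            diverge_genome(small_reference, 0.5, 0.0, seed=1)

    def test_foreign_reads_separable_from_native(self):
        """At 5% divergence, few foreign 150-mers sit within edit distance 2
        of the native genome (binomial bound P(X<=2) ~ 1.8%; assert < 3%)."""
        params = SimulationParams(seed=5, n_genes_per_genotype=40)
        base = build_base_reference(params)
        div, _ = diverge_genome(base, 0.05, 0.002, seed=13)
        rng = np.random.default_rng(99)
        native = base.sequences
        n_close = 0
        n_total = 400
        chroms = list(div.sequences)
        for _ in range(n_total):
            c = chroms[rng.integers(len(chroms))]
            seq = div.sequences[c]
            s = int(rng.integers(0, len(seq) - 150))
            kmer = seq[s : s + 150]
            best = min(
                edlib.align(kmer, native[cc], mode="HW", k=2)["editDistance"]
                for cc in native
            )
            if best >= 0:
                n_close += 1
        assert n_close / n_total < 0.03


class TestSampleExpression:
    def test_normalizes_to_one_million(self, small_reference):
        e = sample_expression(small_reference.genes, "CK", "HL", seed=1)
        assert e.sum() == pytest.approx(1e6, rel=1e-6)

    def test_single_gene_gets_everything(self, small_reference):
        e = sample_expression(small_reference.genes[:1], "CK", "RR", seed=1)
        assert e.iloc[0] == pytest.approx(1e6)

    def test_deterministic_per_key(self, small_reference):
        a = sample_expression(small_reference.genes, "drought", "RL", seed=4)
        b = sample_expression(small_reference.genes, "drought", "RL", seed=4)
        c = sample_expression(small_reference.genes, "CK", "RL", seed=4)
        pd.testing.assert_series_equal(a, b)
        assert not np.allclose(a.to_numpy(), c.to_numpy())


class TestPartition:
    def test_worked_example(self):
        # 100 downward genes at 0.3/0.3 -> 30 RL-direct, 30 RR-only, 40 both
        assert _partition_counts(100, 0.3, 0.3) == (30, 30, 40)

    @pytest.mark.parametrize("n,f_rl,f_deg", [(0, 0.3, 0.3), (7, 0.5, 0.5), (30, 0.34, 0.33)])
    def test_counts_sum_and_stay_nonnegative(self, n, f_rl, f_deg):
        a, b, c = _partition_counts(n, f_rl, f_deg)
        assert a + b + c == n and min(a, b, c) >= 0


class TestGenerateDataset:
    def test_zero_mobile_fractions_yield_empty_truth(self, tmp_path):
        params = SimulationParams(
            seed=2, n_genes_per_genotype=30, fragments_per_sample=300,
            mobile_down_fraction=0.0, mobile_up_fraction=0.0,
        )
        sim = generate_dataset(params, tmp_path)
        assert sim.ground_truth.empty
        # no read in any sink sample derives from a foreign transcript
        for row in sim.sample_sheet.samples():
            native_prefix = "SLg" if row["tissue"] == "HL" else "SPg"
            reads = read_fastq(tmp_path / row["fastq1"], row["sample_id"], 1)
            assert all(r.read_id.split(":")[2].split("/")[0].startswith(native_prefix)
                       for r in reads)

    def test_truth_matches_spiked_reads(self, tiny_sim):
        """Every mobile gene contributes reads to exactly its sink samples."""
        truth = tiny_sim.ground_truth.set_index("gene_id")
        for row in tiny_sim.sample_sheet.samples():
            reads = read_fastq(
                tiny_sim.outdir / row["fastq1"], row["sample_id"], 1
            )
            foreign_genes = {
                r.read_id.split(":")[2].split("/")[0]
                for r in reads
                if not r.read_id.split(":")[2].startswith(
                    "SLg" if row["tissue"] == "HL" else "SPg"
                )
            }
            for g in foreign_genes:
                t = truth.loc[g]
                assert row["tissue"] in t.sink_tissues.split(",")
                assert row["condition"] in t.conditions.split(",")

    def test_spiked_read_counts_track_sink_abundance(self, tiny_sim):
        """Realized foreign read counts agree with the multinomial model
        (chi-square goodness of fit, alpha = 0.01)."""
        truth = tiny_sim.ground_truth
        down = truth[(truth.direction == "down") & truth.conditions.str.contains("CK")]
        spiked = down[down.sink_tissues.str.contains("RR")]
        if len(spiked) < 3:
            pytest.skip("too few spiked genes in this configuration")
        genes_len = {
            g.gene_id: g.exon_length for g in tiny_sim.scion.genes
        }
        row = tiny_sim.sample_sheet.group("RR", "CK").iloc[0]
        reads = read_fastq(tiny_sim.outdir / row["fastq1"], row["sample_id"], 1)
        n_frag = len(reads)
        counts = {g: 0 for g in spiked.gene_id}
        for r in reads:
            g = r.read_id.split(":")[2].split("/")[0]
            if g in counts:
                counts[g] += 1
        native_weight = sum(
            tiny_sim.expression[("CK", "RR")][g.gene_id] * g.exon_length
            for g in tiny_sim.rootstock.genes
        )
        spike_all = truth[truth.sink_tissues.str.contains("RR")
                          & truth.conditions.str.contains("CK")]
        total_weight = native_weight + sum(
            r.sink_tpm * genes_len.get(r.gene_id, 0)
            for r in spike_all.itertuples() if r.direction == "down"
        )
        expected = np.array(
            [r.sink_tpm * genes_len[r.gene_id] / total_weight * n_frag
             for r in spiked.itertuples()]
        )
        observed = np.array([counts[g] for g in spiked.gene_id])
        rest_obs = n_frag - observed.sum()
        rest_exp = n_frag - expected.sum()
        chi2 = ((observed - expected) ** 2 / expected).sum() + (
            (rest_obs - rest_exp) ** 2 / rest_exp
        )
        p = stats.chi2.sf(chi2, df=len(observed))
        assert p > 0.01

    def test_same_seed_same_bytes(self, tmp_path):
        params = SimulationParams(seed=8, n_genes_per_genotype=30,
                                  fragments_per_sample=400)
        a = generate_dataset(params, tmp_path / "a")
        b = generate_dataset(params, tmp_path / "b")
        for rel in ["scion.fasta", "rootstock.fasta", "ground_truth.tsv",
                    "variants.tsv", "sample_sheet.tsv", "reads/CKHL1_1.fastq",
                    "reads/DRR3_2.fastq"]:
            assert (a.outdir / rel).read_bytes() == (b.outdir / rel).read_bytes(), rel

    def test_inconsistent_fractions_rejected_before_writing(self, tmp_path):
        with pytest.raises(ParameterError):
            SimulationParams(rl_direct_fraction=0.7, degradation_fraction=0.7)

    def test_read_length_must_fit_genes(self):
        with pytest.raises(ParameterError):
            SimulationParams(read_length=900, gene_length_range=(800, 1600))
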