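"""Synthetic heterograft experiment generator.

Emulates the two-genotype graft design end to end: a cultivated-tomato-like
scion genome, a wild-relative rootstock genome derived from it by i.i.d.
substitutions (plus optional short indels), tissue expression profiles for
the three sampled tissues (HL scion leaf, RR rootstock root, RL rootstock
lateral-branch leaf) under control (CK) and drought, and paired-end reads
for every tissue x condition x replicate sample with mobile transcripts
spiked across the graft junction.

Downward mobile genes (scion genotype, detected in rootstock tissues) are
partitioned into the three transport classes the sampled design can
distinguish: deposited in RL without passing the root (rl_direct), detected
in the root only, i.e. degraded or diluted before reaching RL (rr_only),
and moving through the root to the leaf (through_root). Upward mobile genes
(rootstock genotype) sink in HL.

All randomness flows from one master seed through named sub-streams, so
adding a stage never perturbs earlier streams and a fixed seed gives
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CONDITIONS,
    GeneModel,
    GenotypeReference,
    SampleSheet,
    TISSUES,
    revcomp,
    write_fasta,
    write_fastq,
    write_gff3,
    write_sample_sheet,
    ReadRecord,
)

SCION = "scion"
ROOTSTOCK = "rootstock"

_TISSUE_CODE = {t: i for i, t in enumerate(TISSUES)}
_COND_CODE = {c: i for i, c in enumerate(CONDITIONS)}
_COND_LABEL = {"CK": "CK", "drought": "D"}

# named sub-streams of the master seed
_STREAM_GENOME = 1
_STREAM_DIVERGE = 2
_STREAM_MOBILE = 3
_STREAM_READS = 4

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ParameterError(ValueError):
    """Raised for inconsistent simulation parameters."""


class GenomeDivergenceError(ValueError):
    """Raised when divergence destroys a gene coordinate mapping."""


def _substream_seed(seed: int, stream: int, *tags: int) -> int:
    """Derive an independent 31-bit sub-seed from the master seed."""
    rng = np.random.default_rng([seed, stream, *tags])
    return int(rng.integers(2**31))


@dataclass
class SimulationParams:
    """Study-design parameters for the synthetic heterograft experiment.

    Abundances are on the TPM scale of the simulated transcriptome
    (``n_genes_per_genotype`` genes normalized to 1e6); see the methods
    note for how the default mobile abundance range maps onto the
    low-abundance regime of a full-size transcriptome.
    """

    seed: int = 1
    n_genes_per_genotype: int = 300
    gene_length_range: tuple[int, int] = (800, 1600)
    n_chromosomes: int = 3
    intergenic_length: int = 150
    divergence: float = 0.05
    indel_rate: float = 0.002
    max_indel_length: int = 3
    read_length: int = 150
    fragment_length_mean: float = 320.0
    fragment_length_sd: float = 40.0
    fragments_per_sample: int = 30000
    error_rate: float = 0.001
    n_replicates: int = 3
    mobile_down_fraction: float = 0.10
    mobile_up_fraction: float = 1 / 30
    drought_specific_fraction: float = 0.25
    mobile_abundance_range: tuple[float, float] = (200.0, 5000.0)
    rl_direct_fraction: float = 0.34
    degradation_fraction: float = 0.33
    min_source_tpm: float = 500.0
    expression_sigma: float = 1.2

    def __post_init__(self) -> None:
        for name in (
            "divergence",
            "indel_rate",
            "error_rate",
            "mobile_down_fraction",
            "mobile_up_fraction",
            "drought_specific_fraction",
            "rl_direct_fraction",
            "degradation_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.rl_direct_fraction + self.degradation_fraction > 1.0 + 1e-12:
            raise ParameterError(
                "rl_direct_fraction + degradation_fraction must be <= 1"
            )
        if self.read_length > self.gene_length_range[0]:
            raise ParameterError("read_length must not exceed the minimum gene length")
        if self.gene_length_range[0] > self.gene_length_range[1]:
            raise ParameterError("gene_length_range must be (lo, hi) with lo <= hi")
        if self.mobile_abundance_range[0] <= 0:
            raise ParameterError("mobile_abundance_range must be positive")
        if self.n_replicates < 1 or self.fragments_per_sample < 1:
            raise ParameterError("n_replicates and fragments_per_sample must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gene_length_range"] = list(self.gene_length_range)
        d["mobile_abundance_range"] = list(self.mobile_abundance_range)
        return d


# ---------------------------------------------------------------------------
# Genome construction and divergence


def build_base_reference(params: SimulationParams, genotype_id: str = SCION) -> GenotypeReference:
    """Random base genome: genes separated by intergenic spacers."""
    rng = np.random.default_rng([params.seed, _STREAM_GENOME])
    n_chrom = params.n_chromosomes
    per_chrom = [params.n_genes_per_genotype // n_chrom] * n_chrom
    for i in range(params.n_genes_per_genotype % n_chrom):
        per_chrom[i] += 1
    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    gene_no = 0
    lo, hi = params.gene_length_range
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        parts: list[np.ndarray] = []
        pos = 0
        spacer0 = int(rng.integers(params.intergenic_length, 2 * params.intergenic_length))
        parts.append(_BASES[rng.integers(0, 4, spacer0)])
        pos += spacer0
        for _ in range(per_chrom[ci]):
            gene_no += 1
            glen = int(rng.integers(lo, hi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            parts.append(_BASES[rng.integers(0, 4, glen)])
            genes.append(
                GeneModel(
                    gene_id=f"SLg{gene_no:04d}",
                    chromosome=chrom,
                    start=pos,
                    end=pos + glen,
                    strand=strand,
                    exon_length=glen,
                )
            )
            pos += glen
            spacer = int(rng.integers(params.intergenic_length, 2 * params.intergenic_length))
            parts.append(_BASES[rng.integers(0, 4, spacer)])
            pos += spacer
        sequences[chrom] = np.concatenate(parts).tobytes().decode("ascii")
    return GenotypeReference(genotype_id, sequences, genes)


def _lift_gene_id(gene_id: str) -> str:
    return "SPg" + gene_id[3:] if gene_id.startswith("SLg") else gene_id + "_div"


def diverge_genome(
    base: GenotypeReference,
    divergence: float,
    indel_rate: float,
    seed: int,
    max_indel_length: int = 3,
    genotype_id: str = ROOTSTOCK,
) -> tuple[GenotypeReference, pd.DataFrame]:
    """Derive a second genotype by i.i.d. substitutions and short indels.

    Gene models are lifted over (ids re-prefixed so the two genotypes never
    share a gene id) and every applied difference is listed in the returned
    variant table (0-based coordinates on the *base* genome). Indel events
    whose span would cover a gene start or end are dropped rather than
    applied, so coordinate liftover is always well defined; if a liftover
    nevertheless fails, a :class:`GenomeDivergenceError` names the genes.
    """
    if not 0.0 <= divergence <= 0.2:
        raise ParameterError(f"divergence must be in [0, 0.2], got {divergence}")
    rng = np.random.default_rng(seed)
    code = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code[b] = i

    new_sequences: dict[str, str] = {}
    new_genes: list[GeneModel] = []
    variants: list[tuple] = []
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in base.genes:
        genes_by_chrom.setdefault(g.chromosome, []).append(g)

    for chrom, seq in base.sequences.items():
        arr = code[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()
        n = len(arr)
        # substitutions
        sub_pos = np.nonzero(rng.random(n) < divergence)[0]
        if sub_pos.size:
            shift = rng.integers(1, 4, sub_pos.size)
            old = arr[sub_pos].copy()
            arr[sub_pos] = (old + shift) % 4
            for p, o, a in zip(sub_pos, old, arr[sub_pos]):
                variants.append((chrom, int(p), "sub", "ACGT"[o], "ACGT"[a]))
        # indel events, skipping any that would cover a gene boundary
        boundaries = np.array(
            sorted(
                {g.start for g in genes_by_chrom.get(chrom, [])}
                | {g.end for g in genes_by_chrom.get(chrom, [])}
            ),
            dtype=np.int64,
        )
        events: list[tuple[int, str, int, str]] = []  # (pos, type, length, inserted)
        if indel_rate > 0:
            cand = np.nonzero(rng.random(n) < indel_rate)[0]
            is_ins = rng.random(cand.size) < 0.5
            lens = rng.integers(1, max_indel_length + 1, cand.size)
            last_end = -1
            for p, ins, ln in zip(cand, is_ins, lens):
                p, ln = int(p), int(ln)
                if p <= last_end:
                    continue  # no overlapping events
                if ins:
                    ins_seq = "".join("ACGT"[b] for b in rng.integers(0, 4, ln))
                    events.append((p, "ins", ln, ins_seq))
                    last_end = p
                else:
                    if p + ln > n:
                        continue
                    span_lo, span_hi = p, p + ln
                    if boundaries.size:
                        j = np.searchsorted(boundaries, span_lo, side="left")
                        if j < boundaries.size and boundaries[j] < span_hi:
                            continue  # would destroy a gene boundary mapping
                    events.append((p, "del", ln, ""))
                    last_end = p + ln - 1

        # assemble mutated sequence and a coordinate-shift table
        pieces: list[str] = []
        shift_pos: list[int] = []
        shift_cum: list[int] = []
        cum = 0
        prev = 0
        mutated = arr  # substitutions applied
        base_str = _BASES[mutated].tobytes().decode("ascii")
        for p, typ, ln, ins_seq in events:
            pieces.append(base_str[prev:p])
            if typ == "ins":
                pieces.append(base_str[p])
                pieces.append(ins_seq)
                variants.append((chrom, p, "ins", base_str[p], base_str[p] + ins_seq))
                cum += ln
                prev = p + 1
                shift_pos.append(p + 1)
            else:
                variants.append((chrom, p, "del", seq[p : p + ln], "-"))
                cum -= ln
                prev = p + ln
                shift_pos.append(p + ln)
            shift_cum.append(cum)
        pieces.append(base_str[prev:])
        new_sequences[chrom] = "".join(pieces)

        sp = np.array(shift_pos, dtype=np.int64)
        sc = np.array(shift_cum, dtype=np.int64)

        def lift(x: int) -> int:
            j = int(np.searchsorted(sp, x, side="right")) - 1
            return x + (int(sc[j]) if j >= 0 else 0)

        bad: list[str] = []
        for g in genes_by_chrom.get(chrom, []):
            ns, ne = lift(g.start), lift(g.end)
            if ns >= ne or ns < 0 or ne > len(new_sequences[chrom]):
                bad.append(g.gene_id)
                continue
            new_genes.append(
                GeneModel(
                    gene_id=_lift_gene_id(g.gene_id),
                    chromosome=chrom,
                    start=ns,
                    end=ne,
                    strand=g.strand,
                    exon_length=ne - ns,
                )
            )
        if bad:
            raise GenomeDivergenceError(
                f"divergence destroyed coordinate mapping for genes: {bad}"
            )

    table = pd.DataFrame(variants, columns=["chrom", "pos", "type", "ref", "alt"])
    table = table.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return GenotypeReference(genotype_id, new_sequences, new_genes), table


# ---------------------------------------------------------------------------
# Expression profiles


def sample_expression(
    genes: list[GeneModel],
    condition: str,
    tissue: str,
    seed: int,
    sigma: float = 1.2,
) -> pd.Series:
    """Log-normal abundance profile normalized to sum 1e6 (TPM scale).

    Deterministic for a given (seed, condition, tissue); the gene set only
    enters through its ids, in order.
    """
    if condition not in _COND_CODE:
        raise ParameterError(f"unknown condition {condition!r}")
    if tissue not in _TISSUE_CODE:
        raise ParameterError(f"unknown tissue {tissue!r}")
    rng = np.random.default_rng(
        [seed, 101, _COND_CODE[condition], _TISSUE_CODE[tissue]]
    )
    x = rng.lognormal(mean=0.0, sigma=sigma, size=len(genes))
    tpm = x / x.sum() * 1e6
    return pd.Series(tpm, index=[g.gene_id for g in genes], name=f"{condition}:{tissue}")


# ---------------------------------------------------------------------------
# Ground truth


GROUND_TRUTH_COLUMNS = [
    "gene_id",
    "origin_genotype",
    "direction",
    "pattern",
    "sink_tissues",
    "conditions",
    "source_tpm",
    "sink_tpm",
]


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size))


@dataclass
class SimulatedDataset:
    """In-memory handle to a generated dataset plus its on-disk layout."""

    outdir: Path
    params: SimulationParams
    scion: GenotypeReference
    rootstock: GenotypeReference
    sample_sheet: SampleSheet
    ground_truth: pd.DataFrame
    variants: pd.DataFrame
    expression: dict[tuple[str, str], pd.Series] = field(default_factory=dict)

    def truth_cells(self) -> set[tuple[str, str, str, str]]:
        """Expected mobile calls as (gene_id, direction, tissue, condition)."""
        cells: set[tuple[str, str, str, str]] = set()
        for row in self.ground_truth.itertuples():
            for t in row.sink_tissues.split(","):
                for c in row.conditions.split(","):
                    cells.add((row.gene_id, row.direction, t, c))
        return cells


def _partition_counts(n: int, rl_fraction: float, deg_fraction: float) -> tuple[int, int, int]:
    """Deterministic rounding of the downward transport-class partition."""
    n_rl = round(rl_fraction * n)
    n_deg = min(round(deg_fraction * n), n - n_rl)
    return n_rl, n_deg, n - n_rl - n_deg


def generate_dataset(params: SimulationParams, outdir: str | Path) -> SimulatedDataset:
    """Generate the full synthetic experiment on disk.

    Writes two reference FASTA/GFF3 pairs, paired FASTQ for every
    tissue x condition x replicate sample, ``sample_sheet.tsv``,
    ``ground_truth.tsv`` and ``variants.tsv``. Reads in each sample are a
    multinomial draw over the native transcripts at the tissue profile
    abundance plus the foreign spiked mobile transcripts at their sink TPM,
    with weights proportional to TPM x transcript length.
    """
    outdir = Path(outdir)
    (outdir / "reads").mkdir(parents=True, exist_ok=True)
    seed = params.seed

    scion = build_base_reference(params, SCION)
    rootstock, variants = diverge_genome(
        scion,
        params.divergence,
        params.indel_rate,
        _substream_seed(seed, _STREAM_DIVERGE),
        max_indel_length=params.max_indel_length,
        genotype_id=ROOTSTOCK,
    )

    expression: dict[tuple[str, str], pd.Series] = {}
    for cond in CONDITIONS:
        expression[(cond, "HL")] = sample_expression(
            scion.genes, cond, "HL", seed, params.expression_sigma
        )
        for tissue in ("RR", "RL"):
            expression[(cond, tissue)] = sample_expression(
                rootstock.genes, cond, tissue, seed, params.expression_sigma
            )

    # --- mobile gene selection -------------------------------------------
    rng_mobile = np.random.default_rng([seed, _STREAM_MOBILE])
    n_genes = params.n_genes_per_genotype
    truth_rows: list[dict] = []

    def _select(eligible: list[str], n: int, what: str) -> list[str]:
        if n == 0:
            return []
        if len(eligible) < n:
            raise ParameterError(
                f"only {len(eligible)} genes pass the source-expression floor "
                f"for {what} mobility; {n} requested"
            )
        return list(rng_mobile.choice(np.array(sorted(eligible)), size=n, replace=False))

    def _conditions(n: int) -> list[str]:
        n_dr = round(params.drought_specific_fraction * n)
        flags = np.zeros(n, dtype=bool)
        if n_dr:
            idx = rng_mobile.choice(n, size=n_dr, replace=False)
            flags[idx] = True
        return ["drought" if f else "CK,drought" for f in flags]

    # downward: scion genes detectable in the source tissue (HL) in both conditions
    n_down = round(params.mobile_down_fraction * n_genes)
    eligible_down = [
        g.gene_id
        for g in scion.genes
        if expression[("CK", "HL")][g.gene_id] >= params.min_source_tpm
        and expression[("drought", "HL")][g.gene_id] >= params.min_source_tpm
    ]
    down_genes = _select(eligible_down, n_down, "downward")
    n_rl, n_deg, n_both = _partition_counts(
        n_down, params.rl_direct_fraction, params.degradation_fraction
    )
    patterns = (["rl_direct"] * n_rl) + (["rr_only"] * n_deg) + (["through_root"] * n_both)
    down_conditions = _conditions(n_down)
    down_tpm = _log_uniform(rng_mobile, *params.mobile_abundance_range, n_down)
    sink_map = {"rl_direct": "RL", "rr_only": "RR", "through_root": "RR,RL"}
    for gid, pat, conds, tpm in zip(down_genes, patterns, down_conditions, down_tpm):
        src = np.mean([expression[(c, "HL")][gid] for c in conds.split(",")])
        truth_rows.append(
            dict(
                gene_id=gid,
                origin_genotype=SCION,
                direction="down",
                pattern=pat,
                sink_tissues=sink_map[pat],
                conditions=conds,
                source_tpm=float(src),
                sink_tpm=float(tpm),
            )
        )

    # upward: rootstock genes detectable in the root (RR) in both conditions
    n_up = round(params.mobile_up_fraction * n_genes)
    eligible_up = [
        g.gene_id
        for g in rootstock.genes
        if expression[("CK", "RR")][g.gene_id] >= params.min_source_tpm
        and expression[("drought", "RR")][g.gene_id] >= params.min_source_tpm
    ]
    up_genes = _select(eligible_up, n_up, "upward")
    up_conditions = _conditions(n_up)
    up_tpm = _log_uniform(rng_mobile, *params.mobile_abundance_range, n_up)
    for gid, conds, tpm in zip(up_genes, up_conditions, up_tpm):
        src = np.mean([expression[(c, "RR")][gid] for c in conds.split(",")])
        truth_rows.append(
            dict(
                gene_id=gid,
                origin_genotype=ROOTSTOCK,
                direction="up",
                pattern="",
                sink_tissues="HL",
                conditions=conds,
                source_tpm=float(src),
                sink_tpm=float(tpm),
            )
        )

    ground_truth = pd.DataFrame(truth_rows, columns=GROUND_TRUTH_COLUMNS)

    # --- read generation --------------------------------------------------
    spikes_by_sample: dict[tuple[str, str], list[tuple[str, GenotypeReference, float]]] = {
        (c, t): [] for c in CONDITIONS for t in TISSUES
    }
    origin_ref = {SCION: scion, ROOTSTOCK: rootstock}
    for row in ground_truth.itertuples():
        for t in row.sink_tissues.split(","):
            for c in row.conditions.split(","):
                spikes_by_sample[(c, t)].append(
                    (row.gene_id, origin_ref[row.origin_genotype], row.sink_tpm)
                )

    sheet_rows = []
    tseq_cache: dict[tuple[str, str], str] = {}

    def transcript_seq(ref: GenotypeReference, gid: str) -> str:
        key = (ref.genotype_id, gid)
        if key not in tseq_cache:
            tseq_cache[key] = ref.gene_sequence(gid)
        return tseq_cache[key]

    for cond in CONDITIONS:
        for tissue in TISSUES:
            native = scion if tissue == "HL" else rootstock
            profile = expression[(cond, tissue)]
            pool: list[tuple[str, GenotypeReference, float]] = [
                (g.gene_id, native, float(profile[g.gene_id])) for g in native.genes
            ]
            pool.extend(spikes_by_sample[(cond, tissue)])
            weights = np.array(
                [tpm * len(transcript_seq(ref, gid)) for gid, ref, tpm in pool]
            )
            p = weights / weights.sum()
            for rep in range(1, params.n_replicates + 1):
                sample_id = f"{_COND_LABEL[cond]}{tissue}{rep}"
                rng = np.random.default_rng(
                    [seed, _STREAM_READS, _COND_CODE[cond], _TISSUE_CODE[tissue], rep]
                )
                r1, r2 = _sample_reads(rng, pool, p, params, sample_id, transcript_seq)
                f1 = outdir / "reads" / f"{sample_id}_1.fastq"
                f2 = outdir / "reads" / f"{sample_id}_2.fastq"
                write_fastq(r1, f1)
                write_fastq(r2, f2)
                # relative paths keep the dataset relocatable and reruns
                # byte-identical across output directories
                sheet_rows.append(
                    dict(
                        sample_id=sample_id,
                        tissue=tissue,
                        condition=cond,
                        replicate=rep,
                        fastq1=str(f1.relative_to(outdir)),
                        fastq2=str(f2.relative_to(outdir)),
                    )
                )

    sheet = SampleSheet(pd.DataFrame(sheet_rows))

    write_fasta(scion, outdir / "scion.fasta")
    write_fasta(rootstock, outdir / "rootstock.fasta")
    write_gff3(scion, outdir / "scion.gff3")
    write_gff3(rootstock, outdir / "rootstock.gff3")
    write_sample_sheet(sheet, outdir / "sample_sheet.tsv")
    ground_truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    variants.to_csv(outdir / "variants.tsv", sep="\t", index=False)

    return SimulatedDataset(
        outdir=outdir,
        params=params,
        scion=scion,
        rootstock=rootstock,
        sample_sheet=sheet,
        ground_truth=ground_truth,
        variants=variants,
        expression=expression,
    )


def _sample_reads(
    rng: np.random.Generator,
    pool: list[tuple[str, GenotypeReference, float]],
    p: np.ndarray,
    params: SimulationParams,
    sample_id: str,
    transcript_seq,
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Draw one replicate's paired-end reads from the transcript pool."""
    rl = params.read_length
    counts = rng.multinomial(params.fragments_per_sample, p)
    reads1: list[ReadRecord] = []
    reads2: list[ReadRecord] = []
    frag_no = 0
    err = params.error_rate
    for (gid, ref, _tpm), cnt in zip(pool, counts):
        if cnt == 0:
            continue
        tseq = transcript_seq(ref, gid)
        tlen = len(tseq)
        flens = np.clip(
            np.rint(rng.normal(params.fragment_length_mean, params.fragment_length_sd, cnt)),
            rl,
            tlen,
        ).astype(np.int64)
        starts = (rng.random(cnt) * (tlen - flens + 1)).astype(np.int64)
        quals = rng.integers(30, 41, size=(cnt, 2, rl)).astype(np.uint8) + 33
        n_errs = rng.binomial(rl, err, size=(cnt, 2))
        for i in range(cnt):
            s, fl = int(starts[i]), int(flens[i])
            seq1 = tseq[s : s + rl]
            seq2 = revcomp(tseq[s + fl - rl : s + fl])
            if n_errs[i, 0]:
                seq1 = _apply_errors(rng, seq1, int(n_errs[i, 0]))
            if n_errs[i, 1]:
                seq2 = _apply_errors(rng, seq2, int(n_errs[i, 1]))
            rid = f"{sample_id}:{frag_no}:{gid}"
            frag_no += 1
            reads1.append(
                ReadRecord(rid + "/1", 1, seq1, quals[i, 0].tobytes().decode("ascii"), sample_id)
            )
            reads2.append(
                ReadRecord(rid + "/2", 2, seq2, quals[i, 1].tobytes().decode("ascii"), sample_id)
            )
    return reads1, reads2


def _apply_errors(rng: np.random.Generator, seq: str, n_errors: int) -> str:
    pos = rng.choice(len(seq), size=n_errors, replace=False)
    arr = bytearray(seq, "ascii")
    idx = {65: 0, 67: 1, 71: 2, 84: 3}
    for pp in pos:
        b = arr[pp]
        shift = int(rng.integers(1, 4))
        arr[pp] = _BASES[(idx.get(b, 0) + shift) % 4]
    return arr.decode("ascii")
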