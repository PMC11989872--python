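"""Standard-format I/O and read quality filtering.

Houses the domain containers shared across the pipeline: a
:class:`GenotypeReference` bundles one graft partner's genome with its gene
models, a :class:`ReadRecord` is a single sequenced mate, and a
:class:`SampleSheet` maps FASTQ files to the tissue x condition x replicate
design (HL/RR/RL x CK/drought x 3).

Coordinates are 0-based half-open everywhere inside the package; GFF3 I/O
converts from/to the 1-based inclusive convention at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

TISSUES = ("HL", "RR", "RL")
CONDITIONS = ("CK", "drought")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised for malformed FASTA/FASTQ/GFF3/sample-sheet input."""


class ValidationError(ValueError):
    """Raised when domain-type invariants are violated."""


@dataclass(frozen=True)
class GeneModel:
    """One gene on a genotype reference.

    ``start``/``end`` are 0-based half-open genomic coordinates.
    ``exon_length`` is the summed exon span of the gene's longest transcript
    and is the length used for TPM normalization.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exon_length: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.exon_length < 1:
            raise ValidationError(f"gene {self.gene_id}: exon_length must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenotypeReference:
    """A genome plus gene models for one graft partner genotype."""

    genotype_id: str
    sequences: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.genotype_id:
            raise ValidationError("genotype_id must be non-empty")
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValidationError(f"duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)
            if g.chromosome not in self.sequences:
                raise ValidationError(
                    f"gene {g.gene_id}: chromosome {g.chromosome!r} absent from reference"
                )
            if g.end > len(self.sequences[g.chromosome]):
                raise ValidationError(
                    f"gene {g.gene_id}: interval exceeds chromosome "
                    f"{g.chromosome} length {len(self.sequences[g.chromosome])}"
                )

    @property
    def genes_by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    def gene_sequence(self, gene: GeneModel | str) -> str:
        """Spliced (here: genomic-span) transcript sequence, 5'->3'."""
        if isinstance(gene, str):
            gene = self.genes_by_id[gene]
        seq = self.sequences[gene.chromosome][gene.start : gene.end]
        return seq if gene.strand == "+" else revcomp(seq)

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


@dataclass(frozen=True, slots=True)
class ReadRecord:
    """One sequenced mate. Qualities are stored as a phred+33 string."""

    read_id: str
    mate: int
    sequence: str
    quality_string: str
    sample_id: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality_string):
            raise ValidationError(
                f"read {self.read_id}: sequence/quality length mismatch"
            )

    @property
    def qualities(self) -> np.ndarray:
        """Per-base phred scores as an int array."""
        return np.frombuffer(self.quality_string.encode("ascii"), dtype=np.uint8) - 33

    def mean_phred(self) -> float:
        return float(self.qualities.mean()) if self.sequence else 0.0

    def n_fraction(self) -> float:
        if not self.sequence:
            return 0.0
        return self.sequence.count("N") / len(self.sequence)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, genotype_id: str | None = None) -> GenotypeReference:
    """Read a FASTA file into a :class:`GenotypeReference` (no gene models).

    Sequences are uppercased. Raises :class:`FormatError` on an empty file or
    a file that contains no FASTA records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: empty FASTA file")
    sequences: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in sequences:
                raise FormatError(f"{path}: duplicate sequence name {rec.id!r}")
            sequences[rec.id] = str(rec.seq).upper()
    except ValueError as exc:
        raise FormatError(f"{path}: malformed FASTA ({exc})") from exc
    if not sequences:
        raise FormatError(f"{path}: no FASTA records found (malformed header?)")
    return GenotypeReference(genotype_id or path.stem, sequences)


def write_fasta(reference: GenotypeReference, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | Path, reference: GenotypeReference) -> list[GeneModel]:
    """Parse gene models from GFF3 and validate them against *reference*.

    One :class:`GeneModel` per ``gene`` feature; ``exon_length`` is the exon
    span sum of the gene's longest transcript (genes without annotated
    transcripts/exons fall back to the gene span).
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        if gene.seqid not in reference.sequences:
            raise ValidationError(
                f"gene {gene.id}: chromosome {gene.seqid!r} absent from reference"
            )
        chrom_len = len(reference.sequences[gene.seqid])
        best_exon_len = 0
        for tx in db.children(gene, level=1):
            exon_len = 0
            for exon in db.children(tx, featuretype="exon"):
                if exon.end > chrom_len or exon.start < 1:
                    raise ValidationError(
                        f"exon of {tx.id} at {exon.seqid}:{exon.start}-{exon.end} "
                        f"outside chromosome bounds"
                    )
                exon_len += exon.end - exon.start + 1
            best_exon_len = max(best_exon_len, exon_len)
        if best_exon_len == 0:
            best_exon_len = gene.end - gene.start + 1
        if gene.end > chrom_len:
            raise ValidationError(
                f"gene {gene.id} at {gene.seqid}:{gene.start}-{gene.end} "
                f"outside chromosome bounds"
            )
        models.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                start=gene.start - 1,  # GFF3 is 1-based inclusive
                end=gene.end,
                strand=gene.strand if gene.strand in "+-" else "+",
                exon_length=best_exon_len,
            )
        )
    return models


def write_gff3(reference: GenotypeReference, path: str | Path) -> None:
    """Write gene models as GFF3 (gene + mRNA + single exon per gene)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in reference.genes:
            start1, end1 = g.start + 1, g.end
            base = f"{g.chromosome}\tgraftmob\t"
            tail = f"\t{start1}\t{end1}\t.\t{g.strand}\t.\t"
            fh.write(base + "gene" + tail + f"ID={g.gene_id}\n")
            fh.write(base + "mRNA" + tail + f"ID={g.gene_id}.1;Parent={g.gene_id}\n")
            fh.write(
                base + "exon" + tail + f"ID={g.gene_id}.1.exon1;Parent={g.gene_id}.1\n"
            )


# ---------------------------------------------------------------------------
# FASTQ


def read_fastq(path: str | Path, sample_id: str = "", mate: int = 1) -> list[ReadRecord]:
    """Read a phred+33 FASTQ file into :class:`ReadRecord` objects."""
    reads: list[ReadRecord] = []
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            reads.append(
                ReadRecord(
                    read_id=title.split()[0],
                    mate=mate,
                    sequence=seq.upper(),
                    quality_string=qual,
                    sample_id=sample_id,
                )
            )
    return reads


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        chunks: list[str] = []
        for r in reads:
            chunks.append(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality_string}\n")
            if len(chunks) >= 10000:
                fh.write("".join(chunks))
                chunks.clear()
        fh.write("".join(chunks))


# ---------------------------------------------------------------------------
# Quality filter


@dataclass
class QCReport:
    n_input: int = 0
    n_kept: int = 0
    n_dropped_low_quality: int = 0
    n_dropped_poly_n: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_dropped_low_quality + self.n_dropped_poly_n


def quality_filter(
    reads: Sequence[ReadRecord],
    min_mean_phred: float = 20.0,
    max_n_fraction: float = 0.10,
) -> tuple[list[ReadRecord], QCReport]:
    """Keep reads with mean phred > *min_mean_phred* and N fraction <= *max_n_fraction*.

    Mirrors the fastp-style pre-filter applied to raw graft RNA-seq (phred
    cutoff 20, poly-N removal). A read failing both rules is counted once,
    under low quality. Empty input yields an empty output and a zeroed
    report.
    """
    kept: list[ReadRecord] = []
    report = QCReport()
    for r in reads:
        report.n_input += 1
        if r.mean_phred() <= min_mean_phred:
            report.n_dropped_low_quality += 1
        elif r.n_fraction() > max_n_fraction:
            report.n_dropped_poly_n += 1
        else:
            kept.append(r)
    report.n_kept = len(kept)
    return kept, report


# ---------------------------------------------------------------------------
# Sample sheet

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "tissue",
    "condition",
    "replicate",
    "fastq1",
    "fastq2",
]


@dataclass
class SampleSheet:
    """The one-grafted-plant / three-samples design table.

    Rows map ``sample_id`` to tissue (HL/RR/RL), condition (CK/drought),
    replicate and its two mate FASTQ paths.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.rows.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        self.rows = self.rows[SAMPLE_SHEET_COLUMNS].copy()
        self.rows["replicate"] = self.rows["replicate"].astype(int)
        bad_tissue = set(self.rows["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise ValidationError(f"unknown tissues: {sorted(bad_tissue)}")
        bad_cond = set(self.rows["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValidationError(f"unknown conditions: {sorted(bad_cond)}")
        key = self.rows[["tissue", "condition", "replicate"]]
        if key.duplicated().any():
            raise ValidationError("duplicate (tissue, condition, replicate) rows")
        if self.rows["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id rows")

    def samples(self) -> Iterable[pd.Series]:
        for _, row in self.rows.iterrows():
            yield row

    def group(self, tissue: str, condition: str) -> pd.DataFrame:
        sel = (self.rows["tissue"] == tissue) & (self.rows["condition"] == condition)
        return self.rows[sel].sort_values("replicate")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.rows.to_csv(path, sep="\t", index=False)
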