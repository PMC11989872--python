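"""Genome-of-origin read classification and mobile-gene calling.

Per sample and direction this implements the read set algebra of the
heterograft pipeline:

1. reads are mapped to the sample's **native** genotype reference at a
   two-edit cap; mapped reads are native transcription;
2. every unmapped read is cross-checked by local search against **both**
   references and assigned to the genome it matches best: a read whose
   foreign local hit outscores any native hit is a candidate mobile read
   (set A / A'); a read matching the native reference at least as well is
   a cross-mapping false positive (set B / B'); no hit anywhere discards
   it;
3. candidate mobile reads are mapped to the foreign reference at a
   one-edit cap; those that map are retained (set C / C') and accumulated
   into per-gene support counts (toward gene sets D / D').

Rootstock tissues (RR, RL) receive scion transcripts, so their foreign
reference is the scion genotype (downward direction); the scion leaf (HL)
receives rootstock transcripts (upward direction).

Gene calls then require support in a minimum number of biological
replicates and expression of the gene in its source tissue (the E / E'
exclusion of source-silent genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .align import (
    AlignmentHit,
    AlignmentIndex,
    LocalAligner,
    align_reads,
    build_index,
)
from .io import GenotypeReference, ReadRecord, ValidationError

_DIRECTION_BY_TISSUE = {"HL": "up", "RR": "down", "RL": "down"}


@dataclass
class PipelineParams:
    """Thresholds of the identification pipeline.

    ``k_first``/``k_second`` are the edit-distance caps of the native and
    foreign mapping passes; a gene needs ``min_reads_per_gene`` retained
    reads in at least ``min_replicates`` replicates, and must be expressed
    in the source tissue (raw count >= ``source_expressed_min_count`` in
    >= ``source_expressed_min_replicates`` source replicates) to be called.
    """

    k_first: int = 2
    k_second: int = 1
    min_reads_per_gene: int = 2
    min_replicates: int = 2
    source_expressed_min_count: int = 5
    source_expressed_min_replicates: int = 2
    min_aligned_fraction: float = 0.5
    min_identity: float = 80.0
    index_k: int = 21

    def __post_init__(self) -> None:
        if self.k_second > self.k_first:
            raise ValidationError("k_second must be <= k_first")
        if self.min_replicates < 1 or self.min_reads_per_gene < 1:
            raise ValidationError("min_replicates and min_reads_per_gene must be >= 1")


def direction_for_tissue(tissue: str) -> str:
    try:
        return _DIRECTION_BY_TISSUE[tissue]
    except KeyError:
        raise ValidationError(f"unknown tissue {tissue!r}") from None


@dataclass
class ClassifiedReadSets:
    """Per-sample realization of the pipeline's read sets."""

    sample_id: str
    direction: str
    mapped_native: list[str]
    unmapped: list[str]
    candidate_mobile: list[str]
    false_positive: list[str]
    discarded: list[str]
    retained: list[AlignmentHit]
    gene_support: dict[str, int]
    native_hits: list[AlignmentHit] = field(default_factory=list, repr=False)

    @property
    def retained_ids(self) -> list[str]:
        return [h.read_id for h in self.retained]

    def summary(self) -> dict[str, int]:
        return {
            "n_reads": len(self.mapped_native) + len(self.unmapped),
            "mapped_native": len(self.mapped_native),
            "unmapped": len(self.unmapped),
            "candidate_mobile": len(self.candidate_mobile),
            "false_positive": len(self.false_positive),
            "discarded": len(self.discarded),
            "retained": len(self.retained),
            "genes_with_support": len(self.gene_support),
        }

    def check_partition(self) -> None:
        """Unmapped reads partition into candidate / false-positive / discarded."""
        if len(self.candidate_mobile) + len(self.false_positive) + len(
            self.discarded
        ) != len(self.unmapped):
            raise ValidationError("unmapped read partition is inconsistent")
        overlap = set(self.candidate_mobile) & set(self.false_positive)
        if overlap:
            raise ValidationError(f"reads both candidate and false positive: {overlap}")


def classify_sample_reads(
    reads: Sequence[ReadRecord],
    native_ref: GenotypeReference,
    foreign_ref: GenotypeReference,
    params: PipelineParams,
    tissue: str,
    sample_id: str | None = None,
    native_index: AlignmentIndex | None = None,
    foreign_index: AlignmentIndex | None = None,
    native_local: LocalAligner | None = None,
    foreign_local: LocalAligner | None = None,
) -> ClassifiedReadSets:
    """Run the per-sample read set algebra (QC-filtered reads in).

    Pre-built alignment indexes / local aligners may be passed to amortize
    construction across replicates; they are built on the fly otherwise.
    """
    direction = direction_for_tissue(tissue)
    sid = sample_id or (reads[0].sample_id if reads else "")

    if native_index is None:
        native_index = build_index(native_ref, params.index_k)
    if foreign_index is None:
        foreign_index = build_index(foreign_ref, params.index_k)
    if native_local is None:
        native_local = LocalAligner(
            native_ref,
            min_aligned_fraction=params.min_aligned_fraction,
            min_identity=params.min_identity,
        )
    if foreign_local is None:
        foreign_local = LocalAligner(
            foreign_ref,
            min_aligned_fraction=params.min_aligned_fraction,
            min_identity=params.min_identity,
        )

    native_hits, unmapped_ids = align_reads(reads, native_index, native_ref, params.k_first)
    unmapped_set = set(unmapped_ids)
    by_id = {}
    for r in reads:
        if r.read_id in unmapped_set:
            by_id.setdefault(r.read_id, []).append(r)

    # Cross-check arbitration. At realistic genotype divergence a genuinely
    # mobile read still produces a local hit on the native genome (its
    # ortholog is only a few percent diverged), so "any native hit" cannot
    # disqualify a read outright; the read is assigned to the genome it
    # matches best. A native hit at least as good as the foreign one marks
    # the read a cross-mapping false positive -- ties (e.g. a read from a
    # segment identical in both genotypes) are conservatively native.
    candidate: list[str] = []
    false_positive: list[str] = []
    discarded: list[str] = []
    candidate_reads: list[ReadRecord] = []
    for rid in unmapped_ids:
        read = by_id[rid][0]
        hit_native = native_local.search(read)
        hit_foreign = foreign_local.search(read)
        if hit_foreign is not None and (
            hit_native is None or hit_foreign.score > hit_native.score
        ):
            candidate.append(rid)
            candidate_reads.append(read)
        elif hit_native is not None:
            false_positive.append(rid)
        else:
            discarded.append(rid)

    retained, _ = align_reads(candidate_reads, foreign_index, foreign_ref, params.k_second)
    gene_support: dict[str, int] = {}
    for h in retained:
        if h.gene_id is not None:
            gene_support[h.gene_id] = gene_support.get(h.gene_id, 0) + 1

    sets = ClassifiedReadSets(
        sample_id=sid,
        direction=direction,
        mapped_native=[h.read_id for h in native_hits],
        unmapped=unmapped_ids,
        candidate_mobile=candidate,
        false_positive=false_positive,
        discarded=discarded,
        retained=retained,
        gene_support=dict(sorted(gene_support.items())),
        native_hits=native_hits,
    )
    sets.check_partition()
    return sets


@dataclass(frozen=True)
class MobileCall:
    """A gene called mobile in one receiving tissue under one condition."""

    gene_id: str
    source_genotype: str
    direction: str
    tissue: str
    condition: str
    replicate_support: int
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        expected = "up" if self.tissue == "HL" else "down"
        if self.direction != expected:
            raise ValidationError(
                f"call {self.gene_id}: direction {self.direction} inconsistent "
                f"with tissue {self.tissue}"
            )


def call_mobile_genes(
    replicate_sets: Sequence[ClassifiedReadSets],
    source_expression: pd.DataFrame | Mapping[str, Sequence[int]],
    params: PipelineParams,
    tissue: str,
    condition: str,
    source_genotype: str,
) -> list[MobileCall]:
    """Replicate-consensus gene calls with the source-expression exclusion.

    *source_expression* holds raw read counts of the candidate (foreign
    genotype) genes in the **source** tissue of this direction, one column
    per source replicate. A gene is called iff it has
    >= ``min_reads_per_gene`` supporting reads in >= ``min_replicates``
    replicates here, and is expressed in the source tissue (count >=
    ``source_expressed_min_count`` in >= ``source_expressed_min_replicates``
    source replicates).
    """
    if source_expression is None:
        raise ValidationError("source expression table is required (E/E' exclusion)")
    if not isinstance(source_expression, pd.DataFrame):
        source_expression = pd.DataFrame(
            {g: list(v) for g, v in source_expression.items()}
        ).T
    direction = direction_for_tissue(tissue)
    for s in replicate_sets:
        if s.direction != direction:
            raise ValidationError(
                f"replicate set {s.sample_id} direction {s.direction} != {direction}"
            )

    genes = sorted(set().union(*(s.gene_support.keys() for s in replicate_sets)))
    calls: list[MobileCall] = []
    for gene in genes:
        counts = tuple(s.gene_support.get(gene, 0) for s in replicate_sets)
        support = sum(c >= params.min_reads_per_gene for c in counts)
        if support < params.min_replicates:
            continue
        if gene in source_expression.index:
            src_counts = source_expression.loc[gene]
            n_expressed = int(
                (src_counts >= params.source_expressed_min_count).sum()
            )
        else:
            n_expressed = 0
        if n_expressed < params.source_expressed_min_replicates:
            continue  # E/E' exclusion: not expressed in the source tissue
        calls.append(
            MobileCall(
                gene_id=gene,
                source_genotype=source_genotype,
                direction=direction,
                tissue=tissue,
                condition=condition,
                replicate_support=support,
                counts=counts,
            )
        )
    return calls
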