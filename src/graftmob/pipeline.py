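"""End-to-end orchestration: qc -> align/classify -> call -> patterns -> quant -> report.

Every stage writes a plain-text table under the output directory, and the
JSON run report is a pure function of those stage files, so rerunning
``report`` recomputes identical numbers. With a fixed dataset and
parameters the whole run is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import quant
from .align import LocalAligner, build_index
from .caller import (
    ClassifiedReadSets,
    MobileCall,
    PipelineParams,
    call_mobile_genes,
    classify_sample_reads,
    direction_for_tissue,
)
from .io import (
    CONDITIONS,
    GenotypeReference,
    SampleSheet,
    quality_filter,
    read_fasta,
    read_fastq,
    read_gff3,
    read_sample_sheet,
)
from .patterns import classify_transport, condition_specific_sets
from .simulate import ROOTSTOCK, SCION, SimulatedDataset


@dataclass
class GraftDataset:
    """References plus sample sheet, as laid out by the simulator."""

    scion: GenotypeReference
    rootstock: GenotypeReference
    sample_sheet: SampleSheet
    root: Path

    @classmethod
    def load(cls, dataset_dir: str | Path) -> "GraftDataset":
        root = Path(dataset_dir)
        scion = read_fasta(root / "scion.fasta", SCION)
        scion.genes = read_gff3(root / "scion.gff3", scion)
        scion.validate()
        rootstock = read_fasta(root / "rootstock.fasta", ROOTSTOCK)
        rootstock.genes = read_gff3(root / "rootstock.gff3", rootstock)
        rootstock.validate()
        sheet = read_sample_sheet(root / "sample_sheet.tsv")
        return cls(scion=scion, rootstock=rootstock, sample_sheet=sheet, root=root)

    @classmethod
    def from_simulated(cls, sim: SimulatedDataset) -> "GraftDataset":
        return cls(
            scion=sim.scion,
            rootstock=sim.rootstock,
            sample_sheet=sim.sample_sheet,
            root=sim.outdir,
        )

    def resolve(self, path: str) -> Path:
        p = Path(path)
        return p if p.is_absolute() else self.root / p

    def native(self, tissue: str) -> GenotypeReference:
        return self.scion if tissue == "HL" else self.rootstock

    def foreign(self, tissue: str) -> GenotypeReference:
        return self.rootstock if tissue == "HL" else self.scion


@dataclass
class PipelineResult:
    outdir: Path
    classified: dict[str, ClassifiedReadSets]
    native_counts: dict[str, pd.Series]  # sample_id -> per-gene raw counts
    native_tpm: dict[str, pd.Series]
    calls: list[MobileCall]
    report: dict = field(default_factory=dict)

    def calls_for(self, direction: str | None = None, tissue: str | None = None,
                  condition: str | None = None) -> list[MobileCall]:
        out = self.calls
        if direction:
            out = [c for c in out if c.direction == direction]
        if tissue:
            out = [c for c in out if c.tissue == tissue]
        if condition:
            out = [c for c in out if c.condition == condition]
        return out


def run_pipeline(
    dataset: GraftDataset | SimulatedDataset,
    outdir: str | Path,
    params: PipelineParams | None = None,
    write_coverage: bool = True,
) -> PipelineResult:
    """Run the full identification pipeline and write every stage output."""
    if isinstance(dataset, SimulatedDataset):
        dataset = GraftDataset.from_simulated(dataset)
    params = params or PipelineParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # shared alignment structures (built once, reused across samples)
    index = {
        SCION: build_index(dataset.scion, params.index_k),
        ROOTSTOCK: build_index(dataset.rootstock, params.index_k),
    }
    local = {
        gid: LocalAligner(
            ref,
            min_aligned_fraction=params.min_aligned_fraction,
            min_identity=params.min_identity,
        )
        for gid, ref in ((SCION, dataset.scion), (ROOTSTOCK, dataset.rootstock))
    }

    qc_rows: list[dict] = []
    summary_rows: list[dict] = []
    support_rows: list[dict] = []
    hit_rows: list[dict] = []
    expr_rows: list[dict] = []
    classified: dict[str, ClassifiedReadSets] = {}
    native_counts: dict[str, pd.Series] = {}
    native_tpm: dict[str, pd.Series] = {}

    for row in dataset.sample_sheet.samples():
        sid, tissue = row["sample_id"], row["tissue"]
        native = dataset.native(tissue)
        foreign = dataset.foreign(tissue)
        reads = []
        for mate, key in ((1, "fastq1"), (2, "fastq2")):
            raw = read_fastq(dataset.resolve(row[key]), sample_id=sid, mate=mate)
            kept, rep = quality_filter(raw)
            qc_rows.append(
                dict(
                    sample_id=sid,
                    mate=mate,
                    n_input=rep.n_input,
                    n_kept=rep.n_kept,
                    n_dropped_low_quality=rep.n_dropped_low_quality,
                    n_dropped_poly_n=rep.n_dropped_poly_n,
                )
            )
            reads.extend(kept)
        sets = classify_sample_reads(
            reads,
            native,
            foreign,
            params,
            tissue=tissue,
            sample_id=sid,
            native_index=index[native.genotype_id],
            foreign_index=index[foreign.genotype_id],
            native_local=local[native.genotype_id],
            foreign_local=local[foreign.genotype_id],
        )
        classified[sid] = sets
        summary_rows.append(dict(sample_id=sid, direction=sets.direction, **sets.summary()))
        for gene, n in sets.gene_support.items():
            support_rows.append(dict(sample_id=sid, gene_id=gene, reads=n))
        for h in sets.retained:
            hit_rows.append(
                dict(
                    sample_id=sid,
                    read_id=h.read_id,
                    genotype=h.genotype_id,
                    chrom=h.chromosome,
                    start=h.start,
                    end=h.end,
                    strand=h.strand,
                    edit_distance=h.edit_distance,
                    gene_id=h.gene_id or "",
                )
            )
        counts, _ = quant.count_reads_per_gene(sets.native_hits, native.genes)
        lengths = pd.Series({g.gene_id: g.exon_length for g in native.genes})
        tpm_s = quant.tpm(counts, lengths)
        native_counts[sid] = counts
        native_tpm[sid] = tpm_s
        for gene in counts.index:
            expr_rows.append(
                dict(sample_id=sid, gene_id=gene, count=int(counts[gene]), tpm=tpm_s[gene])
            )
        # free the read-level payloads; downstream needs counts and support only
        sets.native_hits = []

    pd.DataFrame(qc_rows).to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    pd.DataFrame(summary_rows).to_csv(outdir / "read_sets_summary.tsv", sep="\t", index=False)
    pd.DataFrame(support_rows, columns=["sample_id", "gene_id", "reads"]).to_csv(
        outdir / "gene_support.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        hit_rows,
        columns=["sample_id", "read_id", "genotype", "chrom", "start", "end",
                 "strand", "edit_distance", "gene_id"],
    ).to_csv(outdir / "retained_hits.tsv", sep="\t", index=False)
    pd.DataFrame(expr_rows).to_csv(
        outdir / "expression_tpm.tsv", sep="\t", index=False, float_format="%.6g"
    )

    with open(outdir / "params.json", "w") as fh:
        json.dump(_params_dict(params), fh, indent=2, sort_keys=True)
        fh.write("\n")

    calls = _call_stage(dataset, classified, native_counts, params)
    _write_calls(calls, outdir / "mobile_calls.tsv", params)
    _patterns_stage(calls, outdir)
    _quant_stage(dataset, calls, native_tpm, outdir)
    if write_coverage:
        _coverage_stage(pd.DataFrame(hit_rows, columns=[
            "sample_id", "read_id", "genotype", "chrom", "start", "end",
            "strand", "edit_distance", "gene_id"]), dataset, calls, outdir)

    report = build_report(outdir)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return PipelineResult(
        outdir=outdir,
        classified=classified,
        native_counts=native_counts,
        native_tpm=native_tpm,
        calls=calls,
        report=report,
    )


def _group_samples(sheet: SampleSheet, tissue: str, condition: str) -> list[str]:
    return list(sheet.group(tissue, condition)["sample_id"])


def source_expression_table(
    dataset: GraftDataset,
    native_counts: dict[str, pd.Series],
    direction: str,
    condition: str,
) -> pd.DataFrame:
    """Raw source-tissue counts per replicate for the E/E' exclusion.

    Downward candidates originate in the scion leaf (HL); upward candidates
    originate in the rootstock, whose root and lateral leaf samples are
    pooled per replicate.
    """
    sheet = dataset.sample_sheet
    if direction == "down":
        sids = _group_samples(sheet, "HL", condition)
        cols = {f"rep{i+1}": native_counts[s] for i, s in enumerate(sids)}
        return pd.DataFrame(cols)
    rr = _group_samples(sheet, "RR", condition)
    rl = _group_samples(sheet, "RL", condition)
    cols = {}
    for i in range(max(len(rr), len(rl))):
        total = None
        for sids in (rr, rl):
            if i < len(sids):
                c = native_counts[sids[i]]
                total = c if total is None else total.add(c, fill_value=0)
        cols[f"rep{i+1}"] = total
    return pd.DataFrame(cols).fillna(0).astype(int)


def _call_stage(
    dataset: GraftDataset,
    classified: dict[str, ClassifiedReadSets],
    native_counts: dict[str, pd.Series],
    params: PipelineParams,
) -> list[MobileCall]:
    calls: list[MobileCall] = []
    for condition in CONDITIONS:
        for tissue in ("HL", "RR", "RL"):
            sids = _group_samples(dataset.sample_sheet, tissue, condition)
            if not sids:
                continue
            direction = direction_for_tissue(tissue)
            source = source_expression_table(dataset, native_counts, direction, condition)
            calls.extend(
                call_mobile_genes(
                    [classified[s] for s in sids],
                    source,
                    params,
                    tissue=tissue,
                    condition=condition,
                    source_genotype=dataset.foreign(tissue).genotype_id,
                )
            )
    return calls


def _write_calls(calls: list[MobileCall], path: Path, params: PipelineParams) -> None:
    n_rep = max((len(c.counts) for c in calls), default=3)
    rows = []
    for c in sorted(calls, key=lambda c: (c.direction, c.tissue, c.condition, c.gene_id)):
        row = dict(
            gene_id=c.gene_id,
            genotype=c.source_genotype,
            direction=c.direction,
            tissue=c.tissue,
            condition=c.condition,
            replicate_support=c.replicate_support,
        )
        for i in range(n_rep):
            row[f"counts_r{i+1}"] = c.counts[i] if i < len(c.counts) else 0
        rows.append(row)
    cols = ["gene_id", "genotype", "direction", "tissue", "condition",
            "replicate_support"] + [f"counts_r{i+1}" for i in range(n_rep)]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> list[MobileCall]:
    df = pd.read_csv(path, sep="\t")
    count_cols = [c for c in df.columns if c.startswith("counts_r")]
    calls = []
    for row in df.itertuples():
        calls.append(
            MobileCall(
                gene_id=row.gene_id,
                source_genotype=row.genotype,
                direction=row.direction,
                tissue=row.tissue,
                condition=row.condition,
                replicate_support=int(row.replicate_support),
                counts=tuple(int(getattr(row, c)) for c in count_cols),
            )
        )
    return calls


def _patterns_stage(calls: list[MobileCall], outdir: Path) -> None:
    rows = []
    for condition in (*CONDITIONS, None):
        subset = [c for c in calls if condition is None or c.condition == condition]
        s = classify_transport(subset, condition=condition)
        rows.append(
            dict(
                condition=condition or "merged",
                **s.counts(),
                through_root_genes=";".join(sorted(s.through_root)),
                rl_direct_genes=";".join(sorted(s.rl_direct)),
                rr_only_degraded_genes=";".join(sorted(s.rr_only_degraded)),
            )
        )
    pd.DataFrame(rows).to_csv(outdir / "transport_summary.tsv", sep="\t", index=False)

    venn_rows = []
    for direction, tissue in (("up", "HL"), ("down", "RR"), ("down", "RL")):
        ck = [c for c in calls if c.condition == "CK" and c.tissue == tissue]
        dr = [c for c in calls if c.condition == "drought" and c.tissue == tissue]
        if not ck and not dr:
            venn_rows.append(
                dict(direction=direction, tissue=tissue, ck_only=0, both=0,
                     drought_only=0, ck_only_genes="", both_genes="",
                     drought_only_genes="")
            )
            continue
        v = condition_specific_sets(ck, dr)
        venn_rows.append(
            dict(
                direction=direction,
                tissue=tissue,
                **v.counts(),
                ck_only_genes=";".join(sorted(v.ck_only)),
                both_genes=";".join(sorted(v.both)),
                drought_only_genes=";".join(sorted(v.drought_only)),
            )
        )
    pd.DataFrame(venn_rows).to_csv(outdir / "condition_venn.tsv", sep="\t", index=False)


def _quant_stage(
    dataset: GraftDataset,
    calls: list[MobileCall],
    native_tpm: dict[str, pd.Series],
    outdir: Path,
) -> None:
    """Abundance-class bins and abundance-vs-mobility tests per
    direction x condition, computed on mean source-tissue TPM."""
    bin_rows = []
    test_rows = []
    for condition in CONDITIONS:
        for direction, source_tissue in (("down", "HL"), ("up", "RR")):
            sids = _group_samples(dataset.sample_sheet, source_tissue, condition)
            if not sids:
                continue
            mean_tpm = pd.concat([native_tpm[s] for s in sids], axis=1).mean(axis=1)
            mobile = sorted(
                {c.gene_id for c in calls
                 if c.direction == direction and c.condition == condition}
            )
            bins = quant.bin_abundance(mean_tpm, mobile)
            for r in bins.table.itertuples():
                bin_rows.append(
                    dict(direction=direction, condition=condition, bin=r.bin,
                         n_total=r.n_total, n_mobile=r.n_mobile,
                         mobile_fraction=r.mobile_fraction)
                )
            res = quant.mobility_abundance_test(mean_tpm, mobile, n_permutations=2000, seed=0)
            test_rows.append(
                dict(direction=direction, condition=condition,
                     statistic=res.statistic, z=res.z, p_value=res.p_value,
                     n_mobile=res.n_mobile, n_genes=res.n_genes,
                     top_k=res.top_k, top_k_overlap=res.top_k_overlap,
                     skipped=res.skipped, reason=res.reason)
            )
    pd.DataFrame(bin_rows).to_csv(outdir / "abundance_bins.tsv", sep="\t",
                                  index=False, float_format="%.6g")
    pd.DataFrame(test_rows).to_csv(outdir / "mobility_abundance_test.tsv", sep="\t",
                                   index=False, float_format="%.6g")


def _coverage_stage(
    hits: pd.DataFrame,
    dataset: GraftDataset,
    calls: list[MobileCall],
    outdir: Path,
    max_genes: int = 50,
) -> None:
    """bedGraph coverage of called mobile genes in their sink samples,
    from the retained (second-pass) foreign hits."""
    from .align import AlignmentHit

    covdir = outdir / "coverage"
    covdir.mkdir(exist_ok=True)
    genes_by_id = {
        **dataset.scion.genes_by_id,
        **dataset.rootstock.genes_by_id,
    }
    called_genes = sorted({c.gene_id for c in calls})[:max_genes]
    for gene_id in called_genes:
        gene = genes_by_id.get(gene_id)
        if gene is None:
            continue
        sel = hits[hits["gene_id"] == gene_id]
        gene_hits = [
            AlignmentHit(
                read_id=r.read_id, genotype_id=r.genotype, chromosome=r.chrom,
                start=int(r.start), end=int(r.end), strand=r.strand,
                edit_distance=int(r.edit_distance), gene_id=gene_id,
            )
            for r in sel.itertuples()
        ]
        depth = quant.coverage_track(gene_hits, gene)
        quant.write_bedgraph(
            depth, gene.chromosome, gene.start, covdir / f"{gene_id}.bedgraph"
        )


def _params_dict(params: PipelineParams) -> dict:
    return {
        "k_first": params.k_first,
        "k_second": params.k_second,
        "min_reads_per_gene": params.min_reads_per_gene,
        "min_replicates": params.min_replicates,
        "source_expressed_min_count": params.source_expressed_min_count,
        "source_expressed_min_replicates": params.source_expressed_min_replicates,
        "min_aligned_fraction": params.min_aligned_fraction,
        "min_identity": params.min_identity,
    }


def build_report(outdir: str | Path) -> dict:
    """Assemble the JSON run report purely from the stage files."""
    outdir = Path(outdir)
    summary = pd.read_csv(outdir / "read_sets_summary.tsv", sep="\t")
    calls = pd.read_csv(outdir / "mobile_calls.tsv", sep="\t")
    report: dict = {"samples": {}, "calls": {}, "parameters": {}}
    params_path = outdir / "params.json"
    if params_path.exists():
        report["parameters"] = json.loads(params_path.read_text())
    for row in summary.itertuples():
        report["samples"][row.sample_id] = dict(
            direction=row.direction,
            n_reads=int(row.n_reads),
            mapped_native=int(row.mapped_native),
            unmapped=int(row.unmapped),
            candidate_mobile=int(row.candidate_mobile),
            false_positive=int(row.false_positive),
            retained=int(row.retained),
        )
    for direction in ("up", "down"):
        report["calls"][direction] = {}
        sub = calls[calls["direction"] == direction]
        for tissue in sorted(sub["tissue"].unique()):
            report["calls"][direction][tissue] = {}
            for condition in sorted(sub[sub["tissue"] == tissue]["condition"].unique()):
                genes = sub[(sub["tissue"] == tissue) & (sub["condition"] == condition)]
                report["calls"][direction][tissue][condition] = dict(
                    n=len(genes), genes=sorted(genes["gene_id"]),
                )
    return report


def recovery_metrics(
    calls: list[MobileCall],
    sim: SimulatedDataset,
) -> dict[str, float]:
    """Sensitivity/precision of calls vs simulator ground truth.

    The unit is the (gene, direction, tissue, condition) cell: a truth row
    with two sink tissues under two conditions contributes four cells.
    """
    truth = sim.truth_cells()
    called = {(c.gene_id, c.direction, c.tissue, c.condition) for c in calls}
    tp = len(truth & called)
    return {
        "sensitivity": tp / len(truth) if truth else float("nan"),
        "precision": tp / len(called) if called else float("nan"),
        "n_truth": len(truth),
        "n_called": len(called),
        "n_true_positive": tp,
    }
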