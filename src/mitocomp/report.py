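"""Full-analysis orchestration over one or many genomes.

``run_pipeline`` composes the module-level analyses — composition table,
codon usage, per-gene codon statistics, ENC-plot and PR2-plot point series,
gene-order comparison against a reference order, AT-insertion scan — and
writes one file per product plus a provenance record.  Nothing here computes
anything the individual modules do not; re-running with identical inputs and
parameters yields byte-identical data files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

from . import codon_usage, composition, gene_order, intergenic
from .genome_io import MitogenomeRecord, partition_regions, read_genome
from .registry import PCG

logger = logging.getLogger(__name__)


@dataclass
class AnalysisReport:
    composition_rows: dict = field(default_factory=dict)
    codon_tables: dict = field(default_factory=dict)
    per_gene_stats: dict = field(default_factory=dict)
    rearrangements: dict = field(default_factory=dict)
    insertions: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def analyze_record(record: MitogenomeRecord,
                   code: codon_usage.GeneticCode = codon_usage.INVERTEBRATE_MITO,
                   min_length: int = 100, min_at: float = 0.90,
                   reference: gene_order.GeneOrder | None = None) -> dict:
    """All per-genome products for one record, as in-memory objects."""
    comp = composition.composition_table(record)
    cds = {f.name: codon_usage.extract_feature_sequence(record, f)
           for f in record.features_by_category(PCG)}
    table = codon_usage.count_codons(cds, code) if cds else None
    out = {
        "composition": comp,
        "codon_table": table,
        "per_gene": codon_usage.per_gene_stats(record, code),
        "insertions": intergenic.detect_at_insertions(record, min_length,
                                                      min_at),
        "census": codon_usage.start_stop_census(record, code),
    }
    try:
        order = gene_order.extract_gene_order(record)
        out["order"] = order
        if reference is not None:
            shared = set(reference.labels) & set(order.labels)
            out["rearrangement"] = gene_order.diff_orders(
                reference.restrict(shared), order.restrict(shared))
    except ValueError as exc:
        logger.warning("%s: gene order skipped (%s)", record.identifier, exc)
    return out


def run_pipeline(inputs: list[str | Path], output_dir: str | Path,
                 reference_order_file: str | Path | None = None,
                 code_id: int = 5, min_length: int = 100,
                 min_at: float = 0.90, seed: int | None = None
                 ) -> AnalysisReport:
    """Analyze each input genome and write the product files.

    Unreadable inputs are skipped with a logged reason; if every input is
    skipped a RuntimeError is raised so shells see a nonzero exit.
    """
    if not inputs:
        raise ValueError("no input genomes given")
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    code = codon_usage.GeneticCode.from_table(code_id)
    reference = None
    if reference_order_file is not None:
        orders = gene_order.read_orders(reference_order_file)
        reference = next(iter(orders.values())).normalized("trnM")

    report = AnalysisReport(provenance={
        "inputs": [str(p) for p in inputs],
        "code_id": code_id, "min_length": min_length, "min_at": min_at,
        "seed": seed, "package_version": _pkg_version("mitocomp"),
    })
    comp_lines = []
    codon_lines = []
    gene_lines = []
    enc_plot = ["genome\tgene\tGC3\tENC"]
    pr2_plot = ["genome\tgene\tPR2_x\tPR2_y"]
    orders_json: dict = {}
    bed_parts = []

    n_ok = 0
    for path in inputs:
        try:
            record = read_genome(path)
        except Exception as exc:
            logger.error("skipping %s: %s", path, exc)
            continue
        n_ok += 1
        res = analyze_record(record, code, min_length, min_at, reference)
        report.composition_rows[record.identifier] = res["composition"]
        report.codon_tables[record.identifier] = res["codon_table"]
        report.per_gene_stats[record.identifier] = res["per_gene"]
        report.insertions[record.identifier] = res["insertions"]

        tsv = composition.composition_tsv(res["composition"])
        header, *rows = tsv.strip().split("\n")
        if not comp_lines:
            comp_lines.append("Genome\t" + header)
        comp_lines += [f"{record.identifier}\t{r}" for r in rows]

        if res["codon_table"] is not None:
            df = codon_usage.rscu_table(res["codon_table"])
            if not codon_lines:
                codon_lines.append("Genome\t" + "\t".join(df.columns))
            for row in df.itertuples(index=False):
                codon_lines.append(record.identifier + "\t"
                                   + "\t".join(str(v) for v in row))
        pg = res["per_gene"]
        if not gene_lines:
            gene_lines.append("Genome\t" + "\t".join(pg.columns))
        for row in pg.itertuples(index=False):
            gene_lines.append(record.identifier + "\t"
                              + "\t".join(repr(v) if isinstance(v, float)
                                          else str(v) for v in row))
            d = row._asdict()
            enc_plot.append(f"{record.identifier}\t{d['Gene']}\t"
                            f"{d['GC3'] / 100!r}\t{d['ENC']!r}")
            pr2_plot.append(f"{record.identifier}\t{d['Gene']}\t"
                            f"{d['PR2_x']!r}\t{d['PR2_y']!r}")

        if "order" in res:
            entry = {"order": res["order"].signed_labels()}
            if "rearrangement" in res:
                rr = res["rearrangement"]
                entry["vs_reference"] = rr.to_dict()
                report.rearrangements[record.identifier] = rr
            orders_json[record.identifier] = entry
        bed_parts.append(intergenic.insertions_bed(record, res["insertions"]))

    if n_ok == 0:
        raise RuntimeError("all input genomes failed to load")

    (outdir / "composition.tsv").write_text("\n".join(comp_lines) + "\n")
    (outdir / "codon_usage.tsv").write_text("\n".join(codon_lines) + "\n")
    (outdir / "per_gene_stats.tsv").write_text("\n".join(gene_lines) + "\n")
    (outdir / "enc_plot.tsv").write_text("\n".join(enc_plot) + "\n")
    (outdir / "pr2_plot.tsv").write_text("\n".join(pr2_plot) + "\n")
    (outdir / "gene_order.json").write_text(json.dumps(orders_json, indent=1,
                                                       sort_keys=True))
    (outdir / "insertions.bed").write_text("".join(bed_parts))
    (outdir / "provenance.json").write_text(json.dumps(report.provenance,
                                                       indent=1))
    return report
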