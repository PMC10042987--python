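"""Base composition and AT/GC strand skew.

Strand skews are the standard asymmetry statistics

    AT-skew = (A - T) / (A + T)        GC-skew = (G - C) / (G + C)

computed per region (whole genome, protein-coding genes, tRNAs, rRNAs,
control region).  Both are scale-invariant, so they give identical results
on raw counts and on percentages.  Percentages are taken over counted
(non-N) bases; reported lengths include N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .genome_io import MitogenomeRecord, partition_regions
from .registry import CONTROL, PCG, RRNA, TRNA
from .utils import round_half_up

logger = logging.getLogger(__name__)

#: Region display order mirroring the conventional composition table.
REGION_ORDER = ("Mitogenome", "PCGs", "tRNAs", "rRNAs", "D-loop")
_REGION_KEYS = {"PCGs": PCG, "tRNAs": TRNA, "rRNAs": RRNA, "D-loop": CONTROL}


@dataclass(frozen=True)
class CompositionSummary:
    """One composition-table row (percentages unrounded; round on display)."""

    region: str
    length: int
    pct_a: float
    pct_t: float
    pct_c: float
    pct_g: float
    at_skew: float | None = None
    gc_skew: float | None = None

    @property
    def pct_at(self) -> float:
        return self.pct_a + self.pct_t

    @property
    def pct_gc(self) -> float:
        return self.pct_c + self.pct_g


def skew(a: float, t: float, g: float,
         c: float) -> tuple[float | None, float | None]:
    """AT- and GC-skew from base counts or percentages (scale-invariant).

    A zero denominator makes the corresponding skew undefined, signalled as
    ``None`` rather than a number.
    """
    at = (a - t) / (a + t) if (a + t) > 0 else None
    gc = (g - c) / (g + c) if (g + c) > 0 else None
    return at, gc


def base_composition(sequence: str, region: str = "") -> CompositionSummary:
    """Percent A/T/C/G of a sequence, over non-N bases; skews left unset."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in "ATCG"}
    counted = sum(counts.values())
    if counted == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return CompositionSummary(
        region=region, length=len(seq),
        pct_a=100.0 * counts["A"] / counted,
        pct_t=100.0 * counts["T"] / counted,
        pct_c=100.0 * counts["C"] / counted,
        pct_g=100.0 * counts["G"] / counted,
    )


def composition_table(record: MitogenomeRecord,
                      gene_strand: bool = False) -> list[CompositionSummary]:
    """Composition summaries for the whole circle and each region class.

    Regions lacking annotation are omitted with a logged warning, so a record
    without a control region yields four rows instead of five.
    """
    regions = partition_regions(record, gene_strand=gene_strand)
    sequences = {"Mitogenome": record.sequence}
    for label in REGION_ORDER[1:]:
        seq = regions[_REGION_KEYS[label]]
        if seq:
            sequences[label] = seq
    rows = []
    for label in REGION_ORDER:
        if label not in sequences:
            continue
        row = base_composition(sequences[label], region=label)
        at, gc = skew(row.pct_a, row.pct_t, row.pct_g, row.pct_c)
        rows.append(CompositionSummary(
            region=row.region, length=row.length, pct_a=row.pct_a,
            pct_t=row.pct_t, pct_c=row.pct_c, pct_g=row.pct_g,
            at_skew=at, gc_skew=gc))
    return rows


def composition_tsv(rows: list[CompositionSummary]) -> str:
    """Render rows as a TSV report (2-dp display alongside full precision)."""
    def fmt(x: float | None, dp: int = 2) -> str:
        return "NA" if x is None else f"{round_half_up(x, dp):.{dp}f}"

    header = ("Region\tLength\tA%\tT%\tC%\tG%\tAT%\tGC%\tAT-skew\tGC-skew"
              "\tAT-skew_full\tGC-skew_full")
    lines = [header]
    for r in rows:
        full_at = "NA" if r.at_skew is None else repr(r.at_skew)
        full_gc = "NA" if r.gc_skew is None else repr(r.gc_skew)
        lines.append("\t".join([
            r.region, str(r.length), fmt(r.pct_a), fmt(r.pct_t), fmt(r.pct_c),
            fmt(r.pct_g), fmt(r.pct_at), fmt(r.pct_gc), fmt(r.at_skew),
            fmt(r.gc_skew), full_at, full_gc]))
    return "\n".join(lines) + "\n"
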