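"""Codon-usage bias statistics for mitochondrial protein-coding genes.

Everything here is driven by the synonymous-family structure of a genetic
code (default: NCBI translation table 5, the invertebrate mitochondrial code,
under which AGA/AGG encode Ser, AUA encodes Met and UGA encodes Trp — twelve
2-fold families, six 4-fold, Leu 6-fold, Ser 8-fold, stops {UAA, UAG}).

Statistics
----------
RSCU
    Relative synonymous codon usage: for codon *i* in a family of *k*
    synonyms with family total *m*, ``RSCU_i = k * count_i / m``.  The family
    sum is exactly *k*; RSCU > 1 marks preferred codons.
ENC
    Wright's effective number of codons, generalized to the code's family
    structure.  Per family with *n* observed codons and usage fractions
    *p_i*, the homozygosity estimate is ``F = (n * sum(p_i^2) - 1)/(n - 1)``;
    class averages over families of equal synonymy feed
    ``ENC = sum_k n_aa(k) / F_k``.  ENC ranges from the number of amino acids
    (20: absolute bias) to the code's synonymous capacity (62 under table 5:
    no bias).
ENC-plot null curve
    Expected ENC under pure GC3 mutation pressure:
    ``ENC* = 2 + s + 29/(s^2 + (1-s)^2)`` with ``s = GC3``.  Genes far below
    the curve show bias beyond what their GC3 explains.
PR2
    Parity-rule-2 bias: third-position ``x = G3/(G3+C3)`` against
    ``y = A3/(A3+T3)``; (0.5, 0.5) is the no-strand-bias null.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable

from .genome_io import MitogenomeRecord, extract_feature_sequence
from .registry import PCG
from .utils import round_half_up

logger = logging.getLogger(__name__)

STOP_LABEL = "Ter"

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code with its synonymous-family structure."""

    id: int
    name: str
    forward: dict[str, str]          # RNA codon -> one-letter amino acid
    stop_codons: frozenset[str]
    start_codons: frozenset[str]
    families: dict[str, tuple[str, ...]]   # amino acid -> sense codons

    @classmethod
    def from_table(cls, table_id: int = 5) -> "GeneticCode":
        t = CodonTable.unambiguous_rna_by_id[table_id]
        forward = dict(t.forward_table)
        families: dict[str, list[str]] = {}
        for codon, aa in forward.items():
            families.setdefault(aa, []).append(codon)
        return cls(id=table_id, name=t.names[0] if t.names else str(table_id),
                   forward=forward,
                   stop_codons=frozenset(t.stop_codons),
                   start_codons=frozenset(t.start_codons),
                   families={aa: tuple(sorted(c)) for aa, c in
                             sorted(families.items())})

    @property
    def sense_codons(self) -> frozenset[str]:
        return frozenset(self.forward)

    @property
    def n_amino_acids(self) -> int:
        return len(self.families)

    @property
    def synonymous_capacity(self) -> int:
        """Maximum ENC: total number of sense codons (62 under table 5)."""
        return sum(len(c) for c in self.families.values())

    def family_of(self, codon: str) -> str | None:
        if codon in self.stop_codons:
            return STOP_LABEL
        return self.forward.get(codon)


INVERTEBRATE_MITO = GeneticCode.from_table(5)


@dataclass
class CodonUsageTable:
    """Codon counts under a genetic code.

    ``counts`` covers only the 64 canonical codons (RNA alphabet); codons
    containing N are tallied in ``ambiguous`` and trailing 1–2 nt remainders
    (truncated stops) in ``truncated``.  With ``separate_starts`` counting,
    each gene's initiation codon lands in ``start_counts`` instead — the
    convention some published mitogenome codon tables use for the Met family.
    """

    counts: Counter
    code: GeneticCode
    truncated: int = 0
    ambiguous: int = 0
    start_counts: Counter = field(default_factory=Counter)
    per_gene: dict[str, Counter] = field(default_factory=dict)

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())

    def third_position_counts(self,
                              include_stops: bool = False) -> Counter:
        out: Counter = Counter()
        for codon, n in self.counts.items():
            if not include_stops and codon in self.code.stop_codons:
                continue
            out[codon[2]] += n
        return out


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def count_codons(cds_sequences: list[str] | dict[str, str],
                 code: GeneticCode = INVERTEBRATE_MITO,
                 separate_starts: bool = False) -> CodonUsageTable:
    """Tally non-overlapping in-frame codons across framed CDS sequences.

    Accepts a list of gene-strand sequences or a ``{gene: sequence}`` mapping
    (the latter retains a per-gene breakdown).  A trailing 1–2 nt remainder
    is dropped and tallied as a truncated stop; codons containing N are
    excluded from ``counts``.
    """
    if isinstance(cds_sequences, dict):
        items = list(cds_sequences.items())
    else:
        items = [(f"gene{i + 1}", s) for i, s in enumerate(cds_sequences)]
    table = CodonUsageTable(Counter(), code)
    for name, seq in items:
        rna = _to_rna(seq)
        if len(rna) < 3:
            logger.warning("CDS %s shorter than one codon; skipped", name)
            continue
        gene_counts: Counter = Counter()
        n_full = len(rna) // 3
        for i in range(n_full):
            codon = rna[3 * i:3 * i + 3]
            if "N" in codon:
                table.ambiguous += 1
                continue
            if i == 0 and separate_starts:
                table.start_counts[codon] += 1
                continue
            gene_counts[codon] += 1
        if len(rna) % 3:
            table.truncated += 1
        table.counts += gene_counts
        table.per_gene[name] = gene_counts
    return table


# ---------------------------------------------------------------------------
# RSCU

def _family_map(code: GeneticCode) -> dict[str, tuple[str, ...]]:
    fams = dict(code.families)
    fams[STOP_LABEL] = tuple(sorted(code.stop_codons))
    return fams


def rscu(table: CodonUsageTable,
         met_start_compat: bool = False) -> dict[str, float]:
    """RSCU per codon; unused families are absent, unused codons of a used
    family report 0.0.  Stop codons form their own family.

    ``met_start_compat`` reproduces the convention of folding initiation
    codons into a 4-codon Met family {AUA, AUG, AUU, CGA}: a table's
    start-codon tally supplies the AUU/CGA usage (their in-frame counts stay
    with Ile/Arg).  In that mode the returned mapping carries the folded
    family's values for AUA/AUG, while AUU/CGA keep their Ile/Arg values
    (a flat mapping cannot list a codon in two families at once).
    """
    if table.n_codons == 0 and not table.start_counts:
        raise ValueError("empty codon table")
    fams = _family_map(table.code)
    counts = table.counts
    out: dict[str, float] = {}
    for aa, codons in fams.items():
        m = sum(counts.get(c, 0) for c in codons)
        if m == 0:
            continue
        k = len(codons)
        for c in codons:
            out[c] = k * counts.get(c, 0) / m
    if met_start_compat:
        met = sorted(c for c, aa in table.code.forward.items() if aa == "M")
        extra = sorted(set(("AUU", "CGA")) - set(met))
        folded = {c: counts.get(c, 0) + table.start_counts.get(c, 0)
                  for c in met}
        folded.update({c: table.start_counts.get(c, 0) for c in extra})
        m = sum(folded.values())
        if m > 0:
            k = len(folded)
            for c in met:
                out[c] = k * folded[c] / m
    return out


def rscu_table(table: CodonUsageTable,
               met_start_compat: bool = False) -> pd.DataFrame:
    """Tidy codon-usage report: AminoAcid, Codon, Count, RSCU (2 dp)."""
    values = rscu(table, met_start_compat=met_start_compat)
    fams = _family_map(table.code)
    rows = []
    for aa, codons in sorted(fams.items(),
                             key=lambda kv: _AA3.get(kv[0], kv[0])):
        label = _AA3.get(aa, aa)
        for c in codons:
            if c not in values:
                continue
            count = table.counts.get(c, 0)
            if met_start_compat and aa == "M":
                count += table.start_counts.get(c, 0)
            rows.append((label, c, count, round_half_up(values[c], 2)))
    return pd.DataFrame(rows, columns=["AminoAcid", "Codon", "Count", "RSCU"])


# ---------------------------------------------------------------------------
# GC by codon position

@dataclass(frozen=True)
class CodonPositionGC:
    gc1: float
    gc2: float
    gc3: float
    gc_overall: float
    n_codons: int


def codon_position_gc(cds_sequences: list[str] | dict[str, str],
                      code: GeneticCode = INVERTEBRATE_MITO,
                      exclude_stops: bool = True) -> CodonPositionGC:
    """Percent G+C at codon positions 1/2/3 and pooled over all three."""
    table = count_codons(cds_sequences, code)
    return _position_gc_from_counts(table, exclude_stops=exclude_stops)


def _position_gc_from_counts(table: CodonUsageTable,
                             exclude_stops: bool = True) -> CodonPositionGC:
    gc = [0, 0, 0]
    n = 0
    for codon, count in table.counts.items():
        if exclude_stops and codon in table.code.stop_codons:
            continue
        n += count
        for pos in range(3):
            if codon[pos] in "GC":
                gc[pos] += count
    if n == 0:
        raise ValueError("no codons to score")
    pcts = [100.0 * g / n for g in gc]
    return CodonPositionGC(gc1=pcts[0], gc2=pcts[1], gc3=pcts[2],
                           gc_overall=sum(pcts) / 3.0, n_codons=n)


# ---------------------------------------------------------------------------
# ENC

@dataclass(frozen=True)
class EncResult:
    enc: float
    gc3: float                      # fraction in [0, 1]
    enc_expected_at_gc3: float
    n_codons: int


def enc_expected(gc3: float) -> float:
    """Wright's null ENC at third-position GC content ``s = gc3``."""
    if not 0.0 <= gc3 <= 1.0:
        raise ValueError("gc3 must be a fraction in [0, 1]")
    s = gc3
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def enc(table: CodonUsageTable) -> EncResult:
    """Wright's effective number of codons for a codon-usage table.

    Stop codons are excluded.  Families observed with fewer than 2 codons
    (or with a non-positive homozygosity estimate) are dropped from their
    class average; a synonymy class with no scorable family is imputed as
    the mean of the available class averages.  The result is clamped to the
    code's [n_amino_acids, synonymous_capacity] range.
    """
    code = table.code
    class_f: dict[int, list[float]] = {}
    for aa, codons in code.families.items():
        n = sum(table.counts.get(c, 0) for c in codons)
        if n < 2:
            continue
        sum_p2 = sum((table.counts.get(c, 0) / n) ** 2 for c in codons)
        f_hat = (n * sum_p2 - 1.0) / (n - 1.0)
        if f_hat <= 0.0:
            continue
        class_f.setdefault(len(codons), []).append(f_hat)
    if not class_f:
        raise ValueError("no family with at least 2 observed codons")
    class_sizes = Counter(len(c) for c in code.families.values())
    avail = {k: sum(v) / len(v) for k, v in class_f.items()}
    fallback = sum(avail.values()) / len(avail)
    total = 0.0
    for k, n_aa in sorted(class_sizes.items()):
        total += n_aa / avail.get(k, fallback)
    value = min(max(total, float(code.n_amino_acids)),
                float(code.synonymous_capacity))
    third = table.third_position_counts()
    n3 = sum(third.values())
    gc3 = (third["G"] + third["C"]) / n3 if n3 else 0.0
    non_stop = sum(n for c, n in table.counts.items()
                   if c not in code.stop_codons)
    return EncResult(enc=value, gc3=gc3, enc_expected_at_gc3=enc_expected(gc3),
                     n_codons=non_stop)


def enc_filter(per_gene_enc: list[float],
               threshold: float = 35.0) -> tuple[int, int, float]:
    """Count genes at/below and above an ENC threshold.

    Returns ``(n_at_or_below, n_above, pct_above)``; genes above the
    threshold are the weakly biased ones.
    """
    if not per_gene_enc:
        raise ValueError("empty ENC list")
    n_above = sum(1 for v in per_gene_enc if v > threshold)
    n_total = len(per_gene_enc)
    return n_total - n_above, n_above, 100.0 * n_above / n_total


# ---------------------------------------------------------------------------
# PR2

@dataclass(frozen=True)
class PR2Point:
    x: float | None                  # G3 / (G3 + C3)
    y: float | None                  # A3 / (A3 + T3)


def pr2_point(table: CodonUsageTable) -> PR2Point:
    """Parity-rule-2 coordinates from pooled third-position base counts
    (stop codons excluded).  An undefined component (zero denominator) is
    ``None``; both undefined is an error."""
    third = table.third_position_counts()
    gc = third["G"] + third["C"]
    at = third["A"] + third["U"]
    if gc == 0 and at == 0:
        raise ValueError("no third-position bases to score")
    x = third["G"] / gc if gc else None
    y = third["A"] / at if at else None
    return PR2Point(x=x, y=y)


# ---------------------------------------------------------------------------
# start/stop census and per-gene report

@dataclass(frozen=True)
class StartStopRecord:
    gene: str
    start_codon: str
    stop: str                        # complete stop codon, or remainder
    truncated: bool
    nonstandard_start: bool


def start_stop_census(record: MitogenomeRecord,
                      code: GeneticCode = INVERTEBRATE_MITO
                      ) -> list[StartStopRecord]:
    """Initiation and termination codon of every protein-coding gene.

    Insect mitochondrial PCGs start with ATN (rarely CGA, as in COI) and end
    with a complete UAA/UAG or a truncated T/TA completed to UAA by
    polyadenylation.  Starts outside the ATN set are flagged nonstandard.
    """
    out = []
    for f in sorted(record.features_by_category(PCG), key=lambda f: f.start):
        seq = _to_rna(extract_feature_sequence(record, f))
        if len(seq) < 3:
            logger.warning("PCG %s shorter than one codon", f.name)
            continue
        start = seq[:3]
        remainder = len(seq) % 3
        if remainder:
            stop, truncated = seq[-remainder:], True
        else:
            stop, truncated = seq[-3:], False
        out.append(StartStopRecord(
            gene=f.name, start_codon=start, stop=stop, truncated=truncated,
            nonstandard_start=not (start.startswith("AU")
                                   and start in code.start_codons)))
    return out


def per_gene_stats(record: MitogenomeRecord,
                   code: GeneticCode = INVERTEBRATE_MITO) -> pd.DataFrame:
    """Per-PCG codon statistics: GC1/GC2/GC3/GC, ENC and its null
    expectation, and PR2 coordinates."""
    rows = []
    for f in sorted(record.features_by_category(PCG), key=lambda f: f.start):
        seq = extract_feature_sequence(record, f)
        table = count_codons({f.name: seq}, code)
        if table.n_codons == 0:
            continue
        gc = _position_gc_from_counts(table)
        try:
            e = enc(table)
            enc_val, enc_exp = e.enc, e.enc_expected_at_gc3
        except ValueError:
            enc_val = enc_exp = float("nan")
        p = pr2_point(table)
        rows.append((f.name, table.n_codons, gc.gc1, gc.gc2, gc.gc3,
                     gc.gc_overall, enc_val, enc_exp, p.x, p.y))
    return pd.DataFrame(rows, columns=[
        "Gene", "n_codons", "GC1", "GC2", "GC3", "GC", "ENC", "ENC_expected",
        "PR2_x", "PR2_y"])
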