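"""Annotated circular mitogenome records and their file formats.

The analysis substrate is :class:`MitogenomeRecord`: a circular nucleotide
sequence plus an ordered table of :class:`GeneFeature` annotations.  Internal
coordinates are 0-based half-open; GenBank I/O converts from/to the 1-based
inclusive convention.  A feature spanning the sequence origin is stored as a
single object with ``end > length`` and resolved modulo the genome length.

GenBank and FASTA parsing/serialization is delegated to Biopython's SeqIO;
this module owns coordinate normalization, strand semantics and canonical
gene naming.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from . import registry
from .registry import CONTROL, OTHER, PCG, RRNA, TRNA

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class InputFormatError(ValueError):
    """Raised when an input file cannot be interpreted as a mitogenome."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on the circle.

    ``start``/``end`` are 0-based half-open; ``end`` may exceed the genome
    length for an origin-spanning feature (interpreted modulo length).
    ``strand`` is ``+`` for the majority (J) strand, ``-`` for the minority
    (N) strand.
    """

    name: str
    category: str
    start: int
    end: int
    strand: str
    notes: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start <= 0:
            raise ValueError(f"feature {self.name!r}: empty span "
                             f"[{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.name!r}: strand must be + or -")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MitogenomeRecord:
    """A circular annotated mitochondrial genome."""

    identifier: str
    sequence: str
    features: tuple[GeneFeature, ...] = ()
    is_circular: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputFormatError("empty sequence")
        seq = self.sequence.upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise InputFormatError(f"invalid bases in sequence: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "features", tuple(self.features))
        n = len(seq)
        for f in self.features:
            if not (0 <= f.start < n):
                raise ValueError(f"feature {f.name!r}: start {f.start} "
                                 f"outside [0, {n})")
            if f.width > n:
                raise ValueError(f"feature {f.name!r}: span wider than genome")
            if f.end > n and not self.is_circular:
                raise ValueError(f"feature {f.name!r} spans the origin of a "
                                 "linear record")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def features_by_category(self, category: str) -> tuple[GeneFeature, ...]:
        return tuple(f for f in self.features if f.category == category)

    def feature_by_name(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def sorted_features(self) -> tuple[GeneFeature, ...]:
        return tuple(sorted(self.features, key=lambda f: (f.start, f.end)))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_feature_sequence(record: MitogenomeRecord,
                             feature: GeneFeature) -> str:
    """5'→3' gene sequence: modular slice, reverse-complemented on ``-``."""
    n = record.length
    if feature.width > n:
        raise ValueError("feature span wider than genome")
    if feature.end <= n:
        seq = record.sequence[feature.start:feature.end]
    else:
        seq = record.sequence[feature.start:] + record.sequence[:feature.end - n]
    return reverse_complement(seq) if feature.strand == "-" else seq


def partition_regions(record: MitogenomeRecord,
                      gene_strand: bool = False) -> dict[str, str]:
    """Concatenated sequence of each region class, in genome order.

    Keys are ``PCG``/``tRNA``/``rRNA``/``control``.  By default each gene
    contributes its genome-forward slice so that region composition shares
    one fixed strand with the whole-genome row; ``gene_strand=True`` switches
    to 5'→3' gene sequences instead.
    """
    out: dict[str, str] = {}
    for category in (PCG, TRNA, RRNA, CONTROL):
        parts = []
        for f in sorted(record.features_by_category(category),
                        key=lambda f: f.start):
            if gene_strand:
                parts.append(extract_feature_sequence(record, f))
            else:
                parts.append(extract_feature_sequence(record, replace(f, strand="+")))
        if not parts:
            logger.warning("record %s: no %s features", record.identifier,
                           category)
        out[category] = "".join(parts)
    return out


# ---------------------------------------------------------------------------
# GenBank

_GENBANK_TYPES = {PCG: "CDS", TRNA: "tRNA", RRNA: "rRNA",
                  CONTROL: "D-loop", OTHER: "misc_feature"}


def _feature_name(bio_feature) -> str:
    q = bio_feature.qualifiers
    for key in ("gene", "product", "note", "standard_name"):
        if key in q and q[key]:
            return str(q[key][0])
    return bio_feature.type


def _from_bio_location(loc, n: int) -> tuple[int, int]:
    """Normalize a Biopython location into (start, end) with end>n on wrap."""
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        # origin-spanning join(x..n, 1..k)
        if (len(parts) == 2 and int(parts[1].end) == n
                and int(parts[0].start) == 0):
            return int(parts[1].start), n + int(parts[0].end)
        return int(min(int(p.start) for p in parts)), int(max(int(p.end) for p in parts))
    return int(loc.start), int(loc.end)


def read_genbank(path: str | Path) -> MitogenomeRecord:
    """Read a GenBank flat file into a :class:`MitogenomeRecord`.

    Feature names are normalized through the canonical-name registry;
    unrecognized features keep their label with category ``other``.
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises assorted types
        raise InputFormatError(f"cannot parse GenBank file {path}: {exc}") from exc
    seq = str(rec.seq).upper()
    if not seq:
        raise InputFormatError(f"{path}: record has no sequence")
    n = len(seq)
    circular = rec.annotations.get("topology", "circular") == "circular"
    features = []
    for bf in rec.features:
        if bf.type in ("source", "gene"):
            continue
        name, category = registry.canonical_name(_feature_name(bf))
        if bf.type == "D-loop" and category == OTHER:
            name, category = registry.CONTROL_NAME, CONTROL
        start, end = _from_bio_location(bf.location, n)
        strand = "-" if bf.location.strand == -1 else "+"
        try:
            features.append(GeneFeature(name, category, start, end, strand))
        except ValueError:
            logger.warning("%s: skipping degenerate feature %r", path, name)
    return MitogenomeRecord(identifier=rec.id or rec.name or Path(path).stem,
                            sequence=seq, features=tuple(features),
                            is_circular=circular)


def _to_bio_location(f: GeneFeature, n: int):
    strand = -1 if f.strand == "-" else 1
    if f.end <= n:
        return SimpleLocation(f.start, f.end, strand)
    first = SimpleLocation(f.start, n, strand)
    second = SimpleLocation(0, f.end - n, strand)
    parts = [first, second] if strand == 1 else [second, first]
    return CompoundLocation(parts)


def write_genbank(record: MitogenomeRecord, path: str | Path) -> None:
    """Write a record as a GenBank flat file that round-trips through
    :func:`read_genbank` (identical sequence; same spans/strands/names)."""
    rec = SeqRecord(Seq(record.sequence), id=record.identifier,
                    name=record.identifier[:16].replace(" ", "_"),
                    description="mitochondrial genome")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if record.is_circular else "linear"
    for f in record.features:
        ftype = _GENBANK_TYPES.get(f.category, "misc_feature")
        qualifiers = {"gene": [f.name]}
        if f.category == PCG:
            qualifiers["product"] = [f.name]
        if f.notes:
            qualifiers["note"] = [f.notes]
        rec.features.append(SeqFeature(_to_bio_location(f, record.length),
                                       type=ftype, qualifiers=qualifiers))
    SeqIO.write([rec], str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA + tabular feature file

def write_fasta(record: MitogenomeRecord, path: str | Path) -> None:
    rec = SeqRecord(Seq(record.sequence), id=record.identifier, description="")
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path: str | Path,
               features: tuple[GeneFeature, ...] = ()) -> MitogenomeRecord:
    try:
        rec = SeqIO.read(str(path), "fasta")
    except Exception as exc:
        raise InputFormatError(f"cannot parse FASTA file {path}: {exc}") from exc
    return MitogenomeRecord(identifier=rec.id, sequence=str(rec.seq),
                            features=features)


FEATURE_TABLE_HEADER = "# name\tcategory\tstart\tend\tstrand (0-based half-open)"


def write_feature_table(record: MitogenomeRecord, path: str | Path) -> None:
    lines = [FEATURE_TABLE_HEADER]
    for f in record.features:
        lines.append(f"{f.name}\t{f.category}\t{f.start}\t{f.end}\t{f.strand}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_feature_table(path: str | Path) -> tuple[GeneFeature, ...]:
    features = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, category, start, end, strand = line.split("\t")
        features.append(GeneFeature(name, category, int(start), int(end),
                                    strand))
    return tuple(features)


def read_genome(path: str | Path) -> MitogenomeRecord:
    """Read a genome by extension: ``.gb``/``.gbk``/``.genbank`` as GenBank,
    ``.fa``/``.fasta`` as FASTA with an optional sibling ``.features.tsv``."""
    p = Path(path)
    if p.suffix.lower() in (".gb", ".gbk", ".genbank"):
        return read_genbank(p)
    features: tuple[GeneFeature, ...] = ()
    sibling = p.with_suffix(".features.tsv")
    if sibling.exists():
        features = read_feature_table(sibling)
    return read_fasta(p, features)
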