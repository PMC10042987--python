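"""Intergenic regions and AT-rich insertion detection.

Long near-pure-AT tracts inserted between genes (e.g. at tRNA cluster
junctions) are a hallmark of rearranged moth mitogenomes.  Detection here is
annotation-gap based: enumerate the maximal gaps between consecutive
annotated features around the circle, then flag gaps that are both long and
AT-rich.  The control region counts as a feature, so it is never itself
reported as a gap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .genome_io import MitogenomeRecord
from .utils import round_half_up


@dataclass(frozen=True)
class IntergenicRegion:
    left_gene: str
    right_gene: str
    start: int                      # 0-based half-open, modular
    end: int                        # may exceed genome length on origin wrap
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ATInsertion:
    left_gene: str
    right_gene: str
    start: int
    end: int
    length: int
    at_fraction: float


def intergenic_regions(record: MitogenomeRecord) -> list[IntergenicRegion]:
    """Maximal gaps between consecutive features around the circle.

    Overlapping or abutting features produce no gap.  Gap coordinates are
    genome-forward; a gap spanning the origin has ``end > length``.
    """
    feats = record.sorted_features()
    if not feats:
        raise ValueError("record has no features")
    n = record.length
    out: list[IntergenicRegion] = []
    # walk features in start order, tracking the furthest covered point
    cur_end = feats[0].end
    cur_gene = feats[0].name
    for f in feats[1:]:
        if f.start > cur_end:
            seq = record.sequence[cur_end:f.start]
            out.append(IntergenicRegion(cur_gene, f.name, cur_end, f.start,
                                        seq))
        if f.end > cur_end:
            cur_end, cur_gene = f.end, f.name
    # wrap-around gap back to the first feature
    first = feats[0]
    if record.is_circular:
        wrap_start = first.start + n
        if wrap_start > cur_end:
            start_mod = cur_end % n
            seq = (record.sequence[start_mod:] + record.sequence)[:wrap_start
                                                                  - cur_end]
            out.append(IntergenicRegion(cur_gene, first.name, cur_end,
                                        wrap_start, seq))
    return out


def at_fraction(sequence: str) -> float:
    counted = sum(sequence.upper().count(b) for b in "ACGT")
    if counted == 0:
        return 0.0
    return sum(sequence.upper().count(b) for b in "AT") / counted


def detect_at_insertions(record: MitogenomeRecord, min_length: int = 100,
                         min_at: float = 0.90) -> list[ATInsertion]:
    """Intergenic gaps at least ``min_length`` wide with AT fraction at
    least ``min_at``, sorted by genome position."""
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    if not 0.0 <= min_at <= 1.0:
        raise ValueError("min_at must be a fraction in [0, 1]")
    out = []
    for gap in intergenic_regions(record):
        frac = at_fraction(gap.sequence)
        if gap.length >= min_length and frac >= min_at:
            out.append(ATInsertion(gap.left_gene, gap.right_gene,
                                   gap.start, gap.end, gap.length, frac))
    return sorted(out, key=lambda i: i.start)


def insertions_bed(record: MitogenomeRecord,
                   insertions: list[ATInsertion]) -> str:
    """BED (0-based half-open) lines; an origin-wrapping insertion is split
    into its two on-circle segments."""
    n = record.length
    lines = []
    for ins in insertions:
        name = f"{ins.left_gene}|{ins.right_gene}"
        score = int(round_half_up(100 * ins.at_fraction, 0))
        if ins.end <= n:
            spans = [(ins.start, ins.end)]
        else:
            spans = [(ins.start, n), (0, ins.end - n)]
        for s, e in spans:
            lines.append(f"{record.identifier}\t{s}\t{e}\t{name}\t{score}\t.")
    return "\n".join(lines) + ("\n" if lines else "")


def write_insertions_bed(record: MitogenomeRecord,
                         insertions: list[ATInsertion],
                         path: str | Path) -> None:
    Path(path).write_text(insertions_bed(record, insertions))
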