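"""Gene-order extraction and rearrangement analysis on the circle.

A mitogenome's gene order is a signed circular permutation of canonical gene
labels (sign = coding strand).  Rearrangements between two genomes are
quantified as adjacency breakpoints — the neighbor pairs of one order absent
from the other — and classified from the minimal set of genes whose removal
reconciles the orders: an adjacent transposition is a swap, a relocation with
unchanged sign a translocation, a sign change an inversion.

Unsigned adjacencies are the default (tRNA cluster rearrangements in moths
are order-level findings); signed mode tracks orientation for inversion
detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

from .genome_io import MitogenomeRecord
from .registry import PCG, RRNA, TRNA

DEFAULT_CATEGORIES = frozenset({PCG, TRNA, RRNA})


@dataclass(frozen=True)
class GeneOrder:
    """A signed circular (or linear) permutation of gene labels."""

    labels: tuple[str, ...]          # canonical names, in order
    signs: tuple[int, ...]           # +1 / -1 per label
    circular: bool = True
    anchor: str | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.signs):
            raise ValueError("labels and signs differ in length")
        dupes = {x for x in self.labels if self.labels.count(x) > 1}
        if dupes:
            raise ValueError(f"duplicate gene labels: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_signed_labels(cls, signed: list[str], circular: bool = True,
                           anchor: str | None = None) -> "GeneOrder":
        """Parse ``["trnM", "-trnQ", ...]`` (minus prefix = minority strand)."""
        labels, signs = [], []
        for s in signed:
            s = s.strip()
            if s.startswith("-"):
                labels.append(s[1:])
                signs.append(-1)
            else:
                labels.append(s.lstrip("+"))
                signs.append(1)
        return cls(tuple(labels), tuple(signs), circular=circular,
                   anchor=anchor)

    def restrict(self, keep) -> "GeneOrder":
        """Sub-order over the labels in ``keep`` (e.g. to drop the control
        region, or compare tRNAs only), preserving circular order."""
        pairs = [(l, s) for l, s in zip(self.labels, self.signs) if l in keep]
        if not pairs:
            raise ValueError("restriction removes every gene")
        labels, signs = zip(*pairs)
        anchor = self.anchor if self.anchor in keep else None
        return GeneOrder(labels, signs, circular=self.circular, anchor=anchor)

    def signed_labels(self) -> list[str]:
        return [("-" if s < 0 else "") + l
                for l, s in zip(self.labels, self.signs)]

    def normalized(self, anchor: str | None = None) -> "GeneOrder":
        """Rotate so the anchor comes first with positive orientation; a
        negatively oriented anchor flips the whole circle (reflection with
        sign change), which preserves the genome it denotes."""
        anchor = anchor or self.anchor or self.labels[0]
        if anchor not in self.labels:
            raise ValueError(f"anchor {anchor!r} not in order")
        if not self.circular:
            return self
        i = self.labels.index(anchor)
        labels = self.labels[i:] + self.labels[:i]
        signs = self.signs[i:] + self.signs[:i]
        if signs[0] < 0:
            labels = (labels[0],) + labels[:0:-1]
            signs = tuple(-s for s in (signs[0],) + signs[:0:-1])
        return GeneOrder(labels, signs, circular=True, anchor=anchor)


def extract_gene_order(record: MitogenomeRecord,
                       categories: frozenset[str] = DEFAULT_CATEGORIES,
                       anchor: str = "trnM") -> GeneOrder:
    """Gene order of a record: genes of the requested categories sorted by
    start coordinate around the circle, sign from strand, rotated to the
    anchor (default trnM; falls back to COI, then the first gene)."""
    feats = [f for f in record.sorted_features() if f.category in categories]
    if not feats:
        raise ValueError("record has no features in the requested categories")
    labels = tuple(f.name for f in feats)
    signs = tuple(1 if f.strand == "+" else -1 for f in feats)
    order = GeneOrder(labels, signs, circular=record.is_circular)
    for candidate in (anchor, "COI", labels[0]):
        if candidate in labels:
            return order.normalized(candidate)
    return order


# ---------------------------------------------------------------------------
# adjacencies and breakpoints

def adjacency_set(order: GeneOrder, signed: bool = False) -> frozenset:
    """Neighbor pairs around the circle (all |order| of them when circular,
    |order|-1 when linear).

    Unsigned adjacencies are unordered label pairs.  A signed adjacency is
    the oriented junction (a→b with orientations), canonicalized with its
    reading on the opposite strand (-b→-a).
    """
    n = len(order)
    if n < 2:
        raise ValueError("need at least 2 genes")
    idx = range(n) if order.circular else range(n - 1)
    pairs = []
    for i in idx:
        j = (i + 1) % n
        if signed:
            fwd = (order.labels[i], order.signs[i],
                   order.labels[j], order.signs[j])
            rev = (order.labels[j], -order.signs[j],
                   order.labels[i], -order.signs[i])
            pairs.append(min(fwd, rev))
        else:
            pairs.append(frozenset((order.labels[i], order.labels[j])))
    return frozenset(pairs)


def _require_same_labels(a: GeneOrder, b: GeneOrder) -> None:
    sa, sb = set(a.labels), set(b.labels)
    if sa != sb:
        only_a, only_b = sorted(sa - sb), sorted(sb - sa)
        raise ValueError(f"gene sets differ: only in first={only_a}, "
                         f"only in second={only_b}")


def breakpoint_distance(order1: GeneOrder, order2: GeneOrder,
                        signed: bool = False) -> int:
    """Number of adjacencies of ``order1`` absent from ``order2``
    (symmetric, since both orders have the same number of adjacencies)."""
    _require_same_labels(order1, order2)
    return len(adjacency_set(order1, signed) - adjacency_set(order2, signed))


# ---------------------------------------------------------------------------
# diffing and classification

@dataclass(frozen=True)
class RearrangementReport:
    breakpoints: int
    shared_adjacencies: int
    moved_genes: frozenset[str]
    classification: frozenset[str]   # subset of {swap, translocation, inversion, none}

    def to_dict(self) -> dict:
        return {"breakpoints": self.breakpoints,
                "shared_adjacencies": self.shared_adjacencies,
                "moved_genes": sorted(self.moved_genes),
                "classification": sorted(self.classification)}


def _circular_equal(seq1: tuple, seq2: tuple) -> bool:
    if len(seq1) != len(seq2):
        return False
    if not seq1:
        return True
    if seq1[0] not in seq2:
        return False
    i = seq2.index(seq1[0])
    return seq2[i:] + seq2[:i] == seq1


def _without(order: GeneOrder, removed: frozenset[str],
             signed: bool = False) -> tuple:
    if signed:
        return tuple((l, s) for l, s in zip(order.labels, order.signs)
                     if l not in removed)
    return tuple(l for l in order.labels if l not in removed)


def diff_orders(order1: GeneOrder, order2: GeneOrder,
                signed: bool = False) -> RearrangementReport:
    """Compare two gene orders and classify the observable difference.

    ``moved_genes`` is a minimal set of genes whose removal makes the orders
    identical up to rotation — found exactly by subset search (up to size 4)
    over the genes incident to broken adjacencies, else greedily.
    """
    _require_same_labels(order1, order2)
    adj1 = adjacency_set(order1, signed)
    adj2 = adjacency_set(order2, signed)
    broken = adj1 - adj2
    shared = len(adj1 & adj2)
    sign1 = dict(zip(order1.labels, order1.signs))
    sign2 = dict(zip(order2.labels, order2.signs))
    flipped = {l for l in order1.labels if sign1[l] != sign2[l]}

    if not broken and not flipped:
        return RearrangementReport(0, shared, frozenset(),
                                   frozenset({"none"}))

    candidates = sorted({g for pair in broken
                         for g in (pair if not signed else (pair[0], pair[2]))}
                        | flipped)
    moved: frozenset[str] | None = None
    for k in range(1, min(4, len(candidates)) + 1):
        for combo in combinations(candidates, k):
            removed = frozenset(combo)
            if _circular_equal(_without(order1, removed, signed),
                               _without(order2, removed, signed)):
                moved = removed
                break
        if moved is not None:
            break
    if moved is None:
        # greedy fallback: peel off the gene touching the most broken pairs
        remaining = set(candidates)
        removed: set[str] = set()
        while remaining:
            g = max(remaining, key=lambda g: sum(g in (p if not signed else
                                                       (p[0], p[2]))
                                                 for p in broken))
            removed.add(g)
            remaining.discard(g)
            if _circular_equal(_without(order1, frozenset(removed), signed),
                               _without(order2, frozenset(removed), signed)):
                break
        moved = frozenset(removed)

    classes: set[str] = set()
    if flipped:
        classes.add("inversion")
    # adjacent transposition: swapping two neighboring genes of order1
    # reproduces order2's label sequence
    n = len(order1)
    labels1 = list(order1.labels)
    for i in range(n if order1.circular else n - 1):
        j = (i + 1) % n
        swapped = labels1.copy()
        swapped[i], swapped[j] = swapped[j], swapped[i]
        if _circular_equal(tuple(swapped), order2.labels):
            classes.add("swap")
            break
    if moved and not classes:
        classes.add("translocation")
    if broken and "swap" not in classes and "inversion" not in classes:
        classes.add("translocation")
    return RearrangementReport(len(broken), shared, moved,
                               frozenset(classes))


# ---------------------------------------------------------------------------
# text format: one genome per line, comma-separated signed labels

def write_orders(orders: dict[str, GeneOrder], path: str | Path) -> None:
    lines = [f"{name}\t" + ",".join(o.signed_labels())
             for name, o in orders.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_orders(path: str | Path) -> dict[str, GeneOrder]:
    out: dict[str, GeneOrder] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "\t" in line:
            name, body = line.split("\t", 1)
        else:
            name, body = f"order{len(out) + 1}", line
        out[name] = GeneOrder.from_signed_labels(body.split(","))
    return out
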