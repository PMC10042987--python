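"""Seeded generator of annotated circular mitogenomes with known truth.

The simulator emits a moth-like mitogenome — 37 genes (13 PCGs on known
strands, 22 tRNAs, 2 rRNAs) plus a control region in a configurable circular
order, within the 15–17.1 kb length regime — together with a
:class:`SimulationTruth` sidecar recording exactly what was generated:
the gene order, per-gene codon tallies, per-region composition (targets and
realized recounts) and any planted AT-repeat insertions.  Every statistic in
this package can therefore be tested as a parameter-recovery problem.

Protein-coding genes are built codon by codon (uniform amino-acid choice,
configurable within-family codon weights defaulting to the published litchi
fruit borer usage), with ATN starts (COI forced to CGA by default), complete
UAA/UAG stops or a truncated T.  RNA genes, the control region and small
intergenic spacers are i.i.d. draws from per-region base weights.  All
randomness flows from one integer seed through numpy's Generator, so the
same config yields a byte-identical genome on any platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from . import registry
from .codon_usage import INVERTEBRATE_MITO, GeneticCode
from .composition import base_composition
from .genome_io import (GeneFeature, MitogenomeRecord, partition_regions,
                        reverse_complement)
from .intergenic import at_fraction
from .reference_data import CODON_COUNTS, COMPOSITION
from .registry import CONTROL, PCG, RRNA, TRNA

_RNA_TO_DNA = str.maketrans("U", "T")

#: Default gene lengths (bp), chosen near the reported moth gene sizes;
#: PCG lengths are ≡ 0 mod 3 (complete stop) or ≡ 1 mod 3 (truncated T).
DEFAULT_GENE_LENGTHS = {
    "ND2": 1023, "COI": 1536, "COII": 685, "ATP8": 162, "ATP6": 678,
    "COIII": 790, "ND3": 354, "ND5": 1735, "ND4": 1341, "ND4L": 297,
    "ND6": 531, "CYTB": 1141, "ND1": 936,
    "trnF": 64, "trnL1": 74,
    "trnM": 67, "trnQ": 67, "trnW": 67, "trnL2": 67, "trnK": 67, "trnA": 67,
    "trnR": 67, "trnS1": 67, "trnE": 67, "trnH": 67, "trnT": 67, "trnP": 67,
    "trnS2": 67, "trnV": 67,
    "trnI": 66, "trnC": 66, "trnY": 66, "trnD": 66, "trnG": 66, "trnN": 66,
    "rrnL": 1335, "rrnS": 763, "D-loop": 1389,
}

#: Default per-region base weights (genome-forward A/T/C/G probabilities),
#: set to the reported per-region composition; spacers follow the control
#: region's AT-rich regime.
DEFAULT_BASE_WEIGHTS = {
    TRNA: {b: COMPOSITION["tRNAs"][b] / 100 for b in "ATCG"},
    RRNA: {b: COMPOSITION["rRNAs"][b] / 100 for b in "ATCG"},
    CONTROL: {b: COMPOSITION["D-loop"][b] / 100 for b in "ATCG"},
    "spacer": {b: COMPOSITION["D-loop"][b] / 100 for b in "ATCG"},
}

#: Default within-family codon weights: the published litchi fruit borer
#: codon counts (strongly A/U-ending biased).
DEFAULT_CODON_WEIGHTS = {c: float(n) for c, n in CODON_COUNTS.items()}


def _load_order(name: str) -> list[str]:
    text = resources.files("mitocomp.data").joinpath(name).read_text()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            return line.split(",")
    raise ValueError(f"no order found in {name}")


def gene_plan(order_name: str = "ancestral") -> tuple[tuple[str, str, int, str], ...]:
    """Default genome plan: ``(name, category, length, strand)`` per gene,
    from the shipped gene-order presets (``ancestral`` or ``conopomorpha``)."""
    signed = _load_order(f"{order_name}_order.txt")
    plan = []
    for s in signed:
        strand = "-" if s.startswith("-") else "+"
        name = s.lstrip("+-")
        plan.append((name, registry.category_for(name),
                     DEFAULT_GENE_LENGTHS[name], strand))
    return tuple(plan)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything that determines a simulated genome."""

    seed: int
    plan: tuple[tuple[str, str, int, str], ...] = field(
        default_factory=gene_plan)
    base_weights: dict = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in DEFAULT_BASE_WEIGHTS.items()})
    codon_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_CODON_WEIGHTS))
    planted_insertions: tuple[tuple[tuple[str, str], int, float], ...] = ()
    spacer_range: tuple[int, int] = (1, 6)
    coi_cga_start: bool = True
    code_id: int = 5
    identifier: str = "simulated-mitogenome"

    def __post_init__(self) -> None:
        for region, w in self.base_weights.items():
            total = sum(w.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"base weights for {region} sum to {total}")
        for name, _cat, length, _strand in self.plan:
            if length <= 0:
                raise ValueError(f"gene {name}: non-positive length")
            if registry.category_for(name) == PCG and length % 3 == 2:
                raise ValueError(f"PCG {name}: length must be 0 or 1 mod 3")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Flat key-value config: ``seed = 1``, ``preset = conopomorpha``,
        ``insert = trnR|trnA,205,1.0`` (repeatable), ``spacer = 1,6``,
        ``coi_cga_start = true``."""
        seed = 0
        preset = "ancestral"
        inserts: list[tuple[tuple[str, str], int, float]] = []
        spacer = (1, 6)
        coi = True
        for line in Path(path).read_text().splitlines():
            line = line.split("#")[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip().lower(), value.strip()
            if key == "seed":
                seed = int(value)
            elif key == "preset":
                preset = value
            elif key == "insert":
                junction, length, frac = value.split(",")
                left, right = junction.split("|")
                inserts.append(((left.strip(), right.strip()),
                                int(length), float(frac)))
            elif key == "spacer":
                lo, hi = value.split(",")
                spacer = (int(lo), int(hi))
            elif key == "coi_cga_start":
                coi = value.lower() in ("1", "true", "yes")
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cls(seed=seed, plan=gene_plan(preset),
                   planted_insertions=tuple(inserts), spacer_range=spacer,
                   coi_cga_start=coi)


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside a simulated genome."""

    seed: int
    gene_order: list[str]                       # signed labels, genome order
    target_base_weights: dict                   # region -> base -> prob
    codon_counts: dict                          # gene -> codon -> count
    truncated_genes: list[str]
    insertions: list[dict]                      # left/right/length/at_fraction
    region_lengths: dict                        # region label -> bp
    realized_composition: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, sort_keys=True)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def generate_cds(n_codons: int, codon_weights: dict[str, float],
                 code: GeneticCode = INVERTEBRATE_MITO,
                 truncated_stop: bool = False,
                 rng: np.random.Generator | None = None,
                 seed: int | None = None,
                 start_codon: str | None = None) -> tuple[str, dict[str, int]]:
    """Draw a framed CDS of ``n_codons`` complete codons (start + middles +
    stop unless truncated) plus a trailing T when ``truncated_stop``.

    Middle codons are i.i.d.: a uniform amino-acid choice, then a codon from
    the family's (normalized) weights.  Returns the DNA string and the codon
    tally.  Raises if some amino-acid family has zero total weight.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_codons < 2 and not truncated_stop:
        raise ValueError("need at least a start and a stop codon")
    fam_codons: list[list[str]] = []
    fam_probs: list[np.ndarray] = []
    for aa, codons in code.families.items():
        w = np.array([codon_weights.get(c, 0.0) for c in codons])
        if w.sum() <= 0:
            raise ValueError(f"all-zero codon weights for family {aa}")
        fam_codons.append(list(codons))
        fam_probs.append(w / w.sum())
    counts: dict[str, int] = {}
    parts: list[str] = []

    def emit(codon_rna: str) -> None:
        counts[codon_rna] = counts.get(codon_rna, 0) + 1
        parts.append(codon_rna.translate(_RNA_TO_DNA))

    emit(start_codon or ("AUU" if rng.random() < 0.5 else "AUG"))
    n_middle = n_codons - 1 - (0 if truncated_stop else 1)
    fams = rng.integers(0, len(fam_codons), size=n_middle)
    for f in fams:
        emit(fam_codons[f][rng.choice(len(fam_codons[f]), p=fam_probs[f])])
    if truncated_stop:
        parts.append("T")
    else:
        stops = sorted(code.stop_codons)
        w = np.array([codon_weights.get(c, 1.0) for c in stops])
        w = w / w.sum() if w.sum() > 0 else np.full(len(stops), 1 / len(stops))
        emit(stops[rng.choice(len(stops), p=w)])
    return "".join(parts), counts


def _draw_bases(rng: np.random.Generator, weights: dict[str, float],
                length: int) -> str:
    bases = np.array(list("ATCG"))
    p = np.array([weights[b] for b in "ATCG"])
    return "".join(bases[rng.choice(4, size=length, p=p / p.sum())])


def simulate_mitogenome(config: SimulationConfig
                        ) -> tuple[MitogenomeRecord, SimulationTruth]:
    """Generate a genome and its truth sidecar, deterministically from the
    config's seed."""
    rng = np.random.default_rng(config.seed)
    code = GeneticCode.from_table(config.code_id)
    parts: list[str] = []
    features: list[GeneFeature] = []
    codon_counts: dict[str, dict[str, int]] = {}
    truncated: list[str] = []
    pos = 0
    lo, hi = config.spacer_range
    for name, category, length, strand in config.plan:
        if category == PCG:
            trunc = length % 3 == 1
            start = "CGA" if (name == "COI" and config.coi_cga_start) else None
            gene_seq, counts = generate_cds(
                length // 3, config.codon_weights, code, truncated_stop=trunc,
                rng=rng, start_codon=start)
            assert len(gene_seq) == length
            codon_counts[name] = counts
            if trunc:
                truncated.append(name)
            genome_seq = (reverse_complement(gene_seq) if strand == "-"
                          else gene_seq)
        else:
            weights = config.base_weights.get(
                category, config.base_weights.get("spacer"))
            genome_seq = _draw_bases(rng, weights, length)
        features.append(GeneFeature(name, category, pos, pos + length, strand))
        parts.append(genome_seq)
        pos += length
        spacer_len = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
        if spacer_len:
            parts.append(_draw_bases(rng, config.base_weights["spacer"],
                                     spacer_len))
            pos += spacer_len
    record = MitogenomeRecord(identifier=config.identifier,
                              sequence="".join(parts),
                              features=tuple(features))
    truth = SimulationTruth(
        seed=config.seed,
        gene_order=[("-" if s == "-" else "") + n
                    for n, _c, _l, s in config.plan],
        target_base_weights={k: dict(v)
                             for k, v in config.base_weights.items()},
        codon_counts=codon_counts,
        truncated_genes=truncated,
        insertions=[],
        region_lengths={},
    )
    for junction, length, frac in config.planted_insertions:
        record = plant_insertion(record, junction, length, frac,
                                 seed=int(rng.integers(0, 2**31 - 1)))
        truth.insertions.append({"left": junction[0], "right": junction[1],
                                 "length": length, "at_fraction": frac})
    regions = partition_regions(record)
    truth.region_lengths = {cat: len(seq) for cat, seq in regions.items()
                            if seq}
    truth.region_lengths["Mitogenome"] = record.length
    for label, seq in [("Mitogenome", record.sequence)] + list(regions.items()):
        if not seq:
            continue
        row = base_composition(seq)
        truth.realized_composition[label] = {
            "A": row.pct_a, "T": row.pct_t, "C": row.pct_c, "G": row.pct_g}
    return record, truth


def plant_insertion(record: MitogenomeRecord, junction: tuple[str, str],
                    length: int, at_fraction_target: float = 1.0,
                    seed: int = 0) -> MitogenomeRecord:
    """Insert an AT-repeat tract of ``length`` bases at the junction between
    two adjacent features (pair accepted in either order); every downstream
    feature shifts right.  A zero-length insertion returns the record
    unchanged."""
    if length < 0:
        raise ValueError("negative insertion length")
    if length == 0:
        return record
    feats = record.sorted_features()
    wanted = frozenset(junction)
    point = None
    for i, f in enumerate(feats):
        g = feats[(i + 1) % len(feats)]
        if frozenset((f.name, g.name)) == wanted:
            point = g.start if i + 1 < len(feats) else 0
            break
    if point is None:
        raise ValueError(f"no junction between {junction[0]!r} and "
                         f"{junction[1]!r} in record")
    for f in record.features:
        if f.start < point < f.end or (f.end > record.length
                                       and point < f.end - record.length):
            raise ValueError(f"feature {f.name} spans the insertion point")
    rng = np.random.default_rng(seed)
    tract = list(("TA" * (length // 2 + 1))[:length])
    for i in range(length):
        if rng.random() > at_fraction_target:
            tract[i] = "G" if rng.random() < 0.5 else "C"
    seq = record.sequence[:point] + "".join(tract) + record.sequence[point:]
    new_features = tuple(
        replace(f, start=f.start + length, end=f.end + length)
        if f.start >= point else f
        for f in record.features)
    return MitogenomeRecord(identifier=record.identifier, sequence=seq,
                            features=new_features,
                            is_circular=record.is_circular)


def conopomorpha_config(seed: int) -> SimulationConfig:
    """Preset emulating the litchi fruit borer variant: trnA/trnR swapped
    within the trnA–trnF cluster and pure-AT tracts of 205/178/423 bp at the
    three reported junctions."""
    return SimulationConfig(
        seed=seed, plan=gene_plan("conopomorpha"),
        planted_insertions=(
            (("trnR", "trnA"), 205, 1.0),
            (("trnE", "trnF"), 178, 1.0),
            (("trnS2", "ND1"), 423, 1.0),
        ),
        # genes abut directly so each planted tract is the whole gap and is
        # recovered at its exact length
        spacer_range=(0, 0),
        identifier="simulated-conopomorpha")


def ancestral_config(seed: int) -> SimulationConfig:
    """Preset with the unrearranged lepidopteran gene order, no insertions."""
    return SimulationConfig(seed=seed, plan=gene_plan("ancestral"),
                            identifier="simulated-ancestral")
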