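"""Canonical gene-name registry for insect mitogenomes.

Annotation pipelines label the same 37 mitochondrial genes in many styles
(``COX1`` vs ``COI`` vs ``cytochrome c oxidase subunit I``; ``trnL(CUN)`` vs
``trnL1``; ``12S rRNA`` vs ``rrnS``).  Every feature name entering the package
is mapped through this registry so that downstream statistics, gene-order
comparisons and junction lookups all speak one vocabulary.

Unrecognized names are preserved verbatim with category ``other`` and are
excluded from category-based statistics.
"""

from __future__ import annotations

import re

PCG = "PCG"
TRNA = "tRNA"
RRNA = "rRNA"
CONTROL = "control"
OTHER = "other"

#: The 13 protein-coding genes of the insect mitogenome.
PCG_NAMES = (
    "ND2", "COI", "COII", "ATP8", "ATP6", "COIII", "ND3",
    "ND5", "ND4", "ND4L", "ND6", "CYTB", "ND1",
)

#: The 22 tRNA genes (Leu and Ser each have two isoacceptors).
TRNA_NAMES = (
    "trnM", "trnI", "trnQ", "trnW", "trnC", "trnY", "trnL2", "trnK", "trnD",
    "trnG", "trnA", "trnR", "trnN", "trnS1", "trnE", "trnF", "trnH", "trnT",
    "trnP", "trnS2", "trnL1", "trnV",
)

RRNA_NAMES = ("rrnL", "rrnS")
CONTROL_NAME = "D-loop"

CATEGORY_OF = {name: PCG for name in PCG_NAMES}
CATEGORY_OF.update({name: TRNA for name in TRNA_NAMES})
CATEGORY_OF.update({name: RRNA for name in RRNA_NAMES})
CATEGORY_OF[CONTROL_NAME] = CONTROL

# one-letter / three-letter amino acid for the unambiguous tRNAs
_AA_TRNA = {
    "ala": "trnA", "arg": "trnR", "asn": "trnN", "asp": "trnD", "cys": "trnC",
    "gln": "trnQ", "glu": "trnE", "gly": "trnG", "his": "trnH", "ile": "trnI",
    "lys": "trnK", "met": "trnM", "phe": "trnF", "pro": "trnP", "thr": "trnT",
    "trp": "trnW", "tyr": "trnY", "val": "trnV",
}

# anticodons distinguishing the Leu/Ser isoacceptors (DNA or RNA spelling)
_ANTICODON_TRNA = {
    # trnL1 reads CUN codons (anticodon UAG); trnL2 reads UUR (anticodon UAA)
    "l-cun": "trnL1", "l-tag": "trnL1", "l-uag": "trnL1", "l1": "trnL1",
    "l-uur": "trnL2", "l-taa": "trnL2", "l-uaa": "trnL2", "l2": "trnL2",
    # trnS1 reads AGN codons (anticodon GCU/UCU); trnS2 reads UCN (UGA)
    "s-agn": "trnS1", "s-gct": "trnS1", "s-gcu": "trnS1",
    "s-tct": "trnS1", "s-ucu": "trnS1", "s1": "trnS1",
    "s-ucn": "trnS2", "s-tga": "trnS2", "s-uga": "trnS2", "s2": "trnS2",
}

_SYNONYMS = {
    # protein-coding genes
    "co1": "COI", "cox1": "COI", "coxi": "COI", "coi": "COI",
    "cytochromeoxidasesubunit1": "COI",
    "cytochromecoxidasesubunit1": "COI", "cytochromecoxidasesubuniti": "COI",
    "co2": "COII", "cox2": "COII", "coxii": "COII", "coii": "COII",
    "cytochromeoxidasesubunit2": "COII",
    "cytochromecoxidasesubunit2": "COII", "cytochromecoxidasesubunitii": "COII",
    "co3": "COIII", "cox3": "COIII", "coxiii": "COIII", "coiii": "COIII",
    "cytochromeoxidasesubunit3": "COIII",
    "cytochromecoxidasesubunit3": "COIII",
    "cytochromecoxidasesubunitiii": "COIII",
    "cob": "CYTB", "cytb": "CYTB", "cytochromeb": "CYTB",
    "atp6": "ATP6", "atpase6": "ATP6", "atpsynthasef0subunit6": "ATP6",
    "atp8": "ATP8", "atpase8": "ATP8", "atpsynthasef0subunit8": "ATP8",
    # ribosomal RNAs
    "rrnl": "rrnL", "rrn16": "rrnL", "16s": "rrnL", "16srrna": "rrnL",
    "16sribosomalrna": "rrnL", "lrrna": "rrnL",
    "largesubunitribosomalrna": "rrnL",
    "rrns": "rrnS", "rrn12": "rrnS", "12s": "rrnS", "12srrna": "rrnS",
    "12sribosomalrna": "rrnS", "srrna": "rrnS",
    "smallsubunitribosomalrna": "rrnS",
    # control region
    "dloop": "D-loop", "controlregion": "D-loop", "atrichregion": "D-loop",
    "at-richregion": "D-loop", "a+trichregion": "D-loop",
    "a+t-richregion": "D-loop", "cr": "D-loop",
}
for _n in PCG_NAMES:
    _SYNONYMS[_n.lower()] = _n
    if _n.startswith("ND"):
        _SYNONYMS["nad" + _n[2:].lower()] = _n
        _SYNONYMS["nadh" + _n[2:].lower()] = _n
        _SYNONYMS[f"nadhdehydrogenasesubunit{_n[2:].lower()}"] = _n
for _n in TRNA_NAMES:
    _SYNONYMS[_n.lower()] = _n


def _squash(name: str) -> str:
    return re.sub(r"[\s_'\"()\[\]]+", "", name).lower()


def canonical_name(raw: str) -> tuple[str, str]:
    """Map a raw feature label to ``(canonical_name, category)``.

    Unresolvable labels come back unchanged with category ``other``.
    Leu/Ser tRNAs lacking an isoacceptor mark (anticodon or 1/2 suffix)
    cannot be placed and are treated as unresolved.
    """
    raw = raw.strip()
    if not raw:
        return raw, OTHER
    squashed = _squash(raw)
    if squashed in _SYNONYMS:
        name = _SYNONYMS[squashed]
        return name, CATEGORY_OF[name]

    # tRNA spellings: tRNA-Met, trnM, trnL(CUN), trnS-UCU, trn-S1 ...
    m = re.match(r"(?:trna|trn)[-_\s]?(.+)$", raw, flags=re.IGNORECASE)
    if m:
        rest = m.group(1).strip()
        key = re.sub(r"[\s_()]+", "-", rest).strip("-").lower()
        key = re.sub(r"-+", "-", key)
        if key in _ANTICODON_TRNA:
            return _ANTICODON_TRNA[key], TRNA
        aa = key.split("-")[0]
        if aa in _AA_TRNA:
            return _AA_TRNA[aa], TRNA
        one = {"a": "trnA", "r": "trnR", "n": "trnN", "d": "trnD",
               "c": "trnC", "q": "trnQ", "e": "trnE", "g": "trnG",
               "h": "trnH", "i": "trnI", "k": "trnK", "m": "trnM",
               "f": "trnF", "p": "trnP", "t": "trnT", "w": "trnW",
               "y": "trnY", "v": "trnV"}
        if key in one:
            return one[key], TRNA
    return raw, OTHER


def category_for(name: str) -> str:
    """Category of an already-canonical name (``other`` if unknown)."""
    return CATEGORY_OF.get(name, OTHER)
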