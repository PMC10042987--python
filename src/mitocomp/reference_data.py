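"""Published reference values for the litchi fruit borer mitogenome.

These are the reported characterization numbers for the *Conopomorpha
sinensis* mitochondrial genome (GenBank OK310517, 17,050 bp): the per-region
base-composition table and the protein-coding codon-usage table.  They serve
three roles: regression anchors for the statistics in this package, default
bias targets for the synthetic-genome simulator, and inputs for reproduction
runs when the accession itself is not at hand.
"""

from __future__ import annotations

GENOME_LENGTH = 17_050
PCG_TOTAL_LENGTH = 11_205

#: Reported per-region composition: length and percent A/T/C/G, with the
#: published 2-dp AT/GC skews for cross-checking.
COMPOSITION = {
    "Mitogenome": {"length": 17_050, "A": 42.25, "T": 41.27, "C": 9.62,
                   "G": 6.86, "AT": 83.52, "GC": 16.48,
                   "at_skew": 0.01, "gc_skew": -0.17},
    "PCGs": {"length": 11_205, "A": 34.70, "T": 45.78, "C": 9.19,
             "G": 10.33, "AT": 80.48, "GC": 19.52,
             "at_skew": -0.14, "gc_skew": 0.06},
    "tRNAs": {"length": 1_472, "A": 42.66, "T": 39.88, "C": 7.27,
              "G": 10.19, "AT": 82.54, "GC": 17.46,
              "at_skew": 0.03, "gc_skew": 0.17},
    "rRNAs": {"length": 2_104, "A": 43.11, "T": 42.59, "C": 4.75,
              "G": 9.55, "AT": 85.69, "GC": 14.31,
              "at_skew": 0.01, "gc_skew": 0.34},
    "D-loop": {"length": 1_389, "A": 45.36, "T": 49.89, "C": 3.24,
               "G": 1.51, "AT": 95.25, "GC": 4.75,
               "at_skew": -0.05, "gc_skew": -0.36},
}

#: Reported codon counts over the 13 PCGs (invertebrate mitochondrial code,
#: RNA alphabet).  Initiation codons are tallied separately below, matching
#: the published table's convention of folding them into the Met family.
CODON_COUNTS = {
    # Ala
    "GCU": 60, "GCA": 45, "GCC": 5, "GCG": 2,
    # Arg
    "CGA": 32, "CGU": 17, "CGG": 2, "CGC": 1,
    # Asn
    "AAU": 235, "AAC": 17,
    # Asp
    "GAU": 62, "GAC": 0,
    # Cys
    "UGU": 28, "UGC": 0,
    # Gln
    "CAA": 60, "CAG": 0,
    # Glu
    "GAA": 65, "GAG": 9,
    # Gly
    "GGA": 114, "GGU": 63, "GGG": 21, "GGC": 2,
    # His
    "CAU": 61, "CAC": 5,
    # Ile
    "AUU": 433, "AUC": 12,
    # Leu (6-fold)
    "UUA": 492, "CUA": 27, "CUU": 12, "UUG": 10, "CUC": 0, "CUG": 0,
    # Lys
    "AAA": 96, "AAG": 11,
    # Met
    "AUA": 279, "AUG": 25,
    # Phe
    "UUU": 355, "UUC": 26,
    # Pro
    "CCU": 65, "CCA": 52, "CCC": 5, "CCG": 0,
    # Ser (8-fold)
    "UCU": 113, "AGA": 88, "UCA": 83, "AGU": 30, "UCC": 8, "UCG": 3,
    "AGC": 0, "AGG": 0,
    # stops
    "UAA": 11, "UAG": 2,
    # Thr
    "ACU": 86, "ACA": 62, "ACC": 3, "ACG": 0,
    # Trp
    "UGA": 90, "UGG": 3,
    # Tyr
    "UAU": 207, "UAC": 13,
    # Val
    "GUA": 62, "GUU": 56, "GUG": 5, "GUC": 1,
}

#: Initiation codons reported inside the published Met family row beyond the
#: regular AUA/AUG usage: four AUU starts and the CGA start of COI.
START_CODON_COUNTS = {"AUU": 4, "CGA": 1}

#: Published RSCU spot values (2 dp) for regression tests.
RSCU_REPORTED = {
    "GCU": 2.14, "GCA": 1.61, "GCC": 0.18, "GCG": 0.07,          # Ala
    "UUA": 5.46, "CUA": 0.30, "CUU": 0.13, "UUG": 0.11,          # Leu
    "CUC": 0.00, "CUG": 0.00,
    "UCU": 2.78, "AGA": 2.17, "UCA": 2.04, "AGU": 0.74,          # Ser
    "UCC": 0.20, "UCG": 0.07, "AGC": 0.00, "AGG": 0.00,
    "UAA": 1.69, "UAG": 0.31,                                    # Ter
    "UGA": 1.94, "UGG": 0.06,                                    # Trp
    "UGU": 2.00, "UGC": 0.00,                                    # Cys
}

#: Cross-species ENC screen: 169 protein-coding genes over 13 moth species,
#: of which 17 had ENC above 35 (10.06%).
ENC_SCREEN = {"n_genes": 169, "n_above_35": 17, "pct_above_35": 10.06}

#: Reported AT-repeat insertions: junction -> inserted length (bp).  The
#: third junction sits between trnS2 and ND1 on the genome.
AT_INSERTIONS = {
    ("trnR", "trnA"): 205,
    ("trnE", "trnF"): 178,
    ("trnS2", "ND1"): 423,
}
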