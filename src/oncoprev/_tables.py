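"""Bundled lookup tables: variant-class vocabulary, gene symbols, synonyms, sites.

These are small, user-replaceable defaults. The synonym table is a curated
stand-in covering common legacy aliases of well-known cancer genes; for a real
study the user should supply their own two-column alias table.
"""

from __future__ import annotations

# Controlled variant-class vocabulary used throughout the package.
VARIANT_CLASSES = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift",
        "inframe_indel",
        "splice",
        "silent",
        "noncoding",
        "SV",
        "fusion",
        "other",
    }
)

# Protein-altering consequences retained by consequence filtering.
QUALIFYING_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift", "inframe_indel", "splice"}
)

# MAF Variant_Classification vocabulary -> controlled tokens.
# Covers cBioPortal/TCGA/ICGC export spellings; unmapped tokens become "other".
MAF_CLASS_MAP = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Nonstop_Mutation": "nonsense",
    "Frame_Shift_Del": "frameshift",
    "Frame_Shift_Ins": "frameshift",
    "In_Frame_Del": "inframe_indel",
    "In_Frame_Ins": "inframe_indel",
    "Splice_Site": "splice",
    "Splice_Region": "splice",
    "Silent": "silent",
    "3'UTR": "noncoding",
    "5'UTR": "noncoding",
    "3'Flank": "noncoding",
    "5'Flank": "noncoding",
    "Intron": "noncoding",
    "IGR": "noncoding",
    "RNA": "noncoding",
    "lincRNA": "noncoding",
    "Translation_Start_Site": "other",
    "SV": "SV",
    "Structural_Variant": "SV",
    "Fusion": "fusion",
    "Gene_Fusion": "fusion",
    # already-canonical tokens pass through (round-trip of our own output)
    **{c: c for c in VARIANT_CLASSES},
}

# Well-known cancer gene symbols used to name simulated genes (in rough order
# of pan-cancer prominence, TP53 first) before falling back to G#### symbols.
KNOWN_CANCER_GENES = [
    "TP53", "LRP1B", "PIK3CA", "KRAS", "EGFR", "APC", "KMT2D", "KMT2C",
    "ARID1A", "FAT4", "BRAF", "PTEN", "IDH1", "VHL", "SPOP", "SMAD4",
    "CDKN2A", "NRAS", "HRAS", "CTNNB1", "RB1", "NF1", "ATM", "BRCA1",
    "BRCA2", "ERBB2", "FBXW7", "PBRM1", "STK11", "KEAP1", "NOTCH1",
    "PIK3R1", "MET", "ALK", "RET", "ROS1", "KIT", "PDGFRA", "FGFR3",
    "SMARCA4", "SETD2", "BAP1", "MTOR", "TSC1", "TSC2", "AKT1", "GNAS",
    "POLE", "MSH2", "MLH1",
]

# Curated alias -> official symbol map (legacy/literature names).
DEFAULT_SYNONYMS = {
    "P53": "TP53",
    "ERBB1": "EGFR",
    "HER1": "EGFR",
    "KRAS2": "KRAS",
    "MLL2": "KMT2D",
    "MLL3": "KMT2C",
    "DPC4": "SMAD4",
    "CDKN2": "CDKN2A",
    "MTS1": "CDKN2A",
    "HER2": "ERBB2",
    "NEU": "ERBB2",
    "BAF250A": "ARID1A",
    "MMAC1": "PTEN",
    "LKB1": "STK11",
    "CD246": "ALK",
    "FRAP1": "MTOR",
    "B-RAF": "BRAF",
    "CTNNB": "CTNNB1",
    "HMSH2": "MSH2",
    "HMLH1": "MLH1",
}

# ICD-10 major tumor-site categories used to label simulated sites
# (23 solid-tumor sites, the granularity of registry major-site tables).
ICD10_MAJOR_SITES = [
    "C11",  # nasopharynx
    "C15",  # esophagus
    "C16",  # stomach
    "C18",  # colorectum
    "C22",  # liver
    "C25",  # pancreas
    "C32",  # larynx
    "C34",  # lung
    "C43",  # skin melanoma
    "C50",  # breast
    "C53",  # cervix uteri
    "C54",  # corpus uteri
    "C56",  # ovary
    "C61",  # prostate
    "C62",  # testis
    "C64",  # kidney
    "C67",  # bladder
    "C71",  # brain
    "C73",  # thyroid
    "C81",  # Hodgkin lymphoma
    "C82",  # non-Hodgkin lymphoma
    "C90",  # myeloma
    "C91",  # leukemia
]
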