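"""Packaged summary tables from the published EMF-exposure SILAC study.

These are the study's printed identification, comparison, quantitation
and regulated-protein summaries, frozen here so that report rendering
and the desk-level acceptance checks can run without the external raw
data.  Gene-symbol case is meaningful: mouse symbols are capitalized
(Cryzl1) while human symbols are upper-case (CRYZL1).
"""

from __future__ import annotations

EXPOSURES = ("ELF", "UMTS", "WiFi")
CELL_LINES = ("VH10", "U2OS", "IB10")
CELL_SPECIES = {"VH10": "human", "U2OS": "human", "IB10": "mouse"}

#: Reference proteome sizes (protein accessions incl. splice isoforms).
REFERENCE_PROTEOME_SIZE = {"human": 89796, "mouse": 53213}

#: Identification counts per species / database section / exposure.
IDENTIFICATION_SUMMARY = {
    "human": {
        "Swiss-Prot": {"n_accessions": 42077, "ELF": 12558, "UMTS": 10708, "WiFi": 11434},
        "TrEMBL": {"n_accessions": 47719, "ELF": 13861, "UMTS": 12249, "WiFi": 12740},
        "UniProtKB": {"n_accessions": 89796, "ELF": 26419, "UMTS": 22957, "WiFi": 24174},
    },
    "mouse": {
        "Swiss-Prot": {"n_accessions": 24724, "ELF": 6919, "UMTS": 7518, "WiFi": 7044},
        "TrEMBL": {"n_accessions": 28489, "ELF": 6132, "UMTS": 6588, "WiFi": 6265},
        "UniProtKB": {"n_accessions": 53213, "ELF": 13051, "UMTS": 14106, "WiFi": 13309},
    },
}

#: Printed two-/three-way identification-set comparisons (cardinalities,
#: intersections and unions; percentages/Jaccard are recomputed).
SET_COMPARISONS = [
    {"species": "human", "labels": ("ELF", "UMTS"),
     "cardinalities": (26419, 22957), "intersection": 20711, "union": 28665},
    {"species": "human", "labels": ("ELF", "WiFi"),
     "cardinalities": (26419, 24174), "intersection": 21503, "union": 29090},
    {"species": "human", "labels": ("UMTS", "WiFi"),
     "cardinalities": (22957, 24174), "intersection": 20702, "union": 26429},
    {"species": "mouse", "labels": ("ELF", "UMTS"),
     "cardinalities": (13051, 14106), "intersection": 11365, "union": 15792},
    {"species": "mouse", "labels": ("ELF", "WiFi"),
     "cardinalities": (13051, 13309), "intersection": 11108, "union": 15252},
    {"species": "mouse", "labels": ("UMTS", "WiFi"),
     "cardinalities": (14106, 13309), "intersection": 12154, "union": 15261},
    {"species": "human", "labels": ("ELF", "UMTS", "WiFi"),
     "cardinalities": (26419, 22957, 24174), "intersection": 19389, "union": 30023},
    {"species": "mouse", "labels": ("ELF", "UMTS", "WiFi"),
     "cardinalities": (13051, 14106, 13309), "intersection": 10570, "union": 16409},
]

#: Per (exposure, cell line): identification/quantification counts.
#: n_quant_r1/r2 = groups with >=1 ratio in that replicate;
#: n_complete = all six ratios present in both replicates.
QUANTITATION_SUMMARY = {
    ("ELF", "U2OS"): {"n_ident": 5286, "n_quant_r1": 3237, "n_quant_r2": 3288,
                      "n_complete": 2927, "n_decoys": 97, "n_contaminants": 125},
    ("ELF", "VH10"): {"n_ident": 5286, "n_quant_r1": 3114, "n_quant_r2": 3305,
                      "n_complete": 2854, "n_decoys": 97, "n_contaminants": 125},
    ("ELF", "IB10"): {"n_ident": 4583, "n_quant_r1": 3276, "n_quant_r2": 3389,
                      "n_complete": 3055, "n_decoys": 71, "n_contaminants": 96},
    ("UMTS", "U2OS"): {"n_ident": 4551, "n_quant_r1": 3722, "n_quant_r2": 3656,
                       "n_complete": 3416, "n_decoys": 76, "n_contaminants": 134},
    ("UMTS", "VH10"): {"n_ident": 4551, "n_quant_r1": 3233, "n_quant_r2": 3023,
                       "n_complete": 2761, "n_decoys": 76, "n_contaminants": 134},
    ("UMTS", "IB10"): {"n_ident": 4933, "n_quant_r1": 4199, "n_quant_r2": 4035,
                       "n_complete": 3812, "n_decoys": 66, "n_contaminants": 113},
    ("WiFi", "U2OS"): {"n_ident": 4841, "n_quant_r1": 3656, "n_quant_r2": 3803,
                       "n_complete": 3483, "n_decoys": 71, "n_contaminants": 130},
    ("WiFi", "VH10"): {"n_ident": 4841, "n_quant_r1": 3294, "n_quant_r2": 3336,
                       "n_complete": 3028, "n_decoys": 71, "n_contaminants": 130},
    ("WiFi", "IB10"): {"n_ident": 4662, "n_quant_r1": 4010, "n_quant_r2": 3958,
                       "n_complete": 3704, "n_decoys": 62, "n_contaminants": 112},
}

# Per-method regulated-protein calls.  Each call is
# (gene_symbol, fc_tier, strong_p): fc_tier 1 means FC > 1.2, 2 means
# FC > 1.5, None when no FC marker was printed; strong_p marks the
# highest printed p stringency (p < 0.01).
_C = lambda sym, tier=None, strong=False: (sym, tier, strong)  # noqa: E731

REGULATED_CALLS = {
    ("ELF", "VH10"): {
        "methods": {
            "FC": [_C("MLH1", 2), _C("WDR75", 1)],
            "FC+sigB": [_C("MLH1", 2)],
            "Z-score": [_C("MLH1")],
            "M-score": [_C("MLH1", strong=True), _C("UBE2A"), _C("WDR75")],
            "RankProd": [_C("MLH1", 2, True), _C("LEPREL2", 2), _C("NUMB", 1),
                         _C("WDR75", 1), _C("GINS1", 1)],
            "fcros": [_C("MLH1", 2)],
            "limma": [],
        },
        "up": ["MLH1", "UBE2A", "WDR75", "LEPREL2", "NUMB", "GINS1"],
        "down": [],
    },
    ("ELF", "U2OS"): {
        "methods": {
            "FC": [_C("AMPH", 1), _C("DNMT1", 1)],
            "FC+sigB": [],
            "Z-score": [],
            "M-score": [_C("METAP2"), _C("DNMT1"), _C("NT5C2")],
            "RankProd": [_C("DHX33", 1, True), _C("AMPH", 1, True), _C("TBL3", 1, True),
                         _C("MVK", 1, True), _C("DNMT1", 1, True), _C("LIMD1", 1)],
            "fcros": [_C("AMPH", 2), _C("DHX33", 1), _C("MVK", 1), _C("DNMT1", 1)],
            "limma": [],
        },
        "up": ["MVK", "TBL3", "DHX33"],
        "down": ["AMPH", "DNMT1", "METAP2", "NT5C2", "LIMD1"],
    },
    ("ELF", "IB10"): {
        "methods": {
            "FC": [_C("Rhot1", 1)],
            "FC+sigB": [],
            "Z-score": [],
            "M-score": [_C("Glmn"), _C("Rhot1")],
            "RankProd": [_C("Glmn", 2), _C("Cryzl1", 1), _C("Ap1m1", 1)],
            "fcros": [],
            "limma": [],
        },
        "up": ["Glmn", "Rhot1", "Cryzl1", "Ap1m1"],
        "down": [],
    },
    ("UMTS", "VH10"): {
        "methods": {
            "FC": [_C("SPAG7", 1)],
            "FC+sigB": [],
            "Z-score": [],
            "M-score": [_C("SPAG7")],
            "RankProd": [_C("EXOC2", 2, True), _C("CRYZL1", 2, True),
                         _C("SPAG7", 1, True), _C("DPY30", 1)],
            "fcros": [_C("EXOC2", 2), _C("KDM1A", 1), _C("SPAG7", 1)],
            "limma": [],
        },
        "up": ["SPAG7"],
        "down": ["EXOC2", "DPY30", "KDM1A", "CRYZL1"],
    },
    ("UMTS", "U2OS"): {
        "methods": {
            "FC": [_C("TWISTNB", 1), _C("MBOAT7", 1)],
            "FC+sigB": [_C("TWISTNB", 1), _C("MBOAT7", 1)],
            "Z-score": [],
            "M-score": [_C("MBOAT7", strong=True), _C("EXOC2"), _C("MOGS"), _C("PKP2")],
            "RankProd": [_C("TWISTNB", 2, True), _C("MBOAT7", 1), _C("H2AFY", 1)],
            "fcros": [_C("TWISTNB", 2), _C("MBOAT7", 1)],
            "limma": [],
        },
        "up": [],
        "down": ["MBOAT7", "EXOC2", "MOGS", "H2AFY", "PKP2", "TWISTNB"],
    },
    ("UMTS", "IB10"): {
        "methods": {
            "FC": [_C("Calcoco1", 1), _C("Pcf11", 1), _C("Acbd6", 1)],
            "FC+sigB": [],
            "Z-score": [],
            "M-score": [_C("Acbd6"), _C("Calcoco1")],
            "RankProd": [_C("Acbd6", 2, True), _C("Calcoco1", 1, True),
                         _C("Pcf11", 1), _C("Wipi2", 1)],
            "fcros": [_C("Acbd6", 2), _C("Calcoco1", 1), _C("Pcf11", 1)],
            "limma": [],
        },
        "up": ["Calcoco1", "Pcf11"],
        "down": ["Acbd6", "Wipi2"],
    },
    ("WiFi", "VH10"): {
        "methods": {
            "FC": [_C("LEO1", 1), _C("PNPO", 1)],
            "FC+sigB": [],
            "Z-score": [],
            "M-score": [],
            "RankProd": [_C("LEO1", 1, True), _C("PNPO", 1, True),
                         _C("ANKRD28", 1), _C("KRAS", 1)],
            "fcros": [_C("LEO1", 1), _C("PNPO", 1)],
            "limma": [_C("PNPO", 1)],
        },
        "up": ["ANKRD28"],
        "down": ["LEO1", "PNPO", "KRAS"],
    },
    ("WiFi", "U2OS"): {
        "methods": {
            "FC": [_C("AKAP8L", 1)],
            "FC+sigB": [],
            "Z-score": [],
            "M-score": [_C("AKAP8L")],
            "RankProd": [_C("AKAP8L", 2, True), _C("NUCKS1", 1, True)],
            "fcros": [_C("AKAP8L", 2), _C("NUCKS1", 1)],
            "limma": [],
        },
        "up": [],
        "down": ["AKAP8L", "NUCKS1"],
    },
    ("WiFi", "IB10"): {
        "methods": {
            "FC": [_C("Drosha", 2), _C("Zfp57", 1), _C("Atxn7l3b", 1)],
            "FC+sigB": [_C("Drosha", 2)],
            "Z-score": [_C("Drosha")],
            "M-score": [_C("Atxn7l3b", strong=True), _C("Drosha", strong=True),
                        _C("Zfp57")],
            "RankProd": [_C("Drosha", 2, True), _C("Atxn7l3b", 1, True),
                         _C("Zfp57", 1, True), _C("Nde1", 1, True), _C("Wwc2", 1),
                         _C("Asf1a", 1), _C("Scaf8", 1)],
            "fcros": [_C("Drosha", 2), _C("Zfp57", 1), _C("Atxn7l3b", 1),
                      _C("Nde1", 1)],
            "limma": [],
        },
        "up": ["Drosha", "Atxn7l3b", "Wwc2", "Nde1", "Asf1a"],
        "down": ["Zfp57", "Scaf8"],
    },
}


def combined_set(emf: str, cell_line: str) -> list[str]:
    """Combined (union) regulated symbols for one exposure x cell line."""
    row = REGULATED_CALLS[(emf, cell_line)]
    return list(row["up"]) + list(row["down"])


def unique_symbols_per_exposure() -> dict[str, int]:
    """Unique regulated gene symbols per exposure across cell lines.

    A symbol shared by two cell lines counts once within an exposure;
    symbol case distinguishes species orthologs.
    """
    out = {}
    for emf in EXPOSURES:
        syms = set()
        for cell in CELL_LINES:
            syms.update(combined_set(emf, cell))
        out[emf] = len(syms)
    return out


def regulated_fraction_pct() -> dict[tuple[str, str], float]:
    """Combined-set size as % of completely quantified groups, per
    exposure x cell line."""
    return {
        key: 100.0 * len(combined_set(*key)) / QUANTITATION_SUMMARY[key]["n_complete"]
        for key in QUANTITATION_SUMMARY
    }
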