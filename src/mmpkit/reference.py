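"""Reference constants for the human mitochondrial proteome.

Amino-acid lengths of the 13 proteins encoded by the human reference
mitochondrial genome (rCRS, NC_012920).  Total-site-number statistics depend
only on lengths, so these constants let length-based quantities (e.g. the
share of sites covered by a protein set) be computed without any sequence
download.
"""

HUMAN_MT_PROTEIN_LENGTHS: dict[str, int] = {
    "ND1": 318,
    "ND2": 347,
    "ND3": 115,
    "ND4": 459,
    "ND4L": 98,
    "ND5": 603,
    "ND6": 174,
    "CYTB": 380,
    "CO1": 513,
    "CO2": 227,
    "CO3": 261,
    "ATP6": 226,
    "ATP8": 68,
}

HUMAN_MT_TOTAL_SITES: int = sum(HUMAN_MT_PROTEIN_LENGTHS.values())  # 3789
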