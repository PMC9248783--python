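"""Built-in registry of the assay's published primers.

Six degenerate COI primers (three forward, three reverse) designed for the
eight-species earthworm HRM assay, plus the four non-degenerate primers of
the 16S/COI multiplex assay used to separate *Aporrectodea caliginosa* from
*Aporrectodea longa*.  All sequences 5'->3'.

The nine forward x reverse COI combinations and their published product
lengths (bp) on the reference earthworm COI alignment are kept in
``COI_PAIR_LENGTHS``; only EW_COI_F2 x EW_COI_R1 (158 bp) amplified and
distinguished all eight target species and is the registry's default pair.
"""

from __future__ import annotations

from .insilico import DegeneratePrimer

__all__ = ["PRIMERS", "COI_PAIR_LENGTHS", "DEFAULT_PAIR", "MULTIPLEX_PAIRS", "get_primer"]

PRIMERS: dict[str, DegeneratePrimer] = {
    p.name: p
    for p in [
        DegeneratePrimer("EW_COI_F1", "CATGCATTYGTDATAATYTTCTT"),
        DegeneratePrimer("EW_COI_F2", "GTVTTYATYGGNGGNTTYGGAAA"),
        DegeneratePrimer("EW_COI_F3", "ATRGTDGGDGCHGGWATRAG"),
        DegeneratePrimer("EW_COI_R1", "CCDGTHCCDGCNCCYTTTTC"),
        DegeneratePrimer("EW_COI_R2", "AGAATNAGNGADGGRGGNARNA"),
        DegeneratePrimer("EW_COI_R3", "GADGCWCCHGCYARRTGDARDGA"),
        # multiplex assay: 16S product diagnostic for Apo. caliginosa,
        # COI product diagnostic for Apo. longa
        DegeneratePrimer("16S-Ac-F1", "CTAAATTCTGACCCTTATTC"),
        DegeneratePrimer("WORM-16S-R1", "CCTAAGCCAACATCGAGGTG"),
        DegeneratePrimer("COI-Al-F2", "TGGCTTCTACCTCTAATACT"),
        DegeneratePrimer("COI-Al-R2", "ATGAAGGGAGAAGATGGCCA"),
    ]
}

#: Published product length (bp) of each COI primer combination.
COI_PAIR_LENGTHS: dict[tuple[str, str], int] = {
    ("EW_COI_F1", "EW_COI_R1"): 194,
    ("EW_COI_F1", "EW_COI_R2"): 287,
    ("EW_COI_F1", "EW_COI_R3"): 152,
    ("EW_COI_F2", "EW_COI_R1"): 158,
    ("EW_COI_F2", "EW_COI_R2"): 251,
    ("EW_COI_F2", "EW_COI_R3"): 116,
    ("EW_COI_F3", "EW_COI_R1"): 293,
    ("EW_COI_F3", "EW_COI_R2"): 386,
    ("EW_COI_F3", "EW_COI_R3"): 251,
}

DEFAULT_PAIR: tuple[str, str] = ("EW_COI_F2", "EW_COI_R1")

#: Multiplex pairs with their diagnostic species and product lengths.
MULTIPLEX_PAIRS: dict[str, dict] = {
    "16S_caliginosa": {"fwd": "16S-Ac-F1", "rev": "WORM-16S-R1", "length": 116},
    "COI_longa": {"fwd": "COI-Al-F2", "rev": "COI-Al-R2", "length": 213},
}


def get_primer(name: str) -> DegeneratePrimer:
    """Look up a primer by name; raises KeyError with the known names."""
    try:
        return PRIMERS[name]
    except KeyError:
        raise KeyError(
            f"unknown primer {name!r}; known primers: {sorted(PRIMERS)}"
        ) from None
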