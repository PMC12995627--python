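"""Gene-set registry and subtype vocabulary for the pyroptosis signature.

The nine-gene core signature splits into a pro-pyroptotic arm (inflammasome
activation, caspase signalling, inflammatory cell death) and an
anti-pyroptotic arm (apoptosis inhibition and cell-cycle restraint).  A
separate ten-gene panel covers canonical inflammasome components and is the
basis of the inflammasome activation score.
"""

from __future__ import annotations

SUBTYPES: tuple[str, ...] = (
    "LumA",
    "LumB_HER2neg",
    "LumB_HER2pos",
    "NonLum_HER2pos",
    "TNBC",
)

GROUPS: tuple[str, str] = ("tumor", "control")

PRO_PYROPTOTIC: frozenset[str] = frozenset(
    {"CXCL8", "BAX", "CASP1", "CASP9", "TP53", "MMP9"}
)

ANTI_PYROPTOTIC: frozenset[str] = frozenset({"BCL2", "CDKN1A", "CDKN1B"})

CORE9: frozenset[str] = PRO_PYROPTOTIC | ANTI_PYROPTOTIC

INFLAMMASOME_PANEL: frozenset[str] = frozenset(
    {"IL1B", "IL18", "NLRP3", "PYCARD", "TLR9", "RIPK1", "TNF", "STING1", "JAK3", "CASP1"}
)

#: PYCARD is commonly reported under its protein alias ASC.
GENE_ALIASES: dict[str, str] = {"ASC": "PYCARD"}


def canonical_symbol(symbol: str) -> str:
    """Map known aliases (e.g. ASC) onto their canonical HGNC symbol."""
    return GENE_ALIASES.get(symbol, symbol)
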