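"""Study constants: the RE-DNA duplex and the dead-end modification chemistry.

These are the fixed experimental inputs of the p53 C-terminal modeling
workflow: the 26-bp response-element duplex used for the DNA-bound state and
the elemental compositions of the hydrolyzed (dead-end) BS²G reagent in its
light and heavy isotopologs.
"""

from __future__ import annotations

__all__ = [
    "RESPONSE_ELEMENT_TOP_STRAND", "RESPONSE_ELEMENT_BOTTOM_STRAND",
    "reverse_complement", "BS2G_DEADEND_D0_FORMULA",
    "BS2G_DEADEND_D4_FORMULA", "N_BS2G_CROSSLINKS", "N_DSBU_CROSSLINKS",
    "MODEL_REGION", "CORE_REGION",
]

# 26-mer response element bound specifically by the p53 DNA-binding domain
RESPONSE_ELEMENT_TOP_STRAND = "CGCGGACATGTCCGGACATGTCCCGC"
RESPONSE_ELEMENT_BOTTOM_STRAND = "GCGGGACATGTCCGGACATGTCCGCG"

# hydrolyzed BS2G dead-end modification, light and deuterated isotopologs
BS2G_DEADEND_D0_FORMULA = "C5H6O3"
BS2G_DEADEND_D4_FORMULA = "C5D4H2O3"

# evidence set sizes used for model validation
N_BS2G_CROSSLINKS = 12
N_DSBU_CROSSLINKS = 21

# modelled C-terminal region (NLS + TET + CTD) and its ordered core (TET)
MODEL_REGION = (301, 393)
CORE_REGION = (326, 356)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a DNA sequence (ACGT alphabet)."""
    return sequence.translate(_COMPLEMENT)[::-1]
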