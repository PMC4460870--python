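"""Default amino-acid -> metabolite-id maps for published genome-scale models.

The iJO1366 map uses the standard BiGG identifiers of the 20 cytosolic
L-amino acids (glycine is achiral, hence ``gly_c``).  Yeast consensus models
use opaque accession-style metabolite ids, so the Yeast-6 default is built by
name matching against the loaded model instead of a literal id table; see
:func:`aa_map_from_names`.
"""

from __future__ import annotations

IJO1366_AA_MAP: dict[str, str] = {
    "A": "ala__L_c",
    "R": "arg__L_c",
    "N": "asn__L_c",
    "D": "asp__L_c",
    "C": "cys__L_c",
    "Q": "gln__L_c",
    "E": "glu__L_c",
    "G": "gly_c",
    "H": "his__L_c",
    "I": "ile__L_c",
    "L": "leu__L_c",
    "K": "lys__L_c",
    "M": "met__L_c",
    "F": "phe__L_c",
    "P": "pro__L_c",
    "S": "ser__L_c",
    "T": "thr__L_c",
    "W": "trp__L_c",
    "Y": "tyr__L_c",
    "V": "val__L_c",
}

#: canonical chemical names, lowercased, per one-letter code
AA_NAMES: dict[str, list[str]] = {
    "A": ["l-alanine"],
    "R": ["l-arginine"],
    "N": ["l-asparagine"],
    "D": ["l-aspartate", "l-aspartic acid"],
    "C": ["l-cysteine"],
    "Q": ["l-glutamine"],
    "E": ["l-glutamate", "l-glutamic acid"],
    "G": ["glycine"],
    "H": ["l-histidine"],
    "I": ["l-isoleucine"],
    "L": ["l-leucine"],
    "K": ["l-lysine"],
    "M": ["l-methionine"],
    "F": ["l-phenylalanine"],
    "P": ["l-proline"],
    "S": ["l-serine"],
    "T": ["l-threonine"],
    "W": ["l-tryptophan"],
    "Y": ["l-tyrosine"],
    "V": ["l-valine"],
}
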