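"""Amino-acid property scales packaged as plain data tables.

``KYTE_DOOLITTLE``: hydropathy index (dimensionless; positive = hydrophobic).
``ZAMYATNIN_VOLUME``: residue volume in Å³.

Both are the standard literature tables; any mapping covering the 20
canonical one-letter codes can be passed in their place.
"""

from __future__ import annotations

__all__ = ["KYTE_DOOLITTLE", "ZAMYATNIN_VOLUME", "AMINO_ACIDS"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

ZAMYATNIN_VOLUME: dict[str, float] = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}
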