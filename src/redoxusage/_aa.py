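"""Amino-acid alphabet constants shared across the package.

All composition vectors and ratio tables use the fixed alphabetical
one-letter ordering ``A, C, D, ..., Y`` of the 20 proteinogenic amino
acids. Ambiguity letters are tolerated in sequences but never counted.
"""

from __future__ import annotations

import numpy as np

#: The 20 proteinogenic amino acids, alphabetical one-letter order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Index lookup for the fixed ordering.
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Ambiguity / non-standard letters accepted in sequences, excluded from counts.
AMBIGUITY_LETTERS: frozenset[str] = frozenset("BJOUXZ")

#: Kyte-Doolittle hydropathy scale (kcal-free index; positive = hydrophobic).
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}


def aa_array(mapping: dict[str, float], default: float = 0.0) -> np.ndarray:
    """Expand a per-amino-acid mapping into a length-20 vector in fixed order."""
    out = np.full(20, default, dtype=float)
    for aa, v in mapping.items():
        if aa not in AA_INDEX:
            raise KeyError(f"unknown amino acid {aa!r}")
        out[AA_INDEX[aa]] = v
    return out


def as_mapping(vector: np.ndarray) -> dict[str, float]:
    """Inverse of :func:`aa_array`: a length-20 vector as an ordered dict."""
    v = np.asarray(vector, dtype=float)
    if v.shape != (20,):
        raise ValueError(f"expected a length-20 vector, got shape {v.shape}")
    return {aa: float(v[i]) for i, aa in enumerate(AMINO_ACIDS)}
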