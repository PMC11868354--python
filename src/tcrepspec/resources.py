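"""Shared reference data: amino-acid alphabet and descriptors, TRB gene lists.

The gene lists are data, not code: they seed the synthetic generator's usage
distribution and the default orphon filter, and can be overridden wherever a
function accepts a gene list or orphon set.
"""

from __future__ import annotations

import numpy as np

#: The 20 standard amino acids, alphabetical.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)

# Per-residue physicochemical descriptors used by the CDR3 encoder.
# Hydrophobicity: Kyte-Doolittle; volume in cubic Angstrom; polarity: Grantham.
HYDROPHOBICITY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}
CHARGE = {
    "D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.1,
    **{aa: 0.0 for aa in "ACFGILMNPQSTVWY"},
}
VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5, "Q": 143.8,
    "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7, "L": 166.7, "K": 168.6,
    "M": 162.9, "F": 189.9, "P": 112.7, "S": 89.0, "T": 116.1, "W": 227.8,
    "Y": 193.6, "V": 140.0,
}
POLARITY = {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5,
    "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3,
    "M": 5.7, "F": 5.2, "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4,
    "Y": 6.2, "V": 5.9,
}


def standardized_descriptor_matrix() -> np.ndarray:
    """Return a (20, 4) matrix of z-scored descriptors, row order = AMINO_ACIDS.

    Columns: hydrophobicity, charge, volume, polarity. Z-scoring across the
    20 residues puts the four scales on comparable footing.
    """
    cols = []
    for table in (HYDROPHOBICITY, CHARGE, VOLUME, POLARITY):
        v = np.array([table[aa] for aa in AMINO_ACIDS], dtype=float)
        cols.append((v - v.mean()) / v.std())
    return np.column_stack(cols)


#: Functional human TRBV gene symbols (IMGT nomenclature, allele stripped).
TRBV_GENES = [
    "TRBV2", "TRBV3-1", "TRBV4-1", "TRBV4-2", "TRBV4-3",
    "TRBV5-1", "TRBV5-4", "TRBV5-5", "TRBV5-6", "TRBV5-8",
    "TRBV6-1", "TRBV6-2", "TRBV6-3", "TRBV6-4", "TRBV6-5", "TRBV6-6",
    "TRBV6-8", "TRBV6-9", "TRBV7-2", "TRBV7-3", "TRBV7-4", "TRBV7-6",
    "TRBV7-7", "TRBV7-8", "TRBV7-9", "TRBV9", "TRBV10-1", "TRBV10-2",
    "TRBV10-3", "TRBV11-1", "TRBV11-2", "TRBV11-3", "TRBV12-3", "TRBV12-4",
    "TRBV12-5", "TRBV13", "TRBV14", "TRBV15", "TRBV16", "TRBV18", "TRBV19",
    "TRBV20-1", "TRBV24-1", "TRBV25-1", "TRBV27", "TRBV28", "TRBV29-1",
    "TRBV30",
]

#: Functional human TRBJ gene symbols.
TRBJ_GENES = [
    "TRBJ1-1", "TRBJ1-2", "TRBJ1-3", "TRBJ1-4", "TRBJ1-5", "TRBJ1-6",
    "TRBJ2-1", "TRBJ2-2", "TRBJ2-3", "TRBJ2-4", "TRBJ2-5", "TRBJ2-6",
    "TRBJ2-7",
]

#: Default orphon gene list: TRB segments annotated by IMGT as orphons
#: (located outside the canonical TRB locus). Configurable everywhere it is
#: consumed; membership is tested on normalized symbols.
DEFAULT_ORPHON_GENES = frozenset({
    "TRBV20/OR9-2", "TRBV21/OR9-2", "TRBV22/OR9-2", "TRBV23/OR9-2",
    "TRBV24/OR9-2", "TRBV25/OR9-2", "TRBV26/OR9-2", "TRBV29/OR9-2",
    "TRBVA/OR9-2", "TRBVA", "TRBVB", "TRBVC",
})
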