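"""Amino-acid alphabet shared across the package.

The 20 standard residues are kept in alphabetical one-letter order, which is
also the row order of every PWM matrix and of the tab-separated PWM
interchange files.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
N_AA: int = 20
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GAP: str = "-"

LN20: float = float(np.log(N_AA))


def encode(sequence: str) -> np.ndarray:
    """Encode a protein sequence as integer codes.

    Standard residues map to 0..19 (alphabetical order); any other character
    (X, *, U, ...) maps to 20, which scoring code treats as a neutral residue
    with odds 1.
    """
    out = np.full(len(sequence), N_AA, dtype=np.int64)
    for i, ch in enumerate(sequence):
        out[i] = AA_INDEX.get(ch, N_AA)
    return out


def is_valid_peptide(peptide: str, allow_gap: bool = True) -> bool:
    alphabet = set(AMINO_ACIDS) | ({GAP} if allow_gap else set())
    return all(ch in alphabet for ch in peptide)
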