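"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_DNA_COMP = str.maketrans("ACGTN", "TGCAN")
_RNA_COMP = str.maketrans("ACGUN", "UGCAN")

# integer encoding used by the folding kernels: A=0 C=1 G=2 U/T=3
_ENCODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1]


def transcribe(seq: str) -> str:
    """DNA -> RNA (T becomes U); already-RNA input passes through."""
    return seq.replace("T", "U")


def back_transcribe(seq: str) -> str:
    return seq.replace("U", "T")


def encode(seq: str) -> np.ndarray:
    """Encode an RNA/DNA string as int8 (A=0, C=1, G=2, U/T=3).

    Raises ValueError on any other character.
    """
    try:
        return np.array([_ENCODE[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide {exc.args[0]!r} in sequence") from None
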