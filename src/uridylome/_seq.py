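"""Small sequence utilities shared across modules.

Reads are sequenced cDNA, so everything downstream of the simulator works in
DNA space (U -> T). Encoding maps bases to small integers so alignment inner
loops can run as numpy comparisons.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# A=0 C=1 G=2 T=3; N=4 never equals a read base under != comparisons only if
# reads are N-free, which the simulator guarantees and loaders enforce.
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T").replace("u", "t")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def check_alphabet(seq: str, extra: str = "") -> None:
    allowed = set("ACGT" + extra)
    bad = set(seq.upper()) - allowed
    if bad:
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")
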