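"""Substitution classes and trinucleotide-context bookkeeping.

Somatic substitutions are reported in *pyrimidine space*: every base change
is expressed with a pyrimidine (C or T) reference, collapsing each mutation
with its reverse complement. Six simple classes result (C>A, C>G, C>T, T>A,
T>C, T>G); adding the 5' and 3' flanking bases yields the standard 96-class
trinucleotide catalogue (e.g. ``A[C>A]G``).

Per-class rates only become comparable across regions after dividing by how
often each context occurs in the interrogated territory; context abundance
here is counted double-strandedly — every interior position contributes its
pyrimidine-oriented trinucleotide exactly once, which makes the tally
invariant under reverse complement of the input sequence.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping

import numpy as np

DNA = "ACGT"
PYRIMIDINES = "CT"
_COMP = str.maketrans("ACGTN", "TGCAN")

#: the six pyrimidine-space substitution classes
SBS6: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: the 96 substitution-in-trinucleotide-context classes, class-major order
SBS96: tuple[str, ...] = tuple(
    f"{f5}[{sub}]{f3}" for sub in SBS6 for f5 in DNA for f3 in DNA
)
SBS96_INDEX: Mapping[str, int] = {lab: i for i, lab in enumerate(SBS96)}
SBS6_INDEX: Mapping[str, int] = {lab: i for i, lab in enumerate(SBS6)}

#: the 32 pyrimidine-centred trinucleotides, same ordering as SBS96 contexts
CONTEXTS32: tuple[str, ...] = tuple(
    f"{f5}{c}{f3}" for c in PYRIMIDINES for f5 in DNA for f3 in DNA
)
CONTEXTS32_INDEX: Mapping[str, int] = {c: i for i, c in enumerate(CONTEXTS32)}

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(DNA):
    _BASE_CODE[ord(_b)] = _i
_BASE_CODE[ord("N")] = 4


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMP)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMP)


def encode(seq: str) -> np.ndarray:
    """Encode ACGTN to uint8 codes 0..4."""
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.max(initial=0) == 255:
        raise ValueError("sequence contains characters outside ACGTN")
    return codes


def pyrimidine_substitution(ref: str, alt: str) -> str:
    """Map a substitution to its pyrimidine-space class label."""
    if ref == alt:
        raise ValueError(f"ref equals alt ({ref})")
    if ref not in DNA or alt not in DNA:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    if ref in PYRIMIDINES:
        return f"{ref}>{alt}"
    return f"{complement(ref)}>{complement(alt)}"


def sbs96_class(f5: str, ref: str, alt: str, f3: str) -> str:
    """96-class label for a substitution with its flanking bases.

    Flanks are given in the orientation of ``ref``; purine-reference calls
    are reverse-complemented into pyrimidine orientation.
    """
    if ref in PYRIMIDINES:
        return f"{f5}[{pyrimidine_substitution(ref, alt)}]{f3}"
    return (
        f"{complement(f3)}[{pyrimidine_substitution(ref, alt)}]{complement(f5)}"
    )


def pyr_context(seq: str, pos: int) -> tuple[str, bool]:
    """Pyrimidine-oriented trinucleotide context at an interior position.

    Returns ``(context, pyr_on_forward)`` where the flag records whether the
    pyrimidine of the reference pair sits on the forward strand of ``seq``.
    """
    if not 0 < pos < len(seq) - 1:
        raise ValueError(f"position {pos} has no flanking context")
    tri = seq[pos - 1 : pos + 2]
    if seq[pos] in PYRIMIDINES:
        return tri, True
    return revcomp(tri), False


def context_codes(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised pyrimidine-context ids for all interior positions.

    Returns ``(ctx_ids, pyr_on_forward)`` arrays of length ``len(seq) - 2``,
    ``ctx_ids`` indexing into :data:`CONTEXTS32`.
    """
    code = encode(seq).astype(np.int64)
    if (code == 4).any():
        raise ValueError("ambiguous bases not supported here")
    left, centre, right = code[:-2], code[1:-1], code[2:]
    is_pyr = (centre == 1) | (centre == 3)
    centre_p = np.where(is_pyr, centre, 3 - centre)
    f5 = np.where(is_pyr, left, 3 - right)
    f3 = np.where(is_pyr, right, 3 - left)
    ctx = (centre_p == 3).astype(np.int64) * 16 + f5 * 4 + f3
    return ctx, is_pyr


def sbs96_context_id(class_index: int) -> int:
    """Index into :data:`CONTEXTS32` of the context of a 96-class index."""
    sub, flank = divmod(class_index, 16)
    return (sub >= 3) * 16 + flank


def trinucleotide_abundance(seqs: Iterable[str]) -> np.ndarray:
    """Double-stranded 3-mer abundance over sequences, CONTEXTS32 order."""
    counts = np.zeros(32, dtype=np.int64)
    for seq in seqs:
        if len(seq) < 3:
            continue
        ctx, _ = context_codes(seq)
        counts += np.bincount(ctx, minlength=32)
    return counts


def pyrimidine_base_abundance(seqs: Iterable[str]) -> dict[str, int]:
    """Double-stranded pyrimidine base abundance: C counts C+G, T counts T+A."""
    tally = Counter()
    for seq in seqs:
        tally.update(seq)
    return {
        "C": tally["C"] + tally["G"],
        "T": tally["T"] + tally["A"],
    }
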