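"""Raw duplex read families.

A *family* is the set of raw reads that share one source DNA fragment:
identical (corrected) barcode pair and identical shear points. Reads are
split by the physical strand of the source molecule they derive from; a
family may have zero reads on one strand, in which case no duplex
consensus can exist for it.

All read sequences are stored in reference (plus-strand) orientation, as
they would be after alignment; per-read barcodes keep the orientation they
were observed in, so top-strand reads carry (b1, b2) and bottom-strand
reads carry (b2, b1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["Read", "ReadFamily", "raw_read_table"]


@dataclass
class Read:
    bases: str
    quals: str
    cigar: str
    bc1: str  # observed (possibly corrupted) barcodes, read orientation
    bc2: str

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and quals must have equal length")


@dataclass
class ReadFamily:
    """Raw reads sharing a corrected barcode pair and shear points."""

    family_id: str
    barcode_pair: tuple[str, str]  # true pair, top-strand orientation
    target: str
    frag_start: int
    frag_end: int
    top_reads: list[Read] = field(default_factory=list)
    bottom_reads: list[Read] = field(default_factory=list)
    molecule_id: int | None = None

    @property
    def fragment_length(self) -> int:
        return self.frag_end - self.frag_start

    @property
    def n_reads(self) -> int:
        return len(self.top_reads) + len(self.bottom_reads)

    def all_reads(self) -> list[Read]:
        return list(self.top_reads) + list(self.bottom_reads)


def raw_read_table(families: list[ReadFamily]) -> pd.DataFrame:
    """Flatten families into the raw read table consumed by grouping.

    The table deliberately drops family membership and strand labels —
    those are reconstructed from barcodes and shear points — but keeps the
    observed (possibly corrupted) barcode pair per read.
    """
    rows = []
    for fam in families:
        for strand, reads in (("top", fam.top_reads), ("bottom", fam.bottom_reads)):
            for i, r in enumerate(reads):
                rows.append(
                    {
                        "read_id": f"{fam.family_id}:{strand}:{i}",
                        "bc1": r.bc1,
                        "bc2": r.bc2,
                        "target": fam.target,
                        "frag_start": fam.frag_start,
                        "frag_end": fam.frag_end,
                        "bases": r.bases,
                        "quals": r.quals,
                        "cigar": r.cigar,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "read_id", "bc1", "bc2", "target", "frag_start", "frag_end",
            "bases", "quals", "cigar",
        ],
    )
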