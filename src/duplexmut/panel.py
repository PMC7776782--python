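"""Reference target panels.

A panel is the set of genomic intervals interrogated by hybrid capture:
a handful of endogenous genes with differing transcriptional status plus
multicopy transgenes (a lambda-phage reporter, a human proto-oncogene).
Coordinates are 0-based half-open everywhere in this package; only VCF
output converts to 1-based.

``transcribed_strand`` names the *template* strand read by RNA polymerase;
the stored sequence is always the plus strand. Transcription-coupled repair
preferentially removes lesions from the template strand, which is what the
simulator's strand-bias factor emulates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .contexts import DNA

__all__ = [
    "TargetRegion",
    "generate_reference_panel",
    "write_panel",
    "read_targets",
]


@dataclass(frozen=True)
class TargetRegion:
    """One captured genomic interval with its annotations.

    Parameters
    ----------
    name : str
        Target identifier (used as the contig name for synthetic panels).
    contig, start, end : str, int, int
        0-based half-open interval on ``contig``.
    sequence : str
        Plus-strand sequence of the interval; ``len == end - start``.
    transcribed : bool
        Whether the region is transcribed in the tissues under study.
    transcribed_strand : str or None
        ``"+"`` or ``"-"``: the template strand; ``None`` for
        nontranscribed regions.
    frame_offset : int or None
        Offset of the first complete codon relative to ``start`` (0-2);
        ``None`` marks noncoding regions and disables consequence
        annotation.
    copies_per_genome : int
        ≥ 1; multicopy transgenes (e.g. four tandem *HRAS* copies) weight
        molecule sampling proportionally.
    reportable : tuple of (int, int), optional
        Sub-intervals (target-local, half-open) over which consensus bases
        and variants are reportable after repeat-mask subtraction. ``None``
        means the whole target.
    """

    name: str
    contig: str
    start: int
    end: int
    sequence: str
    transcribed: bool = False
    transcribed_strand: str | None = None
    frame_offset: int | None = None
    copies_per_genome: int = 1
    reportable: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError(
                f"{self.name}: interval length {self.end - self.start} != "
                f"sequence length {len(self.sequence)}"
            )
        if set(self.sequence) - set(DNA):
            raise ValueError(f"{self.name}: sequence contains non-ACGT bases")
        if self.copies_per_genome < 1:
            raise ValueError(f"{self.name}: copies_per_genome must be >= 1")
        if self.transcribed and self.transcribed_strand not in ("+", "-"):
            raise ValueError(
                f"{self.name}: transcribed target needs transcribed_strand +/-"
            )
        if not self.transcribed and self.transcribed_strand is not None:
            raise ValueError(
                f"{self.name}: nontranscribed target cannot have a "
                "transcribed_strand"
            )
        if self.frame_offset is not None and not 0 <= self.frame_offset <= 2:
            raise ValueError(f"{self.name}: frame_offset must be 0-2 or None")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def reportable_intervals(self) -> tuple[tuple[int, int], ...]:
        if self.reportable is None:
            return ((0, self.length),)
        return self.reportable

    @property
    def reportable_length(self) -> int:
        return sum(e - s for s, e in self.reportable_intervals)

    def in_reportable(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.reportable_intervals)


def generate_reference_panel(
    n_targets: int, length: int, seed: int
) -> list[TargetRegion]:
    """Generate a synthetic capture panel.

    Each target lives on its own contig (named after the target). Targets
    alternate nontranscribed / transcribed so that any panel with at least
    two targets exercises both strand-bias regimes; all targets are treated
    as coding in frame 0, and the last target of a multi-target panel is a
    four-copy "transgene" to emulate a tandem multicopy reporter.

    Deterministic for a fixed seed.
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    if length < 30:
        raise ValueError(
            "length must be >= 30 (room for trinucleotide contexts and codons)"
        )
    rng = np.random.default_rng(seed)
    panel = []
    for i in range(n_targets):
        name = f"locus{i + 1:02d}"
        seq = "".join(rng.choice(list(DNA), size=length))
        transcribed = i % 2 == 1
        multicopy = n_targets >= 3 and i == n_targets - 1
        panel.append(
            TargetRegion(
                name=name,
                contig=name,
                start=0,
                end=length,
                sequence=seq,
                transcribed=transcribed and not multicopy,
                transcribed_strand="-" if (transcribed and not multicopy) else None,
                frame_offset=0,
                copies_per_genome=4 if multicopy else 1,
            )
        )
    return panel


def write_panel(
    panel: list[TargetRegion],
    fasta_path: str | Path,
    bed_path: str | Path,
    annotations_path: str | Path,
) -> None:
    """Write a panel as FASTA + BED (0-based half-open) + annotation TSV."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(t.sequence), id=t.contig, description="") for t in panel
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(bed_path, "w") as bed:
        for t in panel:
            bed.write(f"{t.contig}\t{t.start}\t{t.end}\t{t.name}\n")
    pd.DataFrame(
        {
            "name": [t.name for t in panel],
            "transcribed": [t.transcribed for t in panel],
            "transcribed_strand": [
                t.transcribed_strand or "none" for t in panel
            ],
            "frame_offset": [
                "" if t.frame_offset is None else t.frame_offset for t in panel
            ],
            "copies_per_genome": [t.copies_per_genome for t in panel],
        }
    ).to_csv(annotations_path, sep="\t", index=False)


def _read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"{contig}:{start}-{end}"
            if end <= start:
                raise ValueError(f"empty/inverted BED interval: {line}")
            rows.append((contig, start, end, name))
    return rows


def _merge_intervals(
    intervals: list[tuple[int, int]],
) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _subtract(
    interval: tuple[int, int], masks: list[tuple[int, int]]
) -> tuple[tuple[int, int], ...]:
    pieces = []
    cursor, end = interval
    for ms, me in sorted(masks):
        if me <= cursor or ms >= end:
            continue
        if ms > cursor:
            pieces.append((cursor, ms))
        cursor = max(cursor, me)
    if cursor < end:
        pieces.append((cursor, end))
    return tuple(pieces)


def read_targets(
    bed_path: str | Path,
    fasta_path: str | Path,
    annotations_path: str | Path,
    mask_bed_path: str | Path | None = None,
    mask_pad: int = 10,
) -> list[TargetRegion]:
    """Load a panel from BED + FASTA + annotation TSV.

    Overlapping BED records on one contig are merged with a warning. An
    optional mask BED removes, with ``mask_pad`` bases of padding on each
    side, any masked territory from the targets' reportable intervals —
    the same exclusion rule used for repeat-masked sequence in capture
    panel design.
    """
    import pyfaidx

    fasta = pyfaidx.Fasta(str(fasta_path))
    bed = _read_bed(bed_path)

    by_contig: dict[str, list[tuple[int, int, str]]] = {}
    for contig, start, end, name in bed:
        by_contig.setdefault(contig, []).append((start, end, name))
    records: list[tuple[str, int, int, str]] = []
    for contig, ivals in by_contig.items():
        merged = _merge_intervals([(s, e) for s, e, _ in ivals])
        if len(merged) != len(ivals):
            warnings.warn(
                f"{contig}: overlapping BED records merged "
                f"({len(ivals)} -> {len(merged)})"
            )
        names = {n for _, _, n in ivals}
        for k, (s, e) in enumerate(merged):
            name = (
                ivals[k][2]
                if len(merged) == len(ivals)
                else "+".join(sorted(names))
            )
            records.append((contig, s, e, name))

    ann = pd.read_csv(annotations_path, sep="\t", dtype={"name": str}).set_index(
        "name"
    )

    masks_by_contig: dict[str, list[tuple[int, int]]] = {}
    if mask_bed_path is not None:
        for contig, s, e, _ in _read_bed(mask_bed_path):
            masks_by_contig.setdefault(contig, []).append(
                (s - mask_pad, e + mask_pad)
            )

    panel = []
    for contig, start, end, name in records:
        if contig not in fasta:
            raise ValueError(f"BED contig {contig!r} absent from FASTA")
        if end > len(fasta[contig]):
            raise ValueError(
                f"{name}: interval {start}-{end} out of bounds for contig "
                f"{contig} (length {len(fasta[contig])})"
            )
        seq = str(fasta[contig][start:end]).upper()
        row = ann.loc[name] if name in ann.index else None
        transcribed = bool(row["transcribed"]) if row is not None else False
        strand = None
        if row is not None and transcribed:
            strand = str(row["transcribed_strand"])
            strand = None if strand in ("none", "nan", "") else strand
        frame: int | None = None
        if row is not None and not pd.isna(row.get("frame_offset")):
            raw = str(row["frame_offset"]).strip()
            if raw not in ("", "none", "nan"):
                frame = int(float(raw))
        copies = int(row["copies_per_genome"]) if row is not None else 1

        region = TargetRegion(
            name=name,
            contig=contig,
            start=start,
            end=end,
            sequence=seq,
            transcribed=transcribed,
            transcribed_strand=strand,
            frame_offset=frame,
            copies_per_genome=copies,
        )
        if contig in masks_by_contig:
            local = [
                (max(0, ms - start), min(region.length, me - start))
                for ms, me in masks_by_contig[contig]
            ]
            local = [(s_, e_) for s_, e_ in local if e_ > s_]
            reportable = _subtract((0, region.length), local)
            if not reportable:
                warnings.warn(
                    f"{name}: repeat mask (+{mask_pad} bp pad) removes the "
                    "entire target; empty reportable territory"
                )
            region = replace(region, reportable=reportable)
        panel.append(region)
    return panel
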