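"""Duplex consensus calling.

Raw reads are corrected against a barcode whitelist, grouped into families
by (corrected barcode pair, shear points), quality-trimmed, cigar-filtered,
and collapsed into per-strand consensuses. A duplex consensus base is
emitted only where *both* strand consensuses exist and agree; every other
position is masked to N. Families lacking reads on either strand can never
yield a duplex consensus — that asymmetry between single-strand and duplex
calls is what suppresses single-strand damage artifacts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contexts import DNA, encode
from .reads import Read, ReadFamily

__all__ = [
    "correct_barcode",
    "group_families",
    "quality_trim",
    "filter_cigar_groups",
    "strand_consensus",
    "call_duplex_consensus",
    "duplex_consensus_reads",
    "clip_overlap",
    "DuplexConsensusRead",
    "SingleStrandConsensus",
]


@dataclass
class SingleStrandConsensus:
    """Per-strand plurality consensus with per-position read support."""

    bases: str
    support: np.ndarray
    strand: str  # "top" | "bottom"


@dataclass
class DuplexConsensusRead:
    """Consensus of both strand consensuses; N where they disagree."""

    family_id: str
    target: str
    start: int
    end: int
    bases: str
    agreement: np.ndarray  # True where both strands agreed on a base
    molecule_id: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def correct_barcode(
    observed: str,
    whitelist: list[str] | tuple[str, ...],
    max_mismatch: int = 1,
    min_next_distance: int = 2,
) -> str | None:
    """Correct an observed barcode against a whitelist, or reject.

    Accepts the whitelist tag within ``max_mismatch`` of the observation,
    provided the observation's Hamming distance to the next most likely
    whitelist tag is at least ``min_next_distance``; returns ``None``
    otherwise (ambiguous or too distant).
    """
    if not whitelist:
        raise ValueError("whitelist is empty")
    dists = sorted(
        (sum(a != b for a, b in zip(observed, tag)), tag) for tag in whitelist
    )
    best_d, best_tag = dists[0]
    if best_d > max_mismatch:
        return None
    if len(dists) > 1 and dists[1][0] < min_next_distance:
        return None
    return best_tag


def group_families(
    reads: pd.DataFrame, whitelist: list[str]
) -> tuple[list[ReadFamily], dict[str, int]]:
    """Partition a raw read table into families.

    The family key is the corrected barcode pair (canonicalised so both
    read orientations of one molecule collapse together) plus the shear
    point pair; strand labels follow barcode orientation relative to the
    canonical pair. Reads whose barcodes cannot be corrected are dropped
    and counted.

    Returns ``(families, stats)`` with ``stats['rejected_barcode_reads']``.
    """
    corrections: dict[str, str | None] = {}

    def corrected(tag: str) -> str | None:
        if tag not in corrections:
            corrections[tag] = correct_barcode(tag, whitelist)
        return corrections[tag]

    fams: dict[tuple, ReadFamily] = {}
    rejected = 0
    for row in reads.itertuples(index=False):
        c1, c2 = corrected(row.bc1), corrected(row.bc2)
        if c1 is None or c2 is None:
            rejected += 1
            continue
        lo, hi = min(c1, c2), max(c1, c2)
        key = (lo, hi, row.target, int(row.frag_start), int(row.frag_end))
        fam = fams.get(key)
        if fam is None:
            fam = ReadFamily(
                family_id=f"grp{len(fams):07d}",
                barcode_pair=(lo, hi),
                target=row.target,
                frag_start=int(row.frag_start),
                frag_end=int(row.frag_end),
            )
            fams[key] = fam
        read = Read(
            bases=row.bases, quals=row.quals, cigar=row.cigar,
            bc1=row.bc1, bc2=row.bc2,
        )
        if (c1, c2) == (lo, hi):
            fam.top_reads.append(read)
        else:
            fam.bottom_reads.append(read)
    return list(fams.values()), {"rejected_barcode_reads": rejected}


def quality_trim(
    bases: str,
    quals: str,
    trim_quality: int = 20,
    mask_quality: int = 20,
) -> tuple[str, str]:
    """Running-sum 3' quality trimming plus low-quality N masking.

    The suffix is removed at the cut point minimising the running sum of
    ``quality - trim_quality`` accumulated from the 3' end (the classic
    running-sum trimmer); remaining bases below ``mask_quality`` are
    masked to N.
    """
    if len(bases) != len(quals):
        raise ValueError("bases and quals must have equal length")
    q = np.frombuffer(quals.encode("ascii"), dtype=np.uint8).astype(int) - 33
    running = 0
    best = 0
    cut = len(bases)
    for i in range(len(bases) - 1, -1, -1):
        running += q[i] - trim_quality
        if running < best:
            best = running
            cut = i
    bases, q = bases[:cut], q[:cut]
    if len(bases) and (q < mask_quality).any():
        chars = np.array(list(bases))
        chars[q < mask_quality] = "N"
        bases = "".join(chars)
    return bases, quals[:cut]


def filter_cigar_groups(family: ReadFamily) -> ReadFamily | None:
    """Keep only reads matching the family's plurality cigar.

    A tie for the plurality cigar rejects the whole family (``None``):
    with no majority alignment there is no way to tell which reads carry
    artifactual indels.
    """
    counts = Counter(r.cigar for r in family.all_reads())
    if not counts:
        return family
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None
    best = ranked[0][0]
    if len(ranked) == 1:
        return family
    out = ReadFamily(
        family_id=family.family_id,
        barcode_pair=family.barcode_pair,
        target=family.target,
        frag_start=family.frag_start,
        frag_end=family.frag_end,
        top_reads=[r for r in family.top_reads if r.cigar == best],
        bottom_reads=[r for r in family.bottom_reads if r.cigar == best],
        molecule_id=family.molecule_id,
    )
    return out


def strand_consensus(
    reads: list[Read], strand: str, min_agreement: float = 0.7
) -> SingleStrandConsensus | None:
    """Per-position plurality consensus of one strand's reads.

    A base is called when the plurality base holds at least
    ``min_agreement`` of the non-N observations at that position; ties and
    low-agreement positions become N.
    """
    if not reads:
        return None
    length = len(reads[0].bases)
    if any(len(r.bases) != length for r in reads):
        raise ValueError("reads in a family must share one length")
    seqs = {r.bases for r in reads}
    if len(seqs) == 1 and "N" not in reads[0].bases:
        return SingleStrandConsensus(
            bases=reads[0].bases,
            support=np.full(length, len(reads)),
            strand=strand,
        )
    mat = np.stack([encode(r.bases) for r in reads])
    counts = np.zeros((5, length), dtype=int)
    for code in range(5):
        counts[code] = (mat == code).sum(axis=0)
    acgt = counts[:4]
    depth = acgt.sum(axis=0)
    top = acgt.argmax(axis=0)
    top_n = acgt[top, np.arange(length)]
    tie = (acgt == top_n).sum(axis=0) > 1
    ok = (depth > 0) & ~tie & (top_n >= min_agreement * depth)
    chars = np.full(length, "N")
    chars[ok] = np.array(list(DNA))[top[ok]]
    return SingleStrandConsensus(
        bases="".join(chars), support=np.where(ok, top_n, 0), strand=strand
    )


def call_duplex_consensus(
    family: ReadFamily,
    min_reads_per_strand: int = 1,
    min_family_agreement: float = 0.7,
    end_trim: int = 0,
) -> DuplexConsensusRead | None:
    """Collapse one (cigar-filtered) family into a duplex consensus read.

    Returns ``None`` when either strand has fewer than
    ``min_reads_per_strand`` reads — a duplex consensus requires both
    original strands. Positions where the strand consensuses disagree, or
    where either is N, are masked to N. ``end_trim`` shrinks the mapped
    interval by that many bases on each side.
    """
    if (
        len(family.top_reads) < min_reads_per_strand
        or len(family.bottom_reads) < min_reads_per_strand
        or not family.top_reads
        or not family.bottom_reads
    ):
        return None
    top = strand_consensus(family.top_reads, "top", min_family_agreement)
    bottom = strand_consensus(family.bottom_reads, "bottom", min_family_agreement)
    if top.bases == bottom.bases and "N" not in top.bases:
        bases = top.bases
        agreement = np.ones(len(bases), dtype=bool)
    else:
        t = np.array(list(top.bases))
        b = np.array(list(bottom.bases))
        agree = (t == b) & (t != "N")
        chars = np.where(agree, t, "N")
        bases = "".join(chars)
        agreement = agree
    start, end = family.frag_start, family.frag_end
    if end_trim > 0:
        if 2 * end_trim >= len(bases):
            return None
        bases = bases[end_trim : len(bases) - end_trim]
        agreement = agreement[end_trim : len(agreement) - end_trim]
        start, end = start + end_trim, end - end_trim
    return DuplexConsensusRead(
        family_id=family.family_id,
        target=family.target,
        start=start,
        end=end,
        bases=bases,
        agreement=agreement,
        molecule_id=family.molecule_id,
    )


def duplex_consensus_reads(
    families: list[ReadFamily],
    min_reads_per_strand: int = 1,
    min_family_agreement: float = 0.7,
    end_trim: int = 0,
    trim_quality: int = 20,
    mask_quality: int = 20,
) -> tuple[list[DuplexConsensusRead], dict[str, int]]:
    """Run trimming, cigar filtering and duplex calling over families.

    Returns the duplex reads plus yield counters (families in, cigar-tie
    rejections, single-strand-only families, duplex reads out).
    """
    stats = {
        "families_in": len(families),
        "cigar_tie_rejected": 0,
        "no_duplex": 0,
        "duplex_reads": 0,
    }
    out: list[DuplexConsensusRead] = []
    for fam in families:
        filtered = filter_cigar_groups(fam)
        if filtered is None:
            stats["cigar_tie_rejected"] += 1
            continue
        if trim_quality is not None:
            _trim_family(filtered, trim_quality, mask_quality)
        dup = call_duplex_consensus(
            filtered,
            min_reads_per_strand=min_reads_per_strand,
            min_family_agreement=min_family_agreement,
            end_trim=end_trim,
        )
        if dup is None:
            stats["no_duplex"] += 1
            continue
        stats["duplex_reads"] += 1
        out.append(dup)
    return out, stats


def single_strand_consensus_reads(
    families: list[ReadFamily],
    min_family_agreement: float = 0.7,
) -> list[DuplexConsensusRead]:
    """Single-strand consensus reads (no duplex requirement).

    Each strand with at least one read yields one consensus read. This is
    the error-corrected-sequencing mode that does *not* use paired-strand
    information: single-strand damage artifacts survive it, which is what
    the duplex-vs-single-strand comparison demonstrates.
    """
    out: list[DuplexConsensusRead] = []
    for fam in families:
        filtered = filter_cigar_groups(fam)
        if filtered is None:
            continue
        for strand, reads in (
            ("top", filtered.top_reads),
            ("bottom", filtered.bottom_reads),
        ):
            cons = strand_consensus(reads, strand, min_family_agreement)
            if cons is None:
                continue
            out.append(
                DuplexConsensusRead(
                    family_id=f"{fam.family_id}:{strand}",
                    target=fam.target,
                    start=fam.frag_start,
                    end=fam.frag_end,
                    bases=cons.bases,
                    agreement=np.ones(len(cons.bases), dtype=bool),
                    molecule_id=fam.molecule_id,
                )
            )
    return out


def _trim_family(family: ReadFamily, trim_quality: int, mask_quality: int) -> None:
    """Quality-trim reads in place, padding trimmed tails with N.

    Keeping reads at full fragment length (N-padded) preserves columnwise
    alignment within the family.
    """
    for reads in (family.top_reads, family.bottom_reads):
        for r in reads:
            bases, quals = quality_trim(r.bases, r.quals, trim_quality, mask_quality)
            if len(bases) < len(r.bases):
                pad = len(r.bases) - len(bases)
                bases = bases + "N" * pad
                quals = quals + chr(33) * pad
            r.bases, r.quals = bases, quals


def clip_overlap(
    mate_a: tuple[int, int], mate_b: tuple[int, int]
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Balanced hard clipping of an overlapping mate pair.

    Each genomic position of the overlap is kept by exactly one mate; the
    overlap is split at its midpoint, the left mate keeping the extra base
    when the overlap length is odd. Non-overlapping pairs are returned
    unchanged. Intervals are 0-based half-open ``(start, end)``.
    """
    (a_start, a_end), (b_start, b_end) = mate_a, mate_b
    if a_start > b_start or (a_start == b_start and a_end > b_end):
        (b_clip, a_clip) = clip_overlap(mate_b, mate_a)
        return a_clip, b_clip
    ov_start, ov_end = max(a_start, b_start), min(a_end, b_end)
    if ov_start >= ov_end:
        return mate_a, mate_b
    if b_end < a_end:  # mate strictly contained: drop it, keep the container
        return mate_a, (b_start, b_start)
    mid = ov_start + (ov_end - ov_start + 1) // 2  # left mate gets the extra
    return (a_start, mid), (mid, b_end)
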