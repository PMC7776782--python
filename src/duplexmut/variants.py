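"""Pileup and ultrarare variant calling from duplex consensus reads.

Every nonreference duplex base is a candidate mutation: calls are emitted
at any alternate molecule count >= 1, because a duplex consensus base
already encodes agreement of both source strands. N bases never contribute
to depth. Germline polymorphisms are separated from somatic mutations by a
variant-allele-frequency threshold and excluded from downstream
mutant-frequency and clonality analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .consensus import DuplexConsensusRead
from .contexts import DNA, encode
from .panel import TargetRegion

__all__ = [
    "VariantCall",
    "pileup",
    "call_variants",
    "flag_germline",
    "mismatch_frequency",
    "calls_from_truth",
    "calls_to_frame",
    "calls_from_frame",
    "write_vcf",
]


@dataclass
class VariantCall:
    """One (position, alt) observation in one sample."""

    target: str
    position: int  # 0-based
    ref: str
    alt: str
    alt_count: int
    depth: int
    sample: str = ""
    tissue: str = ""
    treatment: str = ""
    germline: bool = False
    clonal: bool = False
    consequence: str = ""

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref equals alt")
        if self.alt_count < 1:
            raise ValueError("alt_count must be >= 1")
        if self.depth < self.alt_count:
            raise ValueError("depth must be >= alt_count")

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth


def pileup(
    reads: list[DuplexConsensusRead], panel: list[TargetRegion]
) -> dict[str, np.ndarray]:
    """Per-target base-count matrices (5 x length; A,C,G,T,N rows).

    Reads must map within panel intervals (synthetic reads carry true
    coordinates); a read outside the panel is an error, not a skip.
    """
    by_name = {t.name: t for t in panel}
    counts = {
        t.name: np.zeros((5, t.length), dtype=np.int64) for t in panel
    }
    for r in reads:
        t = by_name.get(r.target)
        if t is None:
            raise ValueError(f"read maps to unknown target {r.target!r}")
        if r.start < 0 or r.end > t.length:
            raise ValueError(
                f"read {r.family_id} outside target {t.name}: "
                f"{r.start}-{r.end} vs length {t.length}"
            )
        codes = encode(r.bases)
        np.add.at(counts[t.name], (codes, np.arange(r.start, r.end)), 1)
    return counts


def duplex_depth(columns: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Per-position duplex depth (N excluded)."""
    return {name: m[:4].sum(axis=0) for name, m in columns.items()}


def total_duplex_bp(
    columns: dict[str, np.ndarray], panel: list[TargetRegion] | None = None
) -> int:
    """Total duplex base pairs; restricted to reportable territory if set."""
    if panel is None:
        return int(sum(m[:4].sum() for m in columns.values()))
    total = 0
    for t in panel:
        depth = columns[t.name][:4].sum(axis=0)
        for s, e in t.reportable_intervals:
            total += int(depth[s:e].sum())
    return total


def call_variants(
    columns: dict[str, np.ndarray],
    panel: list[TargetRegion],
    min_alt_count: int = 1,
    sample: str = "",
    reportable_only: bool = True,
) -> list[VariantCall]:
    """Emit one call per (position, alt) with count >= ``min_alt_count``.

    Multi-allelic positions yield one call per alternate allele.
    """
    by_name = {t.name: t for t in panel}
    calls: list[VariantCall] = []
    for name, m in columns.items():
        t = by_name[name]
        ref_codes = encode(t.sequence)
        depth = m[:4].sum(axis=0)
        for alt_code in range(4):
            hits = np.flatnonzero(
                (m[alt_code] >= min_alt_count) & (ref_codes != alt_code)
            )
            for pos in hits:
                if reportable_only and not t.in_reportable(int(pos)):
                    continue
                calls.append(
                    VariantCall(
                        target=name,
                        position=int(pos),
                        ref=t.sequence[pos],
                        alt=DNA[alt_code],
                        alt_count=int(m[alt_code, pos]),
                        depth=int(depth[pos]),
                        sample=sample,
                    )
                )
    calls.sort(key=lambda c: (c.target, c.position, c.alt))
    return calls


def flag_germline(
    calls: list[VariantCall], vaf_threshold: float = 0.3
) -> list[VariantCall]:
    """Flag calls at or above the VAF threshold as germline (in place)."""
    if not 0 < vaf_threshold <= 1:
        raise ValueError("vaf_threshold must be in (0, 1]")
    for c in calls:
        c.germline = c.vaf >= vaf_threshold
    return calls


def mismatch_frequency(
    columns: dict[str, np.ndarray], panel: list[TargetRegion]
) -> float:
    """Raw nonreference base fraction of a pileup (N excluded).

    The per-nucleotide mutant frequency of a consensus pileup: total
    nonreference ACGT observations over total duplex depth.
    """
    by_name = {t.name: t for t in panel}
    mismatches = 0
    depth = 0
    for name, m in columns.items():
        ref_codes = encode(by_name[name].sequence)
        acgt = m[:4]
        d = acgt.sum(axis=0)
        ref_support = acgt[ref_codes, np.arange(m.shape[1])]
        mismatches += int((d - ref_support).sum())
        depth += int(d.sum())
    return mismatches / depth if depth else 0.0


def calls_from_truth(
    truth: pd.DataFrame,
    panel: list[TargetRegion],
    n_genomes: int,
    sample: str = "",
) -> list[VariantCall]:
    """Collapse a ground-truth mutation table into ideal variant calls.

    Models a lossless sequencing experiment in which every genome copy
    yields exactly one duplex molecule per target position: depth equals
    ``n_genomes * copies`` and the alternate count is the number of
    molecules carrying the variant. Used for statistical studies of the
    estimators at depths where read-level simulation is unnecessary.
    """
    by_name = {t.name: t for t in panel}
    calls = []
    if not len(truth):
        return calls
    grouped = truth.groupby(["target", "position", "alt"], sort=True)
    for (target, pos, alt), grp in grouped:
        t = by_name[target]
        calls.append(
            VariantCall(
                target=target,
                position=int(pos),
                ref=t.sequence[int(pos)],
                alt=alt,
                alt_count=len(grp),
                depth=n_genomes * t.copies_per_genome,
                sample=sample or (grp["sample"].iloc[0] if "sample" in grp else ""),
            )
        )
    return calls


_CALL_COLUMNS = [
    "sample", "tissue", "treatment", "target", "position", "ref", "alt",
    "alt_count", "depth", "vaf", "germline", "clonal", "consequence",
]


def calls_to_frame(calls: list[VariantCall]) -> pd.DataFrame:
    """Flat TSV-ready mirror of a call list."""
    return pd.DataFrame(
        [
            {
                "sample": c.sample, "tissue": c.tissue,
                "treatment": c.treatment, "target": c.target,
                "position": c.position, "ref": c.ref, "alt": c.alt,
                "alt_count": c.alt_count, "depth": c.depth, "vaf": c.vaf,
                "germline": c.germline, "clonal": c.clonal,
                "consequence": c.consequence,
            }
            for c in calls
        ],
        columns=_CALL_COLUMNS,
    )


def calls_from_frame(df: pd.DataFrame) -> list[VariantCall]:
    calls = []
    for row in df.itertuples(index=False):
        calls.append(
            VariantCall(
                target=row.target, position=int(row.position), ref=row.ref,
                alt=row.alt, alt_count=int(row.alt_count),
                depth=int(row.depth), sample=str(row.sample),
                tissue=str(getattr(row, "tissue", "") or ""),
                treatment=str(getattr(row, "treatment", "") or ""),
                germline=bool(row.germline), clonal=bool(row.clonal),
                consequence=str(getattr(row, "consequence", "") or ""),
            )
        )
    return calls


def write_vcf(
    calls: list[VariantCall],
    panel: list[TargetRegion],
    path: str | Path,
    sample: str,
) -> None:
    """Write one sample's calls as a minimal VCF (1-based positions)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=ALTC,Number=1,Type=Integer,Description='
        '"Alternate duplex molecule count">',
        '##INFO=<ID=DDP,Number=1,Type=Integer,Description="Duplex depth">',
        '##INFO=<ID=VAF,Number=1,Type=Float,Description='
        '"Variant allele frequency">',
        '##FILTER=<ID=germline,Description="VAF above germline threshold">',
    ]
    for t in panel:
        lines.append(f"##contig=<ID={t.contig},length={t.end}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    by_name = {t.name: t for t in panel}
    for c in sorted(calls, key=lambda c: (c.target, c.position, c.alt)):
        t = by_name[c.target]
        filt = "germline" if c.germline else "PASS"
        lines.append(
            f"{t.contig}\t{t.start + c.position + 1}\t.\t{c.ref}\t{c.alt}"
            f"\t.\t{filt}\tALTC={c.alt_count};DDP={c.depth};VAF={c.vaf:.3e}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
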