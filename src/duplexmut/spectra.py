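"""Substitution spectra, strand bias, and coding consequences.

Spectra are context-normalized: raw class counts are divided by the
double-stranded abundance of each class's reference base (6-class) or
trinucleotide context (96-class) in the interrogated territory and then
renormalized to sum to 1, so regions of different base composition become
comparable.

Strand bias contrasts each substitution type with its reciprocal
(complementary) type, both oriented to the coding (nontranscribed) strand
of a transcribed target. Transcription-coupled repair removes lesions from
the template strand, so a transcribed gene shows asymmetric reciprocal
frequencies while a nontranscribed one does not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contexts import (
    DNA,
    SBS6,
    SBS6_INDEX,
    SBS96,
    SBS96_INDEX,
    complement,
    pyrimidine_base_abundance,
    pyrimidine_substitution,
    revcomp,
    sbs96_class,
    trinucleotide_abundance,
    CONTEXTS32_INDEX,
)
from .panel import TargetRegion
from .variants import VariantCall

__all__ = [
    "SpectrumVector",
    "simple_spectrum",
    "trinucleotide_spectrum",
    "StrandBiasResult",
    "strand_bias",
    "annotate_consequence",
    "chi_square_spectrum_test",
    "plot_spectrum",
]

#: the 12 strand-resolved substitution types, coding-strand orientation
SUBSTITUTIONS12: tuple[str, ...] = tuple(
    f"{r}>{a}" for r in DNA for a in DNA if r != a
)


@dataclass(frozen=True)
class SpectrumVector:
    """Raw class counts plus context-normalized proportions."""

    labels: tuple[str, ...]
    counts: np.ndarray
    proportions: np.ndarray | None  # None when unnormalizable (no calls)
    n_dropped: int = 0

    @property
    def normalized(self) -> bool:
        return self.proportions is not None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": self.labels,
                "count": self.counts,
                "proportion": (
                    self.proportions
                    if self.normalized
                    else np.zeros(len(self.labels))
                ),
            }
        )


def _weighted_molecules(calls: list[VariantCall]) -> list[tuple[VariantCall, int]]:
    return [(c, c.alt_count) for c in calls if not c.germline]


def simple_spectrum(
    calls: list[VariantCall], panel: list[TargetRegion]
) -> SpectrumVector:
    """Six-class pyrimidine-space spectrum, base-abundance normalized.

    Each call contributes its alternate molecule count; purine-reference
    calls are complemented into pyrimidine space. Counts are divided by
    the panel's double-stranded pyrimidine base abundance per class and
    renormalized to 1.
    """
    counts = np.zeros(6, dtype=np.int64)
    for c, weight in _weighted_molecules(calls):
        counts[SBS6_INDEX[pyrimidine_substitution(c.ref, c.alt)]] += weight
    abundance = pyrimidine_base_abundance(t.sequence for t in panel)
    denom = np.array([abundance[lab[0]] for lab in SBS6], dtype=float)
    if counts.sum() == 0:
        return SpectrumVector(SBS6, counts, None)
    rates = np.divide(counts, denom, out=np.zeros(6), where=denom > 0)
    return SpectrumVector(SBS6, counts, rates / rates.sum())


def trinucleotide_spectrum(
    calls: list[VariantCall], panel: list[TargetRegion]
) -> SpectrumVector:
    """96-class spectrum normalized by double-stranded 3-mer abundance.

    The context is read from the reference sequence around each call and
    reverse-complemented into pyrimidine orientation when the reference
    base is a purine. Calls at the first or last base of a target have no
    flanking context; they are dropped and counted in ``n_dropped``.
    """
    by_name = {t.name: t for t in panel}
    counts = np.zeros(96, dtype=np.int64)
    dropped = 0
    for c, weight in _weighted_molecules(calls):
        t = by_name[c.target]
        if c.position == 0 or c.position == t.length - 1:
            dropped += 1
            continue
        f5 = t.sequence[c.position - 1]
        f3 = t.sequence[c.position + 1]
        counts[SBS96_INDEX[sbs96_class(f5, c.ref, c.alt, f3)]] += weight
    if counts.sum() == 0:
        return SpectrumVector(SBS96, counts, None, n_dropped=dropped)
    abundance = trinucleotide_abundance(t.sequence for t in panel)
    ctx_of_class = np.array(
        [CONTEXTS32_INDEX[lab[0] + lab[2] + lab[6]] for lab in SBS96]
    )
    denom = abundance[ctx_of_class].astype(float)
    rates = np.divide(counts, denom, out=np.zeros(96), where=denom > 0)
    return SpectrumVector(SBS96, counts, rates / rates.sum(), n_dropped=dropped)


@dataclass(frozen=True)
class StrandBiasResult:
    """Reciprocal-substitution comparison for one target."""

    target: str
    applicable: bool
    table: pd.DataFrame | None  # None when target is nontranscribed

    def fold(self, substitution: str) -> float:
        if not self.applicable:
            raise ValueError(f"{self.target}: strand bias not applicable")
        row = self.table[self.table["substitution"] == substitution]
        return float(row["fold"].iloc[0])


def _binom_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson interval for a binomial proportion."""
    alpha = 1 - conf
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def strand_bias(
    calls: list[VariantCall],
    target: TargetRegion,
    mean_depth: float,
    conf: float = 0.95,
) -> StrandBiasResult:
    """Per-substitution mutant frequencies against their reciprocals.

    All 12 substitution types are oriented to the coding (nontranscribed)
    strand of the target; each type's MF is its molecule count divided by
    (abundance of its reference base x mean duplex depth), with
    Clopper-Pearson CIs. ``fold`` is MF(type) / MF(reciprocal type); a
    zero reciprocal count yields a NaN point estimate with a finite lower
    CI bound (one-sided) rather than infinity.

    Nontranscribed targets return ``applicable=False``.
    """
    if not target.transcribed:
        return StrandBiasResult(target.name, False, None)
    flip = target.transcribed_strand == "+"  # gene coded on the minus strand
    seq = revcomp(target.sequence) if flip else target.sequence
    base_n = {b: seq.count(b) for b in DNA}

    counts = dict.fromkeys(SUBSTITUTIONS12, 0)
    for c, weight in _weighted_molecules(calls):
        if c.target != target.name:
            continue
        ref, alt = (complement(c.ref), complement(c.alt)) if flip else (c.ref, c.alt)
        counts[f"{ref}>{alt}"] += weight

    rows = {}
    for sub in SUBSTITUTIONS12:
        ref = sub[0]
        n_trials = max(1, round(base_n[ref] * mean_depth))
        k = counts[sub]
        lo, hi = _binom_ci(k, n_trials, conf)
        rows[sub] = {
            "substitution": sub,
            "count": k,
            "mf": k / n_trials,
            "mf_low": lo,
            "mf_high": hi,
        }
    out = []
    for sub in SUBSTITUTIONS12:
        rsub = f"{complement(sub[0])}>{complement(sub[2])}"
        a, b = rows[sub], rows[rsub]
        if b["count"] > 0:
            fold = a["mf"] / b["mf"]
            fold_ci = (
                a["mf_low"] / b["mf_high"] if b["mf_high"] > 0 else 0.0,
                a["mf_high"] / b["mf_low"] if b["mf_low"] > 0 else float("inf"),
            )
        else:
            fold = float("nan")
            fold_ci = (
                a["mf_low"] / b["mf_high"] if b["mf_high"] > 0 else 0.0,
                float("inf"),
            )
        out.append(
            {
                **a,
                "reciprocal": rsub,
                "reciprocal_count": b["count"],
                "fold": fold,
                "fold_low": fold_ci[0],
                "fold_high": fold_ci[1],
            }
        )
    return StrandBiasResult(target.name, True, pd.DataFrame(out))


_CODON_TABLE: dict[str, str] = {}


def _translate(codon: str) -> str:
    if not _CODON_TABLE:
        from Bio.Seq import Seq

        for b1 in DNA:
            for b2 in DNA:
                for b3 in DNA:
                    c = b1 + b2 + b3
                    _CODON_TABLE[c] = str(Seq(c).translate())
    return _CODON_TABLE[codon]


def annotate_consequence(call: VariantCall, target: TargetRegion) -> str:
    """Classify a substitution as synonymous / missense / nonsense.

    Uses the standard genetic code on the codon containing the call, read
    in the target's frame. Noncoding targets (``frame_offset is None``)
    return ``"noncoding"``; incomplete codons at target edges or ambiguous
    bases return ``"unclassified"``.
    """
    if target.frame_offset is None:
        return "noncoding"
    rel = call.position - target.frame_offset
    if rel < 0:
        return "unclassified"
    codon_start = target.frame_offset + (rel // 3) * 3
    codon = target.sequence[codon_start : codon_start + 3]
    if len(codon) < 3 or any(b not in DNA for b in codon):
        return "unclassified"
    offset = call.position - codon_start
    if codon[offset] != call.ref:
        raise ValueError(
            f"call ref {call.ref} disagrees with reference codon {codon}"
        )
    mutant = codon[:offset] + call.alt + codon[offset + 1 :]
    aa_ref, aa_alt = _translate(codon), _translate(mutant)
    if aa_alt == aa_ref:
        return "synonymous"
    if aa_alt == "*":
        return "nonsense"
    return "missense"


def chi_square_spectrum_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    min_expected: float = 5.0,
) -> tuple[float, float]:
    """Chi-square homogeneity test between two spectra of raw counts.

    Classes whose expected count falls below ``min_expected`` are pooled
    into a single "other" class (repeatedly, until the table is valid), and
    classes empty in both spectra are dropped first.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("spectra must share class labels")
    keep = (a + b) > 0
    a, b = a[keep], b[keep]
    if a.size == 0:
        raise ValueError("both spectra are all-zero")
    while a.size > 2:
        table = np.vstack([a, b])
        expected = (
            table.sum(axis=1, keepdims=True)
            * table.sum(axis=0, keepdims=True)
            / table.sum()
        )
        bad = (expected < min_expected).any(axis=0)
        if bad.sum() < 2 or bad.all():
            break
        a = np.append(a[~bad], a[bad].sum())
        b = np.append(b[~bad], b[bad].sum())
    stat, p, _, _ = stats.chi2_contingency(np.vstack([a, b]), correction=False)
    return float(stat), float(p)


def plot_spectrum(spectrum: SpectrumVector, ax=None, title: str = ""):
    """Bar plot of a normalized spectrum (96-class plots group by type)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(
            figsize=(12, 3) if len(spectrum.labels) == 96 else (5, 3)
        )
    values = (
        spectrum.proportions
        if spectrum.normalized
        else np.zeros(len(spectrum.labels))
    )
    if len(spectrum.labels) == 96:
        palette = ["#03bcee", "#010101", "#e32926", "#cac9c9", "#a1ce63",
                   "#ebc6c4"]
        colors = [palette[i // 16] for i in range(96)]
    else:
        colors = None
    ax.bar(range(len(values)), values, color=colors)
    ax.set_xticks(range(len(spectrum.labels)))
    ax.set_xticklabels(spectrum.labels, rotation=90, fontsize=4)
    ax.set_ylabel("proportion")
    if title:
        ax.set_title(title)
    return ax
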