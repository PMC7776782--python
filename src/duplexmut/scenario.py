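"""Mutagenesis scenarios: the ground truth the pipeline later estimates.

A scenario fixes, per (tissue, treatment) group, a true per-nucleotide
mutant frequency and a 96-class substitution signature, plus cohort-wide
settings: a transcription-coupled-repair strand-bias factor and a list of
clonal expansions (an identical variant carried by a fixed fraction of
cells). Background somatic mutant frequencies in untreated rodent tissue
sit near 1e-7 per nucleotide; strong mutagens raise them roughly tenfold,
and locus-level frequencies span 1e-8 to 1e-5.

The named signatures below are synthetic, parametric stand-ins shaped like
the classic exposure spectra (they are not a published catalogue):

* ``background`` — ageing-like: C>T at CpG plus oxidative C>A.
* ``bap_like`` — bulky-adduct-like: dominated by C>A (G·C→T·A) with CpG
  preference.
* ``enu_like`` — alkylator-like: T>C and T>A rich.
* ``urethane_like`` — T>A in an NTG context with a T>C shoulder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contexts import DNA, SBS6, SBS96

__all__ = [
    "GroupSpec",
    "CloneSpec",
    "MutagenesisScenario",
    "signature_from_motifs",
    "named_signatures",
]


def signature_from_motifs(motifs: dict[str, float]) -> np.ndarray:
    """Build a normalized 96-vector from motif weights.

    Keys look like ``"N[C>A]N"`` / ``"A[C>T]G"`` — ``N`` matches any flank.
    Weight is spread uniformly over the matching classes; the result sums
    to 1.
    """
    sig = np.zeros(96)
    for motif, weight in motifs.items():
        f5, sub, f3 = motif[0], motif[2:5], motif[6]
        if sub not in SBS6:
            raise ValueError(f"bad substitution in motif {motif!r}")
        hits = [
            i
            for i, lab in enumerate(SBS96)
            if lab[2:5] == sub
            and (f5 == "N" or lab[0] == f5)
            and (f3 == "N" or lab[6] == f3)
        ]
        if not hits:
            raise ValueError(f"motif {motif!r} matches no class")
        sig[hits] += weight / len(hits)
    total = sig.sum()
    if total <= 0:
        raise ValueError("signature has no mass")
    return sig / total


def named_signatures() -> dict[str, np.ndarray]:
    """Synthetic exposure-shaped signatures keyed by name."""
    return {
        "background": signature_from_motifs(
            {"N[C>T]G": 0.40, "N[C>A]N": 0.25, "N[C>G]N": 0.10,
             "N[T>C]N": 0.15, "N[T>A]N": 0.05, "N[C>T]A": 0.05}
        ),
        "bap_like": signature_from_motifs(
            {"N[C>A]G": 0.35, "N[C>A]N": 0.30, "N[C>G]N": 0.17,
             "N[C>T]N": 0.15, "N[T>A]N": 0.03}
        ),
        "enu_like": signature_from_motifs(
            {"N[T>C]N": 0.35, "N[T>A]N": 0.25, "N[C>T]N": 0.25,
             "N[T>G]N": 0.10, "N[C>A]N": 0.05}
        ),
        "urethane_like": signature_from_motifs(
            {"N[T>A]G": 0.45, "N[T>C]N": 0.25, "N[T>G]G": 0.10,
             "N[C>A]N": 0.12, "N[C>T]N": 0.08}
        ),
    }


@dataclass(frozen=True)
class GroupSpec:
    """One (tissue, treatment) cohort group of replicate animals.

    ``mutant_frequency`` is the true per-nucleotide rate — a scalar for
    the whole panel or a ``{target: rate}`` mapping for locus-specific
    mutability.
    """

    tissue: str
    treatment: str
    n_animals: int
    mutant_frequency: float | dict[str, float]
    signature: np.ndarray

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        rates = (
            self.mutant_frequency.values()
            if isinstance(self.mutant_frequency, dict)
            else [self.mutant_frequency]
        )
        if any(r < 0 for r in rates):
            raise ValueError("mutant_frequency must be >= 0")
        sig = np.asarray(self.signature, dtype=float)
        if sig.shape != (96,):
            raise ValueError("signature must be a 96-vector")
        if (sig < 0).any():
            raise ValueError("signature entries must be >= 0")
        if abs(sig.sum() - 1.0) > 1e-6:
            raise ValueError("signature must sum to 1")
        object.__setattr__(self, "signature", sig)


@dataclass(frozen=True)
class CloneSpec:
    """A clonal expansion: one variant carried by a fraction of cells.

    ``tissue``/``treatment`` of ``None`` apply the clone to every group.
    """

    target: str
    position: int
    alt: str
    cell_fraction: float
    tissue: str | None = None
    treatment: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.cell_fraction <= 1:
            raise ValueError("cell_fraction must be in (0, 1]")
        if self.alt not in DNA:
            raise ValueError(f"alt must be one of {DNA}")

    def applies_to(self, tissue: str, treatment: str) -> bool:
        return (self.tissue is None or self.tissue == tissue) and (
            self.treatment is None or self.treatment == treatment
        )


@dataclass(frozen=True)
class MutagenesisScenario:
    """Cohort design plus the true mutational process per group."""

    groups: tuple[GroupSpec, ...]
    strand_bias_factor: float = 1.0
    clones: tuple[CloneSpec, ...] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "clones", tuple(self.clones))
        if self.strand_bias_factor < 1:
            raise ValueError("strand_bias_factor must be >= 1")
        if not self.groups:
            raise ValueError("scenario needs at least one group")

    def sample_table(self) -> list[dict]:
        """Flat per-animal sample sheet with deterministic sample ids."""
        rows = []
        for g in self.groups:
            for a in range(g.n_animals):
                rows.append(
                    {
                        "sample": f"{g.tissue}_{g.treatment}_{a + 1:02d}",
                        "tissue": g.tissue,
                        "treatment": g.treatment,
                        "animal": a + 1,
                    }
                )
        return rows
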