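"""Mutant-frequency estimation, fold induction, and clonality.

The per-nucleotide mutant frequency (MF) of a sample is the number of
mutant nucleotides observed among all duplex molecules divided by the
total number of duplex base pairs interrogated. Counts are treated as
Poisson, with exact (Garwood) confidence intervals.

A recurrent identical variant can mean two things: independent mutations
hitting the same residue, or a clonal expansion of one mutagenic event.
The classifier fits a normal distribution to log10 VAF over non-germline
calls; calls lying far in the upper tail *and* observed in multiple
molecules are deemed clonal, and with clone collapsing enabled a clonal
call contributes a single event to the mutant count no matter how many
molecules carry it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .variants import VariantCall

__all__ = [
    "MutantFrequencyEstimate",
    "poisson_ci",
    "mutant_frequency",
    "fold_induction",
    "ClonalityModel",
    "ClonalityResults",
    "classify_clonality",
    "hotspot_report",
    "cohort_summary",
]


def poisson_ci(count: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) confidence interval for a Poisson count."""
    if count < 0:
        raise ValueError("count must be >= 0")
    alpha = 1 - conf
    lower = 0.0 if count == 0 else stats.chi2.ppf(alpha / 2, 2 * count) / 2
    upper = stats.chi2.ppf(1 - alpha / 2, 2 * count + 2) / 2
    return lower, upper


@dataclass(frozen=True)
class MutantFrequencyEstimate:
    """Mutant-frequency point estimate with its exact Poisson CI."""

    scope: str
    n_mutant: int  # mutant molecules, clonal calls collapsed to 1
    n_mutant_uncollapsed: int  # raw mutant molecule count
    n_sites: int  # distinct (position, alt) pairs
    duplex_bp: int
    mf: float
    ci: tuple[float, float]

    def __str__(self) -> str:
        return (
            f"{self.scope}: MF {self.mf:.3e} "
            f"[{self.ci[0]:.3e}, {self.ci[1]:.3e}] "
            f"({self.n_mutant} mutants / {self.duplex_bp} duplex bp)"
        )


def mutant_frequency(
    calls: list[VariantCall],
    duplex_bp: int,
    clone_collapse: bool = True,
    conf: float = 0.95,
    scope: str = "",
) -> MutantFrequencyEstimate:
    """Per-nucleotide mutant frequency over germline-filtered calls.

    Each call contributes its alternate molecule count; a call classified
    clonal contributes one event when ``clone_collapse`` is set, since the
    whole expansion is attributable to a single mutagenic origin.
    """
    if duplex_bp <= 0:
        raise ValueError("duplex_bp must be > 0")
    somatic = [c for c in calls if not c.germline]
    uncollapsed = sum(c.alt_count for c in somatic)
    collapsed = sum(1 if c.clonal else c.alt_count for c in somatic)
    count = collapsed if clone_collapse else uncollapsed
    lo, hi = poisson_ci(count, conf)
    return MutantFrequencyEstimate(
        scope=scope,
        n_mutant=collapsed,
        n_mutant_uncollapsed=uncollapsed,
        n_sites=len({(c.target, c.position, c.alt) for c in somatic}),
        duplex_bp=duplex_bp,
        mf=count / duplex_bp,
        ci=(lo / duplex_bp, hi / duplex_bp),
    )


def fold_induction(treated_mf: float, control_mf: float) -> float:
    """Ratio of a treated group's mean MF to the control group's."""
    if control_mf < 0 or treated_mf < 0:
        raise ValueError("mutant frequencies must be >= 0")
    if control_mf == 0:
        warnings.warn("control MF is 0; fold induction undefined")
        return float("nan")
    return treated_mf / control_mf


@dataclass(frozen=True)
class ClonalityResults:
    """Fitted log10-VAF distribution and per-call classifications."""

    mean_log_vaf: float
    sd_log_vaf: float
    cutoff_sd: float
    n_calls: int
    labels: tuple[str, ...]  # singlet | multiplet-independent | clonal
    fitted: bool

    @property
    def threshold_log_vaf(self) -> float:
        return self.mean_log_vaf + self.cutoff_sd * self.sd_log_vaf

    @property
    def n_clonal(self) -> int:
        return sum(lab == "clonal" for lab in self.labels)

    def summary(self) -> str:
        lines = [
            "Clonality classification (log-normal VAF outlier model)",
            f"  non-germline calls: {self.n_calls}",
            f"  log10 VAF: mean {self.mean_log_vaf:.3f}, "
            f"sd {self.sd_log_vaf:.3f}",
            f"  outlier threshold: mean + {self.cutoff_sd:g} sd = "
            f"{self.threshold_log_vaf:.3f}",
            f"  clonal calls: {self.n_clonal}",
        ]
        if not self.fitted:
            lines.append("  (too few calls to fit; no call labelled clonal)")
        return "\n".join(lines)


class ClonalityModel:
    """Log-normal VAF outlier model over one sample's somatic calls.

    ``fit`` estimates the normal distribution of log10 VAF by moments
    (the maximum-likelihood fit for a normal) over non-germline calls and
    labels each call:

    * ``clonal`` — log10 VAF above mean + ``cutoff_sd``·sd *and* alternate
      count >= 2 (an expansion needs multiple molecules);
    * ``multiplet-independent`` — multiple molecules but no outlying VAF;
    * ``singlet`` — a single molecule.
    """

    def __init__(self, calls: list[VariantCall], min_calls: int = 5):
        self.calls = [c for c in calls if not c.germline]
        self.min_calls = min_calls

    def fit(self, cutoff_sd: float = 3.0) -> ClonalityResults:
        n = len(self.calls)
        fitted = n >= self.min_calls
        if fitted:
            log_vaf = np.log10([c.vaf for c in self.calls])
            mu = float(log_vaf.mean())
            sd = float(log_vaf.std(ddof=0))
        else:
            if n:
                warnings.warn(
                    f"only {n} non-germline calls (< {self.min_calls}); "
                    "clonality not fitted"
                )
            mu, sd = float("nan"), float("nan")
        labels = []
        threshold = mu + cutoff_sd * sd if fitted else float("inf")
        for c in self.calls:
            if (
                fitted
                and c.alt_count >= 2
                and np.log10(c.vaf) > threshold
            ):
                labels.append("clonal")
            elif c.alt_count >= 2:
                labels.append("multiplet-independent")
            else:
                labels.append("singlet")
        return ClonalityResults(
            mean_log_vaf=mu,
            sd_log_vaf=sd,
            cutoff_sd=cutoff_sd,
            n_calls=n,
            labels=tuple(labels),
            fitted=fitted,
        )


def classify_clonality(
    calls: list[VariantCall], cutoff_sd: float = 3.0, min_calls: int = 5
) -> ClonalityResults:
    """Fit the clonality model and write labels onto the calls."""
    model = ClonalityModel(calls, min_calls=min_calls)
    results = model.fit(cutoff_sd=cutoff_sd)
    for c, lab in zip(model.calls, results.labels):
        c.clonal = lab == "clonal"
    return results


def hotspot_report(
    calls: list[VariantCall],
    hotspots: list[tuple[str, str, int, int]],
    samples: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Summarise clonal recurrence at annotated hotspot residues.

    ``hotspots`` rows are ``(label, target, start, end)`` in target-local
    half-open coordinates (e.g. the three bases of an oncogenic codon);
    ``samples`` lists ``(sample, tissue)`` pairs defining each tissue's
    denominator (defaults to the samples present in ``calls``). One output
    row per (hotspot, tissue) with any data: the "n of m samples" summary.
    """
    if samples is None:
        samples = sorted({(c.sample, c.tissue) for c in calls})
    denom: dict[str, int] = {}
    for _, tissue in samples:
        denom[tissue] = denom.get(tissue, 0) + 1
    rows = []
    for label, target, start, end in hotspots:
        window = [
            c
            for c in calls
            if c.target == target and start <= c.position < end and not c.germline
        ]
        for tissue in sorted(denom):
            here = [c for c in window if c.tissue == tissue]
            clonal_samples = sorted({c.sample for c in here if c.clonal})
            if not here:
                continue
            rows.append(
                {
                    "hotspot": label,
                    "target": target,
                    "tissue": tissue,
                    "samples_with_clonal": len(clonal_samples),
                    "samples_total": denom[tissue],
                    "alt_alleles": ",".join(sorted({c.alt for c in here})),
                    "max_vaf": max(c.vaf for c in here),
                    "n_calls": len(here),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "hotspot", "target", "tissue", "samples_with_clonal",
            "samples_total", "alt_alleles", "max_vaf", "n_calls",
        ],
    )


def cohort_summary(
    per_sample: pd.DataFrame, control_treatment: str = "VC"
) -> dict:
    """Aggregate per-sample MF rows into cohort-level statistics.

    ``per_sample`` needs columns ``sample, tissue, treatment, duplex_bp,
    mf`` (one row per sample, or per sample x target). Returns the duplex
    base-pair grand total, per-(tissue, treatment) mean MFs, and fold
    inductions of every treated group over the control within its tissue.
    """
    required = {"tissue", "treatment", "duplex_bp", "mf"}
    missing = required - set(per_sample.columns)
    if missing:
        raise ValueError(f"per_sample is missing columns {sorted(missing)}")
    grand_total = int(per_sample["duplex_bp"].sum())
    groups = (
        per_sample.groupby(["tissue", "treatment"])
        .agg(mean_mf=("mf", "mean"), duplex_bp=("duplex_bp", "sum"),
             n_samples=("mf", "size"))
        .reset_index()
    )
    folds = []
    for tissue, sub in groups.groupby("tissue"):
        control = sub[sub["treatment"] == control_treatment]
        if control.empty:
            continue
        control_mf = float(control["mean_mf"].iloc[0])
        for row in sub.itertuples(index=False):
            if row.treatment == control_treatment:
                continue
            folds.append(
                {
                    "tissue": tissue,
                    "treatment": row.treatment,
                    "mean_mf": row.mean_mf,
                    "control_mf": control_mf,
                    "fold_induction": fold_induction(row.mean_mf, control_mf),
                }
            )
    return {
        "duplex_bp_total": grand_total,
        "group_means": groups,
        "fold_inductions": pd.DataFrame(
            folds,
            columns=["tissue", "treatment", "mean_mf", "control_mf",
                     "fold_induction"],
        ),
    }
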