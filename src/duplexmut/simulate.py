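"""Synthetic duplex-sequencing data.

Two layers of simulation feed the pipeline:

1. :func:`simulate_true_mutations` draws the *biological* ground truth —
   independent somatic mutations per molecule-nucleotide at the scenario's
   true mutant frequency, redistributed over the 96 substitution-in-context
   classes by the scenario signature, with classes whose pyrimidine sits on
   the template strand of a transcribed target down-weighted by the
   strand-bias factor (transcription-coupled repair), plus injected clonal
   expansions.
2. :func:`simulate_read_families` turns sampled source molecules into raw
   read families: semidegenerate barcode pairs from a whitelist (with
   optional corruption), shear points, per-strand read counts from a
   zero-truncated Poisson, independent per-read sequencing errors, and
   single-strand damage artifacts.

Damage is modelled as guanine oxidation on the damaged strand (G→T in that
strand's own orientation, so bottom-strand damage reads as C→A against the
reference). Because top-strand artifacts require a reference G and
bottom-strand artifacts a reference C, the two strands can never produce
the same artifactual (position, alt) — single-strand damage is structurally
discordant between strands, which is precisely the signal duplex consensus
exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contexts import DNA, complement, context_codes, sbs96_context_id
from .panel import TargetRegion
from .reads import Read, ReadFamily
from .scenario import CloneSpec, MutagenesisScenario

__all__ = [
    "PanelSiteIndex",
    "simulate_true_mutations",
    "simulate_cohort_truth",
    "ErrorModel",
    "FamilyModel",
    "simulate_read_families",
    "zero_truncated_poisson",
]

TRUTH_COLUMNS = ["target", "molecule", "position", "ref", "alt", "clone"]


class PanelSiteIndex:
    """Precomputed per-site context and strand-bias weights for a panel.

    Sites are all interior positions (those with a flanking context) of all
    targets, concatenated. For each of the 32 pyrimidine-centred contexts
    the index holds the eligible site ids; per site it stores the target,
    the local position, whether the pyrimidine of the reference pair is on
    the plus strand, and the per-copy sampling weight.
    """

    def __init__(self, panel: list[TargetRegion]):
        self.panel = list(panel)
        tgt_idx, pos, ctx, pyr_plus, copies, template_hit = [], [], [], [], [], []
        for ti, t in enumerate(self.panel):
            c, p = context_codes(t.sequence)
            n = len(c)
            tgt_idx.append(np.full(n, ti))
            pos.append(np.arange(1, n + 1))
            ctx.append(c)
            pyr_plus.append(p)
            copies.append(np.full(n, t.copies_per_genome))
            if t.transcribed:
                # pyrimidine strand == template strand -> lesion repaired
                hit = p if t.transcribed_strand == "+" else ~p
            else:
                hit = np.zeros(n, dtype=bool)
            template_hit.append(hit)
        self.target_index = np.concatenate(tgt_idx)
        self.position = np.concatenate(pos)
        self.context = np.concatenate(ctx)
        self.pyr_on_plus = np.concatenate(pyr_plus)
        self.copies = np.concatenate(copies)
        self.template_hit = np.concatenate(template_hit)
        self.n_sites = sum(t.length for t in self.panel)
        self.by_context = [
            np.flatnonzero(self.context == c) for c in range(32)
        ]

    def weights(self, strand_bias_factor: float) -> np.ndarray:
        w = np.ones(len(self.context))
        if strand_bias_factor > 1:
            w[self.template_hit] = 1.0 / strand_bias_factor
        return w


def simulate_true_mutations(
    panel: list[TargetRegion],
    mutant_frequency: float | dict[str, float],
    signature: np.ndarray,
    n_genomes: int,
    rng: np.random.Generator,
    strand_bias_factor: float = 1.0,
    clones: tuple[CloneSpec, ...] = (),
    site_index: PanelSiteIndex | None = None,
) -> pd.DataFrame:
    """Draw the ground-truth mutation table for one sample.

    Each molecule-nucleotide mutates independently with probability equal
    to ``mutant_frequency`` (averaged over the panel); the 96-class
    signature redistributes that rate over contexts and alternate alleles.
    A mapping ``{target name: rate}`` instead of a scalar gives each locus
    its own per-nucleotide rate (locus-to-locus mutability variation).
    Clone variants are additionally injected into
    ``floor(cell_fraction * n_genomes)`` molecules, lowest molecule index
    first.

    Returns a DataFrame with columns ``target, molecule, position, ref,
    alt, clone`` where ``molecule`` indexes genome copies
    (``genome * copies + copy``).
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    sig = np.asarray(signature, dtype=float)
    if sig.shape != (96,) or abs(sig.sum() - 1) > 1e-6 or (sig < 0).any():
        raise ValueError("signature must be a nonnegative 96-vector summing to 1")
    idx = site_index if site_index is not None else PanelSiteIndex(panel)
    w = idx.weights(strand_bias_factor)
    if isinstance(mutant_frequency, dict):
        missing = {t.name for t in panel} - set(mutant_frequency)
        if missing:
            raise ValueError(f"no mutant_frequency for targets {sorted(missing)}")
        per_target = np.array(
            [float(mutant_frequency[t.name]) for t in idx.panel]
        )
    else:
        per_target = np.full(len(idx.panel), float(mutant_frequency))
    if (per_target < 0).any():
        raise ValueError("mutant frequencies must be >= 0")
    site_rate = per_target[idx.target_index]

    recs: list[tuple] = []
    if per_target.max() > 0:
        for k in range(96):
            if sig[k] == 0:
                continue
            sites = idx.by_context[sbs96_context_id(k)]
            if len(sites) == 0:
                continue
            ws = w[sites] * idx.copies[sites] * site_rate[sites]
            if ws.sum() == 0:
                continue
            lam = (
                sig[k]
                * (idx.n_sites / len(sites))
                * ws.sum()
                * n_genomes
            )
            n_k = rng.poisson(lam)
            if n_k == 0:
                continue
            chosen = rng.choice(sites, size=n_k, p=ws / ws.sum())
            sub = k // 16
            alt_pyr = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")[sub][2]
            for s in chosen:
                ti = idx.target_index[s]
                t = idx.panel[ti]
                mol = rng.integers(0, n_genomes * t.copies_per_genome)
                pos = int(idx.position[s])
                ref = t.sequence[pos]
                alt = alt_pyr if idx.pyr_on_plus[s] else complement(alt_pyr)
                recs.append((t.name, int(mol), pos, ref, alt, False))

    df = pd.DataFrame(recs, columns=TRUTH_COLUMNS)
    if len(df):
        df = df.drop_duplicates(subset=["target", "molecule", "position"])

    clone_recs = []
    names = {t.name: t for t in panel}
    for clone in clones:
        if clone.target not in names:
            raise ValueError(f"clone target {clone.target!r} not in panel")
        t = names[clone.target]
        if not 0 <= clone.position < t.length:
            raise ValueError(
                f"clone position {clone.position} outside target "
                f"{clone.target} (length {t.length})"
            )
        ref = t.sequence[clone.position]
        if ref == clone.alt:
            raise ValueError("clone alt equals reference base")
        n_carriers = int(np.floor(clone.cell_fraction * n_genomes))
        for mol in range(n_carriers):
            clone_recs.append(
                (t.name, mol, clone.position, ref, clone.alt, True)
            )
    if clone_recs:
        cdf = pd.DataFrame(clone_recs, columns=TRUTH_COLUMNS)
        df = pd.concat([cdf, df], ignore_index=True).drop_duplicates(
            subset=["target", "molecule", "position"], keep="first"
        )
    return df.sort_values(["target", "molecule", "position"]).reset_index(
        drop=True
    )


def simulate_cohort_truth(
    panel: list[TargetRegion],
    scenario: MutagenesisScenario,
    n_genomes: int,
    site_index: PanelSiteIndex | None = None,
) -> pd.DataFrame:
    """Ground-truth tables for every animal of every scenario group.

    All randomness derives from ``scenario.seed`` via spawned substreams,
    so identical scenarios reproduce byte-identical truth tables.
    """
    idx = site_index if site_index is not None else PanelSiteIndex(panel)
    seeds = np.random.SeedSequence(scenario.seed).spawn(
        sum(g.n_animals for g in scenario.groups)
    )
    frames = []
    i = 0
    for g in scenario.groups:
        clones = tuple(
            c for c in scenario.clones if c.applies_to(g.tissue, g.treatment)
        )
        for a in range(g.n_animals):
            rng = np.random.default_rng(seeds[i])
            i += 1
            truth = simulate_true_mutations(
                panel,
                g.mutant_frequency,
                g.signature,
                n_genomes,
                rng,
                strand_bias_factor=scenario.strand_bias_factor,
                clones=clones,
                site_index=idx,
            )
            truth.insert(0, "sample", f"{g.tissue}_{g.treatment}_{a + 1:02d}")
            truth.insert(1, "tissue", g.tissue)
            truth.insert(2, "treatment", g.treatment)
            frames.append(truth)
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class ErrorModel:
    """Per-base noise rates of the sequencing process.

    ``seq_error_rate`` applies independently per read per base;
    ``damage_rate`` applies once per molecule strand at bases matching the
    damage chemistry (default: guanine oxidation, G→T on the damaged
    strand).
    """

    seq_error_rate: float = 0.001
    damage_rate: float = 0.0
    damage_ref: str = "G"
    damage_alt: str = "T"

    def __post_init__(self) -> None:
        for r in (self.seq_error_rate, self.damage_rate):
            if not 0 <= r < 0.5:
                raise ValueError("error rates must be in [0, 0.5)")


@dataclass(frozen=True)
class FamilyModel:
    """Family-size, barcode, and alignment-artifact model."""

    mean_reads_per_strand: float = 3.0
    strand_dropout: float = 0.05
    barcode_length: int = 8
    n_barcodes: int = 16
    barcode_corruption_rate: float = 0.01
    cigar_artifact_rate: float = 0.01
    base_quality: int = 37

    def make_whitelist(self, rng: np.random.Generator) -> list[str]:
        """Random barcode whitelist with pairwise Hamming distance >= 3.

        Distance 3 guarantees that a single corruption keeps margin >= 2
        to the next-best whitelist tag, so the correction rule is exact.
        """
        tags: list[str] = []
        arr: list[np.ndarray] = []
        while len(tags) < self.n_barcodes:
            cand = rng.integers(0, 4, self.barcode_length)
            if all(int((cand != a).sum()) >= 3 for a in arr):
                arr.append(cand)
                tags.append("".join(DNA[c] for c in cand))
        return tags


def zero_truncated_poisson(
    rng: np.random.Generator, mean: float, size: int
) -> np.ndarray:
    """Sample a zero-truncated Poisson by redrawing zeros."""
    out = rng.poisson(mean, size)
    mask = out == 0
    while mask.any():
        out[mask] = rng.poisson(mean, int(mask.sum()))
        mask = out == 0
    return out


def _corrupt(tag: str, rng: np.random.Generator) -> str:
    """Introduce 1 (usually) or 2 mismatches into a barcode."""
    n = 1 if rng.random() < 0.8 else 2
    chars = list(tag)
    for p in rng.choice(len(chars), size=n, replace=False):
        chars[p] = DNA[(DNA.index(chars[p]) + int(rng.integers(1, 4))) % 4]
    return "".join(chars)


def _artifact_cigar(length: int) -> str:
    half = length // 2
    return f"{half}M1I{length - half - 1}M"


def simulate_read_families(
    panel: list[TargetRegion],
    truth: pd.DataFrame | None,
    n_families: int,
    error_model: ErrorModel,
    family_model: FamilyModel,
    rng: np.random.Generator,
    n_genomes: int = 10_000,
    fragment_length: int = 120,
    whitelist: list[str] | None = None,
) -> tuple[list[ReadFamily], list[str]]:
    """Simulate raw read families from sampled source molecules.

    Each family corresponds to one double-stranded source fragment: a
    random shear window on a target sampled proportionally to target
    length x copy number, from a molecule drawn uniformly among
    ``n_genomes * copies`` genome copies. True mutations of that molecule
    (from ``truth``) appear on the reads of *both* strands; damage
    artifacts on exactly one; sequencing errors independently per read.

    Returns ``(families, whitelist)``.
    """
    if n_families < 0:
        raise ValueError("n_families must be >= 0")
    if whitelist is None:
        whitelist = family_model.make_whitelist(rng)
    mut_lookup: dict[tuple[str, int], list[tuple[int, str]]] = {}
    if truth is not None and len(truth):
        for t, m, p, a in zip(
            truth["target"], truth["molecule"], truth["position"], truth["alt"]
        ):
            mut_lookup.setdefault((t, int(m)), []).append((int(p), a))

    lengths = np.array([t.length for t in panel], dtype=float)
    copies = np.array([t.copies_per_genome for t in panel], dtype=float)
    pweights = lengths * copies
    pweights /= pweights.sum()

    tgt = rng.choice(len(panel), size=n_families, p=pweights)
    flens = np.minimum(fragment_length, lengths[tgt].astype(int))
    starts = (rng.random(n_families) * (lengths[tgt] - flens + 1)).astype(int)
    mols = rng.integers(0, (n_genomes * copies[tgt]).astype(int) + 0)
    n_top = zero_truncated_poisson(
        rng, family_model.mean_reads_per_strand, n_families
    )
    n_bottom = zero_truncated_poisson(
        rng, family_model.mean_reads_per_strand, n_families
    )
    drop = rng.random(n_families) < family_model.strand_dropout
    drop_side = rng.random(n_families) < 0.5
    n_top = np.where(drop & drop_side, 0, n_top)
    n_bottom = np.where(drop & ~drop_side, 0, n_bottom)
    dmg_top = (
        rng.binomial(flens, error_model.damage_rate)
        if error_model.damage_rate > 0
        else np.zeros(n_families, dtype=int)
    )
    dmg_bottom = (
        rng.binomial(flens, error_model.damage_rate)
        if error_model.damage_rate > 0
        else np.zeros(n_families, dtype=int)
    )
    bc_idx = np.empty((n_families, 2), dtype=int)
    bc_idx[:, 0] = rng.integers(0, len(whitelist), n_families)
    shift = rng.integers(1, len(whitelist), n_families)
    bc_idx[:, 1] = (bc_idx[:, 0] + shift) % len(whitelist)

    total_reads = int(n_top.sum() + n_bottom.sum())
    err_counts = (
        rng.binomial(
            np.repeat(flens, (n_top + n_bottom)), error_model.seq_error_rate
        )
        if error_model.seq_error_rate > 0
        else np.zeros(total_reads, dtype=int)
    )
    corrupt_flags = rng.random(total_reads) < family_model.barcode_corruption_rate
    artifact_flags = rng.random(total_reads) < family_model.cigar_artifact_rate

    qual_cache = {
        int(fl): chr(33 + family_model.base_quality) * int(fl)
        for fl in np.unique(flens)
    }
    comp_damage_ref = complement(error_model.damage_ref)
    comp_damage_alt = complement(error_model.damage_alt)

    families: list[ReadFamily] = []
    ri = 0  # flat read cursor into err_counts / corrupt / artifact arrays
    for m in range(n_families):
        t = panel[tgt[m]]
        fl = int(flens[m])
        s0 = int(starts[m])
        frag = t.sequence[s0 : s0 + fl]
        muts = mut_lookup.get((t.name, int(mols[m])))
        if muts:
            chars = list(frag)
            for p, a in muts:
                if s0 <= p < s0 + fl:
                    chars[p - s0] = a
            frag = "".join(chars)

        top_tpl, bottom_tpl = frag, frag
        if dmg_top[m]:
            chars = list(top_tpl)
            hit = False
            for p in rng.integers(0, fl, int(dmg_top[m])):
                if chars[p] == error_model.damage_ref:
                    chars[p] = error_model.damage_alt
                    hit = True
            if hit:
                top_tpl = "".join(chars)
        if dmg_bottom[m]:
            chars = list(bottom_tpl)
            hit = False
            for p in rng.integers(0, fl, int(dmg_bottom[m])):
                if chars[p] == comp_damage_ref:
                    chars[p] = comp_damage_alt
                    hit = True
            if hit:
                bottom_tpl = "".join(chars)

        b1, b2 = whitelist[bc_idx[m, 0]], whitelist[bc_idx[m, 1]]
        quals = qual_cache[fl]
        fam = ReadFamily(
            family_id=f"fam{m:07d}",
            barcode_pair=(b1, b2),
            target=t.name,
            frag_start=s0,
            frag_end=s0 + fl,
            molecule_id=int(mols[m]),
        )
        for strand, tpl, count in (
            ("top", top_tpl, int(n_top[m])),
            ("bottom", bottom_tpl, int(n_bottom[m])),
        ):
            obs1, obs2 = (b1, b2) if strand == "top" else (b2, b1)
            for _ in range(count):
                bases = tpl
                if err_counts[ri]:
                    chars = list(bases)
                    for p in rng.integers(0, fl, int(err_counts[ri])):
                        chars[p] = DNA[
                            (DNA.index(chars[p]) + int(rng.integers(1, 4))) % 4
                        ]
                    bases = "".join(chars)
                cigar = (
                    _artifact_cigar(fl) if artifact_flags[ri] else f"{fl}M"
                )
                r1 = _corrupt(obs1, rng) if corrupt_flags[ri] else obs1
                read = Read(bases=bases, quals=quals, cigar=cigar, bc1=r1, bc2=obs2)
                (fam.top_reads if strand == "top" else fam.bottom_reads).append(
                    read
                )
                ri += 1
        families.append(fam)
    return families, whitelist
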