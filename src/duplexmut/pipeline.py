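"""End-to-end pipeline: configuration, stages, and the run manifest.

Each stage reads and writes documented plain-text formats (FASTA, BED,
TSV, VCF, Newick, gzipped FASTQ) so stages can be run independently from
the command line; :func:`run_pipeline` chains them and writes a
machine-readable manifest. All randomness flows from the single config
seed; deterministic stages are byte-identical across reruns.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import LINKAGES, hierarchical_cluster
from .consensus import duplex_consensus_reads, group_families, DuplexConsensusRead
from .metrics import (
    classify_clonality,
    cohort_summary,
    hotspot_report,
    mutant_frequency,
)
from .panel import TargetRegion, generate_reference_panel, read_targets, write_panel
from .reads import raw_read_table
from .scenario import CloneSpec, GroupSpec, MutagenesisScenario, named_signatures
from .simulate import (
    ErrorModel,
    FamilyModel,
    simulate_cohort_truth,
    simulate_read_families,
)
from .spectra import (
    annotate_consequence,
    simple_spectrum,
    strand_bias,
    trinucleotide_spectrum,
)
from .variants import (
    call_variants,
    calls_from_frame,
    calls_to_frame,
    flag_germline,
    pileup,
    total_duplex_bp,
    write_vcf,
)

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``PipelineConfig.from_yaml``)."""

    seed: int
    panel: dict
    cohort: dict
    scenario: dict = dc_field(default_factory=dict)
    sequencing: dict = dc_field(default_factory=dict)
    consensus: dict = dc_field(default_factory=dict)
    calling: dict = dc_field(default_factory=dict)
    clonality: dict = dc_field(default_factory=dict)
    clustering: dict = dc_field(default_factory=dict)
    write_fastq: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        if "seed" not in raw:
            raise ConfigError("config must declare a seed")
        cfg = cls(
            seed=int(raw["seed"]),
            panel=dict(raw.get("panel") or {}),
            cohort=dict(raw.get("cohort") or {}),
            scenario=dict(raw.get("scenario") or {}),
            sequencing=dict(raw.get("sequencing") or {}),
            consensus=dict(raw.get("consensus") or {}),
            calling=dict(raw.get("calling") or {}),
            clonality=dict(raw.get("clonality") or {}),
            clustering=dict(raw.get("clustering") or {}),
            write_fastq=bool(raw.get("write_fastq", True)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.panel:
            raise ConfigError("config needs a panel section")
        generated = "n_targets" in self.panel
        from_files = "fasta" in self.panel
        if not generated and not from_files:
            raise ConfigError(
                "panel must give n_targets/length or fasta/bed/annotations"
            )
        if not self.cohort.get("treatments"):
            raise ConfigError("cohort.treatments must not be empty")
        known = set(named_signatures())
        for name, spec in self.cohort["treatments"].items():
            if "_" in name:
                raise ConfigError(f"treatment name {name!r} contains '_'")
            mf = spec.get("mutant_frequency", -1)
            rates = mf.values() if isinstance(mf, dict) else [mf]
            if any(float(r) < 0 for r in rates):
                raise ConfigError(f"{name}: mutant_frequency must be >= 0")
            if spec.get("signature", "background") not in known:
                raise ConfigError(
                    f"{name}: unknown signature {spec.get('signature')!r}; "
                    f"known: {sorted(known)}"
                )
        for tissue in self.cohort.get("tissues", ["tissue"]):
            if "_" in tissue:
                raise ConfigError(f"tissue name {tissue!r} contains '_'")
        agreement = float(self.consensus.get("min_family_agreement", 0.7))
        if not 0.5 < agreement <= 1:
            raise ConfigError("min_family_agreement must be in (0.5, 1]")
        germline = float(self.calling.get("germline_vaf", 0.3))
        if not 0 < germline <= 1:
            raise ConfigError("germline_vaf must be in (0, 1]")
        for key in ("seq_error_rate", "damage_rate"):
            rate = float(self.sequencing.get(key, 0.0))
            if not 0 <= rate < 0.5:
                raise ConfigError(f"{key} must be in [0, 0.5)")
        if float(self.scenario.get("strand_bias_factor", 1.0)) < 1:
            raise ConfigError("strand_bias_factor must be >= 1")
        linkage = self.clustering.get("linkage", "weighted")
        if linkage not in LINKAGES:
            raise ConfigError(f"linkage must be one of {LINKAGES}")

    # -- derived objects ---------------------------------------------------

    def build_panel(self) -> list[TargetRegion]:
        if "n_targets" in self.panel:
            return generate_reference_panel(
                int(self.panel["n_targets"]),
                int(self.panel.get("length", 300)),
                seed=self.seed,
            )
        return read_targets(
            self.panel["bed"],
            self.panel["fasta"],
            self.panel["annotations"],
            mask_bed_path=self.panel.get("mask"),
            mask_pad=int(self.panel.get("mask_pad", 10)),
        )

    def build_scenario(self) -> MutagenesisScenario:
        sigs = named_signatures()
        groups = []
        for tissue in self.cohort.get("tissues", ["tissue"]):
            for name, spec in self.cohort["treatments"].items():
                groups.append(
                    GroupSpec(
                        tissue=tissue,
                        treatment=name,
                        n_animals=int(self.cohort.get("animals_per_group", 2)),
                        mutant_frequency=(
                            {k: float(v) for k, v in spec["mutant_frequency"].items()}
                            if isinstance(spec["mutant_frequency"], dict)
                            else float(spec["mutant_frequency"])
                        ),
                        signature=sigs[spec.get("signature", "background")],
                    )
                )
        clones = tuple(
            CloneSpec(
                target=c["target"],
                position=int(c["position"]),
                alt=c["alt"],
                cell_fraction=float(c["cell_fraction"]),
                tissue=c.get("tissue"),
                treatment=c.get("treatment"),
            )
            for c in self.scenario.get("clones", [])
        )
        return MutagenesisScenario(
            groups=tuple(groups),
            strand_bias_factor=float(
                self.scenario.get("strand_bias_factor", 1.0)
            ),
            clones=clones,
            seed=self.seed,
        )

    def error_model(self) -> ErrorModel:
        return ErrorModel(
            seq_error_rate=float(self.sequencing.get("seq_error_rate", 0.001)),
            damage_rate=float(self.sequencing.get("damage_rate", 0.0)),
        )

    def family_model(self) -> FamilyModel:
        return FamilyModel(
            mean_reads_per_strand=float(
                self.sequencing.get("mean_reads_per_strand", 3.0)
            ),
            strand_dropout=float(self.sequencing.get("strand_dropout", 0.05)),
            barcode_corruption_rate=float(
                self.sequencing.get("barcode_corruption_rate", 0.01)
            ),
            cigar_artifact_rate=float(
                self.sequencing.get("cigar_artifact_rate", 0.01)
            ),
        )


def _parse_sample(sample: str) -> tuple[str, str]:
    tissue, treatment, _ = sample.split("_")
    return tissue, treatment


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict[str, Path]:
    """Panel + ground truth + raw reads for every sample."""
    outdir.mkdir(parents=True, exist_ok=True)
    panel = cfg.build_panel()
    scenario = cfg.build_scenario()
    paths = {
        "fasta": outdir / "panel.fasta",
        "bed": outdir / "targets.bed",
        "annotations": outdir / "annotations.tsv",
        "truth": outdir / "truth.tsv",
        "readinfo": outdir / "readinfo.tsv.gz",
        "whitelist": outdir / "whitelist.txt",
    }
    write_panel(panel, paths["fasta"], paths["bed"], paths["annotations"])

    n_genomes = int(cfg.cohort.get("n_genomes", 500))
    truth = simulate_cohort_truth(panel, scenario, n_genomes)
    truth.to_csv(paths["truth"], sep="\t", index=False)

    error_model = cfg.error_model()
    family_model = cfg.family_model()
    n_molecules = int(cfg.sequencing.get("n_molecules", 300))
    fragment_length = int(cfg.sequencing.get("fragment_length", 120))
    samples = scenario.sample_table()
    seeds = np.random.SeedSequence(
        (cfg.seed, 1)
    ).spawn(len(samples) + 1)
    whitelist = family_model.make_whitelist(
        np.random.default_rng(seeds[-1])
    )
    tables = []
    for row, seed in zip(samples, seeds):
        rng = np.random.default_rng(seed)
        sample_truth = truth[truth["sample"] == row["sample"]]
        families, _ = simulate_read_families(
            panel,
            sample_truth,
            n_molecules,
            error_model,
            family_model,
            rng,
            n_genomes=n_genomes,
            fragment_length=fragment_length,
            whitelist=whitelist,
        )
        table = raw_read_table(families)
        table.insert(0, "sample", row["sample"])
        tables.append(table)
    reads = pd.concat(tables, ignore_index=True)
    reads.to_csv(paths["readinfo"], sep="\t", index=False)
    paths["whitelist"].write_text("\n".join(whitelist) + "\n")
    if cfg.write_fastq:
        paths["fastq"] = outdir / "reads.fastq.gz"
        with gzip.open(paths["fastq"], "wt") as fq:
            for r in reads.itertuples(index=False):
                fq.write(f"@{r.sample}:{r.read_id}\n{r.bases}\n+\n{r.quals}\n")
    return paths


def stage_consensus(
    readinfo: Path,
    whitelist_path: Path,
    outdir: Path,
    min_reads_per_strand: int = 1,
    min_family_agreement: float = 0.7,
    trim_quality: int = 20,
    mask_quality: int = 20,
    end_trim: int = 5,
) -> dict[str, Path]:
    """Group raw reads into families and call duplex consensus reads."""
    outdir.mkdir(parents=True, exist_ok=True)
    reads = pd.read_csv(readinfo, sep="\t", dtype={"bases": str, "quals": str})
    whitelist = whitelist_path.read_text().split()
    rows = []
    yields = []
    for sample, sub in reads.groupby("sample", sort=True):
        families, group_stats = group_families(sub, whitelist)
        consensus, stats = duplex_consensus_reads(
            families,
            min_reads_per_strand=min_reads_per_strand,
            min_family_agreement=min_family_agreement,
            end_trim=end_trim,
            trim_quality=trim_quality,
            mask_quality=mask_quality,
        )
        duplex_bp = sum(
            len(r.bases) - r.bases.count("N") for r in consensus
        )
        for r in consensus:
            rows.append(
                {
                    "sample": sample,
                    "family_id": r.family_id,
                    "target": r.target,
                    "start": r.start,
                    "cigar": f"{len(r.bases)}M",
                    "bases": r.bases,
                }
            )
        yields.append(
            {
                "sample": sample,
                "duplex_bp": duplex_bp,
                **group_stats,
                **stats,
            }
        )
    paths = {
        "consensus": outdir / "consensus.tsv.gz",
        "yield": outdir / "duplex_yield.tsv",
    }
    pd.DataFrame(rows).to_csv(paths["consensus"], sep="\t", index=False)
    pd.DataFrame(yields).to_csv(paths["yield"], sep="\t", index=False)
    return paths


def _read_consensus(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"bases": str})


def stage_call(
    consensus_path: Path,
    panel: list[TargetRegion],
    outdir: Path,
    min_alt_count: int = 1,
    germline_vaf: float = 0.3,
) -> dict[str, Path]:
    """Pileup, variant calling, germline flagging, consequence annotation."""
    outdir.mkdir(parents=True, exist_ok=True)
    vcf_dir = outdir / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    by_name = {t.name: t for t in panel}
    consensus = _read_consensus(consensus_path)
    frames = []
    depths = []
    for sample, sub in consensus.groupby("sample", sort=True):
        reads = [
            DuplexConsensusRead(
                family_id=r.family_id,
                target=r.target,
                start=int(r.start),
                end=int(r.start) + len(r.bases),
                bases=r.bases,
                agreement=np.ones(len(r.bases), dtype=bool),
            )
            for r in sub.itertuples(index=False)
        ]
        columns = pileup(reads, panel)
        calls = call_variants(
            columns, panel, min_alt_count=min_alt_count, sample=sample
        )
        tissue, treatment = _parse_sample(sample)
        for c in calls:
            c.tissue, c.treatment = tissue, treatment
            c.consequence = annotate_consequence(c, by_name[c.target])
        flag_germline(calls, vaf_threshold=germline_vaf)
        write_vcf(calls, panel, vcf_dir / f"{sample}.vcf", sample)
        frames.append(calls_to_frame(calls))
        row = {"sample": sample, "duplex_bp": total_duplex_bp(columns, panel)}
        for t in panel:
            row[f"duplex_bp_{t.name}"] = total_duplex_bp(
                {t.name: columns[t.name]}, [t]
            )
        depths.append(row)
    paths = {
        "calls": outdir / "calls.tsv",
        "depths": outdir / "depths.tsv",
    }
    nonempty = [f for f in frames if len(f)] or frames[:1]
    pd.concat(nonempty, ignore_index=True).to_csv(
        paths["calls"], sep="\t", index=False
    )
    pd.DataFrame(depths).to_csv(paths["depths"], sep="\t", index=False)
    return paths


def stage_metrics(
    calls_path: Path,
    depths_path: Path,
    outdir: Path,
    panel: list[TargetRegion],
    cutoff_sd: float = 3.0,
    control_treatment: str = "VC",
    hotspots: list[tuple[str, str, int, int]] | None = None,
) -> dict[str, Path]:
    """Clonality classification and mutant-frequency statistics."""
    outdir.mkdir(parents=True, exist_ok=True)
    calls_df = pd.read_csv(calls_path, sep="\t")
    depths = pd.read_csv(depths_path, sep="\t").set_index("sample")

    all_calls = []
    clonality_rows = []
    metric_rows = []
    for sample in depths.index:
        sub = calls_df[calls_df["sample"] == sample]
        calls = calls_from_frame(sub)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = classify_clonality(calls, cutoff_sd=cutoff_sd)
        clonality_rows.append(
            {
                "sample": sample,
                "n_calls": results.n_calls,
                "mean_log_vaf": results.mean_log_vaf,
                "sd_log_vaf": results.sd_log_vaf,
                "n_clonal": results.n_clonal,
                "fitted": results.fitted,
            }
        )
        tissue, treatment = _parse_sample(sample)
        est = mutant_frequency(
            calls, int(depths.loc[sample, "duplex_bp"]), scope=sample
        )
        metric_rows.append(
            {
                "sample": sample, "tissue": tissue, "treatment": treatment,
                "target": "ALL", "n_mutant": est.n_mutant,
                "n_mutant_uncollapsed": est.n_mutant_uncollapsed,
                "duplex_bp": est.duplex_bp, "mf": est.mf,
                "ci_low": est.ci[0], "ci_high": est.ci[1],
            }
        )
        for t in panel:
            bp = int(depths.loc[sample, f"duplex_bp_{t.name}"])
            if bp == 0:
                continue
            sub_calls = [c for c in calls if c.target == t.name]
            est_t = mutant_frequency(sub_calls, bp, scope=f"{sample}:{t.name}")
            metric_rows.append(
                {
                    "sample": sample, "tissue": tissue,
                    "treatment": treatment, "target": t.name,
                    "n_mutant": est_t.n_mutant,
                    "n_mutant_uncollapsed": est_t.n_mutant_uncollapsed,
                    "duplex_bp": bp, "mf": est_t.mf,
                    "ci_low": est_t.ci[0], "ci_high": est_t.ci[1],
                }
            )
        all_calls.extend(calls)

    metrics = pd.DataFrame(metric_rows)
    summary = cohort_summary(
        metrics[metrics["target"] == "ALL"], control_treatment
    )
    paths = {
        "metrics": outdir / "metrics.tsv",
        "clonality": outdir / "clonality.tsv",
        "group_means": outdir / "cohort_summary.tsv",
        "folds": outdir / "fold_inductions.tsv",
        "calls_classified": outdir / "calls_classified.tsv",
    }
    metrics.to_csv(paths["metrics"], sep="\t", index=False)
    pd.DataFrame(clonality_rows).to_csv(paths["clonality"], sep="\t", index=False)
    summary["group_means"].to_csv(paths["group_means"], sep="\t", index=False)
    summary["fold_inductions"].to_csv(paths["folds"], sep="\t", index=False)
    calls_to_frame(all_calls).to_csv(
        paths["calls_classified"], sep="\t", index=False
    )
    if hotspots:
        paths["hotspots"] = outdir / "hotspots.tsv"
        hotspot_report(all_calls, hotspots).to_csv(
            paths["hotspots"], sep="\t", index=False
        )
    return paths


def stage_spectra(
    calls_path: Path,
    depths_path: Path,
    panel: list[TargetRegion],
    outdir: Path,
) -> dict[str, Path]:
    """Per-treatment spectra, per-sample spectrum matrix, strand bias."""
    outdir.mkdir(parents=True, exist_ok=True)
    calls_df = pd.read_csv(calls_path, sep="\t")
    depths = pd.read_csv(depths_path, sep="\t").set_index("sample")
    spec6_rows, spec96_rows = [], []
    for treatment, sub in calls_df.groupby("treatment", sort=True):
        calls = calls_from_frame(sub)
        s6 = simple_spectrum(calls, panel)
        s96 = trinucleotide_spectrum(calls, panel)
        for vec, rows in ((s6, spec6_rows), (s96, spec96_rows)):
            frame = vec.to_frame()
            frame.insert(0, "treatment", treatment)
            rows.append(frame)
    sample_rows = {}
    for sample, sub in calls_df.groupby("sample", sort=True):
        s96 = trinucleotide_spectrum(calls_from_frame(sub), panel)
        if s96.normalized:
            sample_rows[sample] = s96.proportions
    matrix = pd.DataFrame.from_dict(
        sample_rows, orient="index", columns=list(trinucleotide_spectrum([], panel).labels)
    )
    bias_frames = []
    for t in panel:
        if not t.transcribed:
            continue
        for treatment, sub in calls_df.groupby("treatment", sort=True):
            bp_col = f"duplex_bp_{t.name}"
            samples = sorted(sub["sample"].unique())
            bp = depths.loc[samples, bp_col].sum()
            mean_depth = bp / t.length
            if mean_depth == 0:
                continue
            result = strand_bias(
                calls_from_frame(sub[sub["target"] == t.name]), t, mean_depth
            )
            frame = result.table.copy()
            frame.insert(0, "target", t.name)
            frame.insert(1, "treatment", treatment)
            bias_frames.append(frame)
    paths = {
        "spectra6": outdir / "spectra6.tsv",
        "spectra96": outdir / "spectra96.tsv",
        "sample_matrix": outdir / "sample_spectra96.tsv",
    }
    pd.concat(spec6_rows, ignore_index=True).to_csv(
        paths["spectra6"], sep="\t", index=False
    )
    pd.concat(spec96_rows, ignore_index=True).to_csv(
        paths["spectra96"], sep="\t", index=False
    )
    matrix.to_csv(paths["sample_matrix"], sep="\t", index_label="sample")
    if bias_frames:
        paths["strand_bias"] = outdir / "strand_bias.tsv"
        pd.concat(bias_frames, ignore_index=True).to_csv(
            paths["strand_bias"], sep="\t", index=False
        )
    return paths


def stage_cluster(
    matrix_path: Path, outdir: Path, linkage: str = "weighted"
) -> dict[str, Path]:
    """Cluster the per-sample spectrum matrix; Newick + merge table out."""
    outdir.mkdir(parents=True, exist_ok=True)
    matrix = pd.read_csv(matrix_path, sep="\t", index_col="sample")
    paths: dict[str, Path] = {}
    if len(matrix) >= 2:
        dendro = hierarchical_cluster(matrix, linkage=linkage)
        paths["newick"] = outdir / "dendrogram.nwk"
        paths["merges"] = outdir / "merges.tsv"
        paths["newick"].write_text(dendro.to_newick() + "\n")
        dendro.to_frame().to_csv(paths["merges"], sep="\t", index=False)
    else:
        warnings.warn("fewer than 2 samples with spectra; clustering skipped")
    return paths


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run simulate -> consensus -> call -> metrics -> spectra -> cluster.

    Returns the manifest (also written to ``manifest.json``): versions,
    seed, the parameter echo, and every output file with its row count.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = cfg.build_panel()

    paths = stage_simulate(cfg, outdir)
    paths.update(
        stage_consensus(
            paths["readinfo"],
            paths["whitelist"],
            outdir,
            min_reads_per_strand=int(
                cfg.consensus.get("min_reads_per_strand", 1)
            ),
            min_family_agreement=float(
                cfg.consensus.get("min_family_agreement", 0.7)
            ),
            trim_quality=int(cfg.consensus.get("trim_quality", 20)),
            mask_quality=int(cfg.consensus.get("mask_quality", 20)),
            end_trim=int(cfg.consensus.get("end_trim", 5)),
        )
    )
    paths.update(
        stage_call(
            paths["consensus"],
            panel,
            outdir,
            min_alt_count=int(cfg.calling.get("min_alt_count", 1)),
            germline_vaf=float(cfg.calling.get("germline_vaf", 0.3)),
        )
    )
    hotspots = [
        (
            f"{c['target']}:{c['position']}",
            c["target"],
            int(c["position"]),
            int(c["position"]) + 1,
        )
        for c in cfg.scenario.get("clones", [])
    ]
    paths.update(
        stage_metrics(
            paths["calls"],
            paths["depths"],
            outdir,
            panel,
            cutoff_sd=float(cfg.clonality.get("cutoff_sd", 3.0)),
            control_treatment=cfg.cohort.get("control_treatment", "VC"),
            hotspots=hotspots or None,
        )
    )
    paths.update(
        stage_spectra(paths["calls_classified"], paths["depths"], panel, outdir)
    )
    if "sample_matrix" in paths:
        paths.update(
            stage_cluster(
                paths["sample_matrix"],
                outdir,
                linkage=cfg.clustering.get("linkage", "weighted"),
            )
        )

    manifest = {
        "package": "duplexmut",
        "version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": cfg.seed,
        "config": {
            "panel": cfg.panel,
            "cohort": cfg.cohort,
            "scenario": cfg.scenario,
            "sequencing": cfg.sequencing,
            "consensus": cfg.consensus,
            "calling": cfg.calling,
            "clonality": cfg.clonality,
            "clustering": cfg.clustering,
        },
        "outputs": {},
    }
    for name, path in sorted(paths.items()):
        entry: dict = {"path": str(Path(path).relative_to(outdir))}
        if str(path).endswith((".tsv", ".tsv.gz")):
            try:
                entry["rows"] = int(len(pd.read_csv(path, sep="\t")))
            except Exception:
                entry["rows"] = None
        manifest["outputs"][name] = entry
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
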