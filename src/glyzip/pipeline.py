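"""Stage orchestration: file-to-file pipeline stages and the end-to-end run.

Each stage reads and writes plain TSV files, so the shell-composed CLI
subcommands and :func:`run_pipeline` execute exactly the same code paths and
produce byte-identical outputs for the same configuration and seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import coverage_histogram, partition_unique, sweep_metrics
from .composition import fisher_fdr_tests, positional_frequencies
from .core import (
    MotifCountTable,
    MotifInstance,
    ProteinRecord,
    attach_tm_features,
    read_fasta,
    read_instance_table,
    read_protein_metadata,
    read_tm_features,
    write_fasta,
    write_instance_table,
    write_protein_metadata,
    write_tm_features,
)
from .diststats import (
    divergence_vs_uniform,
    fit_power_law,
    fit_zipf,
    jsd,
    kl_divergence,
    lrt_vs_lognormal,
    shannon_entropy,
)
from .extract import RejectionLog, extract_instances
from .redundancy import dedupe, mark_redundant, write_report
from .simulate import GroundTruthManifest, SimConfig, generate_proteome, write_proteome

logger = logging.getLogger(__name__)

_FLOAT_FORMAT = "%.10g"


@dataclass
class PipelineConfig:
    outdir: str = "glyzip_out"
    seed: int = 0
    thresholds: tuple[int, ...] = (20, 40, 60, 80, 100)
    overlap: bool = True
    identity_threshold: float = 95.0
    kl_pseudocount: float = 0.5
    n_boot: int = 200
    composition_threshold: int = 60
    skip_dedupe: bool = False
    # inputs: either a simulation config or FASTA (+ optional sidecars)
    sim: SimConfig | None = None
    input_fasta: str | None = None
    tm_features: str | None = None
    metadata: str | None = None

    def __post_init__(self) -> None:
        self.thresholds = tuple(self.thresholds)
        if list(self.thresholds) != sorted(self.thresholds) or not set(
            self.thresholds
        ) <= {20, 40, 60, 80, 100}:
            raise ValueError("thresholds must be ascending, drawn from {20,40,60,80,100}")
        if self.sim is None and self.input_fasta is None:
            raise ValueError("config needs either a simulation block or an input FASTA")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw and raw["sim"] is not None:
            sim_raw = dict(raw["sim"])
            if "length_range" in sim_raw:
                sim_raw["length_range"] = tuple(sim_raw["length_range"])
            raw["sim"] = SimConfig(**sim_raw)
        return cls(**raw)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(sim: SimConfig, outdir: str | Path) -> dict[str, Path]:
    records, manifest = generate_proteome(sim)
    return write_proteome(records, manifest, outdir)


def load_records(
    fasta: str | Path,
    tm_features: str | Path | None = None,
    metadata: str | Path | None = None,
) -> list[ProteinRecord]:
    records = read_fasta(fasta)
    if metadata is not None:
        meta = read_protein_metadata(metadata)
        for r in records:
            info = meta.get(r.uniprot_id)
            if info:
                r.organism = str(info["organism"])
                r.taxonomy = tuple(info["taxonomy"])
    if tm_features is not None:
        records = attach_tm_features(records, read_tm_features(tm_features))
    return records


def stage_dedupe(
    fasta: str | Path,
    outdir: str | Path,
    tm_features: str | Path | None = None,
    metadata: str | Path | None = None,
    identity_threshold: float = 95.0,
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = load_records(fasta, tm_features, metadata)
    report = mark_redundant(records, identity_threshold=identity_threshold)
    kept = dedupe(records, report)
    paths = {
        "fasta": outdir / "nonredundant.fasta",
        "tm_features": outdir / "nonredundant_tm_features.tsv",
        "metadata": outdir / "nonredundant_proteins.tsv",
        "report": outdir / "redundancy.tsv",
    }
    write_fasta(kept, paths["fasta"])
    write_tm_features({r.uniprot_id: r.tm_features for r in kept}, paths["tm_features"])
    write_protein_metadata(kept, paths["metadata"])
    write_report(records, report, paths["report"])
    return paths


def stage_extract(
    fasta: str | Path,
    out_tsv: str | Path,
    tm_features: str | Path | None = None,
    overlapping: bool = True,
) -> Path:
    records = load_records(fasta, tm_features)
    log = RejectionLog()
    instances = extract_instances(records, overlapping=overlapping, rejection_log=log)
    if log.n_rejected:
        logger.info("extract: rejected %d non-standard windows", log.n_rejected)
    write_instance_table(instances, out_tsv)
    return Path(out_tsv)


def stage_classify(
    instances_tsv: str | Path,
    outdir: str | Path,
    thresholds: Sequence[int] = (20, 40, 60, 80, 100),
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    instances = read_instance_table(instances_tsv)
    paths: dict[str, Path] = {}

    hist = coverage_histogram(instances)
    rows = [
        ("overall", c, v["count"], v["percent"]) for c, v in hist["overall"].items()
    ] + [
        ("tm_subset", c, v["count"], v["percent"]) for c, v in hist["tm_subset"].items()
    ]
    paths["coverage_histogram"] = outdir / "coverage_histogram.tsv"
    pd.DataFrame(rows, columns=["scope", "coverage", "count", "percent"]).to_csv(
        paths["coverage_histogram"], sep="\t", index=False, float_format=_FLOAT_FORMAT
    )

    part_rows = []
    for t in thresholds:
        part = partition_unique(instances, t)
        part_path = outdir / f"partition_t{t}.tsv"
        entries = (
            [(m, "tm_only") for m in sorted(part.tm_only)]
            + [(m, "shared") for m in sorted(part.shared)]
            + [(m, "nontm_only") for m in sorted(part.nontm_only)]
        )
        pd.DataFrame(entries, columns=["motif", "class"]).to_csv(
            part_path, sep="\t", index=False
        )
        paths[f"partition_t{t}"] = part_path
        part_rows.append(
            {
                "t": t,
                "n_tm_instances": part.n_tm_instances,
                "n_nontm_instances": part.n_nontm_instances,
                "unique_tm": len(part.unique_tm),
                "unique_nontm": len(part.unique_nontm),
                "tm_only": len(part.tm_only),
                "nontm_only": len(part.nontm_only),
                "shared": len(part.shared),
            }
        )
    paths["partitions"] = outdir / "partition_summary.tsv"
    pd.DataFrame(part_rows).to_csv(paths["partitions"], sep="\t", index=False)

    metrics = sweep_metrics(instances, thresholds)
    sweep_df = metrics.to_frame()
    chi_rows = [
        {"t": a, "t_next": b, "chi2": stat, "p": p}
        for (a, b), (stat, p) in metrics.chi2_vs_next.items()
    ]
    paths["sweep"] = outdir / "sweep_metrics.tsv"
    sweep_df.to_csv(paths["sweep"], sep="\t", index=False, float_format=_FLOAT_FORMAT)
    paths["chi2"] = outdir / "sweep_chi2.tsv"
    pd.DataFrame(chi_rows).to_csv(
        paths["chi2"], sep="\t", index=False, float_format=_FLOAT_FORMAT
    )
    return paths


def _category_tables(
    instances: Sequence[MotifInstance], t: int
) -> dict[str, MotifCountTable]:
    part = partition_unique(instances, t)
    tm = [i for i in instances if i.tm_coverage >= t]
    nontm = [i for i in instances if i.tm_coverage < t]
    shared_set = part.shared
    shared = [i for i in instances if i.motif in shared_set]
    out = {}
    if tm:
        out[f"TM>={t}"] = MotifCountTable.from_instances(tm, label=f"TM>={t}")
    if nontm:
        out["non-TM"] = MotifCountTable.from_instances(nontm, label="non-TM")
    if shared:
        out["shared"] = MotifCountTable.from_instances(shared, label="shared")
    return out


def _fit_row(table: MotifCountTable, n_boot: int, seed: int) -> dict:
    row: dict = {
        "n_instances": table.total,
        "unique": table.unique,
        "s": math.nan,
        "r_squared": math.nan,
        "zipf_n_points": 0,
        "alpha": math.nan,
        "x_min": math.nan,
        "ks_D": math.nan,
        "lrt_R": math.nan,
        "lrt_p": math.nan,
        "lrt_low_power": False,
        "h_bits": math.nan,
        "ci_low": math.nan,
        "ci_high": math.nan,
        "kl_vs_uniform": math.nan,
        "jsd_vs_uniform": math.nan,
        "fit_flag": "",
    }
    flags = []
    try:
        pl = fit_power_law(table)
        row.update(alpha=pl.alpha, x_min=pl.x_min, ks_D=pl.ks_distance)
        lrt = lrt_vs_lognormal(table, pl)
        row.update(lrt_R=lrt.lrt_R, lrt_p=lrt.lrt_p, lrt_low_power=lrt.low_power)
        zipf_xmin = pl.x_min
    except ValueError as exc:
        flags.append(f"power_law: {exc}")
        zipf_xmin = 1
    for xm in (zipf_xmin, 1):
        try:
            zf = fit_zipf(table, x_min=xm)
            row.update(s=zf.s, r_squared=zf.r_squared, zipf_n_points=zf.n_points)
            break
        except ValueError as exc:
            if xm == 1:
                flags.append(f"zipf: {exc}")
    ent = shannon_entropy(table, n_boot=n_boot, seed=seed)
    row.update(
        h_bits=ent.h_bits,
        ci_low=ent.ci_low if ent.ci_low is not None else math.nan,
        ci_high=ent.ci_high if ent.ci_high is not None else math.nan,
    )
    kl_u, jsd_u = divergence_vs_uniform(table)
    row.update(kl_vs_uniform=kl_u, jsd_vs_uniform=jsd_u)
    row["fit_flag"] = "; ".join(flags)
    return row


def stage_stats(
    instances_tsv: str | Path,
    outdir: str | Path,
    thresholds: Sequence[int] = (20, 40, 60, 80, 100),
    n_boot: int = 200,
    seed: int = 0,
    kl_pseudocount: float = 0.5,
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    instances = read_instance_table(instances_tsv)
    if not instances:
        raise ValueError("stats refused: no instances in input")
    all_table = MotifCountTable.from_instances(instances, label="total")
    if all_table.unique < 2:
        raise ValueError(
            "stats refused: degenerate distribution (fewer than 2 unique motifs)"
        )

    stat_rows = []
    div_rows = []
    for t in thresholds:
        tables = _category_tables(instances, t)
        for name, table in tables.items():
            row = {"t": t, "category": name}
            row.update(_fit_row(table, n_boot=n_boot, seed=seed + t))
            stat_rows.append(row)
        tm_name = f"TM>={t}"
        if tm_name in tables and "non-TM" in tables:
            tm_tab, nt_tab = tables[tm_name], tables["non-TM"]
            div_rows.append(
                {
                    "t": t,
                    "kl_tm_vs_nontm": kl_divergence(tm_tab, nt_tab, kl_pseudocount),
                    "kl_nontm_vs_tm": kl_divergence(nt_tab, tm_tab, kl_pseudocount),
                    "jsd": jsd(tm_tab, nt_tab),
                }
            )
    row = {"t": 0, "category": "total"}
    row.update(_fit_row(all_table, n_boot=n_boot, seed=seed))
    stat_rows.append(row)

    paths = {
        "stats": Path(outdir) / "stats_summary.tsv",
        "divergences": Path(outdir) / "divergences.tsv",
    }
    pd.DataFrame(stat_rows).to_csv(
        paths["stats"], sep="\t", index=False, float_format=_FLOAT_FORMAT
    )
    pd.DataFrame(div_rows).to_csv(
        paths["divergences"], sep="\t", index=False, float_format=_FLOAT_FORMAT
    )
    return paths


def stage_compose(
    instances_tsv: str | Path,
    outdir: str | Path,
    threshold: int = 60,
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    instances = read_instance_table(instances_tsv)
    part = partition_unique(instances, threshold)
    groups = {
        "tm_only": [i for i in instances if i.motif in part.tm_only],
        "nontm_only": [i for i in instances if i.motif in part.nontm_only],
        "shared": [i for i in instances if i.motif in part.shared],
    }
    profiles = {
        name: positional_frequencies(insts, group=name)
        for name, insts in groups.items()
        if insts
    }
    comp_df = pd.concat(
        [p.to_frame() for p in profiles.values()], ignore_index=True
    ) if profiles else pd.DataFrame(
        columns=["group", "position", "residue", "count", "percent"]
    )
    comparisons = [
        ("tm_vs_nontm", "tm_only", "nontm_only"),
        ("shared_vs_tm", "shared", "tm_only"),
        ("shared_vs_nontm", "shared", "nontm_only"),
    ]
    enr_frames = []
    for label, a, b in comparisons:
        if a in profiles and b in profiles:
            enr_frames.append(
                fisher_fdr_tests(profiles[a], profiles[b], comparison=label)
            )
    enr_df = (
        pd.concat(enr_frames, ignore_index=True)
        if enr_frames
        else pd.DataFrame(
            columns=[
                "comparison", "position", "residue", "log2_enrichment",
                "fisher_p", "fdr_q", "tier", "skipped",
            ]
        )
    )
    paths = {
        "composition": outdir / f"composition_t{threshold}.tsv",
        "enrichment": outdir / f"enrichment_t{threshold}.tsv",
    }
    comp_df.to_csv(paths["composition"], sep="\t", index=False, float_format=_FLOAT_FORMAT)
    enr_df.to_csv(paths["enrichment"], sep="\t", index=False, float_format=_FLOAT_FORMAT)
    return paths


def stage_report(outdir: str | Path) -> Path:
    """Assemble the per-threshold summary table from stage outputs."""
    outdir = Path(outdir)
    stats_path = outdir / "stats_summary.tsv"
    if not stats_path.exists():
        raise FileNotFoundError(
            f"report requires {stats_path} — run the stats stage first"
        )
    stats = pd.read_csv(stats_path, sep="\t")
    parts_path = outdir / "partition_summary.tsv"
    div_path = outdir / "divergences.tsv"
    summary = stats
    if parts_path.exists():
        parts = pd.read_csv(parts_path, sep="\t")
        summary = summary.merge(parts, on="t", how="left")
    if div_path.exists():
        div = pd.read_csv(div_path, sep="\t")
        summary = summary.merge(div, on="t", how="left")
    out = outdir / "summary.tsv"
    summary.to_csv(out, sep="\t", index=False, float_format=_FLOAT_FORMAT)
    return out


# ---------------------------------------------------------------------------
# End-to-end
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute load/simulate -> dedupe -> extract -> classify -> stats ->
    compose -> report, writing per-stage TSVs plus a run manifest.

    Deterministic given the config seed; every stochastic stage derives its
    stream from it.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    if config.sim is not None:
        sim = config.sim
        sim_paths = stage_simulate(sim, outdir / "proteome")
        fasta = sim_paths["fasta"]
        tm_tsv = sim_paths["tm_features"]
        meta = sim_paths["metadata"]
        paths.update({f"sim_{k}": v for k, v in sim_paths.items()})
    else:
        fasta = Path(config.input_fasta)
        tm_tsv = Path(config.tm_features) if config.tm_features else None
        meta = Path(config.metadata) if config.metadata else None

    if not config.skip_dedupe:
        dd = stage_dedupe(
            fasta,
            outdir,
            tm_features=tm_tsv,
            metadata=meta,
            identity_threshold=config.identity_threshold,
        )
        paths.update(dd)
        fasta, tm_tsv = dd["fasta"], dd["tm_features"]

    instances_tsv = outdir / "instances.tsv"
    stage_extract(fasta, instances_tsv, tm_features=tm_tsv, overlapping=config.overlap)
    paths["instances"] = instances_tsv

    paths.update(stage_classify(instances_tsv, outdir, config.thresholds))
    paths.update(
        stage_stats(
            instances_tsv,
            outdir,
            thresholds=config.thresholds,
            n_boot=config.n_boot,
            seed=config.seed,
            kl_pseudocount=config.kl_pseudocount,
        )
    )
    paths.update(
        stage_compose(instances_tsv, outdir, threshold=config.composition_threshold)
    )
    paths["summary"] = stage_report(outdir)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": list(config.thresholds),
        "overlap": config.overlap,
        "identity_threshold": config.identity_threshold,
        "kl_pseudocount": config.kl_pseudocount,
        "n_boot": config.n_boot,
        "composition_threshold": config.composition_threshold,
        "simulated": config.sim is not None,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    run_manifest = outdir / "run_manifest.json"
    run_manifest.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["run_manifest"] = run_manifest
    return paths
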