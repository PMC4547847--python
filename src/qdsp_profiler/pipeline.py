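"""End-to-end orchestration: design validation, staged runs, reproducibility.

A run loads (or simulates) an intensity table, validates the experimental
design for the requested analysis mode, executes the stage functions in
dependency order, and writes result tables plus a JSON metadata sidecar.
Every output table carries '#' header comments with the tool version, the
seed, and the sha256 of each input file, so a result can be traced to its
exact inputs; identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .balf import SamParams, balf_day14_ttest, balf_enrichment, balf_timecourse
from .enrichment import enrichment_1d, signature_timecourse
from .io import (
    QDSP_FRACTIONS,
    IntensityTable,
    read_gmt,
    read_protein_groups,
    write_gmt,
    write_protein_groups,
    write_run_metadata,
    write_table,
)
from .qdsp import QdspConfig, cluster_profiles, pca_fractions, run_qdsp
from .synthetic import GeneratorConfig, generate_annotations
from .timecourse import ImputationParams, anova_timecourse, compliance_regression, compute_ratios

logger = logging.getLogger(__name__)

DESIGNS = ("qdsp", "timecourse", "balf")


class ConfigError(ValueError):
    """Configuration schema violation; carries the offending key."""

    def __init__(self, key: str, message: str):
        self.key = key
        super().__init__(f"config key '{key}': {message}")


@dataclass
class RunConfig:
    """Validated parameters of one pipeline run."""

    design: str = "qdsp"
    input: str | None = None  # proteinGroups TSV; None -> simulate
    samples: str | None = None
    gmt: str | None = None
    output_dir: str = "results"
    fdr: float = 0.05
    seed: int = 0
    n_proteins: int = 2000
    downshift: float = 1.8
    width: float = 0.3
    s0_rule: str = "PERCENTILE"
    s0_percentile: float = 5.0
    linkage: str = "average"
    min_members: int = 5
    permutations: int = 10000
    generator: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown key")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        if self.design not in DESIGNS:
            raise ConfigError("design", f"must be one of {DESIGNS}")
        if not 0 < self.fdr < 1:
            raise ConfigError("fdr", "must be in (0, 1)")
        if not self.width > 0:
            raise ConfigError("width", "must be positive")
        if self.downshift < 0:
            raise ConfigError("downshift", "must be non-negative")
        for key in ("input", "samples", "gmt"):
            val = getattr(self, key)
            if val is not None and not Path(val).exists():
                raise ConfigError(key, f"path does not exist: {val}")
        if self.input is not None and self.samples is None:
            raise ConfigError("samples", "required when input is given")


def validate_design(samples: pd.DataFrame, mode: str) -> dict:
    """Check replicate counts, fraction completeness, and condition presence.

    Returns a machine-readable report: ``{"mode", "valid", "violations",
    "replicate_counts"}``.  Reporting only — never raises.
    """
    violations: list[str] = []
    report: dict = {"mode": mode, "violations": violations, "replicate_counts": {}}
    if len(samples) == 0:
        violations.append("no samples")
        report["valid"] = False
        return report
    conditions = set(samples["condition"])
    if "PBS" not in conditions:
        violations.append("no PBS control samples")
    if mode == "QDSP":
        qdsp = samples[samples["fraction"].isin(QDSP_FRACTIONS)]
        if qdsp.empty:
            violations.append("no QDSP fraction samples")
        for (cond, mouse), sub in qdsp.groupby(["condition", "mouse_id"], observed=True):
            missing = set(QDSP_FRACTIONS) - set(sub["fraction"])
            if missing:
                violations.append(
                    f"mouse {mouse} ({cond}) missing fraction(s) {sorted(missing)}"
                )
        if "BLEO" not in conditions:
            violations.append("no treated (BLEO) samples")
    elif mode == "TIMECOURSE":
        treated = samples[samples["condition"] == "BLEO"]
        if treated["timepoint_days"].dropna().nunique() < 2:
            violations.append("fewer than 2 treated time points")
        counts = treated.groupby("timepoint_days", observed=True)["mouse_id"].nunique()
        report["replicate_counts"] = {f"day{int(tp)}": int(c) for tp, c in counts.items()}
        if (counts < 2).any():
            violations.append("treated time point with < 2 mice")
    elif mode == "BALF":
        if "BALF" not in set(samples["compartment"]):
            violations.append("no BALF compartment samples")
        if "BLEO" not in conditions:
            violations.append("no treated (BLEO) samples")
    else:
        violations.append(f"unknown mode {mode!r}")
    report["valid"] = not violations
    return report


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _header(config: RunConfig, inputs: dict[str, str]) -> list[str]:
    lines = [f"qdsp-profiler v{__version__}", f"seed={config.seed}"]
    for name, path in inputs.items():
        lines.append(f"{name}_sha256={_sha256(path)}")
    return lines


def _simulate(config: RunConfig, out_dir: Path) -> tuple[IntensityTable, object, Path]:
    from . import synthetic

    gen_kwargs = dict(config.generator)
    gen_kwargs.setdefault("n_proteins", config.n_proteins)
    gen_kwargs.setdefault("seed", config.seed)
    gen = GeneratorConfig(**gen_kwargs)
    generator = {
        "qdsp": synthetic.generate_qdsp_dataset,
        "timecourse": synthetic.generate_timecourse_dataset,
        "balf": synthetic.generate_balf_dataset,
    }[config.design]
    table, truth = generator(gen)
    pg = out_dir / "proteingroups.tsv"
    sheet = out_dir / "samples.tsv"
    write_protein_groups(table, pg, sheet)
    truth.proteins.to_csv(out_dir / "ground_truth.tsv", sep="\t")
    if truth.mice is not None:
        truth.mice.to_csv(out_dir / "ground_truth_mice.tsv", sep="\t")
    gmt_path = out_dir / "annotations.gmt"
    write_gmt(generate_annotations(truth, noise_frac=0.0, seed=gen.seed), gmt_path)
    write_run_metadata(out_dir / "generator_config.json", asdict(gen))
    return table, truth, gmt_path


def simulate(config: RunConfig) -> dict:
    """Generate a synthetic dataset for the configured design; returns paths."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _simulate(config, out_dir)
    return {"output_dir": str(out_dir)}


def _gene_scores(table: IntensityTable, scores: pd.Series) -> pd.Series:
    """Re-key a per-protein score vector by gene name (protein id fallback)."""
    genes = table.proteins["gene_name"].reindex(scores.index)
    keys = genes.where(genes.astype(bool), scores.index.to_series())
    out = scores.copy()
    out.index = keys
    return out[~out.index.duplicated()]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns {table name: path} of outputs.

    Stages: load-or-simulate, design validation, the design's statistics, and
    (when annotations are available) rank-based enrichment.  A JSON metadata
    sidecar echoes every parameter; warnings go to run.log in the output
    directory.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out_dir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("qdsp_profiler")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)
    try:
        return _run_stages(config, out_dir)
    finally:
        root.removeHandler(log_handler)
        log_handler.close()


def _run_stages(config: RunConfig, out_dir: Path) -> dict:
    inputs: dict[str, str] = {}
    gmt_path = config.gmt
    if config.input is None:
        table, _truth, gmt_gen = _simulate(config, out_dir)
        inputs["proteingroups"] = str(out_dir / "proteingroups.tsv")
        if gmt_path is None:
            gmt_path = str(gmt_gen)
    else:
        table = read_protein_groups(config.input, config.samples)
        inputs["proteingroups"] = str(config.input)
        inputs["samples"] = str(config.samples)
    if gmt_path is not None:
        inputs["gmt"] = str(gmt_path)
    annotations = read_gmt(gmt_path) if gmt_path else None

    report = validate_design(table.samples, config.design.upper())
    if not report["valid"]:
        raise RuntimeError(f"design validation failed: {report['violations']}")
    header = _header(config, inputs)
    outputs: dict[str, str] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out_dir / f"{name}.tsv"
        write_table(df, path, header)
        outputs[name] = str(path)

    if config.design == "qdsp":
        res = run_qdsp(table, QdspConfig(fdr=config.fdr))
        emit("qdsp_stats", res["stats"])
        emit("profiles_normalized", res["normalized"])
        complete = res["normalized"].dropna(axis=0)
        if len(complete) >= 10:
            from .io import zscore_rows

            z = zscore_rows(complete).dropna()
            pca = pca_fractions(z.T, n_components=2)
            emit("pca_scores", pca["scores"])
            emit("pca_loadings", pca["loadings"])
            cluster_profiles(z, linkage=config.linkage)  # validated; dendrogram not persisted
        if annotations is not None:
            share = _gene_scores(table, res["stats"]["insoluble_share_PBS"].dropna())
            emit(
                "enrichment_insoluble_share",
                enrichment_1d(share, annotations, min_members=config.min_members),
            )
    elif config.design == "timecourse":
        params = ImputationParams(downshift=config.downshift, width=config.width, seed=config.seed)
        rm = compute_ratios(table, params)
        ratios_out = rm.ratios.copy()
        ratios_out.columns = [f"ratio_d{tp}_{sid}" for tp, sid in rm.ratios.columns]
        prov_out = rm.provenance.copy()
        prov_out.columns = [f"provenance_d{tp}_{sid}" for tp, sid in rm.provenance.columns]
        emit("ratios", pd.concat([ratios_out, prov_out], axis=1))
        emit("anova", anova_timecourse(rm))
        compliance = table.samples["compliance"]
        pbs_compliance = compliance[table.samples["condition"] == "PBS"].dropna()
        if compliance.notna().any() and len(pbs_compliance):
            emit("compliance", compliance_regression(rm, compliance, pbs_compliance))
        if annotations is not None:
            genes = table.proteins["gene_name"].reindex(rm.ratios.index)
            gene_ratios = rm.ratios.copy()
            gene_ratios.index = genes.where(genes.astype(bool), rm.ratios.index.to_series())
            gene_ratios = gene_ratios[~gene_ratios.index.duplicated()]
            emit(
                "signature_enrichment",
                signature_timecourse(gene_ratios, annotations, alpha=0.05, min_members=config.min_members).set_index("term_id"),
            )
    elif config.design == "balf":
        sam = SamParams(
            s0_rule=config.s0_rule,
            s0_percentile=config.s0_percentile,
            n_permutations=config.permutations,
            seed=config.seed,
        )
        emit("balf_scores", balf_enrichment(table, sam, fdr=config.fdr))
        emit("balf_day14", balf_day14_ttest(table))
        anova, _rm = balf_timecourse(
            table, ImputationParams(downshift=config.downshift, width=config.width, seed=config.seed)
        )
        emit("balf_anova", anova)

    meta = {"version": __version__, "config": asdict(config), "inputs_sha256": {k: _sha256(v) for k, v in inputs.items()}, "outputs": outputs, "design_report": report}
    write_run_metadata(out_dir / "run_metadata.json", meta)
    outputs["run_metadata"] = str(out_dir / "run_metadata.json")
    return outputs
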