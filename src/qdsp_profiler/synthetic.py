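"""Synthetic proteinGroups-style datasets with known ground truth.

Three generators emulate the study designs the statistics are built for:

* :func:`generate_qdsp_dataset` — 4 solubility fractions x {PBS, BLEO} x 4
  replicates.  Each protein belongs to a compartment class (cytosolic,
  membrane, nuclear, cytoskeletal, ECM) with a characteristic fraction-mass
  template; a configurable subset shifts solubility upon injury by convex mass
  transfer between the FR1 and INSOL ends, and another subset changes total
  abundance.
* :func:`generate_timecourse_dataset` — total-tissue time course (treated
  day 3 n=3, day 14 n=7, day 28 n=4, day 56 n=3 against 16 pooled controls)
  with temporal archetypes (early-peak, fibrotic-peak, late-resolution) and a
  per-mouse latent fibrosis burden that peaks at day 14, drives lung
  compliance down, and scales the fibrotic-archetype proteins.
* :func:`generate_balf_dataset` — paired lavage-fluid (BALF) and tissue
  compartments, 4 mice per condition at 6 time points.  BALF intensity is
  elf_weight x secretion + leakage_weight x tissue level, with
  elf_weight >> leakage_weight for epithelial-lining-fluid members.

Intensities are log-normal around their expectation with a configurable
replicate CV; detection follows a logistic curve in log2 intensity, so
missingness is left-censored (missing not at random), matching the
distributions the downshifted-normal imputation assumes.  A fixed seed gives
bit-identical tables and ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import QDSP_FRACTIONS, AnnotationCollection, IntensityTable

CLASSES = ("CYTOSOLIC", "MEMBRANE", "NUCLEAR", "CYTOSKELETAL", "ECM")

DEFAULT_CLASS_PROPORTIONS = {
    "CYTOSOLIC": 0.35,
    "MEMBRANE": 0.25,
    "NUCLEAR": 0.15,
    "CYTOSKELETAL": 0.15,
    "ECM": 0.10,
}

DEFAULT_PROFILE_TEMPLATES = {
    "CYTOSOLIC": (0.70, 0.20, 0.07, 0.03),
    "MEMBRANE": (0.20, 0.45, 0.25, 0.10),
    "NUCLEAR": (0.10, 0.30, 0.45, 0.15),
    "CYTOSKELETAL": (0.08, 0.17, 0.35, 0.40),
    "ECM": (0.02, 0.05, 0.13, 0.80),
}

#: relative effect amplitude per time point (days), by temporal archetype
ARCHETYPE_CURVES = {
    "EARLY": {3: 1.0, 7: 0.60, 14: 0.25, 21: 0.10, 28: 0.05, 56: 0.0},
    "FIBROTIC": {3: 0.20, 7: 0.55, 14: 1.0, 21: 0.60, 28: 0.35, 56: 0.05},
    "LATE": {3: 0.0, 7: 0.05, 14: 0.10, 21: 0.30, 28: 0.55, 56: 1.0},
}

#: latent fibrosis burden per time point (relative units; peak at day 14)
BURDEN_CURVE = {3: 0.4, 7: 0.7, 14: 1.0, 21: 0.6, 28: 0.3, 56: 0.1}


@dataclass
class GeneratorConfig:
    """Study-design and noise parameters shared by the three generators."""

    n_proteins: int = 5000
    seed: int = 0
    class_proportions: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS))
    profile_templates: dict = field(default_factory=lambda: dict(DEFAULT_PROFILE_TEMPLATES))
    abundance_log2_mean: float = 25.0
    abundance_log2_sd: float = 2.5
    replicate_cv: float = 0.25
    missingness_midpoint_log2: float = 16.0
    missingness_slope: float = 1.0
    frac_abundance_changed: float = 0.30
    frac_profile_shifted: float = 0.10
    log2fc_sd: float = 1.5
    shift_mass: float = 0.25
    n_replicates_qdsp: int = 4
    timecourse_design: dict = field(default_factory=lambda: {3: 3, 14: 7, 28: 4, 56: 3})
    n_controls: int = 16
    balf_timepoints: tuple = (3, 7, 14, 21, 28, 56)
    balf_mice_per_condition: int = 4
    frac_elf: float = 0.15
    elf_weight: float = 1.0
    leakage_weight: float = 0.02
    secretion_log2_mean: float = 2.0
    secretion_log2_sd: float = 1.0
    compliance_baseline: float = 0.05
    compliance_coupling: float = 0.7
    compliance_noise_sd: float = 0.08
    burden_mouse_sd: float = 0.25

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        for cls, tmpl in self.profile_templates.items():
            if abs(sum(tmpl) - 1.0) > 1e-9:
                raise ValueError(f"profile template for {cls} must sum to 1")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")

    @property
    def log2_noise_sd(self) -> float:
        """log2-scale replicate noise sd for the configured multiplicative CV."""
        if self.replicate_cv == 0:
            return 0.0
        return float(np.sqrt(np.log1p(self.replicate_cv**2)) / np.log(2))


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery scoring.

    ``proteins``: per-protein class, effect flags, true log2 fold changes and
    shift direction.  ``mice``: per-mouse latent fibrosis burden and
    compliance (time-course designs only).
    """

    proteins: pd.DataFrame
    mice: pd.DataFrame | None = None
    config: GeneratorConfig | None = None


def detection_probability(config: GeneratorConfig, log2_intensity: np.ndarray) -> np.ndarray:
    """Logistic detection curve: P(detected) given a cell's log2 intensity.

    Monotone non-decreasing in intensity; an infinite slope gives a hard
    threshold at the midpoint.
    """
    x = np.asarray(log2_intensity, dtype=float)
    if np.isinf(config.missingness_slope):
        return (x >= config.missingness_midpoint_log2).astype(float)
    z = (x - config.missingness_midpoint_log2) * config.missingness_slope
    return 1.0 / (1.0 + np.exp(-z))


def _apply_missingness(linear: np.ndarray, config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    with np.errstate(divide="ignore"):
        p_detect = detection_probability(config, np.log2(linear))
    detected = rng.random(linear.shape) < p_detect
    return np.where(detected, linear, np.nan)


def _protein_frame(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_proteins
    classes = rng.choice(
        list(config.class_proportions),
        size=n,
        p=list(config.class_proportions.values()),
    )
    frame = pd.DataFrame(
        {
            "gene_name": [f"Gene{i:05d}" for i in range(n)],
            "class": classes,
            "abundance_log2": rng.normal(config.abundance_log2_mean, config.abundance_log2_sd, n),
        },
        index=pd.Index([f"P{i:05d}" for i in range(n)], name="protein_id"),
    )
    return frame


def _noisy(expected: np.ndarray, config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative log-normal replicate noise at the configured CV."""
    sd = config.log2_noise_sd
    if sd == 0:
        return expected.copy()
    return expected * 2.0 ** rng.normal(0.0, sd, expected.shape)


def _shift_template(template: np.ndarray, direction: str, mass: float) -> np.ndarray:
    """Convex mass transfer between the FR1 and INSOL ends of a profile."""
    target = np.array([0.0, 0.0, 0.0, 1.0]) if direction == "TOWARD_INSOLUBLE" else np.array(
        [1.0, 0.0, 0.0, 0.0]
    )
    return (1.0 - mass) * template + mass * target


def generate_qdsp_dataset(config: GeneratorConfig | None = None) -> tuple[IntensityTable, GroundTruth]:
    """Four-fraction solubility-profiling dataset, PBS vs bleomycin day 14."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng([config.seed, 1])
    proteins = _protein_frame(config, rng)
    n = config.n_proteins

    shifted = rng.random(n) < config.frac_profile_shifted
    # injury moves proteins away from their resting solubility end (soluble
    # plasma proteins coagulate into the matrix, insoluble basement-membrane
    # constituents solubilize); mid-profile classes shift either way
    templates0 = np.stack(
        [np.asarray(config.profile_templates[c], dtype=float) for c in proteins["class"]]
    )
    coin = rng.random(n) < 0.5
    direction = np.where(coin, "TOWARD_INSOLUBLE", "TOWARD_SOLUBLE")
    direction = np.where(templates0[:, 3] >= 0.5, "TOWARD_SOLUBLE", direction)
    direction = np.where(templates0[:, 0] >= 0.5, "TOWARD_INSOLUBLE", direction)
    direction = np.where(shifted, direction, "")
    abn_changed = rng.random(n) < config.frac_abundance_changed
    log2fc = np.where(abn_changed, rng.normal(0.0, config.log2fc_sd, n), 0.0)

    templates = np.stack([np.asarray(config.profile_templates[c], dtype=float) for c in proteins["class"]])
    bleo_templates = templates.copy()
    for i in np.flatnonzero(shifted):
        bleo_templates[i] = _shift_template(templates[i], direction[i], config.shift_mass)

    total = 2.0 ** proteins["abundance_log2"].to_numpy()
    cols, col_meta, blocks = [], [], []
    for cond, tmpl, fc in (("PBS", templates, np.zeros(n)), ("BLEO", bleo_templates, log2fc)):
        cond_total = total * 2.0**fc
        for rep in range(1, config.n_replicates_qdsp + 1):
            for j, frac in enumerate(QDSP_FRACTIONS):
                expected = cond_total * tmpl[:, j]
                blocks.append(_noisy(expected, config, rng))
                sid = f"{cond}_{frac}_R{rep}"
                cols.append(sid)
                col_meta.append(
                    {
                        "sample_id": sid,
                        "condition": cond,
                        "timepoint_days": 14 if cond == "BLEO" else np.nan,
                        "fraction": frac,
                        "replicate": rep,
                        "mouse_id": f"{cond}_m{rep}",
                        "compartment": "TISSUE",
                        "compliance": np.nan,
                    }
                )
    values = np.column_stack(blocks)
    values = _apply_missingness(values, config, rng)

    samples = pd.DataFrame(col_meta).set_index("sample_id")
    vdf = pd.DataFrame(values, index=proteins.index, columns=cols)
    table = IntensityTable(vdf, proteins[["gene_name"]].copy(), samples, {"design": "QDSP"})

    truth_df = proteins[["gene_name", "class", "abundance_log2"]].copy()
    truth_df["profile_shifted"] = shifted
    truth_df["shift_direction"] = direction
    truth_df["abundance_changed"] = abn_changed
    truth_df["true_log2fc"] = log2fc
    return table, GroundTruth(truth_df, None, config)


def _mouse_burden_compliance(
    config: GeneratorConfig, design: dict, rng: np.random.Generator, prefix: str = ""
) -> pd.DataFrame:
    """Per-mouse latent burden and compliance for a treated + control design.

    ``design`` maps time point -> number of treated mice; controls (burden 0)
    are appended per ``config.n_controls``.
    """
    rows = []
    for tp, n_mice in design.items():
        for k in range(1, n_mice + 1):
            burden = BURDEN_CURVE[tp] * float(
                np.exp(rng.normal(0.0, config.burden_mouse_sd))
            )
            rows.append(
                {"mouse_id": f"{prefix}BLEO_d{tp}_m{k}", "condition": "BLEO", "timepoint_days": tp, "burden": burden}
            )
    for k in range(1, config.n_controls + 1):
        rows.append(
            {"mouse_id": f"{prefix}PBS_m{k}", "condition": "PBS", "timepoint_days": np.nan, "burden": 0.0}
        )
    mice = pd.DataFrame(rows).set_index("mouse_id")
    noise = rng.normal(0.0, config.compliance_noise_sd, len(mice))
    mice["compliance"] = config.compliance_baseline * np.exp(
        -config.compliance_coupling * mice["burden"].to_numpy() + noise
    )
    return mice


def _assign_archetypes(
    config: GeneratorConfig, rng: np.random.Generator, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """(archetype label or '', amplitude) per protein; fibrotic amplitudes are
    positive (fibrosis proteins accumulate with burden)."""
    affected = rng.random(n) < config.frac_abundance_changed
    archetype = rng.choice(list(ARCHETYPE_CURVES), size=n)
    archetype = np.where(affected, archetype, "")
    amplitude = rng.normal(0.0, config.log2fc_sd, n)
    amplitude[archetype == "FIBROTIC"] = np.abs(amplitude[archetype == "FIBROTIC"])
    amplitude[archetype == ""] = 0.0
    return archetype, amplitude


def _true_fc_frame(archetype: np.ndarray, amplitude: np.ndarray, timepoints) -> pd.DataFrame:
    out = {}
    for tp in timepoints:
        curve = np.array([ARCHETYPE_CURVES[a][tp] if a else 0.0 for a in archetype])
        out[f"true_log2fc_d{tp}"] = amplitude * curve
    return pd.DataFrame(out)


def generate_timecourse_dataset(config: GeneratorConfig | None = None) -> tuple[IntensityTable, GroundTruth]:
    """Tissue time-course dataset with burden-coupled compliance."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng([config.seed, 2])
    proteins = _protein_frame(config, rng)
    n = config.n_proteins
    timepoints = sorted(config.timecourse_design)

    archetype, amplitude = _assign_archetypes(config, rng, n)
    mice = _mouse_burden_compliance(config, config.timecourse_design, rng)

    mean_burden = {tp: BURDEN_CURVE[tp] * float(np.exp(0.5 * config.burden_mouse_sd**2)) for tp in timepoints}
    base = 2.0 ** proteins["abundance_log2"].to_numpy()
    cols, col_meta, blocks = [], [], []
    for mouse_id, mrow in mice.iterrows():
        if mrow["condition"] == "BLEO":
            tp = int(mrow["timepoint_days"])
            curve = np.array([ARCHETYPE_CURVES[a][tp] if a else 0.0 for a in archetype])
            coupling = np.where(archetype == "FIBROTIC", mrow["burden"] / mean_burden[tp], 1.0)
            effect = amplitude * curve * coupling
            expected = base * 2.0**effect
        else:
            expected = base
        blocks.append(_noisy(expected, config, rng))
        sid = f"{mouse_id}_TOTAL"
        cols.append(sid)
        col_meta.append(
            {
                "sample_id": sid,
                "condition": mrow["condition"],
                "timepoint_days": mrow["timepoint_days"],
                "fraction": "TOTAL",
                "replicate": int(mouse_id.rsplit("_m", 1)[1]),
                "mouse_id": mouse_id,
                "compartment": "TISSUE",
                "compliance": mrow["compliance"],
            }
        )
    values = _apply_missingness(np.column_stack(blocks), config, rng)
    samples = pd.DataFrame(col_meta).set_index("sample_id")
    vdf = pd.DataFrame(values, index=proteins.index, columns=cols)
    table = IntensityTable(vdf, proteins[["gene_name"]].copy(), samples, {"design": "TIMECOURSE"})

    truth_df = proteins[["gene_name", "class", "abundance_log2"]].copy()
    truth_df["archetype"] = archetype
    truth_df["amplitude"] = amplitude
    fc = _true_fc_frame(archetype, amplitude, timepoints)
    fc.index = truth_df.index
    truth_df = pd.concat([truth_df, fc], axis=1)
    truth_df["signature"] = [
        f"{a}_{'UP' if amp > 0 else 'DOWN'}" if a else "" for a, amp in zip(archetype, amplitude)
    ]
    return table, GroundTruth(truth_df, mice, config)


def generate_balf_dataset(config: GeneratorConfig | None = None) -> tuple[IntensityTable, GroundTruth]:
    """Paired BALF + tissue dataset over six time points.

    Expected BALF intensity = elf_weight x secretion + leakage_weight x tissue
    level; ELF members carry the secretion term, everything else only leaks.
    Injury effects (temporal archetypes) act on the secretion level of
    affected ELF members.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng([config.seed, 3])
    proteins = _protein_frame(config, rng)
    n = config.n_proteins
    timepoints = list(config.balf_timepoints)

    elf_member = rng.random(n) < config.frac_elf
    secretion_shift = rng.normal(config.secretion_log2_mean, config.secretion_log2_sd, n)
    archetype, amplitude = _assign_archetypes(config, rng, n)
    # only ELF members show injury-driven secretion changes in BALF
    archetype = np.where(elf_member, archetype, "")
    amplitude = np.where(elf_member, amplitude, 0.0)

    design = {tp: config.balf_mice_per_condition for tp in timepoints}
    rows = []
    for cond in ("PBS", "BLEO"):
        for tp in timepoints:
            for k in range(1, config.balf_mice_per_condition + 1):
                rows.append(
                    {"mouse_id": f"{cond}_d{tp}_m{k}", "condition": cond, "timepoint_days": tp}
                )
    mice = pd.DataFrame(rows).set_index("mouse_id")

    tissue_level = 2.0 ** proteins["abundance_log2"].to_numpy()
    secretion_base = tissue_level * 2.0**secretion_shift * np.where(elf_member, config.elf_weight, 0.0)

    cols, col_meta, blocks = [], [], []
    for mouse_id, mrow in mice.iterrows():
        tp = int(mrow["timepoint_days"])
        if mrow["condition"] == "BLEO":
            curve = np.array([ARCHETYPE_CURVES[a][tp] if a else 0.0 for a in archetype])
            secretion = secretion_base * 2.0 ** (amplitude * curve)
        else:
            secretion = secretion_base
        balf_expected = secretion + config.leakage_weight * tissue_level
        for compartment, expected, frac in (
            ("BALF", balf_expected, "BALF"),
            ("TISSUE", tissue_level, "TOTAL"),
        ):
            sid = f"{mouse_id}_{compartment}"
            blocks.append(_noisy(expected, config, rng))
            cols.append(sid)
            col_meta.append(
                {
                    "sample_id": sid,
                    "condition": mrow["condition"],
                    "timepoint_days": tp,
                    "fraction": frac,
                    "replicate": int(mouse_id.rsplit("_m", 1)[1]),
                    "mouse_id": mouse_id,
                    "compartment": compartment,
                    "compliance": np.nan,
                }
            )
    values = _apply_missingness(np.column_stack(blocks), config, rng)
    samples = pd.DataFrame(col_meta).set_index("sample_id")
    vdf = pd.DataFrame(values, index=proteins.index, columns=cols)
    table = IntensityTable(vdf, proteins[["gene_name"]].copy(), samples, {"design": "BALF"})

    truth_df = proteins[["gene_name", "class", "abundance_log2"]].copy()
    truth_df["elf_member"] = elf_member
    truth_df["secretion_log2_shift"] = secretion_shift
    truth_df["archetype"] = archetype
    truth_df["amplitude"] = amplitude
    fc = _true_fc_frame(archetype, amplitude, timepoints)
    fc.index = truth_df.index
    truth_df = pd.concat([truth_df, fc], axis=1)
    return table, GroundTruth(truth_df, mice, config)


def generate_annotations(
    truth: GroundTruth, noise_frac: float = 0.0, seed: int = 0
) -> AnnotationCollection:
    """Gene-set terms derived from the ground truth, with membership noise.

    One term per compartment class (plus one per non-empty signature / ELF
    flag when present), keyed by gene name.  ``noise_frac`` of each term's
    members are swapped with random non-members, degrading the sets toward a
    random annotation.
    """
    if not 0 <= noise_frac < 1:
        raise ValueError("noise_frac must be in [0, 1)")
    proteins = truth.proteins
    genes = proteins["gene_name"]
    terms: dict[str, dict] = {}
    for cls, sub in proteins.groupby("class"):
        terms[str(cls)] = {"label": str(cls), "category": "compartment_class", "members": set(genes.loc[sub.index])}
    if "signature" in proteins.columns:
        for sig, sub in proteins[proteins["signature"] != ""].groupby("signature"):
            terms[str(sig)] = {"label": str(sig), "category": "signature", "members": set(genes.loc[sub.index])}
    if "elf_member" in proteins.columns and proteins["elf_member"].any():
        terms["ELF"] = {
            "label": "ELF",
            "category": "compartment",
            "members": set(genes.loc[proteins["elf_member"]]),
        }
    rng = np.random.default_rng([seed, 4])
    if noise_frac > 0:
        all_genes = set(genes)
        for rec in terms.values():
            members = sorted(rec["members"])
            k = int(round(noise_frac * len(members)))
            if k == 0:
                continue
            non_members = sorted(all_genes - rec["members"])
            k = min(k, len(non_members), len(members))
            drop = rng.choice(len(members), size=k, replace=False)
            add = rng.choice(len(non_members), size=k, replace=False)
            new = rec["members"] - {members[i] for i in drop}
            new |= {non_members[i] for i in add}
            rec["members"] = new
    return AnnotationCollection(terms)


def null_config(config: GeneratorConfig | None = None, **overrides) -> GeneratorConfig:
    """A copy of ``config`` with every effect switched off (null simulations)."""
    config = config or GeneratorConfig()
    return replace(
        config,
        frac_abundance_changed=0.0,
        frac_profile_shifted=0.0,
        compliance_coupling=0.0,
        **overrides,
    )
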