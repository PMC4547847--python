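"""Data model and readers/writers for protein intensity tables and gene-set annotations.

The central container is :class:`IntensityTable`, a proteins x samples matrix of
linear label-free MS intensities with explicit missingness (NaN) plus per-protein
and per-sample metadata.  Input tables follow the wide tab-separated
``proteinGroups`` dialect emitted by common MS quantification software: one row
per protein group, per-sample ``Intensity <name>`` / ``LFQ intensity <name>`` /
``iBAQ <name>`` columns, and ``Reverse`` / ``Potential contaminant`` flag
columns.  A sample sheet maps intensity columns to experimental design fields
(condition, time point, solubility fraction, replicate, compartment, lung
compliance).

Zero intensities are non-detection sentinels in label-free output and are
converted to missing on read; they are never treated as measured zeros.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

CONDITIONS = ("PBS", "BLEO")
FRACTIONS = ("FR1", "FR2", "FR3", "INSOL", "TOTAL", "BALF")
QDSP_FRACTIONS = ("FR1", "FR2", "FR3", "INSOL")
COMPARTMENTS = ("TISSUE", "BALF")

#: sample-sheet fields beyond the column name itself
SAMPLE_FIELDS = (
    "sample_id",
    "condition",
    "timepoint_days",
    "fraction",
    "replicate",
    "mouse_id",
    "compartment",
    "compliance",
)

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class SampleKey:
    """Design metadata for one MS sample (one intensity column)."""

    sample_id: str
    condition: str
    fraction: str
    replicate: int
    mouse_id: str
    compartment: str = "TISSUE"
    timepoint_days: int | None = None
    compliance: float | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.fraction not in FRACTIONS:
            raise ValueError(f"unknown fraction label {self.fraction!r}")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")
        if self.compliance is not None and not self.compliance > 0:
            raise ValueError("compliance must be positive when present")


@dataclass
class IntensityTable:
    """Proteins x samples matrix of linear intensities with design metadata.

    Attributes
    ----------
    values : pd.DataFrame
        Linear intensities, index = protein_id, columns = sample_id, NaN = missing.
        Stored intensities are strictly positive.
    proteins : pd.DataFrame
        Indexed by protein_id; columns include ``gene_name`` and optionally
        ``sequence`` and ``n_theoretical_peptides``.
    samples : pd.DataFrame
        Indexed by sample_id; columns are the :data:`SAMPLE_FIELDS`.
    """

    values: pd.DataFrame
    proteins: pd.DataFrame
    samples: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.proteins.index):
            raise ValueError("values index does not match protein metadata index")
        if not self.values.columns.equals(self.samples.index):
            raise ValueError("values columns do not match sample metadata index")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate protein_id {dup!r}")
        if self.samples.index.has_duplicates:
            dup = self.samples.index[self.samples.index.duplicated()][0]
            raise ValueError(f"duplicate sample_id {dup!r}")
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy() <= 0).any():
                raise ValueError("stored intensities must be positive (zeros are missing)")

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def select_samples(self, **criteria) -> "IntensityTable":
        """Subset by sample-metadata equality, e.g. ``select_samples(condition="PBS")``.

        A criterion value may be a list/tuple/set, meaning membership.
        """
        mask = pd.Series(True, index=self.samples.index)
        for key, val in criteria.items():
            col = self.samples[key]
            if isinstance(val, (list, tuple, set, frozenset)):
                mask &= col.isin(list(val))
            else:
                mask &= col == val
        ids = self.samples.index[mask]
        return IntensityTable(
            self.values.loc[:, ids], self.proteins.copy(), self.samples.loc[ids].copy(), dict(self.meta)
        )

    def log2(self) -> pd.DataFrame:
        """log2-transformed intensities (NaN preserved)."""
        return np.log2(self.values)


@dataclass
class AnnotationCollection:
    """Gene-set annotations: term_id -> {label, category, members}."""

    terms: dict[str, dict]

    def __post_init__(self) -> None:
        for term_id, rec in self.terms.items():
            members = rec.get("members")
            if not members:
                raise ValueError(f"annotation term {term_id!r} has no members")
            rec["members"] = set(members)
            rec.setdefault("label", term_id)
            rec.setdefault("category", "")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.items())

    def members(self, term_id: str) -> set[str]:
        return self.terms[term_id]["members"]


# ---------------------------------------------------------------------------
# proteinGroups dialect
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet (TSV or YAML) into a DataFrame indexed by column name.

    Each record maps one intensity column of the proteinGroups file to design
    fields.  Required fields: ``column``, ``sample_id``, ``condition``,
    ``fraction``, ``replicate``, ``mouse_id``.  Optional: ``timepoint_days``,
    ``compartment`` (default TISSUE), ``compliance``.
    """
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            records = yaml.safe_load(fh)
        sheet = pd.DataFrame(records)
    else:
        sheet = pd.read_csv(path, sep="\t")
    if "column" not in sheet.columns or "sample_id" not in sheet.columns:
        raise ValueError("sample sheet needs 'column' and 'sample_id' fields")
    sheet = sheet.set_index("column")
    for fld, default in (("compartment", "TISSUE"), ("timepoint_days", np.nan), ("compliance", np.nan)):
        if fld not in sheet.columns:
            sheet[fld] = default
    bad = set(sheet["fraction"]) - set(FRACTIONS)
    if bad:
        raise ValueError(f"unknown fraction label(s) {sorted(bad)}")
    bad = set(sheet["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown condition label(s) {sorted(bad)}")
    return sheet


def _flagged(series: pd.Series) -> pd.Series:
    return series.fillna("").astype(str).str.strip() == "+"


def read_protein_groups(path: str | Path, sample_sheet: str | Path | pd.DataFrame) -> IntensityTable:
    """Parse a proteinGroups-dialect TSV into an :class:`IntensityTable`.

    Rows flagged in the ``Reverse`` or ``Potential contaminant`` columns are
    removed (counts logged and recorded in ``table.meta``); intensities of 0 or
    blank become missing.  Every sample-sheet entry must resolve to exactly one
    column of the file.
    """
    if not isinstance(sample_sheet, pd.DataFrame):
        sample_sheet = read_sample_sheet(sample_sheet)
    raw = pd.read_csv(
        path,
        sep="\t",
        dtype={"Reverse": str, "Potential contaminant": str},
        float_precision="round_trip",
    )

    n_rev = n_con = 0
    if "Reverse" in raw.columns:
        rev = _flagged(raw["Reverse"])
        n_rev = int(rev.sum())
        raw = raw.loc[~rev]
    if "Potential contaminant" in raw.columns:
        con = _flagged(raw["Potential contaminant"])
        n_con = int(con.sum())
        raw = raw.loc[~con]
    logger.info("filtered %d reverse and %d contaminant rows", n_rev, n_con)

    id_col = "Majority protein IDs" if "Majority protein IDs" in raw.columns else "Protein IDs"
    if id_col not in raw.columns:
        raise ValueError("no protein id column ('Majority protein IDs' or 'Protein IDs') found")
    ids = raw[id_col].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValueError(f"duplicate protein_id {dup!r}")

    missing_cols = [c for c in sample_sheet.index if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"sample sheet column(s) not in file: {missing_cols}")

    values = raw[list(sample_sheet.index)].apply(pd.to_numeric, errors="coerce")
    values = values.where(values > 0)  # 0 and negatives are non-detections
    values.columns = sample_sheet["sample_id"].to_numpy()
    values.index = ids.to_numpy()
    values.index.name = "protein_id"

    proteins = pd.DataFrame(index=values.index)
    proteins["gene_name"] = (
        raw["Gene names"].fillna("").astype(str).to_numpy() if "Gene names" in raw.columns else ""
    )
    if "Sequence" in raw.columns:
        proteins["sequence"] = raw["Sequence"].fillna("").astype(str).to_numpy()

    samples = sample_sheet.reset_index(drop=True).set_index("sample_id")
    samples = samples.reindex(columns=[f for f in SAMPLE_FIELDS if f != "sample_id"])
    samples["replicate"] = samples["replicate"].astype(int)

    meta = {"n_reverse_removed": n_rev, "n_contaminant_removed": n_con, "source": str(path)}
    return IntensityTable(values, proteins, samples, meta)


def write_protein_groups(table: IntensityTable, path: str | Path, sheet_path: str | Path | None = None) -> None:
    """Write an :class:`IntensityTable` back to the proteinGroups dialect.

    Non-missing intensities round-trip exactly (``repr`` formatting); missing
    cells are written as 0, the dialect's non-detection sentinel.  Optionally
    writes the matching sample sheet.
    """
    out = pd.DataFrame({"Majority protein IDs": table.values.index})
    out["Gene names"] = table.proteins["gene_name"].to_numpy()
    if "sequence" in table.proteins.columns:
        out["Sequence"] = table.proteins["sequence"].to_numpy()
    for sid in table.values.columns:
        out[f"Intensity {sid}"] = table.values[sid].fillna(0).map(repr).to_numpy()
    out["Reverse"] = ""
    out["Potential contaminant"] = ""
    out.to_csv(path, sep="\t", index=False)
    if sheet_path is not None:
        sheet = table.samples.reset_index()
        sheet.insert(0, "column", "Intensity " + sheet["sample_id"].astype(str))
        sheet.to_csv(sheet_path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path, comment_lines: list[str] | None = None) -> None:
    """Write a result table as TSV, optionally preceded by '#' header comments."""
    with open(path, "w") as fh:
        for line in comment_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=True, lineterminator="\n")


def write_run_metadata(path: str | Path, metadata: dict) -> None:
    """JSON run-metadata sidecar (versions, seed, filter counts, parameters)."""
    with open(path, "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_gmt(path: str | Path, category: str = "") -> AnnotationCollection:
    """Read gene sets in the GMT dialect: term <tab> description <tab> members..."""
    terms: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            terms[parts[0]] = {
                "label": parts[1] or parts[0],
                "category": category,
                "members": {m for m in parts[2:] if m},
            }
    return AnnotationCollection(terms)


def write_gmt(annotations: AnnotationCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term_id, rec in annotations:
            members = "\t".join(sorted(rec["members"]))
            fh.write(f"{term_id}\t{rec['label']}\t{members}\n")


# ---------------------------------------------------------------------------
# protein-level utilities
# ---------------------------------------------------------------------------

def count_tryptic_peptides(
    sequence: str, min_len: int = 7, max_len: int = 30
) -> int:
    """Number of fully cleaved tryptic peptides with length in [min_len, max_len].

    Trypsin cleaves C-terminal of K/R, suppressed when the next residue is P;
    no missed cleavages.  This is the theoretical-peptide denominator used for
    iBAQ normalization.
    """
    if not sequence:
        warnings.warn("empty sequence: 0 theoretical peptides", stacklevel=2)
        return 0
    illegal = set(sequence) - _AA
    if illegal:
        raise ValueError(f"illegal amino-acid character(s) {sorted(illegal)}")
    count = 0
    start = 0
    for i, res in enumerate(sequence):
        at_end = i == len(sequence) - 1
        cleave = res in "KR" and not at_end and sequence[i + 1] != "P"
        if cleave or at_end:
            if min_len <= i + 1 - start <= max_len:
                count += 1
            start = i + 1
    return count


def compute_ibaq(intensity: float, n_theoretical_peptides: int) -> float:
    """iBAQ value: summed intensity / number of theoretical tryptic peptides."""
    if n_theoretical_peptides == 0:
        warnings.warn("iBAQ undefined for 0 theoretical peptides", stacklevel=2)
        return np.nan
    if intensity <= 0 or n_theoretical_peptides < 0:
        raise ValueError("intensity and peptide count must be positive")
    return intensity / n_theoretical_peptides


def stoichiometry(ibaq_values: pd.Series | dict) -> pd.Series:
    """Normalize a protein family's iBAQ values to a relative stoichiometry.

    Missing members are excluded and the remainder renormalized to sum 1.
    """
    s = pd.Series(ibaq_values, dtype=float)
    valid = s.dropna()
    if valid.empty or valid.sum() <= 0:
        raise ValueError("no valid positive iBAQ values in family")
    out = pd.Series(np.nan, index=s.index)
    out.loc[valid.index] = valid / valid.sum()
    return out


def match_omics(
    protein_ratios: pd.Series | dict,
    fpkm_table: pd.Series | dict,
    rna_ratios: pd.Series | dict | None = None,
    fpkm_log2_cutoff: float = -1.0,
) -> pd.DataFrame:
    """Match per-gene protein ratios with transcript FPKM values.

    Retains the key intersection with log2(FPKM) >= cutoff and a quantified
    protein.  The returned frame carries ``protein_log2_ratio``, ``fpkm_log2``
    and, when RNA ratios are given, ``rna_log2_ratio``; the Pearson correlation
    of the two ratio columns is stored in ``frame.attrs["pearson_r"]``.
    """
    prot = pd.Series(protein_ratios, dtype=float).dropna()
    fpkm = pd.Series(fpkm_table, dtype=float)
    with np.errstate(divide="ignore"):
        fpkm_log2 = np.log2(fpkm.where(fpkm > 0))
    genes = prot.index.intersection(fpkm_log2.index[fpkm_log2 >= fpkm_log2_cutoff])
    if len(genes) == 0:
        raise ValueError("no genes pass the FPKM cutoff in both datasets")
    out = pd.DataFrame(
        {"protein_log2_ratio": prot.loc[genes], "fpkm_log2": fpkm_log2.loc[genes]}
    )
    if rna_ratios is not None:
        rna = pd.Series(rna_ratios, dtype=float)
        out["rna_log2_ratio"] = rna.reindex(genes)
        both = out.dropna(subset=["protein_log2_ratio", "rna_log2_ratio"])
        if len(both) >= 3:
            x = both["protein_log2_ratio"].to_numpy()
            y = both["rna_log2_ratio"].to_numpy()
            xc, yc = x - x.mean(), y - y.mean()
            out.attrs["pearson_r"] = float(
                (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
            )
    return out


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scoring (sample sd, ddof=1) over non-missing entries.

    Rows with zero spread become all-missing with a warning.
    """
    arr = matrix.to_numpy(dtype=float)
    mean = np.nanmean(arr, axis=1, keepdims=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(arr, axis=1, ddof=1, keepdims=True)
    degenerate = ~(sd > 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-spread row(s) set to missing", stacklevel=2
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (arr - mean) / sd
    z[degenerate[:, 0], :] = np.nan
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
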