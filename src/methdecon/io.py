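"""Tabular artifact input/output with strict validation.

The pipeline exchanges four kinds of delimited-text artifacts: beta-value
matrices (CpG probes x samples, tab-delimited by default), sample sheets
(CSV), probe manifests modeled on the Illumina HumanMethylation450
annotation (CSV), and result tables (CSV).  Everything round-trips through
pandas; validation is performed here so downstream code can assume clean
containers.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Allowed gene-region group tokens (Illumina ``UCSC_RefGene_Group`` values).
REGION_GROUPS = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR")

#: Allowed relation-to-CpG-island tokens.
ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")

#: Tumor molecular subtype labels (PAM50) accepted in sample sheets.
SUBTYPES = ("Basal-like", "Her2", "LumA", "LumB", "Normal-like", "unknown")

STAGES = ("I", "II", "III", "IV", "missing")

MISSING_TOKEN = "NA"

#: Values this far outside [0, 1] are clamped; farther is an error.
BETA_BOUND_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when an artifact violates its schema or invariants."""


@dataclasses.dataclass
class BetaMatrix:
    """CpG-by-sample methylation fractions in [0, 1].

    ``values`` is an ``(m, n)`` float array with ``NaN`` marking missing
    cells.  Probe and sample identifiers are unique and ordered.
    """

    probe_ids: pd.Index
    sample_ids: pd.Index
    values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = pd.Index(self.probe_ids, dtype=object)
        self.sample_ids = pd.Index(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.probe_ids, "probe id")
        _check_unique(self.sample_ids, "sample id")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"({len(self.probe_ids)} probes, {len(self.sample_ids)} samples)"
            )
        self.values = _clamp_unit_interval(self.values, self.probe_ids, self.sample_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    def select_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        idx = self.probe_ids.get_indexer(probe_ids)
        if (idx < 0).any():
            missing = [p for p, i in zip(probe_ids, idx) if i < 0]
            raise KeyError(f"probes not in matrix: {missing[:5]}")
        return BetaMatrix(pd.Index(probe_ids), self.sample_ids, self.values[idx])

    def select_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        idx = self.sample_ids.get_indexer(sample_ids)
        if (idx < 0).any():
            missing = [s for s, i in zip(sample_ids, idx) if i < 0]
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return BetaMatrix(self.probe_ids, pd.Index(sample_ids), self.values[:, idx])


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}(s): {dup[:5]}")


def _clamp_unit_interval(
    values: np.ndarray, probe_ids: pd.Index, sample_ids: pd.Index
) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        low = values < -BETA_BOUND_TOL
        high = values > 1.0 + BETA_BOUND_TOL
    if low.any() or high.any():
        i, j = np.argwhere(low | high)[0]
        raise ValidationError(
            f"beta value {values[i, j]!r} at probe {probe_ids[i]!r}, "
            f"sample {sample_ids[j]!r} outside [0, 1]"
        )
    return np.clip(values, 0.0, 1.0)


# ---------------------------------------------------------------------------
# beta matrices


def read_beta_matrix(path: str | Path, sep: str = "\t") -> BetaMatrix:
    """Read a probes-x-samples beta matrix from delimited text.

    First column holds probe ids, header row holds sample ids.  Missing
    entries are the token ``NA``.  Values outside [0, 1] by more than 1e-9
    are a hard error; values inside the tolerance are clamped.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=sep, index_col=0, na_values=[MISSING_TOKEN],
                        keep_default_na=False, dtype=object)
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        try:
            values[:, j] = pd.to_numeric(frame[col], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(frame[col], errors="coerce")
            row = frame.index[int(np.argmax(bad.isna() & frame[col].notna()))]
            raise ValidationError(
                f"non-numeric beta value in {path.name} at probe {row!r}, "
                f"sample {col!r}"
            ) from None
    return BetaMatrix(frame.index, pd.Index(frame.columns), values)


def write_beta_matrix(betas: BetaMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a beta matrix; round-trips through :func:`read_beta_matrix`."""
    frame = betas.to_frame()
    frame.index.name = "probe_id"
    frame.to_csv(path, sep=sep, na_rep=MISSING_TOKEN, float_format="%.17g")


# ---------------------------------------------------------------------------
# sample sheets


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample sheet (sample_id, tissue_status, subtype, stage, age).

    Normal samples may carry missing subtype/stage/age; tumor rows must have
    a valid tissue label.  Returns a normalized copy with canonical dtypes.
    """
    required = ["sample_id", "tissue_status", "subtype", "stage", "age"]
    missing_cols = [c for c in required if c not in sheet.columns]
    if missing_cols:
        raise ValidationError(f"sample sheet missing columns: {missing_cols}")
    out = sheet.loc[:, required].copy()
    out["sample_id"] = out["sample_id"].astype(str)
    _check_unique(pd.Index(out["sample_id"]), "sample id")
    bad_status = ~out["tissue_status"].isin(["tumor", "normal"])
    if bad_status.any():
        raise ValidationError(
            f"invalid tissue_status values: "
            f"{out.loc[bad_status, 'tissue_status'].unique().tolist()}"
        )
    out["subtype"] = out["subtype"].fillna("unknown")
    bad_sub = ~out["subtype"].isin(SUBTYPES)
    if bad_sub.any():
        raise ValidationError(
            f"invalid subtype values: {out.loc[bad_sub, 'subtype'].unique().tolist()}"
            f" (allowed: {list(SUBTYPES)})"
        )
    out["stage"] = out["stage"].fillna("missing").astype(str)
    out.loc[out["stage"] == "nan", "stage"] = "missing"
    bad_stage = ~out["stage"].isin(STAGES)
    if bad_stage.any():
        raise ValidationError(
            f"invalid stage values: {out.loc[bad_stage, 'stage'].unique().tolist()}"
        )
    out["age"] = pd.to_numeric(out["age"], errors="coerce")
    if (out["age"].dropna() < 0).any():
        raise ValidationError("negative age in sample sheet")
    return out.reset_index(drop=True)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, na_values=[MISSING_TOKEN])
    return validate_sample_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    validate_sample_sheet(sheet).to_csv(path, index=False, na_rep=MISSING_TOKEN)


# ---------------------------------------------------------------------------
# probe manifests


MANIFEST_COLUMNS = [
    "probe_id", "chrom", "pos", "gene_names", "gene_groups",
    "island_relation", "mask_snp", "mask_crossreactive", "mask_sex",
]


def split_gene_annotation(gene_names: str, gene_groups: str) -> list[tuple[str, str]]:
    """Split semicolon-delimited parallel gene/region lists into pairs.

    Empty annotation yields zero pairs.  Parallel lists of unequal length
    are a validation error.
    """
    names = [g for g in str(gene_names).split(";") if g] if gene_names else []
    groups = [g for g in str(gene_groups).split(";") if g] if gene_groups else []
    if len(names) != len(groups):
        raise ValidationError(
            f"gene_names {gene_names!r} and gene_groups {gene_groups!r} "
            f"split to unequal lengths ({len(names)} vs {len(groups)})"
        )
    for g in groups:
        if g not in REGION_GROUPS:
            raise ValidationError(
                f"unknown gene-region group {g!r}; allowed: {list(REGION_GROUPS)}"
            )
    return list(zip(names, groups))


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing_cols:
        raise ValidationError(f"manifest missing columns: {missing_cols}")
    out = manifest.loc[:, MANIFEST_COLUMNS].copy()
    out["probe_id"] = out["probe_id"].astype(str)
    _check_unique(pd.Index(out["probe_id"]), "probe id")
    out["gene_names"] = out["gene_names"].fillna("").astype(str)
    out["gene_groups"] = out["gene_groups"].fillna("").astype(str)
    for _, row in out.iterrows():
        split_gene_annotation(row["gene_names"], row["gene_groups"])
    bad_rel = ~out["island_relation"].isin(ISLAND_RELATIONS)
    if bad_rel.any():
        raise ValidationError(
            f"invalid island_relation values: "
            f"{out.loc[bad_rel, 'island_relation'].unique().tolist()}"
        )
    pos = pd.to_numeric(out["pos"], errors="coerce")
    has_chrom = out["chrom"].notna() & (out["chrom"].astype(str) != "")
    if (pos[has_chrom] < 1).any():
        raise ValidationError("manifest pos must be >= 1 (coordinates are 1-based)")
    out["pos"] = pos
    for col in ("mask_snp", "mask_crossreactive", "mask_sex"):
        out[col] = out[col].fillna(False).astype(bool)
    return out.reset_index(drop=True)


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path, na_values=[MISSING_TOKEN])
    return validate_manifest(manifest)


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    validate_manifest(manifest).to_csv(path, index=False, na_rep=MISSING_TOKEN)


# ---------------------------------------------------------------------------
# result tables


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write result tables as CSVs with deterministic order.

    DMGR-style tables (recognized by a ``median_q`` column) are sorted by
    median q ascending, then gene, then region, so repeated runs of the same
    analysis produce byte-identical files.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in sorted(tables):
        table = tables[name].copy()
        sort_cols = [c for c in ("median_q", "gene", "region") if c in table.columns]
        if sort_cols:
            table = table.sort_values(sort_cols, kind="mergesort")
        path = out_dir / f"{name}.csv"
        table.to_csv(path, index=False, na_rep=MISSING_TOKEN, float_format="%.17g")
        written.append(path)
    return written
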