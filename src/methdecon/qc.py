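"""Probe filtering and cohort assembly.

Probes are removed for two reasons, applied in order: (1) detection failure
— a detection p-value above threshold in strictly more than a given
fraction of samples — and (2) quality masks from the manifest (SNP in
probe, cross-reactive, sex-chromosome).  A probe hit by both rules is
counted once, under the first rule.  Cohort assembly restricts tumors to
those with a usable molecular subtype and dichotomizes stage into
early (I/II) and late (III/IV), yielding the eight subtype-by-stage strata
each compared against the full normal set.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .io import BetaMatrix, ValidationError

logger = logging.getLogger(__name__)

ANALYSIS_SUBTYPES = ("Basal-like", "Her2", "LumA", "LumB")
EARLY_STAGES = ("I", "II")
LATE_STAGES = ("III", "IV")


@dataclasses.dataclass
class FilterReport:
    """Bookkeeping for one probe-filter pass."""

    n_input_probes: int
    n_detection_failed: int
    n_mask_removed: int
    n_retained: int
    detection_failed_ids: list[str]
    mask_removed_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": ["input", "detection_failed", "mask_removed", "retained"],
                "n_probes": [
                    self.n_input_probes,
                    self.n_detection_failed,
                    self.n_mask_removed,
                    self.n_retained,
                ],
            }
        )


def filter_probes(
    betas: BetaMatrix,
    manifest: pd.DataFrame,
    detection_p: np.ndarray | None = None,
    p_threshold: float = 1.0e-5,
    sample_fraction: float = 0.25,
) -> tuple[BetaMatrix, FilterReport]:
    """Apply detection-p and manifest-mask probe filters.

    ``detection_p`` is an (m, n) matrix aligned to ``betas``; a probe fails
    detection when its p-value exceeds ``p_threshold`` in strictly more
    than ``sample_fraction`` of samples.  Mask filtering then removes
    probes with any of ``mask_snp``, ``mask_crossreactive``, ``mask_sex``.
    Probe order is preserved.  Every input probe lands in exactly one of
    {retained, detection-failed, mask-removed}.
    """
    manifest_idx = pd.Index(manifest["probe_id"])
    missing = betas.probe_ids.difference(manifest_idx)
    if len(missing):
        raise ValidationError(
            f"manifest missing {len(missing)} probes present in beta matrix, "
            f"e.g. {missing[:5].tolist()}"
        )
    m, n = betas.shape
    detection_failed = np.zeros(m, dtype=bool)
    if detection_p is not None:
        detection_p = np.asarray(detection_p, dtype=float)
        if detection_p.shape != (m, n):
            raise ValidationError(
                f"detection_p shape {detection_p.shape} does not match betas {betas.shape}"
            )
        frac_failed = (detection_p > p_threshold).mean(axis=1)
        detection_failed = frac_failed > sample_fraction

    mask_cols = manifest.set_index("probe_id").loc[
        betas.probe_ids, ["mask_snp", "mask_crossreactive", "mask_sex"]
    ]
    masked = mask_cols.any(axis=1).to_numpy()
    mask_removed = masked & ~detection_failed  # overlap counted under first rule

    keep = ~(detection_failed | mask_removed)
    report = FilterReport(
        n_input_probes=m,
        n_detection_failed=int(detection_failed.sum()),
        n_mask_removed=int(mask_removed.sum()),
        n_retained=int(keep.sum()),
        detection_failed_ids=betas.probe_ids[detection_failed].tolist(),
        mask_removed_ids=betas.probe_ids[mask_removed].tolist(),
    )
    filtered = BetaMatrix(
        betas.probe_ids[keep], betas.sample_ids, betas.values[keep]
    )
    logger.info(
        "probe filter: %d input, %d detection-failed, %d mask-removed, %d retained",
        report.n_input_probes, report.n_detection_failed,
        report.n_mask_removed, report.n_retained,
    )
    return filtered, report


@dataclasses.dataclass
class Cohort:
    """Stratified analysis cohort.

    ``strata`` maps ``(subtype, stage_group)`` with stage_group in
    {"early", "late"} to lists of tumor sample ids; every stratum is
    compared against the shared ``normal_ids``.  ``tumor_ids`` is the full
    retained tumor set (tumors with missing stage are retained here but
    appear in no stratum).
    """

    strata: dict[tuple[str, str], list[str]]
    normal_ids: list[str]
    tumor_ids: list[str]
    excluded: pd.DataFrame

    @property
    def n_early(self) -> int:
        return sum(len(v) for (s, g), v in self.strata.items() if g == "early")

    @property
    def n_late(self) -> int:
        return sum(len(v) for (s, g), v in self.strata.items() if g == "late")


def assemble_cohort(sheet: pd.DataFrame) -> Cohort:
    """Build the eight subtype-by-stage strata from a validated sample sheet.

    Tumors without a subtype assignment, or labeled Normal-like, are
    excluded (the Normal-like class is dropped for limited sample size).
    Tumors with missing stage stay in the retained tumor total but join no
    stage-stratified model.  Normal samples are always retained, regardless
    of missing covariates.
    """
    normals = sheet[sheet["tissue_status"] == "normal"]
    tumors = sheet[sheet["tissue_status"] == "tumor"]
    if normals.empty:
        raise ValidationError("cohort has no normal samples; models are tumor-vs-normal")

    keep = tumors["subtype"].isin(ANALYSIS_SUBTYPES)
    excluded = tumors.loc[~keep].assign(
        reason=np.where(
            tumors.loc[~keep, "subtype"] == "Normal-like",
            "normal_like_subtype",
            "missing_subtype",
        )
    )
    tumors = tumors.loc[keep]

    strata: dict[tuple[str, str], list[str]] = {}
    for subtype in ANALYSIS_SUBTYPES:
        sub = tumors[tumors["subtype"] == subtype]
        strata[(subtype, "early")] = sub.loc[
            sub["stage"].isin(EARLY_STAGES), "sample_id"
        ].tolist()
        strata[(subtype, "late")] = sub.loc[
            sub["stage"].isin(LATE_STAGES), "sample_id"
        ].tolist()
    if all(len(v) == 0 for v in strata.values()):
        logger.warning("all tumor strata are empty (no tumors with usable stage)")
    n_missing_stage = int((tumors["stage"] == "missing").sum())
    if n_missing_stage:
        logger.info(
            "%d tumors have missing stage; retained in totals, in no stratum",
            n_missing_stage,
        )
    return Cohort(
        strata=strata,
        normal_ids=normals["sample_id"].tolist(),
        tumor_ids=tumors["sample_id"].tolist(),
        excluded=excluded.reset_index(drop=True),
    )
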