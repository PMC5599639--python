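"""End-to-end pipeline: simulate -> filter -> deconvolve -> test -> DMGRs.

One :class:`RunConfig` drives a fully reproducible run: every stochastic
stage draws its seed deterministically from the config seed and the
stratum label, every output file is hashed into a run manifest, and an
identical config yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, qc
from .deconvolution import ReferenceFreeMixture
from .ewas import fit_adjusted_ewas
from .regions import call_dmgrs, intersect_strata, map_probes_to_regions
from .simulate import simulate_cell_methylomes, simulate_cohort, simulate_manifest

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Analysis constants and mode flags for one pipeline run."""

    workspace: str = "workspace"
    q_cutoff: float = 0.01
    p_threshold: float = 1.0e-5
    sample_fraction: float = 0.25
    k_min: int = 2
    k_max: int = 10
    n_boot: int = 10
    seed: int = 0
    adjust_age: bool = True
    collapse_mode: str = "gene_region"      # or island_context
    dmgr_rule: str = "median"               # or any
    sub_simplex: bool = False
    min_stratum_tumors: int = 3
    # synthetic workspace defaults
    sim_probes: int = 600
    sim_celltypes: int = 3
    sim_tumors: int = 60
    sim_normals: int = 60
    sim_separation: float = 0.7
    sim_noise_sd: float = 0.1
    sim_n_spiked: int = 30
    sim_delta: float = 0.3

    def validate(self) -> "RunConfig":
        if not 0 < self.q_cutoff < 1:
            raise ValueError("q_cutoff must be in (0, 1)")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if not 0 <= self.sample_fraction < 1:
            raise ValueError("sample_fraction must be in [0, 1)")
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError("need 2 <= k_min <= k_max")
        if self.collapse_mode not in ("gene_region", "island_context"):
            raise ValueError("collapse_mode must be gene_region or island_context")
        if self.dmgr_rule not in ("median", "any"):
            raise ValueError("dmgr_rule must be median or any")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)  # CLI overrides win
        return cls(**data).validate()

    def stage_seed(self, label: str) -> int:
        """Deterministic per-stage seed below 2**31."""
        return (self.seed * 1_000_003 + zlib.crc32(label.encode())) % (2**31)


def make_workspace(config: RunConfig) -> Path:
    """Generate a self-contained synthetic workspace on disk."""
    config.validate()
    ws = Path(config.workspace)
    ws.mkdir(parents=True, exist_ok=True)
    seed = config.stage_seed("simulate")
    M_star = simulate_cell_methylomes(
        config.sim_probes, config.sim_celltypes, config.sim_separation, seed=seed
    )
    rng = np.random.default_rng(seed + 1)
    # spike probes where a +/-delta shift keeps expectations inside [0, 1]:
    # shift lowly methylated probes up, highly methylated ones down
    delta = config.sim_delta
    can_up = M_star.max(axis=1) <= 1.0 - delta
    can_down = M_star.min(axis=1) >= delta
    eligible = np.flatnonzero(can_up | can_down)
    if eligible.size < config.sim_n_spiked:
        eligible = np.arange(config.sim_probes)
    spiked = sorted(rng.choice(eligible, size=config.sim_n_spiked,
                               replace=False).tolist())
    signs = np.where(can_up[spiked], 1.0, -1.0)
    betas, sheet, truth = simulate_cohort(
        M_star, config.sim_tumors, config.sim_normals,
        spiked_probes=spiked, delta=signs * delta,
        noise_sd=config.sim_noise_sd, seed=seed,
    )
    manifest = simulate_manifest(config.sim_probes)
    io.write_beta_matrix(betas, ws / "betas.tsv")
    io.write_sample_sheet(sheet, ws / "samples.csv")
    io.write_manifest(manifest, ws / "manifest.csv")
    pd.DataFrame({
        "probe_id": truth.spiked_probes,
        "delta": [truth.delta[p] for p in truth.spiked_probes],
    }).to_csv(ws / "truth_spikes.csv", index=False)
    logger.info("synthetic workspace written to %s", ws)
    return ws


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full per-stratum analysis; returns the run manifest.

    Stages per stratum: deconvolution (K selection unless k_min == k_max),
    cell-type-adjusted per-CpG testing, q-values, DMGR calling.  Early and
    late strata are then intersected.  Every output file's sha256 goes
    into ``run_manifest.json``.
    """
    config.validate()
    ws = Path(config.workspace)
    out = ws / "results"
    out.mkdir(parents=True, exist_ok=True)

    betas = io.read_beta_matrix(ws / "betas.tsv")
    sheet = io.read_sample_sheet(ws / "samples.csv")
    manifest = io.read_manifest(ws / "manifest.csv")
    detection = None
    det_path = ws / "detection_p.tsv"
    if det_path.exists():
        detection = io.read_beta_matrix(det_path).values

    filtered, report = qc.filter_probes(
        betas, manifest, detection_p=detection,
        p_threshold=config.p_threshold, sample_fraction=config.sample_fraction,
    )
    report.to_frame().to_csv(out / "filter_report.csv", index=False)

    cohort = qc.assemble_cohort(sheet)
    mapping = map_probes_to_regions(manifest, mode=config.collapse_mode)

    stratum_calls: dict[str, pd.DataFrame] = {}
    for (subtype, stage_group), tumor_ids in sorted(cohort.strata.items()):
        label = f"{subtype}_{stage_group}"
        if len(tumor_ids) < config.min_stratum_tumors:
            logger.warning("stratum %s has %d tumors (<%d); skipped",
                           label, len(tumor_ids), config.min_stratum_tumors)
            continue
        sample_ids = list(tumor_ids) + list(cohort.normal_ids)
        Y = filtered.select_samples(sample_ids)
        model = ReferenceFreeMixture(Y, sub_simplex=config.sub_simplex)
        seed = config.stage_seed(f"deconvolve/{label}")
        if config.k_min == config.k_max:
            K = config.k_min
            logger.info("stratum %s: K selection skipped, forced K=%d", label, K)
            ksel = None
        else:
            ksel = model.select_k(range(config.k_min, config.k_max + 1),
                                  n_boot=config.n_boot, seed=seed)
            ksel.to_frame().to_csv(out / f"kselect_{label}.csv", index=False)
            K = ksel.chosen_K
        result, fit = fit_adjusted_ewas(
            Y, sheet, K=K, adjust_age=config.adjust_age,
            q_cutoff=config.q_cutoff, seed=seed,
            sub_simplex=config.sub_simplex,
        )
        pd.DataFrame(fit.M).to_csv(
            out / f"M_{label}.tsv", sep="\t", float_format="%.10g")
        pd.DataFrame(fit.Omega, index=sample_ids).to_csv(
            out / f"Omega_{label}.tsv", sep="\t", float_format="%.10g")
        result.frame.to_csv(out / f"cpg_results_{label}.csv", index=False,
                            na_rep=io.MISSING_TOKEN, float_format="%.10g")

        calls = call_dmgrs(result.frame, mapping, q_cutoff=config.q_cutoff,
                           rule=config.dmgr_rule, stratum=label)
        io.write_results({f"dmgr_{label}": calls}, out)
        stratum_calls[label] = calls

    for stage_group in ("early", "late"):
        group = {k: v for k, v in stratum_calls.items() if k.endswith(stage_group)}
        if len(group) >= 2:
            inter = intersect_strata(group)
            inter.to_frame().to_csv(out / f"overlap_{stage_group}.csv", index=False)
            inter.shared_frame().to_csv(out / f"shared_dmgrs_{stage_group}.csv",
                                        index=False)

    run_manifest = {
        "config": dataclasses.asdict(config),
        "files": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "run_manifest.json"
        },
    }
    (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2,
                                                      sort_keys=True))
    return run_manifest
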