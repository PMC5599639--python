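"""Synthetic bulk-methylation cohorts with known cell-mixture ground truth.

The generator emulates normalized 450K-style beta matrices arising from a
Dirichlet mixture of latent cell-type methylomes: each sample's expected
methylome is a convex combination ``M* @ omega_i`` of ``K`` cell-type
profiles, tumor samples receive a mean shift on a spiked probe set, an age
slope can act on designated probes, and measurement noise is added on the
logit scale (logit-normal betas stay inside (0, 1) and reproduce the
bimodal marginals of array data).  Every artifact that the rest of the
pipeline consumes — beta matrix, sample sheet, probe manifest, expression
matrix — can be generated with a known :class:`SyntheticTruth`.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import BetaMatrix, ISLAND_RELATIONS, REGION_GROUPS, validate_manifest, validate_sample_sheet

logger = logging.getLogger(__name__)

_LOGIT_EPS = 1e-6


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth for one simulated cohort.

    Attributes
    ----------
    M_star : (m, K) array
        True cell-type methylomes in [0, 1].
    Omega_star : (n, K) array
        True per-sample cell-type proportions; rows on the simplex.
    spiked_probes : list of str
        Probe ids carrying a tumor effect.
    delta : dict probe_id -> float
        Signed tumor effect per spiked probe, on the beta scale.
    age_effect_probes : dict probe_id -> float
        Slope in beta units per year (applied to centered age).
    noise_sd : float
        Logit-scale noise standard deviation.
    seed : int
    """

    M_star: np.ndarray
    Omega_star: np.ndarray
    spiked_probes: list[str]
    delta: dict[str, float]
    age_effect_probes: dict[str, float]
    noise_sd: float
    seed: int


def simulate_cell_methylomes(
    m: int, K: int, separation: float = 0.5, seed: int = 0
) -> np.ndarray:
    """Draw an ``(m, K)`` matrix of cell-type methylomes.

    Each entry comes from a bimodal beta mixture (low mode near 0.1, high
    mode near 0.9).  A fraction ``separation`` of probes is *discordant*:
    its cell types are assigned opposing modes (for K=2 exactly opposite;
    for K>2 a random non-constant mode assignment), which is what makes the
    mixture identifiable.  Concordant probes share one mode across all
    cell types.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 1 <= K <= m:
        raise ValueError(f"need 1 <= K <= m, got K={K}, m={m}")
    if not 0.0 <= separation <= 1.0:
        raise ValueError("separation must be in [0, 1]")
    rng = np.random.default_rng(seed)
    discordant = rng.random(m) < separation
    modes = np.empty((m, K), dtype=int)
    base = rng.integers(0, 2, size=m)
    modes[:] = base[:, None]
    n_disc = int(discordant.sum())
    if K > 1 and n_disc:
        # non-constant mode vector per discordant probe; K=2 -> opposite modes
        disc_modes = np.empty((n_disc, K), dtype=int)
        for r in range(n_disc):
            v = rng.integers(0, 2, size=K)
            while v.min() == v.max():
                v = rng.integers(0, 2, size=K)
            disc_modes[r] = v
        modes[discordant] = disc_modes
    low = rng.beta(2.0, 18.0, size=(m, K))    # mean 0.1
    high = rng.beta(18.0, 2.0, size=(m, K))   # mean 0.9
    return np.where(modes == 1, high, low)


def _label_cycle(subtypes: tuple[str, ...], stages: tuple[str, ...],
                 n: int) -> tuple[list[str], list[str]]:
    """Round-robin over the full subtype x stage product."""
    ns = len(subtypes)
    return (
        [subtypes[i % ns] for i in range(n)],
        [stages[(i // ns) % len(stages)] for i in range(n)],
    )


def simulate_cohort(
    M_star: np.ndarray,
    n_tumor: int,
    n_normal: int,
    dirichlet_alpha: np.ndarray | list[float] | None = None,
    spiked_probes: list[int] | None = None,
    delta: float | np.ndarray = 0.0,
    age_effect_probes: dict[int, float] | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
    subtype_scheme: tuple[str, ...] = ("Basal-like", "Her2", "LumA", "LumB"),
    stage_scheme: tuple[str, ...] = ("I", "II", "III", "IV"),
    tumor_alpha: np.ndarray | list[float] | None = None,
) -> tuple[BetaMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate a tumor/normal cohort from cell-type methylomes.

    Per sample i, proportions ``omega_i ~ Dirichlet(alpha)``; the expected
    beta vector is ``M_star @ omega_i`` plus the tumor shift ``delta`` on
    spiked probes (tumor samples only) plus the age slope times centered
    age.  Noise is added on the logit scale with sd ``noise_sd`` and mapped
    back through the inverse logit; with ``noise_sd=0`` values are returned
    untransformed so the noiseless identity ``Y = M* Omega*^T`` holds
    exactly.  Final values are truncated to [0, 1].

    ``tumor_alpha`` optionally gives tumor samples a different Dirichlet
    parameter than normals — a pure cell-composition shift with no
    methylome change, used to probe cell-type confounding.

    Returns ``(BetaMatrix, sample sheet DataFrame, SyntheticTruth)``.
    """
    M_star = np.asarray(M_star, dtype=float)
    m, K = M_star.shape
    n = n_tumor + n_normal
    if dirichlet_alpha is None:
        # uniform over the simplex: bulk samples span the full range of
        # mixing proportions, which is also what makes the decomposition
        # identifiable (the data's convex hull pins the fitted simplex)
        dirichlet_alpha = np.ones(K)
    dirichlet_alpha = np.asarray(dirichlet_alpha, dtype=float)
    if dirichlet_alpha.shape != (K,) or (dirichlet_alpha <= 0).any():
        raise ValueError("dirichlet_alpha must be a strictly positive length-K vector")
    rng = np.random.default_rng(seed)

    if tumor_alpha is None:
        omega = rng.dirichlet(dirichlet_alpha, size=n)
    else:
        tumor_alpha = np.asarray(tumor_alpha, dtype=float)
        omega = np.vstack([
            rng.dirichlet(tumor_alpha, size=n_tumor),
            rng.dirichlet(dirichlet_alpha, size=n_normal),
        ])
    if K == 1:
        mu = np.repeat(M_star, n, axis=1)  # exact: no summation round-off
    else:
        mu = M_star @ omega.T  # (m, n)

    probe_ids = [f"cg{i:08d}" for i in range(m)]
    sample_ids = [f"T{i:04d}" for i in range(n_tumor)] + [
        f"N{i:04d}" for i in range(n_normal)
    ]
    is_tumor = np.array([True] * n_tumor + [False] * n_normal)

    spiked_probes = list(spiked_probes or [])
    delta_arr = np.broadcast_to(np.asarray(delta, dtype=float), (len(spiked_probes),))
    if spiked_probes:
        mu[np.asarray(spiked_probes)[:, None], is_tumor] += delta_arr[:, None]

    age = rng.uniform(35.0, 80.0, size=n)
    age_c = age - age.mean()
    age_effect_probes = dict(age_effect_probes or {})
    for probe_idx, slope in age_effect_probes.items():
        mu[probe_idx] += slope * age_c

    overshoot = np.maximum(mu - 1.0, -mu).max(initial=0.0)
    if overshoot > 0.2:
        warnings.warn(
            f"expected beta values exceed [0, 1] by up to {overshoot:.3f} "
            "before truncation; effect sizes are likely unrealistic",
            stacklevel=2,
        )
    mu = np.clip(mu, 0.0, 1.0)
    if noise_sd > 0:
        z = logit(np.clip(mu, _LOGIT_EPS, 1.0 - _LOGIT_EPS))
        z += rng.normal(0.0, noise_sd, size=mu.shape)
        y = expit(z)
    else:
        y = mu
    betas = BetaMatrix(pd.Index(probe_ids), pd.Index(sample_ids), y)

    tumor_subtypes, tumor_stages = _label_cycle(subtype_scheme, stage_scheme, n_tumor)
    sheet = pd.DataFrame({
        "sample_id": sample_ids,
        "tissue_status": np.where(is_tumor, "tumor", "normal"),
        "subtype": tumor_subtypes + ["unknown"] * n_normal,
        "stage": tumor_stages + ["missing"] * n_normal,
        "age": age,
    })
    sheet = validate_sample_sheet(sheet)

    truth = SyntheticTruth(
        M_star=M_star,
        Omega_star=omega,
        spiked_probes=[probe_ids[i] for i in spiked_probes],
        delta={probe_ids[i]: float(d) for i, d in zip(spiked_probes, delta_arr)},
        age_effect_probes={probe_ids[i]: float(s) for i, s in age_effect_probes.items()},
        noise_sd=float(noise_sd),
        seed=int(seed),
    )
    return betas, sheet, truth


def simulate_manifest(
    m: int,
    probes_per_gene: int = 6,
    chrom: str = "chr1",
    start: int = 10_000,
    spacing: int = 500,
) -> pd.DataFrame:
    """Build a probe manifest for ``m`` synthetic probes.

    Genes are laid out in contiguous blocks; within each block the probes
    cycle through all six gene-region classes (TSS1500 ... 3'UTR), so
    gene-region collapsing sees every class.  Island relations cycle
    through the six annotation values.  No masks are set.
    """
    probe_ids = [f"cg{i:08d}" for i in range(m)]
    genes = [f"GENE{i // probes_per_gene:05d}" for i in range(m)]
    groups = [REGION_GROUPS[i % len(REGION_GROUPS)] for i in range(m)]
    manifest = pd.DataFrame({
        "probe_id": probe_ids,
        "chrom": chrom,
        "pos": [start + i * spacing for i in range(m)],
        "gene_names": genes,
        "gene_groups": groups,
        "island_relation": [ISLAND_RELATIONS[i % len(ISLAND_RELATIONS)] for i in range(m)],
        "mask_snp": False,
        "mask_crossreactive": False,
        "mask_sex": False,
    })
    return validate_manifest(manifest)


def simulate_expression(
    betas: BetaMatrix,
    manifest: pd.DataFrame,
    coupled_genes: set[str],
    rho: float = -0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a gene-by-sample expression matrix coupled to methylation.

    For genes in ``coupled_genes``, expression is generated through a
    Gaussian copula against the gene's mean promoter (TSS1500/TSS200)
    methylation, with the latent correlation chosen as ``2*sin(pi*rho/6)``
    so the realized Spearman correlation targets ``rho``.  Uncoupled genes
    are independent noise.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    genes = sorted(set(
        g for gn in manifest["gene_names"] for g in str(gn).split(";") if g
    ))
    unknown = set(coupled_genes) - set(genes)
    if unknown:
        raise ValueError(f"coupled genes absent from manifest: {sorted(unknown)[:5]}")
    n = len(betas.sample_ids)
    frame = betas.to_frame()
    # latent Gaussian correlation achieving Spearman rho under the copula
    r = 2.0 * np.sin(np.pi * rho / 6.0)
    expr = np.empty((len(genes), n))
    promoter = {"TSS1500", "TSS200"}
    for gi, gene in enumerate(genes):
        if gene in coupled_genes:
            rows = [
                row.probe_id
                for row in manifest.itertuples()
                if any(
                    name == gene and group in promoter
                    for name, group in zip(
                        str(row.gene_names).split(";"), str(row.gene_groups).split(";")
                    )
                )
            ]
            meth = frame.loc[rows].mean(axis=0).to_numpy() if rows else rng.random(n)
            ranks = pd.Series(meth).rank(method="average").to_numpy()
            z = _normal_scores(ranks)
            expr[gi] = r * z + np.sqrt(max(0.0, 1.0 - r * r)) * rng.normal(size=n)
        else:
            expr[gi] = rng.normal(size=n)
    return pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=betas.sample_ids)


def _normal_scores(ranks: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return norm.ppf(ranks / (len(ranks) + 1.0))
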