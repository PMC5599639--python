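"""Per-CpG tumor-vs-normal linear models with cell-type adjustment.

For each CpG the methylation beta is regressed on an intercept, a tumor
indicator, optionally age, and K-1 of the K inferred cell-type proportion
columns (one column is dropped — by default the cell type with the largest
mean proportion — to avoid the exact collinearity of simplex rows).  The
tumor coefficient is tested with a two-sided t-test; p-values are
converted to Storey q-values.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import BetaMatrix, ValidationError
from .deconvolution import MixtureResults

logger = logging.getLogger(__name__)


def qvalues(p: np.ndarray, lambda_grid: np.ndarray | None = None) -> np.ndarray:
    """Storey q-values.

    pi0 is estimated as ``#{p > lambda} / (m (1 - lambda))`` on the grid
    (default 0.05, 0.10, ..., 0.95), smoothed by a cubic polynomial fit and
    evaluated at the largest lambda, then clamped to (0, 1].  With a
    single-point grid the raw estimate at that lambda is used; forcing
    ``lambda_grid=[0]`` (pi0 = 1 when no p is exactly 0) reproduces
    Benjamini-Hochberg adjusted p-values.  q-values are computed by the
    step-up ``min_{j >= i} pi0 * m * p_(j) / j`` on the sorted p-values and
    are invariant to input order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.951, 0.05)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    m = p.size
    pi0_at = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lambda_grid])
    if lambda_grid.size >= 4:
        coef = np.polyfit(lambda_grid, pi0_at, deg=3)
        pi0 = float(np.polyval(coef, lambda_grid.max()))
    else:
        pi0 = float(pi0_at[-1])
    pi0 = min(max(pi0, 1.0 / m), 1.0)  # clamp to (0, 1]
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclasses.dataclass
class CpGAssociationResults:
    """Per-CpG test results with a statsmodels-flavored summary."""

    frame: pd.DataFrame          # probe_id, beta_tumor, se, p, q, n_used, direction
    q_cutoff: float
    adjusted_for_age: bool
    n_celltype_covariates: int
    dropped_celltype: int | None

    @property
    def n_significant(self) -> int:
        return int((self.frame["q"] < self.q_cutoff).sum())

    def significant(self) -> pd.DataFrame:
        return self.frame[self.frame["q"] < self.q_cutoff].copy()

    def summary(self) -> str:
        f = self.frame
        ok = f["p"].notna()
        lines = [
            "Per-CpG tumor-vs-normal association",
            "===================================",
            f"probes tested:        {int(ok.sum())} of {len(f)}",
            f"age adjusted:         {self.adjusted_for_age}",
            f"cell-type covariates: {self.n_celltype_covariates}"
            + (f" (dropped column {self.dropped_celltype})"
               if self.dropped_celltype is not None else ""),
            f"q < {self.q_cutoff:g}:            {self.n_significant}"
            f" ({(f['q'] < self.q_cutoff).mean():.1%})",
            f"hyper / hypo among significant: "
            f"{int(((f['q'] < self.q_cutoff) & (f['direction'] == 'hyper')).sum())}"
            f" / {int(((f['q'] < self.q_cutoff) & (f['direction'] == 'hypo')).sum())}",
        ]
        return "\n".join(lines)


class CpGAssociation:
    """Model object for cell-type-adjusted per-CpG differential methylation.

    Parameters
    ----------
    betas : BetaMatrix
        Probes x samples methylation fractions (original missingness kept;
        samples with a missing beta are dropped probe-wise).
    sheet : DataFrame
        Validated sample sheet covering every sample in ``betas``.
    fit : MixtureResults or (n, K) array, optional
        Deconvolution fit aligned to the samples of ``betas``; its first
        K-1 proportion columns (after dropping the reference cell type)
        enter the design.  ``None`` fits the unadjusted model.
    adjust_age : bool
        Include age as a covariate; samples with missing age are dropped.
    drop_celltype : {"largest_mean", int}
        Which proportion column to leave out of the design.
    """

    def __init__(
        self,
        betas: BetaMatrix,
        sheet: pd.DataFrame,
        fit: MixtureResults | np.ndarray | None = None,
        adjust_age: bool = True,
        drop_celltype: str | int = "largest_mean",
    ):
        self.betas = betas
        sheet = sheet.set_index("sample_id", drop=False)
        missing = betas.sample_ids.difference(sheet.index)
        if len(missing):
            raise ValidationError(f"sample sheet missing samples: {missing[:5].tolist()}")
        self.sheet = sheet.loc[betas.sample_ids]
        if isinstance(fit, MixtureResults):
            omega = fit.Omega
            if fit.sample_ids is not None:
                frame = pd.DataFrame(omega, index=fit.sample_ids)
                omega = frame.loc[betas.sample_ids].to_numpy()
        elif fit is not None:
            omega = np.asarray(fit, dtype=float)
        else:
            omega = None
        if omega is not None and omega.shape[0] != len(betas.sample_ids):
            raise ValidationError("Omega rows are not aligned to the beta-matrix samples")
        self.omega = omega
        self.adjust_age = adjust_age
        self.drop_celltype = drop_celltype

    def _design(self) -> tuple[np.ndarray, np.ndarray, int | None, list[str]]:
        """Build the common design matrix; returns (X, keep_mask, dropped, names)."""
        n = len(self.betas.sample_ids)
        tumor = (self.sheet["tissue_status"] == "tumor").to_numpy(dtype=float)
        cols = [np.ones(n), tumor]
        names = ["intercept", "tumor"]
        keep = np.ones(n, dtype=bool)
        if self.adjust_age:
            age = self.sheet["age"].to_numpy(dtype=float)
            keep &= ~np.isnan(age)
            cols.append(age)
            names.append("age")
        dropped = None
        if self.omega is not None:
            K = self.omega.shape[1]
            if self.drop_celltype == "largest_mean":
                dropped = int(np.argmax(self.omega.mean(axis=0)))
            else:
                dropped = int(self.drop_celltype)
            for k in range(K):
                if k != dropped:
                    cols.append(self.omega[:, k])
                    names.append(f"celltype_{k}")
        X = np.column_stack(cols)
        return X, keep, dropped, names

    def fit(self, q_cutoff: float = 0.01,
            lambda_grid: np.ndarray | None = None) -> CpGAssociationResults:
        """Run OLS per probe and attach Storey q-values."""
        Y = self.betas.values
        X_full, keep, dropped, names = self._design()
        if keep.sum() < X_full.shape[1] + 3:
            raise ValidationError(
                f"only {int(keep.sum())} usable samples for {X_full.shape[1]} "
                "parameters; need >= 3 residual degrees of freedom"
            )
        tumor_flags = (self.sheet["tissue_status"] == "tumor").to_numpy()
        if not tumor_flags[keep].any() or tumor_flags[keep].all():
            raise ValidationError("stratum must contain both tumor and normal samples")
        X = X_full[keep]
        Yk = Y[:, keep]
        m = Yk.shape[0]
        beta = np.full(m, np.nan)
        se = np.full(m, np.nan)
        pvals = np.full(m, np.nan)
        n_used = np.zeros(m, dtype=int)

        complete = ~np.isnan(Yk).any(axis=1)
        t_idx = 1  # tumor column
        if complete.any():
            b, s, pv = _ols_tumor(X, Yk[complete], t_idx)
            beta[complete], se[complete], pvals[complete] = b, s, pv
            n_used[complete] = X.shape[0]
        for j in np.flatnonzero(~complete):
            obs = ~np.isnan(Yk[j])
            n_used[j] = int(obs.sum())
            Xj = X[obs]
            if n_used[j] < Xj.shape[1] + 3:
                continue
            if np.linalg.matrix_rank(Xj) < Xj.shape[1]:
                continue  # flagged missing, not silently dropped: row kept with NaN
            b, s, pv = _ols_tumor(Xj, Yk[j][obs][None, :], t_idx)
            beta[j], se[j], pvals[j] = b[0], s[0], pv[0]

        q = np.full(m, np.nan)
        ok = ~np.isnan(pvals)
        if ok.any():
            q[ok] = qvalues(pvals[ok], lambda_grid=lambda_grid)
        frame = pd.DataFrame({
            "probe_id": self.betas.probe_ids,
            "beta_tumor": beta,
            "se": se,
            "p": pvals,
            "q": q,
            "n_used": n_used,
            "direction": np.where(np.isnan(beta), "",
                                  np.where(beta > 0, "hyper", "hypo")),
        })
        return CpGAssociationResults(
            frame=frame, q_cutoff=q_cutoff, adjusted_for_age=self.adjust_age,
            n_celltype_covariates=0 if self.omega is None else self.omega.shape[1] - 1,
            dropped_celltype=dropped,
        )


def _ols_tumor(X: np.ndarray, Y_rows: np.ndarray, t_idx: int):
    """Vectorized OLS of many responses on one design; t-test on column t_idx.

    ``Y_rows`` is (m, n) with no missing entries.  Probes with zero
    residual variance (constant response) get NaN results.
    """
    n, p = X.shape
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        return (np.full(Y_rows.shape[0], np.nan),) * 3
    B = XtX_inv @ X.T @ Y_rows.T           # (p, m)
    resid = Y_rows.T - X @ B               # (n, m)
    dof = n - p
    rss = (resid ** 2).sum(axis=0)
    sigma2 = rss / dof
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(sigma2 * XtX_inv[t_idx, t_idx])
        tstat = B[t_idx] / se
    pv = 2.0 * stats.t.sf(np.abs(tstat), dof)
    # a constant response has zero residual variance AND zero effect: missing.
    # (a noiseless true effect also has rss ~ 0 but a varying response; its
    # t statistic is infinite and p underflows to 0, which is kept.)
    degenerate = Y_rows.var(axis=1) <= 1e-300
    if degenerate.any():
        pv = pv.copy()
        pv[degenerate] = np.nan
        se[degenerate] = np.nan
    b = B[t_idx].copy()
    b[degenerate] = np.nan
    return b, se, pv


def fit_adjusted_ewas(
    betas: BetaMatrix,
    sheet: pd.DataFrame,
    K: int,
    adjust_age: bool = True,
    n_iter: int = 2,
    q_cutoff: float = 0.01,
    seed: int = 0,
    sub_simplex: bool = False,
    fit_kwargs: dict | None = None,
) -> tuple[CpGAssociationResults, "MixtureResults"]:
    """Jointly estimate cell-type proportions and per-CpG tumor effects.

    A genuine methylation difference between tumors and normals is itself
    a (rank-one) structure in the beta matrix, so factorizing the raw data
    lets the phenotype effect leak into the estimated proportions, whose
    tumor-correlated error then biases the adjusted per-CpG tests.  The
    two estimands are therefore separated by alternation: after an initial
    pass on all probes, each round re-factorizes the matrix *excluding*
    the probes currently called significant (``q < q_cutoff``) and then
    re-tests every CpG against the new proportions.  ``n_iter`` extra
    rounds (default 2) are enough for the call set to stabilize.

    Composition confounding is still captured: when tumor and normal
    differ only in cell proportions, the adjusted per-CpG tests call
    nothing, no probe is excluded, and the proportions keep their
    tumor-associated component.  At most half the probes are ever
    excluded (the most significant ones), so the factorization always
    retains the bulk of the mixture signal.

    Returns the final association results and the final mixture fit.
    """
    from .deconvolution import ReferenceFreeMixture

    fit_kwargs = dict(fit_kwargs or {})
    Y0 = betas.values
    m = Y0.shape[0]
    exclude = np.zeros(m, dtype=bool)
    result = None
    fit = None
    for _ in range(n_iter + 1):
        model = ReferenceFreeMixture(Y0[~exclude], sub_simplex=sub_simplex)
        fit = model.fit(K, seed=seed, **fit_kwargs)
        result = CpGAssociation(
            betas, sheet, fit=fit.Omega, adjust_age=adjust_age
        ).fit(q_cutoff=q_cutoff)
        q = result.frame["q"].to_numpy()
        with np.errstate(invalid="ignore"):
            exclude = q < q_cutoff
        if exclude.sum() > m // 2:  # keep at least half the probes
            order = np.argsort(np.where(np.isnan(q), np.inf, q))
            exclude = np.zeros(m, dtype=bool)
            exclude[order[: m // 2]] = True
    fit.sample_ids = betas.sample_ids
    return result, fit


def test_cpgs(
    Y: BetaMatrix,
    sheet: pd.DataFrame,
    fit: MixtureResults | np.ndarray | None,
    adjust_age: bool = True,
    q_cutoff: float = 0.01,
    drop_celltype: str | int = "largest_mean",
) -> CpGAssociationResults:
    """One-call wrapper: cell-type-adjusted per-CpG tumor/normal testing."""
    model = CpGAssociation(Y, sheet, fit=fit, adjust_age=adjust_age,
                           drop_celltype=drop_celltype)
    return model.fit(q_cutoff=q_cutoff)
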