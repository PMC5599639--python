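"""Reference-free cell-type deconvolution by constrained NMF.

The model assumes each bulk methylome is a convex combination of ``K``
latent cell-type methylomes:  ``Y = M @ Omega.T`` with ``Y`` the (m, n)
beta matrix, ``M`` the (m, K) matrix of cell-type-specific methylation
states constrained to [0, 1], and ``Omega`` the (n, K) matrix of
per-sample cell-type proportions constrained to the probability simplex.

Fitting alternates two exact convex steps:

* each row of ``Omega`` solves a K-dimensional quadratic program
  ``min ||y_i - M w||^2  s.t.  w >= 0, sum(w) = 1`` (active-set solver);
* ``M`` is updated by box-constrained least squares via vectorized
  coordinate-descent sweeps (each clipped update is the exact coordinate
  minimizer, so the Frobenius objective never increases).

``K`` is chosen by bootstrapped deviance: for each candidate the model is
fit on the full data, sample-level bootstrap resamples define out-of-bag
sample sets, proportions are re-fit against the fixed ``M``, and a
Gaussian profile deviance of the out-of-bag reconstruction is averaged
over replicates; the minimizing ``K`` wins, ties going to the smaller
value.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls
from scipy.special import logit

from .io import BetaMatrix

logger = logging.getLogger(__name__)

_RIDGE = 1e-10


# ---------------------------------------------------------------------------
# simplex-constrained quadratic programming


def solve_simplex_ls(M: np.ndarray, y: np.ndarray, sub_simplex: bool = False) -> np.ndarray:
    """Solve ``min ||y - M w||^2`` subject to ``w >= 0`` and ``sum(w) = 1``.

    With ``sub_simplex=True`` the equality is relaxed to ``sum(w) <= 1``.
    Exact active-set solution of the K-dimensional QP (K is small); the
    Gram matrix is ridge-regularized by 1e-10 for numerical safety.
    """
    H = M.T @ M + _RIDGE * np.eye(M.shape[1])
    c = M.T @ y
    if sub_simplex:
        # if the nonnegativity-only optimum already satisfies sum <= 1 it is
        # optimal; otherwise the sum constraint is active -> simplex problem
        R = np.linalg.cholesky(H).T
        w, _ = nnls(R, np.linalg.solve(R.T, c))
        if w.sum() <= 1.0 + 1e-12:
            return w
    return _simplex_qp(H, c)


def _simplex_qp(H: np.ndarray, c: np.ndarray, max_iter: int = 200) -> np.ndarray:
    """Active-set solver for ``min 0.5 w'Hw - c'w`` on the unit simplex."""
    K = H.shape[0]
    free = np.ones(K, dtype=bool)
    for _ in range(max_iter):
        idx = np.flatnonzero(free)
        k = len(idx)
        # equality-constrained KKT system on the free set
        A = np.zeros((k + 1, k + 1))
        A[:k, :k] = H[np.ix_(idx, idx)]
        A[:k, k] = 1.0
        A[k, :k] = 1.0
        rhs = np.concatenate([c[idx], [1.0]])
        sol = np.linalg.solve(A, rhs)
        w_free, lam = sol[:k], sol[k]
        if (w_free < -1e-12).any():
            drop = idx[int(np.argmin(w_free))]
            free[drop] = False
            if free.sum() == 0:  # pragma: no cover - cannot happen with sum=1
                free[drop] = True
                break
            continue
        w = np.zeros(K)
        w[idx] = np.clip(w_free, 0.0, None)
        grad = H @ w - c
        bound = ~free
        if bound.any():
            mult = grad[bound] + lam
            if (mult < -1e-10).any():
                release = np.flatnonzero(bound)[int(np.argmin(mult))]
                free[release] = True
                continue
        return w / w.sum()
    logger.warning("simplex QP active-set did not settle; returning last iterate")
    w = np.zeros(K)
    w[np.flatnonzero(free)] = 1.0 / free.sum()
    return w


def _fit_omega(Y: np.ndarray, M: np.ndarray, sub_simplex: bool = False) -> np.ndarray:
    """Row-wise simplex least squares of all samples against fixed ``M``.

    The equality-constrained (sum-to-one) solution is computed for all
    samples in one vectorized solve; only samples whose interior solution
    violates nonnegativity fall back to the per-sample active-set QP.
    """
    n = Y.shape[1]
    K = M.shape[1]
    H = M.T @ M + _RIDGE * np.eye(K)
    C = M.T @ Y  # (K, n)
    out = np.empty((n, K))
    if sub_simplex:
        R = np.linalg.cholesky(H).T
        Rinv_t = np.linalg.inv(R.T)
        for i in range(n):
            w, _ = nnls(R, Rinv_t @ C[:, i])
            if w.sum() <= 1.0 + 1e-12:
                out[i] = w
            else:
                out[i] = _simplex_qp(H, C[:, i])
        return out
    Hinv_C = np.linalg.solve(H, C)          # (K, n)
    Hinv_1 = np.linalg.solve(H, np.ones(K))
    lam = (Hinv_C.sum(axis=0) - 1.0) / Hinv_1.sum()
    W = Hinv_C - np.outer(Hinv_1, lam)      # interior KKT solution, (K, n)
    out[:] = W.T
    violating = np.flatnonzero((W < -1e-12).any(axis=0))
    for i in violating:
        out[i] = _simplex_qp(H, C[:, i])
    np.clip(out, 0.0, None, out=out)
    out /= out.sum(axis=1, keepdims=True)
    return out


def _update_M(Y: np.ndarray, M: np.ndarray, Omega: np.ndarray, sweeps: int = 4) -> np.ndarray:
    """Box-constrained least-squares update of ``M`` by coordinate descent.

    Each column update is the exact minimizer of the Frobenius objective in
    that column with the others fixed, clipped to [0, 1]; the objective is
    therefore non-increasing.
    """
    G = Omega.T @ Omega  # (K, K)
    B = Y @ Omega        # (m, K)
    M = M.copy()
    K = M.shape[1]
    for _ in range(sweeps):
        for k in range(K):
            gkk = G[k, k]
            if gkk <= _RIDGE:
                continue  # component unused in this iterate
            num = B[:, k] - M @ G[:, k] + M[:, k] * gkk
            M[:, k] = np.clip(num / gkk, 0.0, 1.0)
    return M


# ---------------------------------------------------------------------------
# model / results objects


@dataclasses.dataclass
class MixtureResults:
    """Fitted decomposition ``Y ~ M @ Omega.T``.

    ``objective_trace`` records the Frobenius reconstruction error after
    every alternating iteration and is non-increasing.
    """

    K: int
    M: np.ndarray
    Omega: np.ndarray
    objective_trace: np.ndarray
    converged: bool
    seed: int
    probe_ids: object = None
    sample_ids: object = None

    @property
    def reconstruction_error(self) -> float:
        return float(self.objective_trace[-1])

    def reconstruction(self) -> np.ndarray:
        return self.M @ self.Omega.T

    def summary(self) -> str:
        lines = [
            "Reference-free mixture decomposition",
            "====================================",
            f"cell types (K):        {self.K}",
            f"probes x samples:      {self.M.shape[0]} x {self.Omega.shape[0]}",
            f"Frobenius error:       {self.reconstruction_error:.6g}",
            f"iterations:            {len(self.objective_trace)}",
            f"converged:             {self.converged}",
            "mean cell-type proportions: "
            + ", ".join(f"{v:.3f}" for v in self.Omega.mean(axis=0)),
        ]
        return "\n".join(lines)


@dataclasses.dataclass
class KSelectionResult:
    """Bootstrapped-deviance model-size selection."""

    candidate_Ks: list[int]
    mean_boot_deviance: np.ndarray
    chosen_K: int
    n_boot: int
    seed: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "K": self.candidate_Ks,
            "mean_boot_deviance": self.mean_boot_deviance,
            "chosen": [k == self.chosen_K for k in self.candidate_Ks],
        })


class ReferenceFreeMixture:
    """Constrained-NMF deconvolution model for a beta matrix.

    Parameters
    ----------
    Y : BetaMatrix or (m, n) array
        Bulk methylation fractions.  Missing entries are mean-imputed per
        probe before fitting (association testing elsewhere keeps the
        original missingness).
    sub_simplex : bool
        If True, proportion rows satisfy ``sum(w) <= 1`` instead of
        ``sum(w) = 1``.
    """

    def __init__(self, Y: BetaMatrix | np.ndarray, sub_simplex: bool = False):
        if isinstance(Y, BetaMatrix):
            self.probe_ids = Y.probe_ids
            self.sample_ids = Y.sample_ids
            values = Y.values.copy()
        else:
            self.probe_ids = None
            self.sample_ids = None
            values = np.asarray(Y, dtype=float).copy()
        self.n_imputed = int(np.isnan(values).sum())
        if self.n_imputed:
            means = np.nanmean(values, axis=1)
            means = np.where(np.isnan(means), 0.5, means)
            rows, cols = np.nonzero(np.isnan(values))
            values[rows, cols] = means[rows]
            logger.info("mean-imputed %d missing beta values for fitting", self.n_imputed)
        self.Y = values
        self.sub_simplex = sub_simplex

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        K: int,
        init: str = "kmeans",
        max_iter: int = 1000,
        tol: float = 1e-6,
        n_restarts: int = 5,
        seed: int = 0,
    ) -> MixtureResults:
        """Alternating least squares fit for a fixed number of cell types."""
        m, n = self.Y.shape
        if K < 2:
            raise ValueError(f"need K >= 2, got K={K}")
        if n == 1:
            # degenerate single-sample input: fit proceeds, the one
            # proportion row is simply some simplex point
            return self._als(np.full((1, K), 1.0 / K), K, max_iter, tol, seed)
        if K > n:
            raise ValueError(f"need K <= n_samples ({n}), got K={K}")
        if init not in ("kmeans", "random"):
            raise ValueError("init must be 'kmeans' or 'random'")
        rng = np.random.default_rng(seed)
        best: MixtureResults | None = None
        n_starts = n_restarts if init == "random" else max(1, n_restarts)
        for r in range(n_starts):
            if init == "kmeans" and r == 0:
                omega0 = self._kmeans_init(K, rng)
            else:
                omega0 = rng.dirichlet(np.ones(K), size=n)
            res = self._als(omega0, K, max_iter, tol, seed)
            if best is None or res.reconstruction_error < best.reconstruction_error:
                best = res
        return best

    def _kmeans_init(self, K: int, rng: np.random.Generator) -> np.ndarray:
        from sklearn.cluster import KMeans

        Z = logit(np.clip(self.Y.T, 1e-6, 1 - 1e-6))  # samples x probes
        km = KMeans(n_clusters=K, n_init=3, random_state=int(rng.integers(2**31)))
        labels = km.fit_predict(Z)
        omega0 = np.full((self.Y.shape[1], K), 0.1 / max(K - 1, 1))
        omega0[np.arange(len(labels)), labels] = 0.9
        return omega0 / omega0.sum(axis=1, keepdims=True)

    def _als(
        self, omega0: np.ndarray, K: int, max_iter: int, tol: float, seed: int
    ) -> MixtureResults:
        Y = self.Y
        omega = omega0
        M = _update_M(Y, np.full((Y.shape[0], K), 0.5), omega)
        trace = []
        prev = np.inf
        converged = False
        for _ in range(max_iter):
            omega = _fit_omega(Y, M, self.sub_simplex)
            M = _update_M(Y, M, omega)
            obj = float(np.linalg.norm(Y - M @ omega.T))
            trace.append(obj)
            if prev - obj < tol * max(prev, 1e-12):
                converged = True
                break
            prev = obj
        if not converged:
            logger.warning("ALS did not converge in %d iterations", max_iter)
        return MixtureResults(
            K=K, M=M, Omega=omega, objective_trace=np.asarray(trace),
            converged=converged, seed=seed,
            probe_ids=self.probe_ids, sample_ids=self.sample_ids,
        )

    # -- model-size selection ----------------------------------------------

    def select_k(
        self,
        K_range: range | list[int] = range(2, 11),
        n_boot: int = 10,
        seed: int = 0,
        df_correct: bool = True,
        fit_kwargs: dict | None = None,
    ) -> KSelectionResult:
        """Choose ``K`` minimizing the mean bootstrapped deviance.

        For each candidate ``K`` the model is fit on the full data; each
        bootstrap replicate resamples samples with replacement, the
        cell-type methylomes are re-fit on the resample (warm-started from
        the full fit), proportions of the out-of-resample samples are then
        fit holding that ``M`` fixed, and the Gaussian profile deviance of
        the out-of-resample reconstruction is computed.  Replicates with
        fewer than ``K`` distinct samples, or an empty out-of-bag set, are
        redrawn.  Ties in the mean deviance break toward smaller ``K``.
        """
        Ks = sorted(K_range)
        n = self.Y.shape[1]
        if n < max(Ks):
            raise ValueError(f"need n >= max(K_range) = {max(Ks)}, have n = {n}")
        fit_kwargs = dict(fit_kwargs or {})
        # candidate fits feed a deviance comparison; they do not need the
        # final-fit iteration budget
        fit_kwargs.setdefault("n_restarts", 3)
        fit_kwargs.setdefault("max_iter", 300)
        fit_kwargs.setdefault("tol", 1e-5)
        rng = np.random.default_rng(seed)
        # one shared set of resamples for every candidate K: the deviance
        # differences between Ks are far smaller than the between-resample
        # variation, so the comparison must be paired
        replicates = [self._draw_bootstrap_oob(rng, n, max(Ks))
                      for _ in range(n_boot)]
        mean_dev = np.empty(len(Ks))
        for ki, K in enumerate(Ks):
            res = self.fit(K, seed=seed, **fit_kwargs)
            devs = []
            for inbag, oob in replicates:
                M_b = self._refit_M(res.M, inbag)
                devs.append(self._oob_deviance(M_b, oob, K, df_correct))
            mean_dev[ki] = float(np.mean(devs))
        chosen = Ks[int(np.argmin(mean_dev))]  # argmin takes first -> smaller K on ties
        return KSelectionResult(
            candidate_Ks=Ks, mean_boot_deviance=mean_dev,
            chosen_K=chosen, n_boot=n_boot, seed=seed,
        )

    def _draw_bootstrap_oob(
        self, rng: np.random.Generator, n: int, K: int
    ) -> tuple[np.ndarray, np.ndarray]:
        for _ in range(100):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(idx)) < K:
                logger.info("degenerate bootstrap resample (<%d distinct); redrawn", K)
                continue
            oob = np.setdiff1d(np.arange(n), idx)
            if oob.size:
                return idx, oob
            logger.info("bootstrap resample left no out-of-bag samples; redrawn")
        raise RuntimeError("could not draw a usable bootstrap resample")

    def _refit_M(self, M0: np.ndarray, inbag: np.ndarray,
                 max_iter: int = 25, tol: float = 1e-5) -> np.ndarray:
        """Warm-started ALS refit of the methylomes on a bootstrap resample."""
        Y_in = self.Y[:, inbag]
        M = M0
        prev = np.inf
        for _ in range(max_iter):
            W = _fit_omega(Y_in, M, self.sub_simplex)
            M = _update_M(Y_in, M, W)
            obj = float(np.linalg.norm(Y_in - M @ W.T))
            if prev - obj < tol * max(prev, 1e-12):
                break
            prev = obj
        return M

    def _oob_deviance(
        self, M: np.ndarray, oob: np.ndarray, K: int, df_correct: bool
    ) -> float:
        """Gaussian profile deviance of the out-of-bag reconstruction.

        Per probe j: ``n_oob * log(RSS_j / df)`` with ``df = n_oob - K + 1``
        (the per-sample proportion fit spends K-1 degrees of freedom) when
        ``df_correct``; ``df = n_oob`` gives the uncorrected form.
        """
        Y_oob = self.Y[:, oob]
        W = _fit_omega(Y_oob, M, self.sub_simplex)
        resid = Y_oob - M @ W.T
        n_oob = oob.size
        rss = np.maximum((resid ** 2).sum(axis=1), 1e-300)
        df = max(n_oob - K + 1, 1) if df_correct else n_oob
        return float(n_oob * np.log(rss / df).sum())


# ---------------------------------------------------------------------------
# functional wrappers and truth matching


def fit_mixture(
    Y: BetaMatrix | np.ndarray,
    K: int,
    init: str = "kmeans",
    max_iter: int = 1000,
    tol: float = 1e-6,
    seed: int = 0,
    sub_simplex: bool = False,
    n_restarts: int = 5,
) -> MixtureResults:
    """Fit ``Y = M @ Omega.T`` with ``K`` cell types (one-call wrapper)."""
    model = ReferenceFreeMixture(Y, sub_simplex=sub_simplex)
    return model.fit(K, init=init, max_iter=max_iter, tol=tol, seed=seed,
                     n_restarts=n_restarts)


def select_K(
    Y: BetaMatrix | np.ndarray,
    K_range: range | list[int] = range(2, 11),
    n_boot: int = 10,
    seed: int = 0,
    **kwargs,
) -> KSelectionResult:
    """Bootstrapped-deviance choice of the number of cell types."""
    model = ReferenceFreeMixture(Y)
    return model.select_k(K_range=K_range, n_boot=n_boot, seed=seed, **kwargs)


def match_columns(estimate: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Optimal column matching of an estimate to a ground-truth matrix.

    Returns the permutation ``perm`` (Hungarian assignment maximizing
    column correlation) such that ``estimate[:, perm]`` aligns with
    ``truth``.  Used whenever fits are compared to simulation truth, since
    the decomposition is identifiable only up to column permutation.
    """
    Kt = truth.shape[1]
    Ke = estimate.shape[1]
    cost = np.zeros((Kt, Ke))
    for i in range(Kt):
        for j in range(Ke):
            t, e = truth[:, i], estimate[:, j]
            st, se = t.std(), e.std()
            if st < 1e-12 or se < 1e-12:
                cost[i, j] = -np.mean((t - t.mean()) * (e - e.mean()))
            else:
                cost[i, j] = -np.corrcoef(t, e)[0, 1]
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(Kt, dtype=int)
    perm[rows] = cols
    return perm
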