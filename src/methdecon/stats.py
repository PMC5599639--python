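"""Region-category enrichment and methylation-expression correlation."""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import BetaMatrix

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class EnrichmentResult:
    """2x2 Fisher exact enrichment of one region class in a call set.

    Table layout: rows = in/out of call set, columns = in/out of the
    region category.  The odds ratio is the sample OR ``(a*d)/(b*c)``; the
    95% CI is Woolf's logit interval with a Haldane 0.5 correction applied
    to all cells when any cell is zero.  A table with an empty margin
    (e.g. calls == universe) is flagged degenerate and the OR undefined.
    """

    table: np.ndarray
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    degenerate: bool = False


def region_enrichment(
    calls: set, universe: set, category: str,
    key_region_index: int = 1,
) -> EnrichmentResult:
    """Fisher exact test for enrichment of a region class among calls.

    ``calls`` and ``universe`` are sets of (gene, region) units with
    ``calls`` a subset of ``universe``; ``category`` is a region class
    such as ``"Body"``.
    """
    if not universe:
        raise ValueError("universe of tested units is empty")
    if not calls <= universe:
        raise ValueError("calls must be a subset of the universe")
    in_cat = {u for u in universe if u[key_region_index] == category}
    a = len(calls & in_cat)
    b = len(calls - in_cat)
    c = len(in_cat - calls)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    _, p = sps.fisher_exact(table, alternative="two-sided")
    degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
    if degenerate:
        logger.warning("degenerate 2x2 enrichment table %s; OR undefined", table.tolist())
        return EnrichmentResult(table, np.nan, np.nan, np.nan, float(p), True)
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    cells = table.astype(float)
    if (cells == 0).any():
        cells = cells + 0.5  # Haldane correction for the CI
    log_or = np.log((cells[0, 0] * cells[1, 1]) / (cells[0, 1] * cells[1, 0]))
    se = np.sqrt((1.0 / cells).sum())
    ci_low, ci_high = np.exp(log_or - 1.96 * se), np.exp(log_or + 1.96 * se)
    return EnrichmentResult(table, float(odds), float(ci_low), float(ci_high), float(p))


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact permutation p-value for Spearman rho (two-sided), n <= 10."""
    from itertools import permutations

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in permutations(ry):
        r = abs(np.corrcoef(rx, np.asarray(perm))[0, 1])
        count += r >= obs - 1e-12
        total += 1
    return count / total


def methylation_expression_correlation(
    betas: BetaMatrix,
    expression: pd.DataFrame,
    pairs: list[tuple[str, str]],
    alpha: float = 0.05,
    exact_max_n: int = 0,
) -> pd.DataFrame:
    """Spearman correlation of probe methylation with gene expression.

    ``pairs`` lists (probe_id, gene) couples; samples are matched by id and
    rows with missing values dropped per pair.  Pairs with fewer than 5
    shared samples are skipped (logged).  Significance uses a Bonferroni
    threshold ``alpha / n_pairs_tested``.  With ``exact_max_n > 0`` pairs
    of at most that size get an exact permutation p-value; otherwise the
    midrank t-approximation from scipy is used.  Results sorted by p.
    """
    beta_frame = betas.to_frame()
    shared_samples = beta_frame.columns.intersection(expression.columns)
    rows = []
    for probe_id, gene in pairs:
        if probe_id not in beta_frame.index or gene not in expression.index:
            logger.info("pair (%s, %s) absent from inputs; skipped", probe_id, gene)
            continue
        x = beta_frame.loc[probe_id, shared_samples].to_numpy(dtype=float)
        y = expression.loc[gene, shared_samples].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 5:
            logger.info("pair (%s, %s) has %d shared samples (<5); skipped",
                        probe_id, gene, int(ok.sum()))
            continue
        rho, p = sps.spearmanr(x[ok], y[ok])
        if 0 < exact_max_n >= ok.sum():
            p = _exact_spearman_p(x[ok], y[ok])
        rows.append({"probe_id": probe_id, "gene": gene,
                     "rho": float(rho), "p": float(p), "n": int(ok.sum())})
    result = pd.DataFrame(rows, columns=["probe_id", "gene", "rho", "p", "n"])
    n_tested = len(result)
    alpha_bonf = alpha / n_tested if n_tested else np.nan
    result["alpha_bonferroni"] = alpha_bonf
    result["significant"] = result["p"] < alpha_bonf if n_tested else False
    return result.sort_values("p", kind="mergesort").reset_index(drop=True)


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """Per-test threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
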