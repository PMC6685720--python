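"""Univariate statistics for pre/post imaging outcomes and exposure.

Covers the paired pre/post comparisons of ROI fractional anisotropy (FA),
the two-sample patient/control comparison, Spearman dose-response tests with
threshold sweeps, the hemispheric laterality index, and the serum-tau vs FA
association. Every test returns a :class:`TestResult` record carrying the
test name, sample size, statistic, two-tailed p and the options used, so
result tables are self-describing.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .hits import decile_thresholds, suprathreshold_counts_by_player

OUTCOME_COLUMNS = (
    "player_id", "group", "fa_pre_left", "fa_post_left",
    "fa_pre_right", "fa_post_right", "delta_left", "delta_right",
    "laterality", "tau",
)


@dataclass
class TestResult:
    """One hypothesis test: name, statistic, two-tailed p, n, options."""

    name: str
    statistic: float
    pvalue: float
    n: int
    options: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.isfinite(self.pvalue) and not 0.0 <= self.pvalue <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.pvalue}")

    def to_dict(self) -> dict:
        d = {"test": self.name, "statistic": self.statistic,
             "pvalue": self.pvalue, "n": self.n}
        d.update(self.options)
        return d


# ---------------------------------------------------------------------------
# laterality index
# ---------------------------------------------------------------------------

def laterality_index(delta_right, delta_left):
    """Hemispheric laterality of FA change.

    ``(dR - dL) / (|dR| + |dL|)``, bounded in [-1, 1]; positive values mean
    the change is right-lateralized. Undefined (NaN) when both deltas are
    exactly zero. Antisymmetric under hemisphere swap and invariant to a
    common positive rescaling of both deltas.
    """
    dr = np.asarray(delta_right, dtype=float)
    dl = np.asarray(delta_left, dtype=float)
    if not (np.all(np.isfinite(dr)) and np.all(np.isfinite(dl))):
        raise ValueError("laterality_index requires finite deltas")
    denom = np.abs(dr) + np.abs(dl)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (dr - dl) / np.where(denom > 0, denom, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def solve_delta_left(delta_right, laterality_target, fallback_scale=0.01):
    """Back-solve the left-hemisphere delta that realizes a laterality target.

    Given dR and a target L in (-1, 1), returns dL such that
    ``laterality_index(dR, dL) == L``. For dR < 0 the solution is
    ``dR (1 + L) / (1 - L)``; for dR > 0 it is ``dR (1 - L) / (1 + L)``
    (both keep dL on the side of zero that makes the absolute values
    consistent). dR = 0 admits only L = +-1; there ``-L * fallback_scale``
    is returned, matching the sign of the target.
    """
    dr = np.atleast_1d(np.asarray(delta_right, dtype=float))
    L = np.atleast_1d(np.asarray(laterality_target, dtype=float))
    if np.any(np.abs(L) >= 1.0):
        raise ValueError("laterality target must lie strictly inside (-1, 1)")
    dl = np.empty_like(dr)
    neg, pos, zero = dr < 0, dr > 0, dr == 0
    dl[neg] = dr[neg] * (1.0 + L[neg]) / (1.0 - L[neg])
    dl[pos] = dr[pos] * (1.0 - L[pos]) / (1.0 + L[pos])
    dl[zero] = -L[zero] * fallback_scale
    return dl if np.asarray(delta_right).ndim else float(dl[0])


# ---------------------------------------------------------------------------
# location tests
# ---------------------------------------------------------------------------

def paired_location_test(pre, post) -> tuple[TestResult, TestResult]:
    """Paired pre/post comparison: two-tailed paired t and Wilcoxon.

    The Wilcoxon signed-rank test drops zero differences (Wilcoxon's
    original rule) and uses the exact null when sample size permits. If all
    differences are zero both tests report no effect (statistic 0, p = 1).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.size < 3:
        raise ValueError("paired test needs equal-length vectors, n >= 3")
    n = pre.size
    d = post - pre
    if np.allclose(d, 0.0):
        t_res = TestResult("paired_t", 0.0, 1.0, n, {"note": "all differences zero"})
        w_res = TestResult("wilcoxon_signed_rank", 0.0, 1.0, n,
                           {"note": "all differences zero"})
        return t_res, w_res
    t_stat, t_p = sps.ttest_rel(post, pre)
    nz = d[d != 0.0]
    w_stat, w_p = sps.wilcoxon(nz, zero_method="wilcox", alternative="two-sided",
                               method="exact" if nz.size <= 25 else "auto")
    return (
        TestResult("paired_t", float(t_stat), float(t_p), n, {"tails": 2}),
        TestResult("wilcoxon_signed_rank", float(w_stat), float(w_p), n,
                   {"tails": 2, "zero_method": "wilcox", "n_nonzero": int(nz.size)}),
    )


def two_sample_test(group_a, group_b, welch: bool = False) -> TestResult:
    """Two-sample t test, two-tailed; pooled variance unless ``welch``."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("two-sample test needs >= 2 observations per group")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return TestResult("two_sample_t", 0.0, 1.0, a.size + b.size,
                          {"note": "degenerate: zero variance, equal means"})
    stat, p = sps.ttest_ind(a, b, equal_var=not welch)
    return TestResult("two_sample_t", float(stat), float(p), a.size + b.size,
                      {"variance": "welch" if welch else "pooled", "tails": 2})


# ---------------------------------------------------------------------------
# rank correlation
# ---------------------------------------------------------------------------

def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-tailed exact permutation p for Spearman rho (full enumeration).

    Enumerates all n! pairings of midranks, vectorized over the inner
    product; feasible for n <= 10 (10! = 3.6M). Ties handled by midranks.
    """
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    n = rx.size
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.int8)
    sx, sy = rx.std(), ry.std()
    # rho is monotone in sum_i rx[perm[i]] * ry[i]; evaluate it for all n!
    # pairings in blocks to bound memory at n = 10 (10! = 3.6M rows)
    n_extreme = 0
    for block in np.array_split(perms, max(1, perms.shape[0] // 500_000)):
        stats_blk = (rx[block] * ry).sum(axis=1)
        rho_blk = (stats_blk / n - rx.mean() * ry.mean()) / (sx * sy)
        n_extreme += int(np.sum(np.abs(rho_blk) >= abs(rho_obs) - 1e-12))
    return n_extreme / perms.shape[0]


def spearman_corr(x, y, exact_max_n: int = 10) -> TestResult:
    """Spearman rank correlation with a two-tailed p.

    Ties get midranks. For n <= ``exact_max_n`` the p-value comes from full
    enumeration of the permutation null; above that from the t
    approximation ``t = rho sqrt((n-2)/(1-rho^2))``. A constant input vector
    makes rho undefined (NaN, flagged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ValueError("spearman_corr needs equal-length vectors, n >= 4")
    n = x.size
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult("spearman", np.nan, np.nan, n,
                          {"note": "undefined: constant input"})
    rho = float(sps.spearmanr(x, y).statistic)
    if n <= exact_max_n:
        p = _exact_spearman_p(x, y, rho)
        method = "exact_permutation"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * sps.t.sf(abs(t), n - 2)
        method = "t_approximation"
    return TestResult("spearman", rho, float(p), n, {"p_method": method, "tails": 2})


# ---------------------------------------------------------------------------
# dose-response and tau association
# ---------------------------------------------------------------------------

def dose_response_sweep(
    log: pd.DataFrame,
    metric: str,
    outcomes: pd.DataFrame,
    thresholds=None,
    hemisphere: str = "right",
    inclusive: bool = True,
) -> pd.DataFrame:
    """Spearman dose-response at each force threshold.

    For every threshold, counts each player's hits at or above it and
    correlates (Spearman) the counts with the FA change of the chosen
    hemisphere (right by default, the ROI where the exposure effect is
    expected). ``thresholds=None`` sweeps the 9 interior deciles of the
    pooled metric distribution. A threshold at which all counts are equal is
    flagged as degenerate (rho undefined).

    Returns one row per threshold: threshold, rho, pvalue, n, degenerate.
    """
    if hemisphere not in ("left", "right"):
        raise ValueError("hemisphere must be 'left' or 'right'")
    if thresholds is None:
        thresholds = decile_thresholds(log, metric)
    thresholds = np.atleast_1d(np.asarray(thresholds, dtype=float))
    if thresholds.size == 0:
        raise ValueError("thresholds must be non-empty")
    players = outcomes["player_id"].tolist()
    missing = set(pd.unique(log["player_id"])) - set(players)
    if missing:
        raise ValueError(f"hit log contains players absent from outcomes: {sorted(missing)!r}")
    delta = outcomes.set_index("player_id")[f"delta_{hemisphere}"].loc[players].to_numpy()
    rows = []
    for thr in thresholds:
        counts = suprathreshold_counts_by_player(
            log, metric, thr, players=players, inclusive=inclusive
        ).to_numpy(dtype=float)
        if np.ptp(counts) == 0:
            rows.append({"threshold": thr, "rho": np.nan, "pvalue": np.nan,
                         "n": len(players), "degenerate": True})
            continue
        res = spearman_corr(counts, delta)
        rows.append({"threshold": thr, "rho": res.statistic, "pvalue": res.pvalue,
                     "n": res.n, "degenerate": False})
    return pd.DataFrame(rows)


def tau_fa_association(tau, fa, method: str = "spearman") -> TestResult:
    """Correlation between serum tau (pg/mL) and post-injury FA.

    Rank correlation by default; ``method='pearson'`` for the linear
    coefficient. The estimator used is recorded in the result options.
    """
    tau = np.asarray(tau, dtype=float)
    fa = np.asarray(fa, dtype=float)
    keep = np.isfinite(tau) & np.isfinite(fa)
    tau, fa = tau[keep], fa[keep]
    if tau.size < 4:
        raise ValueError("tau-FA association needs >= 4 complete pairs")
    if method == "spearman":
        res = spearman_corr(tau, fa)
        res.name = "tau_fa_spearman"
        res.options["estimator"] = "spearman"
        return res
    if method == "pearson":
        if np.ptp(tau) == 0 or np.ptp(fa) == 0:
            return TestResult("tau_fa_pearson", np.nan, np.nan, tau.size,
                              {"note": "undefined: constant input"})
        r, p = sps.pearsonr(tau, fa)
        return TestResult("tau_fa_pearson", float(r), float(p), tau.size,
                          {"estimator": "pearson", "tails": 2})
    raise ValueError("method must be 'spearman' or 'pearson'")
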