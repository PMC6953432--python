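"""Robust trimmed-mean statistics and behavioral indices.

Group comparisons use 20%-trimmed means with winsorized variances: the
Yuen two-sample statistic, its paired analog on difference scores, and a
heteroscedastic one-way ANOVA for trimmed means. Null distributions are
obtained by bootstrap resampling of trimmed-mean-centered groups, which
keeps the tests calibrated under unequal variances and heavy tails —
common in per-animal electrophysiology and engulfment data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_TRIM = 0.2
DEFAULT_N_BOOT = 5000


@dataclass
class RobustTestResult:
    statistic: float
    p_value: float
    ci_low: float  # percentile-bootstrap CI for the trimmed-mean difference
    ci_high: float
    trim: float
    n_boot: int
    seed: int | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.trim < 0.5):
            raise ValueError("trim must be in [0, 0.5)")


def _check_trim(n: int, trim: float) -> int:
    if not (0 <= trim < 0.5):
        raise ValueError("trim must be in [0, 0.5)")
    g = int(np.floor(trim * n))
    if n - 2 * g < 1:
        raise ValueError(f"trimming {trim} leaves no values from n={n}")
    return g


def trimmed_mean(x: np.ndarray, trim: float = DEFAULT_TRIM) -> float:
    """Mean after removing floor(trim*n) smallest and largest values."""
    x = np.sort(np.asarray(x, dtype=float))
    g = _check_trim(x.size, trim)
    return float(x[g : x.size - g].mean())


def _tm_rows(sorted_rows: np.ndarray, g: int) -> np.ndarray:
    n = sorted_rows.shape[-1]
    return sorted_rows[..., g : n - g].mean(axis=-1)


def _winvar_rows(sorted_rows: np.ndarray, g: int) -> np.ndarray:
    """Winsorized variance (ddof=1) of pre-sorted rows."""
    n = sorted_rows.shape[-1]
    w = sorted_rows.copy()
    if g > 0:
        w[..., :g] = w[..., g : g + 1]
        w[..., n - g :] = w[..., n - g - 1 : n - g]
    return w.var(axis=-1, ddof=1)


def winsorized_variance(x: np.ndarray, trim: float = DEFAULT_TRIM) -> float:
    x = np.sort(np.asarray(x, dtype=float))
    g = _check_trim(x.size, trim)
    return float(_winvar_rows(x[None, :], g)[0])


def _trimmed_se2(sorted_rows: np.ndarray, g: int) -> np.ndarray:
    """Squared standard error of the trimmed mean (Yuen's d)."""
    n = sorted_rows.shape[-1]
    h = n - 2 * g
    sw2 = _winvar_rows(sorted_rows, g)
    return (n - 1) * sw2 / (h * (h - 1))


def _yuen_t(xs: np.ndarray, ys: np.ndarray, gx: int, gy: int) -> np.ndarray:
    d = _trimmed_se2(xs, gx) + _trimmed_se2(ys, gy)
    return (_tm_rows(xs, gx) - _tm_rows(ys, gy)) / np.sqrt(d)


def _boot_idx(rng: np.random.Generator, n_boot: int, n: int) -> np.ndarray:
    return rng.integers(0, n, size=(n_boot, n))


def yuen_boot(
    x: np.ndarray,
    y: np.ndarray,
    trim: float = DEFAULT_TRIM,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
) -> RobustTestResult:
    """Bootstrap Yuen test for two independent trimmed means.

    The null distribution resamples each group after centering at its own
    trimmed mean; p is two-sided (proportion of |T*| >= |T|, with +1
    smoothing). The CI is the percentile interval of the bootstrapped
    trimmed-mean difference on the uncentered data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    gx, gy = _check_trim(x.size, trim), _check_trim(y.size, trim)
    if x.size - 2 * gx < 2 or y.size - 2 * gy < 2:
        raise ValueError("groups too small after trimming")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        same = trimmed_mean(x, trim) == trimmed_mean(y, trim)
        d = trimmed_mean(x, trim) - trimmed_mean(y, trim)
        return RobustTestResult(
            statistic=0.0 if same else np.inf,
            p_value=1.0 if same else 1.0 / (n_boot + 1),
            ci_low=d, ci_high=d, trim=trim, n_boot=n_boot, seed=seed,
            degenerate=True,
        )
    t_obs = float(_yuen_t(np.sort(x)[None, :], np.sort(y)[None, :], gx, gy)[0])
    rng = np.random.default_rng(seed)
    xc = x - trimmed_mean(x, trim)
    yc = y - trimmed_mean(y, trim)
    ix = _boot_idx(rng, n_boot, x.size)
    iy = _boot_idx(rng, n_boot, y.size)
    xs = np.sort(xc[ix], axis=-1)
    ys = np.sort(yc[iy], axis=-1)
    t_star = _yuen_t(xs, ys, gx, gy)
    p = (1 + np.count_nonzero(np.abs(t_star) >= abs(t_obs))) / (1 + n_boot)
    diffs = _tm_rows(np.sort(x[ix], axis=-1), gx) - _tm_rows(
        np.sort(y[iy], axis=-1), gy
    )
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return RobustTestResult(
        statistic=t_obs, p_value=float(p), ci_low=float(lo), ci_high=float(hi),
        trim=trim, n_boot=n_boot, seed=seed,
    )


def yuen_paired(
    x: np.ndarray,
    y: np.ndarray,
    trim: float = DEFAULT_TRIM,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
) -> RobustTestResult:
    """Bootstrap Yuen test for paired samples, on difference scores.

    The paired statistic is the one-sample Yuen statistic of d = x - y:
    trimmed mean of d over the SE of the trimmed mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    d = x - y
    g = _check_trim(d.size, trim)
    if d.size - 2 * g < 2:
        raise ValueError("sample too small after trimming")
    if np.ptp(d) == 0:
        null = d[0] == 0
        return RobustTestResult(
            statistic=0.0 if null else np.inf,
            p_value=1.0 if null else 1.0 / (n_boot + 1),
            ci_low=float(d[0]), ci_high=float(d[0]),
            trim=trim, n_boot=n_boot, seed=seed, degenerate=True,
        )
    ds = np.sort(d)[None, :]
    t_obs = float(_tm_rows(ds, g)[0] / np.sqrt(_trimmed_se2(ds, g)[0]))
    rng = np.random.default_rng(seed)
    dc = d - trimmed_mean(d, trim)
    idx = _boot_idx(rng, n_boot, d.size)
    dsb = np.sort(dc[idx], axis=-1)
    t_star = _tm_rows(dsb, g) / np.sqrt(_trimmed_se2(dsb, g))
    p = (1 + np.count_nonzero(np.abs(t_star) >= abs(t_obs))) / (1 + n_boot)
    tms = _tm_rows(np.sort(d[idx], axis=-1), g)
    lo, hi = np.percentile(tms, [2.5, 97.5])
    return RobustTestResult(
        statistic=t_obs, p_value=float(p), ci_low=float(lo), ci_high=float(hi),
        trim=trim, n_boot=n_boot, seed=seed,
    )


def _t1way_stat(groups_sorted: list[np.ndarray], gs: list[int]) -> np.ndarray:
    """Heteroscedastic trimmed-means one-way statistic, vectorized over rows."""
    J = len(groups_sorted)
    d = [_trimmed_se2(gr, g) for gr, g in zip(groups_sorted, gs)]
    w = [1.0 / di for di in d]
    tm = [_tm_rows(gr, g) for gr, g in zip(groups_sorted, gs)]
    U = sum(w)
    xbar = sum(wi * ti for wi, ti in zip(w, tm)) / U
    A = sum(wi * (ti - xbar) ** 2 for wi, ti in zip(w, tm)) / (J - 1)
    hs = [gr.shape[-1] - 2 * g for gr, g in zip(groups_sorted, gs)]
    B = (
        2.0
        * (J - 2)
        / (J**2 - 1)
        * sum((1 - wi / U) ** 2 / (h - 1) for wi, h in zip(w, hs))
    )
    return A / (1.0 + B)


def t1way_boot(
    groups: list[np.ndarray],
    trim: float = DEFAULT_TRIM,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
    posthoc: bool = False,
):
    """Bootstrapped heteroscedastic one-way ANOVA for trimmed means.

    Groups are centered at their trimmed means, resampled ``n_boot`` times,
    and the observed statistic is compared against the bootstrap null
    (one-sided, F-like). With ``posthoc=True`` a dict of pairwise
    trimmed-mean contrasts with percentile-bootstrap CIs is also returned.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    gs = [_check_trim(g.size, trim) for g in groups]
    for g, gi in zip(groups, gs):
        if g.size - 2 * gi < 2:
            raise ValueError("a group is too small after trimming")
    if all(np.ptp(g) == 0 for g in groups):
        tms = [trimmed_mean(g, trim) for g in groups]
        equal = len(set(tms)) == 1
        res = RobustTestResult(
            statistic=0.0 if equal else np.inf,
            p_value=1.0 if equal else 1.0 / (n_boot + 1),
            ci_low=np.nan, ci_high=np.nan,
            trim=trim, n_boot=n_boot, seed=seed, degenerate=True,
        )
        return (res, {}) if posthoc else res
    f_obs = float(
        _t1way_stat([np.sort(g)[None, :] for g in groups], gs)[0]
    )
    rng = np.random.default_rng(seed)
    centered = [g - trimmed_mean(g, trim) for g in groups]
    idxs = [_boot_idx(rng, n_boot, g.size) for g in groups]
    sorted_boot = [np.sort(c[i], axis=-1) for c, i in zip(centered, idxs)]
    f_star = _t1way_stat(sorted_boot, gs)
    p = (1 + np.count_nonzero(f_star >= f_obs)) / (1 + n_boot)
    res = RobustTestResult(
        statistic=f_obs, p_value=float(p), ci_low=np.nan, ci_high=np.nan,
        trim=trim, n_boot=n_boot, seed=seed,
    )
    if not posthoc:
        return res
    contrasts = {}
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            da = _tm_rows(np.sort(groups[a][idxs[a]], axis=-1), gs[a])
            db = _tm_rows(np.sort(groups[b][idxs[b]], axis=-1), gs[b])
            lo, hi = np.percentile(da - db, [2.5, 97.5])
            contrasts[(a, b)] = {
                "difference": trimmed_mean(groups[a], trim)
                - trimmed_mean(groups[b], trim),
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
    return res, contrasts


def discrimination_ratio(t_novel: float, t_other: float) -> float:
    """(novel - familiar) / (novel + familiar) interaction time.

    The same formula serves single-interaction-time ratios. Undefined when
    no interaction occurred at all.
    """
    if t_novel < 0 or t_other < 0:
        raise ValueError("interaction times must be non-negative")
    total = t_novel + t_other
    if total == 0:
        raise ValueError("discrimination ratio undefined: zero interaction")
    return (t_novel - t_other) / total
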