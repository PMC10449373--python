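"""Local similarity analysis for microbial time series.

Local similarity (LS) captures associations between two series that may hold
only over a subinterval and may be offset by a bounded time delay.  After
rank-based normal-score normalization ("percentileZ"), the LS score of series
``x`` and ``y`` with delay limit ``D`` is

    LS = (1/n) * max over aligned windows (|start_x - start_y| <= D)
         of | sum_k  x[start_x + k] * y[start_y + k] |

computed exactly by a dynamic program over the ``2D+1`` alignment diagonals.
Significance is assessed by permuting the time order of one series (add-one
permutation p), and a shifted Spearman rank correlation (SSCC) at the
LS-optimal delay provides the matching *global* association measure.  Across
all pairs of a series set, Benjamini–Hochberg FDR control is applied
separately to the LS and SSCC p-value families; an association is kept only
when both the raw p and the q-value clear the significance level for at
least one family.

Delay convention: the stored delay is ``d = start_x - start_y``; ``d = +1``
means ``x`` lags ``y`` (the best alignment matches ``x`` at time ``t``
against ``y`` at time ``t-1``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata, spearmanr
from statsmodels.stats.multitest import multipletests

from .tables import OtuTable

EDGE_COLUMNS = [
    "otu_a",
    "otu_b",
    "ls_score",
    "sign",
    "delay",
    "start_a",
    "start_b",
    "length",
    "ls_p",
    "ls_q",
    "sscc",
    "sscc_p",
    "sscc_q",
    "edge_type",
    "network",
    "significant",
    "n_interpolated",
]


# ---------------------------------------------------------------------------
# Normalization and gap handling
# ---------------------------------------------------------------------------

def percentile_z(series) -> np.ndarray:
    """Rank-based normal-score transform: z_i = Phi^-1(rank_i / (n + 1)).

    Ties receive averaged ranks; the transform is order preserving.  A
    constant series maps to all zeros with a warning (such series carry no
    association signal and are excluded from testing upstream).
    """
    s = np.asarray(series, dtype=float)
    n = len(s)
    if n < 3:
        raise ValueError("need at least three points to normalize")
    if np.ptp(s) == 0:
        warnings.warn("constant series normalizes to all zeros")
        return np.zeros(n)
    ranks = rankdata(s, method="average")
    return norm.ppf(ranks / (n + 1))


def interpolate_missing(series, mask) -> np.ndarray:
    """Fill missing time points: linear interior, nearest at the ends.

    ``mask`` is True where the point is missing.  At least two observed
    points are required.
    """
    s = np.asarray(series, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != s.shape:
        raise ValueError("mask shape mismatch")
    obs = np.nonzero(~mask)[0]
    if len(obs) < 2:
        raise ValueError("need at least two observed points to interpolate")
    t = np.arange(len(s))
    out = s.copy()
    # np.interp is linear inside and clamps to the boundary values outside
    out[mask] = np.interp(t[mask], obs, s[obs])
    return out


# ---------------------------------------------------------------------------
# Local similarity dynamic program
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LSResult:
    """Optimal local alignment of two normalized series.

    ``score`` is the non-negative LS magnitude; ``sign`` is +1 if the optimum
    came from the positive (co-varying) accumulation and -1 from the negative
    one.  ``delay = start_x - start_y``; ``start_x``/``start_y`` are 0-based
    window starts and ``length`` the window length.
    """

    score: float
    sign: int
    delay: int
    start_x: int
    start_y: int
    length: int

    @property
    def signed_score(self) -> float:
        return self.sign * self.score


def local_similarity(x, y, D: int = 1) -> LSResult:
    """Exact LS via dynamic programming over alignment diagonals.

    For each delay ``d`` with ``|d| <= D`` the products ``x[j+d] * y[j]``
    along the diagonal are scanned with a clamped running sum (the classic
    max-subarray-with-reset recurrence), once for positive and once for
    negative accumulation.  Ties are broken toward the smallest ``|d|``, then
    positive sign, then the earliest window start, so a synchronous reading
    is preferred whenever scores tie.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series differ in length")
    n = len(x)
    if n == 0:
        raise ValueError("empty series")
    best = None  # (score, sign, d, start_x, start_y, length)
    for d in sorted(range(-D, D + 1), key=lambda v: (abs(v), v)):
        i0 = max(0, d)
        i1 = (n - 1) + min(0, d)
        if i1 < i0:
            continue
        prods = x[i0 : i1 + 1] * y[i0 - d : i1 - d + 1]
        for sign, p in ((1, prods), (-1, -prods)):
            s = 0.0
            seg_start = 0
            for k, pk in enumerate(p):
                s = s + pk
                if s <= 0.0:
                    s = 0.0
                    seg_start = k + 1
                    continue
                if best is None or s > best[0] + 1e-12:
                    best = (s, sign, d, i0 + seg_start, i0 - d + seg_start, k - seg_start + 1)
    if best is None:
        return LSResult(0.0, 1, 0, 0, 0, 1)
    score, sign, d, sx, sy, length = best
    return LSResult(score / n, sign, d, sx, sy, length)


def local_similarity_batch(x, Y, D: int = 1) -> np.ndarray:
    """|LS| magnitudes of ``x`` against each row of ``Y`` (vectorized DP).

    Used for permutation null distributions, where only the magnitude
    matters; returns an array of length ``Y.shape[0]``.
    """
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = len(x)
    best = np.zeros(Y.shape[0])
    for d in range(-D, D + 1):
        i0 = max(0, d)
        i1 = (n - 1) + min(0, d)
        if i1 < i0:
            continue
        P = x[i0 : i1 + 1][None, :] * Y[:, i0 - d : i1 - d + 1]
        sp = np.zeros(Y.shape[0])
        sn = np.zeros(Y.shape[0])
        for k in range(P.shape[1]):
            sp = np.maximum(sp + P[:, k], 0.0)
            sn = np.maximum(sn - P[:, k], 0.0)
            np.maximum(best, sp, out=best)
            np.maximum(best, sn, out=best)
    return best / n


def permutation_pvalue(x, y, D: int = 1, n_perm: int = 1000, seed: int = 0) -> float:
    """Permutation p-value for the LS magnitude (add-one rule).

    The time order of ``y`` is shuffled ``n_perm`` times and the LS magnitude
    recomputed; ``p = (1 + #{|LS_perm| >= |LS_obs|}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    obs = local_similarity(x, y, D).score
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    perms = rng.permuted(np.tile(np.arange(len(y)), (n_perm, 1)), axis=1)
    null = local_similarity_batch(x, y[perms], D)
    return float((1 + int((null >= obs - 1e-12).sum())) / (1 + n_perm))


# ---------------------------------------------------------------------------
# Shifted Spearman (global association)
# ---------------------------------------------------------------------------

def _aligned(x, y, d):
    """Overlapping points when x is shifted against y by d = start_x - start_y."""
    n = len(x)
    if d >= 0:
        return x[d:], y[: n - d]
    return x[: n + d], y[-d:]


def spearman_shifted(x, y, d: int = 0, n_perm: int = 1000, seed: int = 0):
    """Spearman rank correlation at a fixed alignment delay, permutation p.

    The overlap after shifting must contain at least five points.  The
    p-value permutes the time order of ``y`` (re-aligning and re-ranking the
    overlap each time) with the add-one rule on ``|rho|``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series differ in length")
    n = len(x)
    if n - abs(d) < 5:
        raise ValueError("overlap shorter than five points")
    xa, ya = _aligned(x, y, d)
    rho = spearmanr(xa, ya).statistic
    if not np.isfinite(rho):
        rho = 0.0
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    Yp = y[perms]
    Ya = Yp[:, : n - d] if d >= 0 else Yp[:, -d:]
    rx = rankdata(xa)
    rx = rx - rx.mean()
    RY = rankdata(Ya, axis=1)
    RY = RY - RY.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(rx) * np.linalg.norm(RY, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        null = np.where(denom > 0, RY @ rx / denom, 0.0)
    p = (1 + int((np.abs(null) >= abs(rho) - 1e-12).sum())) / (1 + n_perm)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# Series sets and the pairwise association table
# ---------------------------------------------------------------------------

@dataclass
class TimeSeriesSet:
    """Normalized OTU series over a common time grid.

    ``X`` is OTUs x T (percentileZ-normalized, gaps filled); ``mask`` flags
    originally-missing time points; ``n_interpolated`` counts them per
    series.  Only series with at least six observed points and non-constant
    values are eligible for association testing.
    """

    otu_ids: list
    X: np.ndarray
    mask: np.ndarray  # True where the time point was missing (filled)
    normalization: str = "percentileZ"
    n_interpolated: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not np.isfinite(self.X).all():
            raise ValueError("non-finite normalized values")
        if self.n_interpolated is None:
            self.n_interpolated = np.broadcast_to(
                self.mask.sum(), (len(self.otu_ids),)
            ).copy() if self.mask.ndim == 1 else self.mask.sum(axis=1)

    @property
    def n_times(self) -> int:
        return self.X.shape[1]


def prepare_timeseries(
    table: OtuTable,
    times,
    full_times=None,
    fill: str = "linear",
    min_observed: int = 6,
) -> TimeSeriesSet:
    """Build normalized per-OTU series from one lake's table.

    ``times`` are the time indices of the table rows (present samples, in
    order); ``full_times`` the complete sampling grid (defaults to the
    observed range).  Gaps are filled (``fill`` in none/zero/linear/nearest)
    *before* percentileZ normalization; constant series and series with
    fewer than ``min_observed`` collected points are dropped with a warning.
    """
    times = list(times)
    full_times = list(full_times) if full_times is not None else list(
        range(min(times), max(times) + 1)
    )
    pos = {t: k for k, t in enumerate(full_times)}
    T = len(full_times)
    mask = np.ones(T, dtype=bool)
    for t in times:
        mask[pos[t]] = False
    frac = table.counts / table.counts.sum(axis=1, keepdims=True)
    keep_ids, rows = [], []
    n_obs = len(times)
    for k, otu in enumerate(table.otu_ids):
        series = np.full(T, np.nan)
        series[~mask] = frac[:, k]
        if n_obs < min_observed:
            warnings.warn(f"{otu}: fewer than {min_observed} observed points; dropped")
            continue
        if np.ptp(frac[:, k]) == 0:
            warnings.warn(f"{otu}: constant series; dropped")
            continue
        if mask.any():
            if fill == "linear":
                series = interpolate_missing(series, mask)
            elif fill == "nearest":
                obs = np.nonzero(~mask)[0]
                idx = obs[np.argmin(np.abs(obs[:, None] - np.arange(T)[None, :]), axis=0)]
                series = series[idx]
            elif fill == "zero":
                series[mask] = 0.0
            elif fill == "none":
                raise ValueError("series has gaps but fill='none'")
            else:
                raise ValueError(f"unknown fill method {fill!r}")
        keep_ids.append(otu)
        rows.append(percentile_z(series))
    if not rows:
        raise ValueError("no eligible series")
    X = np.vstack(rows)
    return TimeSeriesSet(
        otu_ids=keep_ids,
        X=X,
        mask=mask,
        normalization="percentileZ",
        n_interpolated=np.full(len(keep_ids), int(mask.sum())),
    )


def pairwise_associations(
    ts: TimeSeriesSet,
    D: int = 1,
    alpha: float = 0.01,
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Test every unordered pair of series; FDR-controlled edge calls.

    For each pair the LS optimum (score, sign, delay, window) and its
    permutation p are computed, then the shifted Spearman correlation at the
    LS-optimal delay with its own permutation p.  Benjamini–Hochberg
    q-values are computed separately for the LS and SSCC families.  An edge
    is significant when raw p < alpha AND q < alpha in at least one family;
    ``edge_type`` is SSCC when the global family passes (a global
    association subsumes the local one), else LS; ``network`` is synchronous
    at delay 0 and time_shifted otherwise.
    """
    k = len(ts.otu_ids)
    if k < 2:
        raise ValueError("need at least two eligible series")
    n = ts.n_times
    rows = []
    for i, j in combinations(range(k), 2):
        x, y = ts.X[i], ts.X[j]
        pair_seed = np.random.SeedSequence([seed, i, j])
        s1, s2 = pair_seed.spawn(2)
        res = local_similarity(x, y, D)
        rng = np.random.default_rng(s1)
        perms = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
        null = local_similarity_batch(x, y[perms], D)
        ls_p = (1 + int((null >= res.score - 1e-12).sum())) / (1 + n_perm)
        rho, sscc_p = spearman_shifted(
            x, y, res.delay, n_perm=n_perm, seed=s2
        )
        rows.append(
            {
                "otu_a": ts.otu_ids[i],
                "otu_b": ts.otu_ids[j],
                "ls_score": res.score,
                "sign": res.sign,
                "delay": res.delay,
                "start_a": res.start_x,
                "start_b": res.start_y,
                "length": res.length,
                "ls_p": ls_p,
                "sscc": rho,
                "sscc_p": sscc_p,
                "n_interpolated": int(ts.n_interpolated[i] + ts.n_interpolated[j]),
            }
        )
    df = pd.DataFrame(rows)
    df["ls_q"] = multipletests(df["ls_p"], method="fdr_bh")[1]
    df["sscc_q"] = multipletests(df["sscc_p"], method="fdr_bh")[1]
    ls_pass = (df["ls_p"] < alpha) & (df["ls_q"] < alpha)
    sscc_pass = (df["sscc_p"] < alpha) & (df["sscc_q"] < alpha)
    df["significant"] = ls_pass | sscc_pass
    df["edge_type"] = np.where(sscc_pass, "SSCC", "LS")
    df["network"] = np.where(df["delay"] == 0, "synchronous", "time_shifted")
    return df[EDGE_COLUMNS]


def significant_edges(df: pd.DataFrame) -> pd.DataFrame:
    return df.loc[df["significant"]].reset_index(drop=True)
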