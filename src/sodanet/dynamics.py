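"""Dissimilarity-based community dynamics statistics.

Bray–Curtis dissimilarity, consecutive-sample turnover, time distance decay,
distance-based permutational ANOVA (one- and two-way, sequential sums of
squares on Gower-centred squared distances), Mantel correlation, a Pearson
collinearity screen for environmental variables, and a permutation
group-comparison test.

All permutation procedures follow the add-one rule
``p = (1 + #{stat_perm >= stat_obs}) / (1 + n_perm)`` and are reproducible
from an integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from .tables import OtuTable


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def bray_curtis(u, v) -> float:
    """Bray–Curtis dissimilarity sum|u-v| / sum(u+v), in [0, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors differ in length")
    if (u < 0).any() or (v < 0).any():
        raise ValueError("negative abundances")
    denom = (u + v).sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.abs(u - v).sum() / denom)


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarity matrix with ids."""

    ids: list
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)

    def submatrix(self, ids) -> "DistanceMatrix":
        pos = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.d[np.ix_(pos, pos)])


def bc_matrix(table: OtuTable) -> DistanceMatrix:
    """All pairwise Bray–Curtis dissimilarities between samples."""
    d = squareform(pdist(table.counts, metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, d)


# ---------------------------------------------------------------------------
# Turnover and distance decay
# ---------------------------------------------------------------------------

def turnover_series(table: OtuTable, times) -> pd.DataFrame:
    """Bray–Curtis between consecutive *present* samples of one lake.

    ``times`` gives the time index of each table row (rows must already be in
    time order and contain only collected samples).  Dry dates simply do not
    appear, so a consecutive pair may span a desiccation gap — the turnover
    proxy then measures the cross-gap community change.
    """
    times = list(times)
    if len(times) != len(table.sample_ids):
        raise ValueError("times must match table rows")
    if len(times) < 2:
        raise ValueError("need at least two present samples")
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("times must be strictly increasing")
    counts = table.counts
    rows = [
        {"t1": times[i], "t2": times[i + 1], "bc": bray_curtis(counts[i], counts[i + 1])}
        for i in range(len(times) - 1)
    ]
    return pd.DataFrame(rows, columns=["t1", "t2", "bc"])


def distance_decay(table: OtuTable, times) -> dict:
    """Within-lake pairwise Bray–Curtis grouped by time lag |Δt|."""
    times = list(times)
    if len(times) < 3:
        raise ValueError("need at least three present samples")
    counts = table.counts
    out: dict[int, list[float]] = {}
    for i in range(len(times)):
        for j in range(i + 1, len(times)):
            lag = abs(times[j] - times[i])
            out.setdefault(lag, []).append(bray_curtis(counts[i], counts[j]))
    return dict(sorted(out.items()))


def decay_frame(decay: dict) -> pd.DataFrame:
    rows = [{"lag": lag, "bc": v} for lag, vals in decay.items() for v in vals]
    return pd.DataFrame(rows, columns=["lag", "bc"])


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    """Sequential-term permutational ANOVA table."""

    terms: list  # dicts: term, df, ss, pseudo_f, r2, p
    total_ss: float
    residual_ss: float
    residual_df: int
    n_perm: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.terms)
        resid = {
            "term": "Residual",
            "df": self.residual_df,
            "ss": self.residual_ss,
            "pseudo_f": np.nan,
            "r2": self.residual_ss / self.total_ss,
            "p": np.nan,
        }
        return pd.concat([df, pd.DataFrame([resid])], ignore_index=True)


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _dummy(labels) -> np.ndarray:
    labels = pd.Categorical(labels)
    return pd.get_dummies(labels, drop_first=False).to_numpy(dtype=float)


def _hat(x: np.ndarray) -> np.ndarray:
    # projection via pseudo-inverse; tolerates rank-deficient dummy coding
    return x @ np.linalg.pinv(x)


def permanova(
    d: DistanceMatrix,
    factors,
    n_perm: int = 999,
    seed: int = 0,
    interaction: bool = True,
) -> PermanovaResult:
    """Distance-based permutational multivariate ANOVA (adonis-style).

    ``factors`` is a mapping ``name -> labels`` (one or two factors, in the
    order the sequential decomposition should use).  With two factors and
    ``interaction=True`` an A×B term is added.  Total sum of squares is
    obtained by Gower-centring the squared distances; term sums of squares
    are sequential (Type I) differences of projection traces; significance is
    assessed by permuting samples (rows and columns of the distance matrix
    simultaneously).
    """
    names = list(factors)
    if not 1 <= len(names) <= 2:
        raise ValueError("one or two factors required")
    n = len(d.ids)
    labels = {k: np.asarray(list(factors[k])) for k in names}
    for k, lab in labels.items():
        if len(lab) != n:
            raise ValueError(f"factor {k!r} length mismatch")
        levels, counts = np.unique(lab, return_counts=True)
        if len(levels) < 2:
            raise ValueError(f"factor {k!r} has a single level")
        if (counts < 2).any():
            raise ValueError(f"factor {k!r} has a level with fewer than 2 samples")

    g = _gower_center(d.d)
    total_ss = float(np.trace(g))

    # sequential model matrices
    blocks = [np.ones((n, 1))]
    term_names = []
    for k in names:
        blocks.append(_dummy(labels[k]))
        term_names.append(k)
    if len(names) == 2 and interaction:
        inter = [f"{a}\x1f{b}" for a, b in zip(labels[names[0]], labels[names[1]])]
        if len(set(inter)) > len(set(labels[names[0]])) and len(set(inter)) > len(
            set(labels[names[1]])
        ):
            blocks.append(_dummy(inter))
            term_names.append(f"{names[0]}:{names[1]}")

    hats, ranks = [], []
    x = np.empty((n, 0))
    for b in blocks:
        x = np.hstack([x, b])
        hats.append(_hat(x))
        ranks.append(np.linalg.matrix_rank(x))
    resid_df = n - ranks[-1]
    if resid_df <= 0:
        raise ValueError("no residual degrees of freedom")

    # tr(H G) = sum(H * G) for symmetric H, so permutation loops avoid matmuls
    hat_diffs = [hats[k] - hats[k - 1] for k in range(1, len(hats))]
    resid_proj = np.eye(n) - hats[-1]

    def term_stats(gmat):
        ss, fs = [], []
        resid_ss = float((resid_proj * gmat).sum())
        ms_res = resid_ss / resid_df
        for k, hd in enumerate(hat_diffs):
            ss_k = float((hd * gmat).sum())
            df_k = ranks[k + 1] - ranks[k]
            ss.append((ss_k, df_k))
            fs.append((ss_k / df_k) / ms_res if ms_res > 0 else np.inf)
        return ss, fs, resid_ss

    ss_obs, f_obs, resid_ss = term_stats(g)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(term_names), dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        _, f_perm, _ = term_stats(gp)
        exceed += np.asarray(f_perm) >= np.asarray(f_obs) - 1e-12
    pvals = (1 + exceed) / (1 + n_perm)

    terms = [
        {
            "term": term_names[i],
            "df": ss_obs[i][1],
            "ss": ss_obs[i][0],
            "pseudo_f": f_obs[i],
            "r2": ss_obs[i][0] / total_ss,
            "p": float(pvals[i]),
        }
        for i in range(len(term_names))
    ]
    return PermanovaResult(
        terms=terms,
        total_ss=total_ss,
        residual_ss=resid_ss,
        residual_df=resid_df,
        n_perm=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Mantel, collinearity, group comparison
# ---------------------------------------------------------------------------

def mantel(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999, seed: int = 0):
    """Mantel correlation between two distance matrices over the same ids.

    Pearson r of the upper triangles; p by permuting the ids of the second
    matrix (add-one rule).
    """
    if d1.ids != d2.ids:
        raise ValueError("distance matrices must share ids and order")
    x = d1.condensed()
    y = d2.condensed()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant distance matrix: correlation undefined")
    r_obs = pearsonr(x, y).statistic
    n = len(d1.ids)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = squareform(d2.d[np.ix_(perm, perm)], checks=False)
        if abs(pearsonr(x, yp).statistic) >= abs(r_obs) - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return float(r_obs), float(p)


def collinearity_screen(env: pd.DataFrame, threshold: float = 0.7) -> list:
    """Flag variable pairs with |Pearson r| strictly above ``threshold``.

    ``env`` holds one column per environmental variable (samples as rows);
    correlations use pairwise-complete observations.  Constant variables are
    excluded with a warning.
    """
    keep = []
    for col in env.columns:
        vals = env[col].dropna()
        if vals.nunique() <= 1:
            warnings.warn(f"variable {col!r} is constant; excluded from screen")
        else:
            keep.append(col)
    corr = env[keep].corr(method="pearson")
    flagged = []
    for i, a in enumerate(keep):
        for b in keep[i + 1 :]:
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) > threshold:
                flagged.append((a, b, float(r)))
    return flagged


def compare_groups(values, labels, n_perm: int = 9999, seed: int = 0) -> float:
    """Two-sided permutation test for a difference of group means.

    The observed |mean(group1) - mean(group2)| is compared against the
    permutation distribution obtained by shuffling group labels; the add-one
    rule keeps p strictly positive.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    m1 = labels == groups[0]
    if m1.sum() < 2 or (~m1).sum() < 2:
        raise ValueError("each group needs at least two values")
    obs = abs(values[m1].mean() - values[~m1].mean())
    n1 = int(m1.sum())
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(values))
        v1 = values[perm[:n1]]
        v2 = values[perm[n1:]]
        if abs(v1.mean() - v2.mean()) >= obs - 1e-12:
            exceed += 1
    return float((1 + exceed) / (1 + n_perm))
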