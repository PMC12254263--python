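"""Community-level temporal analyses.

Pairwise Bray-Curtis similarity between samples, its decay/recurrence as a
function of time lag (binned at the ~monthly 30.5-day sampling interval,
where annually repeating communities show local similarity maxima at 12,
24, ... month lags), Mantel tests between community and environmental
distance matrices, and Spearman correlations of per-module summed
abundances against environmental parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import AbundanceMatrix

__all__ = ["TimeDecay", "bray_curtis", "time_decay", "mantel_test",
           "module_env_spearman", "significance_stars"]


@dataclass
class TimeDecay:
    pair_lags: np.ndarray          # days between the two samples of each pair
    pair_similarities: np.ndarray  # NaN-free; undefined pairs excluded
    pair_bins: np.ndarray          # bin index of each pair
    bin_centers: np.ndarray        # (k + 0.5) * width for non-empty bins
    bin_means: np.ndarray
    bin_width: float


def _as_matrix(matrix) -> tuple[np.ndarray, list]:
    if isinstance(matrix, AbundanceMatrix):
        return matrix.values.to_numpy(dtype=float), list(matrix.values.columns)
    df = pd.DataFrame(matrix)
    return df.to_numpy(dtype=float), list(df.columns)


def bray_curtis(matrix, min_detect: float = 0.0) -> pd.DataFrame:
    """Pairwise Bray-Curtis *similarity* between sample columns.

    Values below ``min_detect`` are zeroed first (detection-threshold
    sensitivity analysis).  similarity = 1 - sum|x-y| / sum(x+y); the
    diagonal is 1.  A pair where both samples are entirely zero has an
    undefined similarity and is returned as NaN, to be excluded downstream
    rather than conflated with true dissimilarity.
    """
    x, samples = _as_matrix(matrix)
    if x.shape[1] < 2:
        raise ValueError("need at least two samples")
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    x = np.where(x >= min_detect, x, 0.0) if min_detect > 0 else x
    # |xi - yi| summed, vectorized over pairs
    diff = np.abs(x[:, :, None] - x[:, None, :]).sum(axis=0)
    tot = (x[:, :, None] + x[:, None, :]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = 1.0 - diff / tot
    sim[tot == 0] = np.nan
    np.fill_diagonal(sim, 1.0)
    # all-zero sample: even its self-similarity is undefined
    zero_col = x.sum(axis=0) == 0
    for i in np.flatnonzero(zero_col):
        sim[i, i] = np.nan
    return pd.DataFrame(sim, index=samples, columns=samples)


def time_decay(sim: pd.DataFrame, dates, bin_width: float = 30.5) -> TimeDecay:
    """Bin pairwise similarities by the time lag between their samples.

    Bin k covers lags in [k*w, (k+1)*w); the bin mean is the arithmetic
    mean of pair similarities.  Self-pairs (lag 0 from i == j) are
    excluded, as are pairs whose similarity is undefined (NaN).  Empty
    bins are absent from the output, not reported as 0.
    """
    dates = np.asarray(dates, dtype=float)
    s = sim.to_numpy(dtype=float)
    if s.shape[0] != s.shape[1] or s.shape[0] != dates.size:
        raise ValueError("dates must align with the similarity matrix")
    iu, ju = np.triu_indices(s.shape[0], k=1)
    lags = np.abs(dates[iu] - dates[ju])
    vals = s[iu, ju]
    keep = ~np.isnan(vals)
    lags, vals = lags[keep], vals[keep]
    bins = np.floor(lags / bin_width).astype(int)
    uniq = np.unique(bins)
    means = np.array([vals[bins == k].mean() for k in uniq])
    return TimeDecay(
        pair_lags=lags,
        pair_similarities=vals,
        pair_bins=bins,
        bin_centers=(uniq + 0.5) * bin_width,
        bin_means=means,
        bin_width=bin_width,
    )


def _check_dist(d: np.ndarray, name: str) -> None:
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"{name} must be square")
    if d.shape[0] < 3:
        raise ValueError(f"{name} must be at least 3 x 3")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError(f"{name} must have a zero diagonal")


def mantel_test(
    dist_a,
    dist_b,
    method: str = "spearman",
    permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel test between two distance matrices.

    The statistic is the (Pearson or Spearman) correlation of the strictly
    lower-triangular entries; the null permutes rows and columns of the
    second matrix simultaneously.  p = (#{permuted >= observed} + 1) /
    (permutations + 1), ties counted conservatively.  A zero-variance
    triangle yields (nan, 1.0).
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    _check_dist(a, "dist_a")
    _check_dist(b, "dist_b")
    if a.shape != b.shape:
        raise ValueError("distance matrices must have the same dimension")
    n = a.shape[0]
    il, jl = np.tril_indices(n, k=-1)
    va = a[il, jl]
    vb = b[il, jl]
    if va.std() == 0 or vb.std() == 0:
        return float("nan"), 1.0
    if method == "pearson":
        ra, rb = va, vb
    elif method == "spearman":
        ra, rb = stats.rankdata(va), stats.rankdata(vb)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    ra = (ra - ra.mean()) / ra.std()

    def corr(v: np.ndarray) -> float:
        if method == "spearman":
            v = stats.rankdata(v)
        sd = v.std()
        if sd == 0:
            return np.nan
        return float(np.mean(ra * (v - v.mean())) / sd)

    observed = corr(vb)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        p = rng.permutation(n)
        perm = b[np.ix_(p, p)][il, jl]
        r = corr(perm)
        if not np.isnan(r) and r >= observed:
            count += 1
    return observed, (count + 1) / (permutations + 1)


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def module_env_spearman(
    module_abundance: pd.DataFrame, env: pd.DataFrame
) -> pd.DataFrame:
    """Spearman rho of each module's summed abundance vs each parameter.

    ``module_abundance`` is modules x samples; ``env`` is indexed by
    sample_id with one column per environmental parameter.  Two-sided p
    from the t approximation with mid-ranked ties; constant series yield
    NaN.  Requires at least five shared samples.
    """
    env = env.set_index("sample_id") if "sample_id" in env.columns else env
    shared = [s for s in module_abundance.columns if s in env.index]
    if len(shared) < 5:
        raise ValueError("need at least 5 shared samples")
    num_env = env.loc[shared].select_dtypes("number")
    rows = []
    for mod, series in module_abundance[shared].iterrows():
        for param in num_env.columns:
            y = num_env[param].to_numpy(dtype=float)
            xv = series.to_numpy(dtype=float)
            if np.std(xv) == 0 or np.std(y) == 0:
                rho, p = float("nan"), float("nan")
            else:
                rho, p = stats.spearmanr(xv, y)
            rows.append(
                {"module": mod, "parameter": param, "rho": rho, "p": p,
                 "stars": significance_stars(p)}
            )
    return pd.DataFrame(rows)
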