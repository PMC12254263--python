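"""Virus-host association network inference from co-occurring time series.

Pipeline: abundance series are interpolated onto a regular grid and
low-pass filtered by keeping the first 16 Fourier coefficients; pairwise
Pearson correlations between the reconstructed temporal profiles form an
undirected graph (r > 0.7 after Benjamini-Hochberg correction); Louvain
community detection labels seasonal modules; Convergent Cross Mapping
adds direction to correlated virus-host pairs (a host "drives" a virus
when the virus's delay embedding cross-maps the host with skill that
converges as library size grows); Normalized Mutual Information with a
permutation null weights retained edges; and extended Local Similarity
Analysis scores time-lagged association on the raw series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .abundance import AbundanceMatrix

__all__ = [
    "TemporalProfile", "CCMResult", "DirectedNetwork",
    "fourier_profile", "profile_correlation_graph", "bh_adjust",
    "louvain_modules", "ccm_pair", "nmi_weight", "edge_significance",
    "elsa_pair", "build_ccm_network",
]


@dataclass
class TemporalProfile:
    entity_id: str
    grid_times: np.ndarray
    coefficients: np.ndarray   # 16 complex rfft coefficients (DC included)
    reconstruction: np.ndarray
    n_obs: int                 # original (pre-interpolation) observation count


@dataclass
class CCMResult:
    library_sizes: np.ndarray
    skills: np.ndarray
    convergent: bool
    embedding_dim: int
    lag_tau: int


@dataclass
class DirectedNetwork:
    nodes: pd.DataFrame            # node_id, kind (vOTU | ASV)
    undirected_edges: pd.DataFrame  # a, b, r, p, q
    directed_edges: pd.DataFrame   # source, target, skill, delta, nmi, p_perm
    modules: dict = field(default_factory=dict)


def fourier_profile(
    series,
    dates,
    grid_step: float = 30.5,
    n_coeff: int = 16,
    entity_id: str = "",
) -> TemporalProfile:
    """Truncated-Fourier temporal profile of one abundance series.

    The series is linearly interpolated onto a regular grid spanning the
    observation window, transformed with the real-input FFT, and all
    coefficients above index ``n_coeff - 1`` are zeroed (DC retained); the
    reconstruction is the inverse transform.  Acts as a low-pass filter
    that keeps up to ``n_coeff - 1`` annual-scale harmonics of the window.
    """
    series = np.asarray(series, dtype=float)
    dates = np.asarray(dates, dtype=float)
    if series.size != dates.size:
        raise ValueError("series and dates must align")
    if series.size < 4:
        raise ValueError("need at least 4 observations")
    if not np.all(np.isfinite(series)):
        raise ValueError("series must be finite")
    order = np.argsort(dates)
    dates, series = dates[order], series[order]
    n_grid = int(np.floor((dates[-1] - dates[0]) / grid_step)) + 1
    if n_grid < 2 * n_coeff:
        raise ValueError(
            f"grid of {n_grid} points cannot support {n_coeff} coefficients"
        )
    grid = dates[0] + grid_step * np.arange(n_grid)
    interp = np.interp(grid, dates, series)
    coeff = np.fft.rfft(interp)
    kept = coeff[:n_coeff].copy()
    truncated = np.zeros_like(coeff)
    truncated[:n_coeff] = kept
    recon = np.fft.irfft(truncated, n=n_grid)
    return TemporalProfile(entity_id, grid, kept, recon, n_obs=series.size)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def profile_correlation_graph(
    profiles: list[TemporalProfile],
    r_min: float = 0.7,
    bh_alpha: float = 0.05,
    n_obs: int | None = None,
) -> pd.DataFrame:
    """Undirected co-occurrence edges between temporal profiles.

    Pearson r between reconstructions; two-sided p from the t distribution
    with df = n_obs - 2, where n_obs is the original observation count
    (grid interpolation manufactures no information); BH across all
    evaluated pairs; an edge is retained iff r > r_min (positive only) and
    q <= bh_alpha.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    lens = {p.reconstruction.size for p in profiles}
    if len(lens) != 1:
        raise ValueError("profiles must share a common grid")
    x = np.vstack([p.reconstruction for p in profiles])
    ids = [p.entity_id for p in profiles]
    if n_obs is None:
        n_obs = min(p.n_obs for p in profiles)
    sd = x.std(axis=1)
    ok = sd > 0
    if not ok.all():
        warnings.warn(
            f"{(~ok).sum()} zero-variance profiles skipped", RuntimeWarning,
            stacklevel=2,
        )
    xi = np.flatnonzero(ok)
    if xi.size < 2:
        return pd.DataFrame(columns=["a", "b", "r", "p", "q"])
    r = np.corrcoef(x[xi])
    iu, ju = np.triu_indices(xi.size, k=1)
    rv = np.clip(r[iu, ju], -1.0, 1.0)
    df = n_obs - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rv * np.sqrt(df / (1.0 - rv**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(rv) >= 1.0, 0.0, p)
    q = bh_adjust(p)
    edges = pd.DataFrame(
        {
            "a": [ids[xi[i]] for i in iu],
            "b": [ids[xi[j]] for j in ju],
            "r": rv,
            "p": p,
            "q": q,
        }
    )
    return edges[(edges["r"] > r_min) & (edges["q"] <= bh_alpha)].reset_index(
        drop=True
    )


def louvain_modules(edges: pd.DataFrame, seed: int = 0,
                    resolution: float = 1.0, restarts: int = 8) -> dict:
    """Louvain community labels for a weighted undirected edge set.

    Greedy modularity optimization (local moving + aggregation).  The
    algorithm is restarted ``restarts`` times with seeds derived from
    ``seed`` and the highest-modularity partition is kept, making the
    result deterministic given the seed.  ``resolution`` < 1 favors
    coarser communities (sub-seasonal phase groups within one seasonal
    module are merged rather than split).
    """
    if len(edges) == 0:
        raise ValueError("empty graph")
    g = nx.Graph()
    for a, b, w in edges[["a", "b", "r"]].itertuples(index=False):
        if w <= 0:
            raise ValueError("edge weights must be positive")
        g.add_edge(a, b, weight=float(w))
    rng = np.random.default_rng(seed)
    best, best_q = None, -np.inf
    for _ in range(max(1, restarts)):
        comms = nx.community.louvain_communities(
            g, weight="weight", seed=int(rng.integers(2**31 - 1)),
            resolution=resolution,
        )
        q = nx.community.modularity(g, comms, weight="weight",
                                    resolution=resolution)
        if q > best_q:
            best, best_q = comms, q
    comms = sorted(best, key=lambda c: (-len(c), min(c)))
    return {node: i for i, comm in enumerate(comms) for node in comm}


def _embed(y: np.ndarray, e: int, tau: int) -> np.ndarray:
    n = y.size
    nv = n - (e - 1) * tau
    return np.column_stack([y[(e - 1 - k) * tau:(e - 1 - k) * tau + nv]
                            for k in range(e)])


def _simplex_predict(
    dist: np.ndarray, lib: np.ndarray, target_vals: np.ndarray, k: int
) -> np.ndarray:
    """Simplex projection: for every row of ``dist`` predict from the k
    nearest library columns with exponential distance weights."""
    d = dist[:, lib]
    # exclude self-matches (distance exactly 0 from the same index)
    nt = dist.shape[0]
    self_col = np.searchsorted(lib, np.arange(nt))
    rows = np.arange(nt)
    valid = (self_col < lib.size)
    sc = np.where(valid, np.minimum(self_col, lib.size - 1), 0)
    is_self = valid & (lib[sc] == rows)
    d = d.copy()
    d[rows[is_self], sc[is_self]] = np.inf
    k = min(k, lib.size - 1) if is_self.any() else min(k, lib.size)
    if k < 1:
        return np.full(nt, np.nan)
    idx = np.argpartition(d, k - 1, axis=1)[:, :k]
    dk = np.take_along_axis(d, idx, axis=1)
    dmin = dk.min(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.exp(-dk / np.where(dmin > 0, dmin, 1.0))
    w[dk == np.inf] = 0.0
    # exact-match neighbors dominate
    zero_rows = dmin[:, 0] == 0
    if zero_rows.any():
        w[zero_rows] = (dk[zero_rows] == 0).astype(float)
    wsum = w.sum(axis=1)
    wsum[wsum == 0] = np.nan
    vals = target_vals[lib[idx]]
    return (w * vals).sum(axis=1) / wsum


def _skill(obs: np.ndarray, pred: np.ndarray) -> float:
    good = np.isfinite(pred)
    if good.sum() < 3:
        return np.nan
    o, p = obs[good], pred[good]
    if o.std() == 0 or p.std() == 0:
        return np.nan
    return float(np.corrcoef(o, p)[0, 1])


def _self_prediction_skill(y: np.ndarray, e: int, tau: int) -> float:
    """Leave-one-out one-step self-forecast skill of y at embedding dim e."""
    emb = _embed(y, e, tau)
    if emb.shape[0] < e + 3:
        return -np.inf
    pred_from = emb[:-1]
    target = y[(e - 1) * tau + 1:]
    dist = np.sqrt(((pred_from[:, None, :] - pred_from[None, :, :]) ** 2).sum(-1))
    lib = np.arange(pred_from.shape[0])
    pred = _simplex_predict(dist, lib, target, e + 1)
    return _skill(target, pred)


def select_embedding_dim(y: np.ndarray, tau: int = 1,
                         candidates=range(2, 7)) -> int:
    """Embedding dimension maximizing univariate simplex self-prediction."""
    best_e, best_s = None, -np.inf
    for e in candidates:
        s = _self_prediction_skill(y, e, tau)
        if np.isfinite(s) and s > best_s:
            best_e, best_s = e, s
    return best_e if best_e is not None else min(candidates)


def ccm_pair(
    x,
    y,
    E: int | None = None,
    tau: int = 1,
    lib_sizes=None,
    n_boot: int = 50,
    seed: int = 0,
    convergence_gain: float = 0.1,
) -> CCMResult:
    """Convergent cross mapping: does x drive y?

    Delay-embeds y and uses simplex projection (E+1 neighbors, exponential
    distance weights, leave-one-out) to predict the contemporaneous x
    values from y's reconstructed states.  If y's dynamics are forced by
    x, the embedding of y contains x's states and the cross-map skill
    (Pearson r of observed vs predicted x) increases with library size.
    ``convergent`` requires skill(L_max) - skill(L_min) > convergence_gain
    and skill(L_max) > 0.  E defaults to the dimension maximizing y's
    self-prediction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("series must align")
    if np.std(y) == 0 or np.std(x) == 0:
        return CCMResult(np.array([]), np.array([]), False, E or 2, tau)
    if E is None:
        E = select_embedding_dim(y, tau)
    if x.size < 5 * E:
        raise ValueError(f"series length {x.size} < 5*E = {5 * E}")
    emb = _embed(y, E, tau)
    nv = emb.shape[0]
    target = x[(E - 1) * tau:]
    if lib_sizes is None:
        # geometric ladder from a small library (where a genuine cross-map
        # is still data-starved but a mere forcing correlation has already
        # plateaued) up to the full embedding
        lo = max(E + 2, min(nv // 8, 16))
        lib_sizes = np.unique(
            np.geomspace(lo, nv, 6).round().astype(int)
        )
    else:
        lib_sizes = np.unique(np.asarray(lib_sizes, dtype=int))
        lib_sizes = lib_sizes[(lib_sizes >= E + 2) & (lib_sizes <= nv)]
    dist = np.sqrt(((emb[:, None, :] - emb[None, :, :]) ** 2).sum(-1))
    rng = np.random.default_rng(seed)
    skills = np.empty(lib_sizes.size)
    for i, L in enumerate(lib_sizes):
        if L >= nv:
            lib = np.arange(nv)
            pred = _simplex_predict(dist, lib, target, E + 1)
            skills[i] = _skill(target, pred)
            continue
        vals = []
        for _ in range(n_boot):
            lib = np.sort(rng.choice(nv, size=int(L), replace=False))
            pred = _simplex_predict(dist, lib, target, E + 1)
            s = _skill(target, pred)
            if np.isfinite(s):
                vals.append(s)
        skills[i] = np.mean(vals) if vals else np.nan
    finite = np.isfinite(skills)
    convergent = bool(
        finite.sum() >= 2
        and skills[finite][-1] - skills[finite][0] > convergence_gain
        and skills[finite][-1] > 0
    )
    return CCMResult(lib_sizes, skills, convergent, E, tau)


def _equal_frequency_labels(x: np.ndarray, bins: int) -> np.ndarray:
    n = x.size
    ranks = np.empty(n, dtype=np.int64)
    ranks[np.argsort(x, kind="stable")] = np.arange(n)
    return (ranks * bins) // n


def _nmi_from_labels(lx: np.ndarray, ly: np.ndarray, bins: int) -> float:
    joint = np.bincount(lx * bins + ly, minlength=bins * bins).astype(float)
    joint = joint.reshape(bins, bins)
    n = joint.sum()
    px = joint.sum(axis=1) / n
    py = joint.sum(axis=0) / n
    hx = -np.sum(px[px > 0] * np.log(px[px > 0]))
    hy = -np.sum(py[py > 0] * np.log(py[py > 0]))
    if hx == 0 or hy == 0:
        return 0.0
    pj = joint / n
    nz = pj > 0
    mi = np.sum(pj[nz] * (np.log(pj[nz]) - np.log(np.outer(px, py)[nz])))
    # Miller-Madow bias correction: raw plug-in MI overestimates by about
    # (occupied cells - occupied rows - occupied cols + 1) / 2n
    k_joint = int(nz.sum())
    k_x = int((px > 0).sum())
    k_y = int((py > 0).sum())
    mi -= (k_joint - k_x - k_y + 1) / (2.0 * n)
    return float(max(0.0, min(1.0, mi / np.sqrt(hx * hy))))


def nmi_weight(x, y, bins: int | None = None) -> float:
    """Normalized mutual information of two series in [0, 1].

    Each series is discretized into equal-frequency bins (floor(sqrt(n))
    by default, ties broken by stable rank order) and NMI is computed with
    the geometric-mean entropy normalization; 0 when either marginal
    entropy is 0.  Invariant under strictly monotone transforms.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("series must align")
    if x.size < 8:
        raise ValueError("need at least 8 observations")
    if bins is None:
        bins = int(np.floor(np.sqrt(x.size)))
    lx = _equal_frequency_labels(x, bins)
    ly = _equal_frequency_labels(y, bins)
    return _nmi_from_labels(lx, ly, bins)


def edge_significance(
    x,
    y,
    weight_fn=None,
    n_perm: int = 1000,
    scheme: str = "circular",
    seed: int = 0,
) -> float:
    """Permutation p-value for an edge weight.

    The circular scheme rotates y by a uniform random offset >= 1,
    preserving its autocorrelation; the shuffle scheme fully permutes y
    (anti-conservative on autocorrelated series).  p uses the +1
    correction: (#{permuted >= observed} + 1) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    n = y.size
    if weight_fn is None or weight_fn is nmi_weight:
        bins = int(np.floor(np.sqrt(n)))
        lx = _equal_frequency_labels(x, bins)
        ly = _equal_frequency_labels(y, bins)
        observed = _nmi_from_labels(lx, ly, bins)
        count = 0
        for _ in range(n_perm):
            if scheme == "circular":
                lp = np.roll(ly, int(rng.integers(1, n)))
            elif scheme == "shuffle":
                lp = rng.permutation(ly)
            else:
                raise ValueError("scheme must be 'circular' or 'shuffle'")
            if _nmi_from_labels(lx, lp, bins) >= observed:
                count += 1
        return (count + 1) / (n_perm + 1)
    observed = weight_fn(x, y)
    count = 0
    for _ in range(n_perm):
        if scheme == "circular":
            yp = np.roll(y, int(rng.integers(1, n)))
        elif scheme == "shuffle":
            yp = rng.permutation(y)
        else:
            raise ValueError("scheme must be 'circular' or 'shuffle'")
        if weight_fn(x, yp) >= observed:
            count += 1
    return (count + 1) / (n_perm + 1)


def _rank_normal(x: np.ndarray) -> np.ndarray:
    n = x.size
    return stats.norm.ppf((stats.rankdata(x) - 0.5) / n)


def _ls_scores(xz: np.ndarray, yz: np.ndarray, max_delay: int) -> np.ndarray:
    """Signed local-similarity score for each delay in [-D, D].

    ``yz`` may be 2-D (n_series, n); returns (n_series, 2D+1).  Delay d
    aligns x_t with y_{t+d} (d > 0: y follows x).  The dynamic program
    tracks the best positive and best negative partial-sum alignment;
    scores are normalized by the full series length.
    """
    if yz.ndim == 1:
        yz = yz[None, :]
    n = xz.size
    out = np.empty((yz.shape[0], 2 * max_delay + 1))
    for di, d in enumerate(range(-max_delay, max_delay + 1)):
        if d >= 0:
            xa = xz[: n - d]
            ya = yz[:, d:]
        else:
            xa = xz[-d:]
            ya = yz[:, : n + d]
        prod = xa[None, :] * ya
        spos = np.zeros(yz.shape[0])
        sneg = np.zeros(yz.shape[0])
        best_pos = np.zeros(yz.shape[0])
        best_neg = np.zeros(yz.shape[0])
        for t in range(prod.shape[1]):
            spos = np.maximum(0.0, spos + prod[:, t])
            sneg = np.maximum(0.0, sneg - prod[:, t])
            best_pos = np.maximum(best_pos, spos)
            best_neg = np.maximum(best_neg, sneg)
        out[:, di] = np.where(best_pos >= best_neg, best_pos, -best_neg) / n
    return out


def elsa_pair(
    x,
    y,
    max_delay: int = 2,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, int, float]:
    """Extended local similarity analysis of two series.

    Both series are rank-normal transformed; a dynamic program finds the
    highest-scoring contiguous run of co-varying (or anti-varying) values
    at each delay in [-max_delay, +max_delay].  Returns (signed score,
    optimal delay = argmax |score| with ties to the smallest |delay|,
    permutation p from the full-shuffle null on |score|).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("series must align")
    if x.size < 8:
        raise ValueError("need at least 8 observations")
    xz = _rank_normal(x)
    yz = _rank_normal(y)
    scores = _ls_scores(xz, yz, max_delay)[0]
    delays = np.arange(-max_delay, max_delay + 1)
    order = np.lexsort((delays < 0, np.abs(delays), -np.abs(scores)))
    best = order[0]
    ls, opt = float(scores[best]), int(delays[best])
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(yz) for _ in range(n_perm)])
        perm_scores = _ls_scores(xz, perms, max_delay)
        perm_best = np.abs(perm_scores).max(axis=1)
        p = (np.sum(perm_best >= abs(ls)) + 1) / (n_perm + 1)
    else:
        p = float("nan")
    return ls, opt, float(p)


def build_ccm_network(
    votu: AbundanceMatrix,
    asv: AbundanceMatrix,
    grid_step: float = 30.5,
    n_coeff: int = 16,
    r_min: float = 0.7,
    bh_alpha: float = 0.05,
    E: int | None = None,
    tau: int = 1,
    n_boot: int = 10,
    n_perm: int = 200,
    convergence_gain: float = 0.1,
    resolution: float = 1.0,
    seed: int = 0,
) -> DirectedNetwork:
    """Full virus-host network inference pipeline.

    Fourier profiles -> positive-correlation graph (BH-filtered) ->
    Louvain modules on the whole graph -> CCM on the correlated
    vOTU-ASV pairs, keeping a directed ASV -> vOTU edge when the vOTU's
    embedding cross-maps the ASV convergently (the host drives the
    virus) -> NMI weight and circular-permutation significance on raw
    series for retained edges.
    """
    if votu.sample_dates is None or asv.sample_dates is None:
        raise ValueError("both matrices need sample_dates")
    shared = [s for s in votu.sample_ids if s in set(asv.sample_ids)]
    if not shared:
        raise ValueError("no shared samples between matrices")
    v_dates = votu.sample_dates[[votu.sample_ids.index(s) for s in shared]]
    vx = votu.values[shared]
    ax = asv.values[shared]

    profiles = []
    kinds = {}
    for eid, row in vx.iterrows():
        kinds[eid] = "vOTU"
        profiles.append(fourier_profile(row.to_numpy(), v_dates, grid_step,
                                        n_coeff, entity_id=eid))
    for eid, row in ax.iterrows():
        kinds[eid] = "ASV"
        profiles.append(fourier_profile(row.to_numpy(), v_dates, grid_step,
                                        n_coeff, entity_id=eid))

    edges = profile_correlation_graph(profiles, r_min=r_min,
                                      bh_alpha=bh_alpha, n_obs=len(shared))
    nodes = pd.DataFrame(
        {"node_id": list(kinds), "kind": [kinds[k] for k in kinds]}
    )
    if len(edges) == 0:
        warnings.warn("empty correlation graph; returning empty network",
                      RuntimeWarning, stacklevel=2)
        return DirectedNetwork(
            nodes, edges,
            pd.DataFrame(columns=["source", "target", "skill", "delta",
                                  "nmi", "p_perm"]),
            {},
        )
    modules = louvain_modules(edges, seed=seed, resolution=resolution)

    # directed evaluation only on correlated ASV-vOTU pairs
    pairs = []
    for a, b in edges[["a", "b"]].itertuples(index=False):
        if kinds[a] != kinds[b]:
            host, vir = (a, b) if kinds[a] == "ASV" else (b, a)
            pairs.append((host, vir))

    e_cache: dict[str, int] = {}
    rng = np.random.default_rng(seed)
    rows = []
    for host, vir in pairs:
        hx = ax.loc[host].to_numpy()
        vy = vx.loc[vir].to_numpy()
        e_dim = E
        if e_dim is None:
            if vir not in e_cache:
                e_cache[vir] = select_embedding_dim(vy, tau)
            e_dim = e_cache[vir]
        res = ccm_pair(hx, vy, E=e_dim, tau=tau, n_boot=n_boot,
                       seed=int(rng.integers(2**31 - 1)),
                       convergence_gain=convergence_gain)
        if not res.convergent:
            continue
        finite = res.skills[np.isfinite(res.skills)]
        nmi = nmi_weight(hx, vy)
        p_perm = edge_significance(hx, vy, n_perm=n_perm, scheme="circular",
                                   seed=int(rng.integers(2**31 - 1)))
        rows.append(
            {"source": host, "target": vir, "skill": float(finite[-1]),
             "delta": float(finite[-1] - finite[0]), "nmi": nmi,
             "p_perm": p_perm}
        )
    directed = pd.DataFrame(
        rows, columns=["source", "target", "skill", "delta", "nmi", "p_perm"]
    )
    return DirectedNetwork(nodes, edges, directed, modules)
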