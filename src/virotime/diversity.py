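"""Iterative-subsampling alpha diversity with rarefaction slopes.

Viral read counts are subsampled without replacement (multivariate
hypergeometric draws, matching vegan's ``rrarefy``) on a grid of depths;
richness, Shannon diversity (natural log) and Pielou evenness are averaged
over iterations.  The rarefaction slope at a depth — the finite difference
of mean richness over the preceding grid step — measures the remaining
rate of discovery and is comparable across samples of unequal depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RarefactionCurve", "default_depth_grid", "subsample_metrics",
           "rarefaction_slope"]


@dataclass
class RarefactionCurve:
    sample_id: str
    depths: np.ndarray
    mean_richness: np.ndarray
    mean_shannon: np.ndarray
    mean_evenness: np.ndarray
    se_richness: np.ndarray
    iterations: int


def default_depth_grid(max_depth: int = 30_000, step: int = 50) -> np.ndarray:
    """The 50..30000 grid at 50-count intervals."""
    return np.arange(step, max_depth + 1, step)


def _shannon(counts: np.ndarray) -> float:
    pos = counts[counts > 0]
    if pos.size == 0:
        return 0.0
    p = pos / pos.sum()
    return float(-(p * np.log(p)).sum())


def subsample_metrics(
    counts,
    depth_grid=None,
    iterations: int = 100,
    seed: int = 0,
    sample_id: str = "",
) -> RarefactionCurve:
    """Monte-Carlo rarefaction of one sample's integer count vector.

    Depths exceeding the sample total are skipped (recorded as absent),
    never extrapolated.  Evenness is Pielou's J = H / ln(S), defined as 0
    when richness <= 1.
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("empty count vector")
    as_int = np.asarray(counts, dtype=np.int64)
    if not np.array_equal(as_int, counts) or (as_int < 0).any():
        raise ValueError(
            "counts must be non-negative integers; convert normalized "
            "abundances to read counts before rarefying"
        )
    counts = as_int
    total = int(counts.sum())
    if depth_grid is None:
        depth_grid = default_depth_grid()
    depth_grid = np.asarray(depth_grid, dtype=np.int64)
    if not np.all(np.diff(depth_grid) > 0):
        raise ValueError("depth grid must be strictly increasing")
    depths = depth_grid[depth_grid <= total]

    rng = np.random.default_rng(seed)
    n_d = depths.size
    rich = np.empty((iterations, n_d))
    shan = np.empty((iterations, n_d))
    even = np.empty((iterations, n_d))
    for it in range(iterations):
        for j, d in enumerate(depths):
            sub = rng.multivariate_hypergeometric(counts, int(d))
            s = int((sub > 0).sum())
            h = _shannon(sub)
            rich[it, j] = s
            shan[it, j] = h
            even[it, j] = h / np.log(s) if s > 1 else 0.0
    se = rich.std(axis=0, ddof=1) / np.sqrt(iterations) if iterations > 1 \
        else np.zeros(n_d)
    return RarefactionCurve(
        sample_id=sample_id,
        depths=depths,
        mean_richness=rich.mean(axis=0),
        mean_shannon=shan.mean(axis=0),
        mean_evenness=even.mean(axis=0),
        se_richness=se,
        iterations=iterations,
    )


def rarefaction_slope(curve: RarefactionCurve, at_depth: int = 1000) -> float:
    """Entities discovered per additional read at ``at_depth``.

    Finite difference of mean richness between ``at_depth`` and the
    preceding grid depth.
    """
    idx = np.flatnonzero(curve.depths == at_depth)
    if idx.size == 0 or idx[0] == 0:
        raise KeyError(
            f"depth {at_depth} (and its predecessor) must be on the curve grid"
        )
    i = int(idx[0])
    dd = float(curve.depths[i] - curve.depths[i - 1])
    return float((curve.mean_richness[i] - curve.mean_richness[i - 1]) / dd)
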