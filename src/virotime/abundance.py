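"""Coverage-based abundance normalization (cVCR and cVGB).

The coverage-based virus-to-cell ratio (cVCR) divides a virus's mean read
coverage by the estimated number of cellular genomes sequenced in the same
metagenome, itself estimated as the mean coverage of 16 universal
single-copy ribosomal proteins.  The coverage-per-gigabase variant (cVGB)
divides (trimmed) mean coverage by the sample's sequencing effort in Gbp.
Both apply a detection filter: a virus counts as present only when more
than ``breadth_min`` (default 25%) of its sequence is covered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import DEFAULT_MARKER_IDS

__all__ = [
    "AbundanceMatrix",
    "estimate_cell_genomes",
    "compute_cvcr",
    "compute_cvgb",
]


@dataclass
class AbundanceMatrix:
    """Entity x sample non-negative abundance matrix with a metric tag."""

    values: pd.DataFrame
    metric: str
    sample_dates: np.ndarray | None = field(default=None)

    def __post_init__(self):
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundance values must be non-negative")
        if self.sample_dates is not None:
            self.sample_dates = np.asarray(self.sample_dates, dtype=float)
            if len(self.sample_dates) != self.values.shape[1]:
                raise ValueError("sample_dates must match sample columns")

    @property
    def entity_ids(self):
        return list(self.values.index)

    @property
    def sample_ids(self):
        return list(self.values.columns)


def _check_coverage_table(cov: pd.DataFrame) -> None:
    required = {"sample_id", "contig_id", "mean_coverage", "breadth"}
    missing = required - set(cov.columns)
    if missing:
        raise ValueError(f"coverage table missing columns: {sorted(missing)}")
    if cov.duplicated(["sample_id", "contig_id"]).any():
        raise ValueError("duplicate (sample, contig) pairs in coverage table")
    b = cov["breadth"].to_numpy(dtype=float)
    if ((b < 0) | (b > 1)).any():
        raise ValueError("breadth must lie in [0, 1]")
    if (cov["mean_coverage"].to_numpy(dtype=float) < 0).any():
        raise ValueError("coverages must be non-negative")


def estimate_cell_genomes(
    markers: pd.DataFrame,
    sample: str,
    marker_ids: tuple[str, ...] = DEFAULT_MARKER_IDS,
) -> float:
    """Estimated cellular genome copies sequenced in one metagenome.

    Arithmetic mean of the configured single-copy marker coverages; a
    marker absent from the table contributes 0 (a missing single-copy gene
    in a sequenced sample is evidence of low cellular coverage, not missing
    data).
    """
    sub = markers[markers["sample_id"] == sample]
    if sub.empty:
        raise KeyError(f"sample {sample!r} not present in marker table")
    by_marker = sub.set_index("marker_id")["mean_coverage"]
    total = float(sum(by_marker.get(m, 0.0) for m in marker_ids))
    return total / len(marker_ids)


def _pivot(cov: pd.DataFrame, value_col: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    values = cov.pivot(index="contig_id", columns="sample_id",
                       values=value_col).fillna(0.0).sort_index()
    breadth = cov.pivot(index="contig_id", columns="sample_id",
                        values="breadth").fillna(0.0).sort_index()
    values = values[sorted(values.columns)]
    breadth = breadth[values.columns]
    return values, breadth


def compute_cvcr(
    cov: pd.DataFrame,
    markers: pd.DataFrame,
    breadth_min: float = 0.25,
    marker_ids: tuple[str, ...] = DEFAULT_MARKER_IDS,
    sample_dates: np.ndarray | None = None,
) -> AbundanceMatrix:
    """Coverage-based virus-to-cell ratio matrix.

    ``cVCR(v, s) = mean_coverage(v, s) / cell_estimate(s)`` where breadth
    strictly exceeds ``breadth_min``; entries failing the filter are 0.
    Entities that never pass the filter are kept as all-zero rows so that
    downstream prevalence filters can decide their fate.
    """
    if not 0.0 <= breadth_min < 1.0:
        raise ValueError("breadth_min must lie in [0, 1)")
    _check_coverage_table(cov)
    values, breadth = _pivot(cov, "mean_coverage")
    cells = pd.Series(
        {s: estimate_cell_genomes(markers, s, marker_ids) for s in values.columns}
    )
    masked = values.where(breadth.to_numpy() > breadth_min, 0.0)
    bad = (cells <= 0) & (masked.sum(axis=0) > 0)
    if bad.any():
        raise ZeroDivisionError(
            "zero cellular genome estimate with nonzero viral coverage in "
            f"samples {list(cells.index[bad])}"
        )
    safe_cells = cells.replace(0.0, np.nan)
    out = masked.div(safe_cells, axis=1).fillna(0.0)
    return AbundanceMatrix(out, metric="cVCR", sample_dates=sample_dates)


def compute_cvgb(
    cov: pd.DataFrame,
    sample_gbp: pd.Series,
    breadth_min: float = 0.25,
    use_trimmed: bool = True,
    sample_dates: np.ndarray | None = None,
) -> AbundanceMatrix:
    """Viral coverage per gigabase pair of sequenced metagenome."""
    if not 0.0 <= breadth_min < 1.0:
        raise ValueError("breadth_min must lie in [0, 1)")
    _check_coverage_table(cov)
    col = "trimmed_mean_coverage" if use_trimmed else "mean_coverage"
    if col not in cov.columns:
        raise ValueError(f"coverage table lacks column {col!r}")
    values, breadth = _pivot(cov, col)
    gbp = pd.Series(sample_gbp).reindex(values.columns)
    if gbp.isna().any() or (gbp <= 0).any():
        raise ValueError("sample_gbp must be positive for every sample")
    masked = values.where(breadth.to_numpy() > breadth_min, 0.0)
    out = masked.div(gbp, axis=1)
    return AbundanceMatrix(out, metric="cVGB", sample_dates=sample_dates)
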