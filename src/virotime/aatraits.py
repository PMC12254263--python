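"""Per-protein amino-acid traits and their environmental correlates.

Traits with a cold-adaptation interpretation: single-residue frequencies
(G, S, P, C), biochemical group fractions, the arginine/lysine ratio,
molecular weight, the aliphatic index (Ikai; higher in thermophiles), the
isoelectric point on the EMBOSS pKa scale, and the nitrogen usage score

    NUS = (4 F(R) + 3 F(H) + 2 F(K,N,Q,W) + F(rest)) / length,

the mean number of nitrogen atoms carried per residue (side chain plus
backbone), which trades off against nitrogen limitation in cold,
oligotrophic waters.  Sample-level trait vectors are protein means;
trait-environment association uses Mantel tests (Bray-Curtis trait
distances vs Euclidean environmental distances, Spearman statistic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .seasonality import mantel_test, significance_stars

__all__ = [
    "SequenceRejected", "ProteinTraitVector", "residue_counts", "nus",
    "aliphatic_index", "isoelectric_point", "trait_vector",
    "sample_trait_matrix", "trait_env_mantel", "TRAIT_GROUPS",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# group membership is configuration: the convention below is ordinary
# biochemistry usage and is recorded in output metadata
TRAIT_GROUPS = {
    "acidic": ("D", "E"),
    "polar_charged": ("D", "E", "H", "K", "R"),
    "polar_uncharged": ("S", "T", "N", "Q", "C", "Y"),
    "aromatic": ("F", "W", "Y"),
}

# nitrogen atoms per residue (backbone amide + side chain)
_NUS_COEFF = {aa: 1 for aa in STANDARD_AA}
_NUS_COEFF.update({"R": 4, "H": 3, "K": 2, "N": 2, "Q": 2, "W": 2})

# EMBOSS pKa scale
_PKA_POSITIVE = {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
_PKA_NEGATIVE = {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}


class SequenceRejected(ValueError):
    """Sequence contains ambiguous/non-standard residues and is removed."""


@dataclass
class ProteinTraitVector:
    protein_id: str
    length: int
    freq_G: float
    freq_S: float
    freq_P: float
    freq_C: float
    frac_acidic: float
    frac_polar_uncharged: float
    frac_polar_charged: float
    frac_aromatic: float
    rk_ratio: float          # NaN sentinel when K is absent
    molecular_weight: float
    aliphatic_index: float
    pI: float
    nus: float


def _clean(seq: str) -> str:
    return str(seq).strip().rstrip("*").upper()


def residue_counts(seq: str, reject: str = "strict") -> dict[str, int]:
    """Counts over the 20 standard residues.

    ``reject='strict'`` (default) removes any sequence with a letter
    outside the 20 standard residues; ``reject='x_only'`` removes only
    sequences containing the ambiguity code X (other letters still cannot
    be counted and raise).  Trailing stop characters are stripped first.
    """
    s = _clean(seq)
    if not s:
        raise ValueError("empty sequence")
    extra = set(s) - set(STANDARD_AA)
    if extra:
        if reject == "strict" or "X" in extra:
            raise SequenceRejected(
                f"sequence contains non-standard residues {sorted(extra)}"
            )
        raise ValueError(f"uncountable residues {sorted(extra)}")
    return {aa: s.count(aa) for aa in STANDARD_AA}


def nus(seq: str, reject: str = "strict") -> float:
    """Nitrogen usage score, in [1, 4] nitrogen atoms per residue."""
    counts = residue_counts(seq, reject)
    n = sum(counts.values())
    return sum(_NUS_COEFF[aa] * c for aa, c in counts.items()) / n


def aliphatic_index(seq: str, reject: str = "strict") -> float:
    """Ikai aliphatic index: X_A + 2.9 X_V + 3.9 (X_I + X_L), mole percent."""
    counts = residue_counts(seq, reject)
    n = sum(counts.values())
    return 100.0 * (
        counts["A"] + 2.9 * counts["V"] + 3.9 * (counts["I"] + counts["L"])
    ) / n


def _net_charge(ph: float, counts: dict[str, int]) -> float:
    pos = sum(
        n / (1.0 + 10.0 ** (ph - pka))
        for pka, n in (
            (_PKA_POSITIVE["Nterm"], 1),
            (_PKA_POSITIVE["K"], counts["K"]),
            (_PKA_POSITIVE["R"], counts["R"]),
            (_PKA_POSITIVE["H"], counts["H"]),
        )
    )
    neg = sum(
        n / (1.0 + 10.0 ** (pka - ph))
        for pka, n in (
            (_PKA_NEGATIVE["Cterm"], 1),
            (_PKA_NEGATIVE["D"], counts["D"]),
            (_PKA_NEGATIVE["E"], counts["E"]),
            (_PKA_NEGATIVE["C"], counts["C"]),
            (_PKA_NEGATIVE["Y"], counts["Y"]),
        )
    )
    return pos - neg


def isoelectric_point(seq: str, reject: str = "strict",
                      tol: float = 1e-4) -> float:
    """pH of zero net charge under the EMBOSS pKa scale.

    The Henderson-Hasselbalch net charge is strictly decreasing in pH, so
    bisection on [0, 14] converges to the unique root (to |Q| < tol).
    """
    counts = residue_counts(seq, reject)
    lo, hi = 0.0, 14.0
    # drive the bracket below 1e-7 pH so the root is located to well
    # within the |Q| tolerance even where the charge curve is flat
    while hi - lo > 1e-7:
        mid = 0.5 * (lo + hi)
        q = _net_charge(mid, counts)
        if abs(q) < tol and hi - lo < 1e-4:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def trait_vector(seq: str, protein_id: str = "",
                 reject: str = "strict") -> ProteinTraitVector:
    """All per-protein traits; raises SequenceRejected on ambiguous input."""
    counts = residue_counts(seq, reject)
    n = sum(counts.values())

    def frac(group: tuple[str, ...]) -> float:
        return sum(counts[a] for a in group) / n

    rk = counts["R"] / counts["K"] if counts["K"] > 0 else float("nan")
    mw = ProteinAnalysis(_clean(seq)).molecular_weight()
    return ProteinTraitVector(
        protein_id=protein_id,
        length=n,
        freq_G=counts["G"] / n,
        freq_S=counts["S"] / n,
        freq_P=counts["P"] / n,
        freq_C=counts["C"] / n,
        frac_acidic=frac(TRAIT_GROUPS["acidic"]),
        frac_polar_uncharged=frac(TRAIT_GROUPS["polar_uncharged"]),
        frac_polar_charged=frac(TRAIT_GROUPS["polar_charged"]),
        frac_aromatic=frac(TRAIT_GROUPS["aromatic"]),
        rk_ratio=rk,
        molecular_weight=mw,
        aliphatic_index=aliphatic_index(seq, reject),
        pI=isoelectric_point(seq, reject),
        nus=nus(seq, reject),
    )


_TRAIT_COLS = [
    "freq_G", "freq_S", "freq_P", "freq_C", "frac_acidic",
    "frac_polar_uncharged", "frac_polar_charged", "frac_aromatic",
    "rk_ratio", "molecular_weight", "aliphatic_index", "pI", "nus",
]


def sample_trait_matrix(
    proteins: dict[str, list[tuple[str, str]]],
    reject: str = "strict",
) -> pd.DataFrame:
    """Sample x trait matrix of unweighted per-protein trait means.

    ``proteins`` maps sample_id to (protein_id, sequence) pairs (as
    produced by the generator or parsed from per-sample FASTA).  Rejected
    sequences are counted and excluded; NaN trait values (R/K with no
    lysine) are excluded pairwise; a sample with zero valid proteins is
    dropped with a warning.  The removal count per sample is stored in
    ``result.attrs['removed']``.
    """
    rows = {}
    removed = {}
    for sample, seqs in proteins.items():
        vecs = []
        n_removed = 0
        for pid, seq in seqs:
            try:
                vecs.append(trait_vector(seq, pid, reject))
            except SequenceRejected:
                n_removed += 1
        removed[sample] = n_removed
        if not vecs:
            warnings.warn(
                f"sample {sample!r} has no valid proteins; excluded",
                RuntimeWarning, stacklevel=2,
            )
            continue
        df = pd.DataFrame([v.__dict__ for v in vecs])
        rows[sample] = df[_TRAIT_COLS].mean(skipna=True)
    out = pd.DataFrame(rows).T
    out.index.name = "sample_id"
    out.attrs["removed"] = removed
    out.attrs["groups"] = TRAIT_GROUPS
    return out


def trait_env_mantel(
    traits: pd.DataFrame,
    env: pd.DataFrame,
    permutations: int = 9999,
    seed: int = 0,
) -> pd.DataFrame:
    """Mantel (Spearman) association of each trait with each parameter.

    Per trait: Bray-Curtis distances between samples on that trait; per
    environmental parameter: Euclidean distances; the seasonality Mantel
    machinery supplies the permutation test.  Returns a long table with
    rho, p, and significance stars.
    """
    env = env.set_index("sample_id") if "sample_id" in env.columns else env
    shared = [s for s in traits.index if s in env.index]
    if len(shared) < 4:
        raise ValueError("need at least 4 shared samples")
    t = traits.loc[shared]
    e = env.loc[shared].select_dtypes("number")
    rng = np.random.default_rng(seed)
    rows = []
    for trait in t.columns:
        x = t[trait].to_numpy(dtype=float)
        if np.isnan(x).any() or np.ptp(x) == 0:
            for param in e.columns:
                rows.append({"trait": trait, "parameter": param,
                             "rho": float("nan"), "p": float("nan"),
                             "stars": ""})
            continue
        ssum = x[:, None] + x[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            d_trait = np.where(ssum > 0,
                               np.abs(x[:, None] - x[None, :]) / ssum, 0.0)
        np.fill_diagonal(d_trait, 0.0)
        for param in e.columns:
            y = e[param].to_numpy(dtype=float)
            d_env = np.abs(y[:, None] - y[None, :])
            rho, p = mantel_test(
                d_trait, d_env, method="spearman",
                permutations=permutations,
                seed=int(rng.integers(2**31 - 1)),
            )
            rows.append({"trait": trait, "parameter": param, "rho": rho,
                         "p": p, "stars": significance_stars(p)})
    return pd.DataFrame(rows)
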