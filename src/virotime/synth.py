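"""Seeded synthetic data with the statistical structure the analyses assume.

Generates four-year, near-monthly time series of environmental forcing, a
host community with Gaussian environmental niches organized into seasonal
guilds, viruses that lag-follow their hosts through discrete forced
Lotka-Volterra dynamics, read-coverage observations of both, temperature-
biased protein sequences, and latitudinal abundance profiles with planted
bimodality.  Every generator is a pure function of (config, seed) and
records its ground truth so that downstream analyses can be scored as
parameter-recovery problems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

YEAR_DAYS = 365.0

__all__ = [
    "SeasonalSignal",
    "EnvironmentConfig",
    "TrueCommunity",
    "gen_environment",
    "gen_community",
    "gen_coverage",
    "asv_relative_abundance",
    "gen_proteins",
    "write_protein_fastas",
    "gen_latitude_profiles",
    "DEFAULT_MARKER_IDS",
]

# 16 universal single-copy ribosomal proteins used as the cellular-genome
# denominator; the identity of the set is configuration, not data.
DEFAULT_MARKER_IDS = (
    "rpL2", "rpL3", "rpL4", "rpL5", "rpL6", "rpL14", "rpL15", "rpL16",
    "rpL18", "rpL22", "rpL24", "rpS3", "rpS8", "rpS10", "rpS17", "rpS19",
)


@dataclass(frozen=True)
class SeasonalSignal:
    """Annual sinusoid: mean + amplitude * cos(2*pi*(t - peak_day)/365)."""

    mean: float
    amplitude: float
    peak_day: float
    noise_sd: float = 0.0

    def evaluate(self, days: np.ndarray) -> np.ndarray:
        return self.mean + self.amplitude * np.cos(
            2.0 * np.pi * (days - self.peak_day) / YEAR_DAYS
        )


@dataclass(frozen=True)
class EnvironmentConfig:
    """Seasonal forcing for a high-latitude mooring site.

    Defaults emulate the West Spitsbergen Current: temperature peaking in
    late summer, mixed layer depth in anti-phase (winter deepening), PAR
    truncated to zero through a 120-day polar night, and polar water
    fraction peaking in late summer.
    """

    temperature: SeasonalSignal = SeasonalSignal(3.0, 3.0, 210.0, 0.3)
    salinity: SeasonalSignal = SeasonalSignal(34.8, 0.3, 30.0, 0.05)
    oxygen: SeasonalSignal = SeasonalSignal(310.0, 25.0, 120.0, 4.0)
    mld: SeasonalSignal = SeasonalSignal(150.0, 130.0, 15.0, 10.0)
    par: SeasonalSignal = SeasonalSignal(0.0, 30.0, 172.0, 0.5)
    chlorophyll: SeasonalSignal = SeasonalSignal(1.2, 1.1, 160.0, 0.15)
    polar_water_fraction: SeasonalSignal = SeasonalSignal(0.30, 0.22, 240.0, 0.03)
    polar_night_days: float = 120.0

    def scale_noise(self, factor: float) -> "EnvironmentConfig":
        """Return a copy with every noise_sd multiplied by ``factor``."""
        kw = {}
        for name in ("temperature", "salinity", "oxygen", "mld", "par",
                     "chlorophyll", "polar_water_fraction"):
            sig: SeasonalSignal = getattr(self, name)
            kw[name] = replace(sig, noise_sd=sig.noise_sd * factor)
        return replace(self, **kw)


def gen_environment(
    n_samples: int,
    interval_days: float = 30.5,
    seed: int = 0,
    config: EnvironmentConfig | None = None,
) -> pd.DataFrame:
    """Generate an environment table at a regular sampling interval.

    Returns a DataFrame with one row per sample (``sample_id`` S000..),
    ``date`` in days since origin, and the seven physicochemical columns.
    PAR is truncated at zero and is exactly zero throughout the configured
    polar-night window; polar water fraction is clipped to [0, 1]; MLD is
    floored at 1 m.
    """
    if n_samples < 4:
        raise ValueError("n_samples must be >= 4")
    if interval_days <= 0:
        raise ValueError("interval_days must be positive")
    cfg = config or EnvironmentConfig()
    rng = np.random.default_rng(seed)
    days = np.arange(n_samples, dtype=float) * interval_days

    def noisy(sig: SeasonalSignal) -> np.ndarray:
        vals = sig.evaluate(days)
        if sig.noise_sd > 0:
            vals = vals + rng.normal(0.0, sig.noise_sd, size=n_samples)
        return vals

    temperature = noisy(cfg.temperature)
    salinity = noisy(cfg.salinity)
    oxygen = noisy(cfg.oxygen)
    mld = np.maximum(noisy(cfg.mld), 1.0)
    chlorophyll = np.maximum(noisy(cfg.chlorophyll), 0.0)
    pwf = np.clip(noisy(cfg.polar_water_fraction), 0.0, 1.0)

    # PAR: cosine with a hard zero window of polar_night_days around the
    # winter trough.  cos threshold c0 makes the dark season exactly the
    # configured length before truncation.
    c0 = np.cos(np.pi * (YEAR_DAYS - cfg.polar_night_days) / YEAR_DAYS)
    phase = np.cos(2.0 * np.pi * (days - cfg.par.peak_day) / YEAR_DAYS)
    par = cfg.par.amplitude * (phase - c0) / (1.0 - c0)
    if cfg.par.noise_sd > 0:
        par = par + rng.normal(0.0, cfg.par.noise_sd, size=n_samples)
    par = np.maximum(par, 0.0)

    return pd.DataFrame(
        {
            "sample_id": [f"S{i:03d}" for i in range(n_samples)],
            "date": days,
            "temperature": temperature,
            "salinity": salinity,
            "oxygen": oxygen,
            "mld": mld,
            "par": par,
            "chlorophyll": chlorophyll,
            "polar_water_fraction": pwf,
        }
    )


@dataclass
class TrueCommunity:
    """Ground-truth host/virus trajectories with planted guilds and lags."""

    host_abundance: pd.DataFrame   # hosts x samples, arbitrary cells/mL-like units
    virus_abundance: pd.DataFrame  # viruses x samples
    host_of: dict[str, str]        # virus -> host
    lag_of: dict[str, int]         # virus -> sampling-step lag in {0,1,2}
    guild_of: dict[str, int]       # entity (host or virus) -> guild label
    dates: np.ndarray = field(default_factory=lambda: np.empty(0))


def _guild_growth_rates(
    env: pd.DataFrame,
    n_guilds: int,
    guild_phase_days,
    niche_breadth: float,
    r_max: float,
    phase_offsets: np.ndarray | None = None,
) -> np.ndarray:
    """Gaussian niche response of each guild to the environment.

    Each guild's niche center is the standardized environmental state
    (temperature, oxygen, PAR, MLD) at its preferred day of year.  ``phase_offsets`` (n_guilds x n_years,
    days) shifts each guild's preferred day per year, emulating
    interannually varying bloom timing.  Returns (n_guilds, n_samples)
    growth rates in [0, r_max].
    """
    # phases of these four drivers straddle the year (winter MLD maximum,
    # spring oxygen, early-summer PAR, late-summer temperature), so the
    # annual trajectory in standardized niche space is an injective loop
    # and every preferred day maps to a distinct environmental state
    feats = env[["temperature", "oxygen", "par", "mld"]].to_numpy(dtype=float)
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    z = (feats - mu) / sd
    dates = np.asarray(env["date"], dtype=float)
    doy = dates % YEAR_DAYS
    years = (dates // YEAR_DAYS).astype(int)
    if guild_phase_days is None:
        guild_phase_days = [(g + 0.5) * YEAR_DAYS / n_guilds for g in range(n_guilds)]
    out = np.empty((n_guilds, len(env)))
    for g, phi in enumerate(guild_phase_days):
        target = np.full(len(env), phi % YEAR_DAYS)
        if phase_offsets is not None:
            target = (phi + phase_offsets[g, years]) % YEAR_DAYS
        # niche center for the year's (possibly shifted) preferred day
        for t in range(len(env)):
            circ = np.minimum(np.abs(doy - target[t]),
                              YEAR_DAYS - np.abs(doy - target[t]))
            c = z[np.argmin(circ)]
            d2 = ((z[t] - c) ** 2).sum()
            out[g, t] = r_max * np.exp(
                -d2 / (2.0 * niche_breadth**2 * z.shape[1])
            )
    return out


def gen_community(
    env: pd.DataFrame,
    n_hosts: int,
    n_viruses: int,
    n_guilds: int = 4,
    coupling: float = 12.0,
    seed: int = 0,
    *,
    r_max: float = 2.5,
    mortality: float = 0.6,
    niche_breadth: float = 1.0,
    virus_mortality: float = 3.0,
    predation: float = 0.05,
    immigration: float = 0.05,
    substeps: int = 8,
    sigma_interannual: float = 0.6,
    sigma_phase_days: float = 15.0,
    sigma_host: float = 0.10,
    sigma_virus: float = 0.15,
    guild_phase_days=None,
    center_jitter: float = 0.15,
    lag_probs: tuple[float, float, float] = (0.41, 0.34, 0.25),
    host_scale: float = 1e5,
    virus_scale: float = 1e5,
    ceiling: float = 1e6,
) -> TrueCommunity:
    """Simulate a forced discrete Lotka-Volterra host-virus community.

    Hosts follow ``h' = h * exp(dt*(r_g(env)*(1-h) - d0 - a*v))`` where r_g
    is the guild's Gaussian niche response; each virus tracks its host at
    an integer sampling-step lag via
    ``v' = v * exp(dt*(b*h_lag*(1-v) - m)) + eps*dt``.  ``coupling`` is b
    (per sampling interval); the immigration term eps is a seed-bank floor
    that lets a virus re-grow promptly when its host returns (0 gives
    strict decay when b = 0).  Viral kinetics are much faster than the
    ~monthly sampling interval (latent periods of hours to days), so the
    maps are iterated on ``substeps`` sub-intervals per sampling step
    (dt = 1/substeps) and recorded at the sampling grid; the planted lags
    remain exact integer numbers of sampling steps.  Multiplicative
    lognormal noise (per sampling step) applies to both populations, and
    abundances are clipped at ``ceiling`` with a warning if the regime
    diverges.
    """
    if not (n_viruses >= n_hosts >= n_guilds >= 1):
        raise ValueError("require n_viruses >= n_hosts >= n_guilds >= 1")
    if coupling < 0:
        raise ValueError("coupling must be >= 0")
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    rng = np.random.default_rng(seed)
    n_t = len(env)
    n_years = int(np.asarray(env["date"], dtype=float).max() // YEAR_DAYS) + 1
    phase_offsets = (rng.normal(0.0, sigma_phase_days, size=(n_guilds, n_years))
                     if sigma_phase_days > 0 else None)
    rates = _guild_growth_rates(env, n_guilds, guild_phase_days,
                                niche_breadth, r_max, phase_offsets)

    # interannual bloom-magnitude variability shared within a guild: the
    # same season differs between years (a guild blooming strongly in one
    # year and weakly the next), realized as a guild x year factor on the
    # carrying capacities; this shared envelope is what distinguishes
    # guild-mates beyond their seasonal phase
    years = (np.asarray(env["date"], dtype=float) // YEAR_DAYS).astype(int)
    if sigma_interannual > 0:
        year_fac = np.exp(rng.normal(0.0, sigma_interannual,
                                     size=(n_guilds, years.max() + 1)))
    else:
        year_fac = np.ones((n_guilds, years.max() + 1))

    host_guild = np.arange(n_hosts) % n_guilds
    # small per-host jitter on the niche so hosts within a guild differ
    host_rates = rates[host_guild] * np.exp(
        rng.normal(0.0, center_jitter, size=(n_hosts, 1))
    )

    virus_host = rng.integers(0, n_hosts, size=n_viruses)
    virus_lag = rng.choice([0, 1, 2], size=n_viruses, p=list(lag_probs))

    # virus pressure on each host: mean over its viruses
    n_virus_of = np.bincount(virus_host, minlength=n_hosts).astype(float)
    n_virus_of[n_virus_of == 0] = 1.0

    int_ceiling = ceiling / max(host_scale, virus_scale)
    dt = 1.0 / substeps
    n_sub = (n_t - 1) * substeps + 1
    hs = np.empty((n_hosts, n_sub))
    vs = np.empty((n_viruses, n_sub))
    hs[:, 0] = 0.2 * np.exp(rng.normal(0.0, 0.1, size=n_hosts))
    vs[:, 0] = 0.05 * np.exp(rng.normal(0.0, 0.1, size=n_viruses))
    # lognormal noise applied per sampling step, spread over substeps
    noise_h = (rng.normal(0.0, sigma_host, size=(n_hosts, n_t - 1))
               if sigma_host > 0 else np.zeros((n_hosts, n_t - 1)))
    noise_v = (rng.normal(0.0, sigma_virus, size=(n_viruses, n_t - 1))
               if sigma_virus > 0 else np.zeros((n_viruses, n_t - 1)))
    clipped = False
    lag_sub = virus_lag * substeps
    virus_guild = host_guild[virus_host]
    for tau in range(n_sub - 1):
        t = tau // substeps  # sampling interval index (zero-order forcing)
        k_h = year_fac[host_guild, years[t]]
        k_v = year_fac[virus_guild, years[t]]
        pressure = np.bincount(virus_host, weights=vs[:, tau], minlength=n_hosts)
        pressure /= n_virus_of
        growth = (host_rates[:, t] * (1.0 - hs[:, tau] / k_h) - mortality
                  - predation * pressure)
        hs[:, tau + 1] = hs[:, tau] * np.exp(dt * (growth + noise_h[:, t]))
        h_lag = hs[virus_host, np.maximum(tau - lag_sub, 0)]
        vg = coupling * h_lag * (1.0 - vs[:, tau] / k_v) - virus_mortality
        vs[:, tau + 1] = (vs[:, tau] * np.exp(dt * (vg + noise_v[:, t]))
                          + immigration * dt)
        if (hs[:, tau + 1] > int_ceiling).any() or (vs[:, tau + 1] > int_ceiling).any():
            clipped = True
            hs[:, tau + 1] = np.minimum(hs[:, tau + 1], int_ceiling)
            vs[:, tau + 1] = np.minimum(vs[:, tau + 1], int_ceiling)
    if clipped:
        warnings.warn("community dynamics hit the abundance ceiling; clipped",
                      RuntimeWarning, stacklevel=2)
    h = hs[:, ::substeps]
    v = vs[:, ::substeps]

    host_ids = [f"H{i:03d}" for i in range(n_hosts)]
    virus_ids = [f"V{i:03d}" for i in range(n_viruses)]
    samples = list(env["sample_id"])
    guild_of = {hid: int(g) for hid, g in zip(host_ids, host_guild)}
    guild_of.update(
        {vid: int(host_guild[hh]) for vid, hh in zip(virus_ids, virus_host)}
    )
    return TrueCommunity(
        host_abundance=pd.DataFrame(h * host_scale, index=host_ids, columns=samples),
        virus_abundance=pd.DataFrame(v * virus_scale, index=virus_ids, columns=samples),
        host_of={vid: host_ids[hh] for vid, hh in zip(virus_ids, virus_host)},
        lag_of={vid: int(l) for vid, l in zip(virus_ids, virus_lag)},
        guild_of=guild_of,
        dates=np.asarray(env["date"], dtype=float),
    )


def gen_coverage(
    community: TrueCommunity,
    contig_lengths: pd.Series | dict | None = None,
    sample_gbp: pd.Series | float | None = None,
    marker_count: int = 16,
    seed: int = 0,
    *,
    noise_sd: float = 0.25,
    cov_per_unit: float = 2e-4,
    marker_cov_per_unit: float = 2e-5,
    ref_gbp: float = 10.0,
    marker_ids: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Observe the community through read coverage with depth variation.

    Per-sample viral coverage = true abundance x depth factor x lognormal
    noise, where the depth factor is sample Gbp over a fixed 10-Gbp
    reference.  Marker coverage for each single-copy marker tracks total
    host abundance the same way.  Breadth follows the saturating map
    ``min(1, 1 - exp(-0.75 * coverage))`` so that low-abundance entities
    exercise the 25%-breadth detection filter.

    Returns (coverage table, marker coverage table, per-sample Gbp).
    """
    rng = np.random.default_rng(seed)
    samples = list(community.virus_abundance.columns)
    viruses = list(community.virus_abundance.index)
    n_s, n_v = len(samples), len(viruses)

    if contig_lengths is None:
        contig_lengths = pd.Series(
            rng.integers(10_000, 80_001, size=n_v), index=viruses
        )
    else:
        contig_lengths = pd.Series(contig_lengths).reindex(viruses)
    if (contig_lengths <= 0).any() or contig_lengths.isna().any():
        raise ValueError("every contig needs a positive length")
    if (contig_lengths < 10_000).any():
        raise ValueError("contig lengths must be >= 10000 bp")

    if sample_gbp is None:
        sample_gbp = pd.Series(
            ref_gbp * np.exp(rng.normal(0.0, 0.3, size=n_s)), index=samples
        )
    elif np.isscalar(sample_gbp):
        sample_gbp = pd.Series(float(sample_gbp), index=samples)
    else:
        sample_gbp = pd.Series(sample_gbp).reindex(samples)
    if (sample_gbp <= 0).any():
        raise ValueError("sample_gbp must be positive")

    depth = (sample_gbp / ref_gbp).to_numpy()
    abund = community.virus_abundance.to_numpy()
    obs_noise = (np.exp(rng.normal(0.0, noise_sd, size=(n_v, n_s)))
                 if noise_sd > 0 else np.ones((n_v, n_s)))
    cov = abund * cov_per_unit * depth[None, :] * obs_noise
    breadth = np.minimum(1.0, 1.0 - np.exp(-0.75 * cov))

    cov_table = pd.DataFrame(
        {
            "sample_id": np.repeat(samples, n_v),
            "contig_id": np.tile(viruses, n_s),
            "length_bp": np.tile(contig_lengths.to_numpy(), n_s),
            "mean_coverage": cov.T.ravel(),
            "trimmed_mean_coverage": cov.T.ravel(),
            "breadth": breadth.T.ravel(),
        }
    )

    if marker_ids is None:
        marker_ids = DEFAULT_MARKER_IDS[:marker_count]
    if len(marker_ids) != marker_count:
        raise ValueError("marker_ids length must equal marker_count")
    total_host = community.host_abundance.to_numpy().sum(axis=0)
    m_noise = (np.exp(rng.normal(0.0, noise_sd, size=(marker_count, n_s)))
               if noise_sd > 0 else np.ones((marker_count, n_s)))
    m_cov = total_host[None, :] * marker_cov_per_unit * depth[None, :] * m_noise
    marker_table = pd.DataFrame(
        {
            "sample_id": np.repeat(samples, marker_count),
            "marker_id": np.tile(marker_ids, n_s),
            "mean_coverage": m_cov.T.ravel(),
        }
    )
    return cov_table, marker_table, sample_gbp


def asv_relative_abundance(
    community: TrueCommunity, seed: int = 0, noise_sd: float = 0.15
) -> pd.DataFrame:
    """Hosts observed as a 16S-style relative-abundance matrix (hosts x samples)."""
    rng = np.random.default_rng(seed)
    h = community.host_abundance.to_numpy()
    if noise_sd > 0:
        h = h * np.exp(rng.normal(0.0, noise_sd, size=h.shape))
    rel = h / h.sum(axis=0, keepdims=True)
    return pd.DataFrame(rel, index=community.host_abundance.index,
                        columns=community.host_abundance.columns)


AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
# rough open-ocean proteome composition; only the relative ordering matters
_BASE_FREQ = {
    "A": 0.082, "C": 0.012, "D": 0.056, "E": 0.062, "F": 0.040,
    "G": 0.071, "H": 0.021, "I": 0.062, "K": 0.056, "L": 0.093,
    "M": 0.023, "N": 0.044, "P": 0.044, "Q": 0.037, "R": 0.051,
    "S": 0.063, "T": 0.054, "V": 0.069, "W": 0.012, "Y": 0.033,
}
_ALIPHATIC = ("A", "V", "I", "L")
_POLAR_UNCHARGED = ("S", "T", "N", "Q", "C", "Y")


def gen_proteins(
    temperature_by_sample: pd.Series,
    n_proteins: int = 200,
    mean_length: int = 150,
    bias_strength: float = 0.5,
    seed: int = 0,
    temp_scale: float = 20.0,
) -> dict[str, list[tuple[str, str]]]:
    """Draw protein sequences with a temperature-dependent composition bias.

    The aliphatic residues (A, V, I, L) gain probability mass linearly with
    temperature (scaled by ``bias_strength`` per ``temp_scale`` deg C around
    the across-sample mean) while polar-uncharged residues lose the same
    mass, emulating the cold-adaptation signal of polar proteomes.  Only
    the 20 standard residues are emitted.  Returns
    ``{sample_id: [(protein_id, sequence), ...]}``.
    """
    if mean_length < 30:
        raise ValueError("mean_length must be >= 30")
    if bias_strength < 0:
        raise ValueError("bias_strength must be >= 0")
    rng = np.random.default_rng(seed)
    temps = pd.Series(temperature_by_sample, dtype=float)
    t_ref = temps.mean()
    base = np.array([_BASE_FREQ[a] for a in AA20])
    base = base / base.sum()
    ali_mask = np.isin(AA20, _ALIPHATIC)
    pol_mask = np.isin(AA20, _POLAR_UNCHARGED)
    q_ali = base[ali_mask].sum()
    q_pol = base[pol_mask].sum()

    out: dict[str, list[tuple[str, str]]] = {}
    for sample, temp in temps.items():
        delta = bias_strength * (temp - t_ref) / temp_scale
        p = base.copy()
        p[ali_mask] *= 1.0 + delta
        p[pol_mask] *= 1.0 - delta * q_ali / q_pol
        if (p < 0).any():
            warnings.warn(
                f"composition bias clipped negative probabilities in {sample}",
                RuntimeWarning, stacklevel=2,
            )
            p = np.maximum(p, 0.0)
        p = p / p.sum()
        lengths = np.maximum(30, rng.poisson(mean_length, size=n_proteins))
        residues = rng.choice(len(AA20), size=int(lengths.sum()), p=p)
        seqs = []
        pos = 0
        for j, ln in enumerate(lengths):
            seq = "".join(AA20[residues[pos:pos + ln]])
            pos += ln
            seqs.append((f"{sample}_p{j:05d}", seq))
        out[str(sample)] = seqs
    return out


def write_protein_fastas(proteins, outdir) -> list[str]:
    """Write one FASTA per sample; returns the written paths."""
    from pathlib import Path

    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for sample, seqs in proteins.items():
        records = [SeqRecord(Seq(s), id=pid, description="") for pid, s in seqs]
        path = outdir / f"proteins_{sample}.fasta"
        seqio_write(records, str(path), "fasta")
        paths.append(str(path))
    return paths


def gen_latitude_profiles(
    n_votus: int,
    frac_bimodal: float = 0.5,
    north_center: float = 61.0,
    south_center: float = -51.0,
    sd: float = 5.0,
    n_samples: int = 121,
    seed: int = 0,
    *,
    lat_min: float = -70.0,
    lat_max: float = 80.0,
    center_jitter: float = 2.0,
    noise_sd: float = 0.02,
    secondary_amp: tuple[float, float] = (0.55, 0.9),
    depth_m: float = 20.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Latitudinal coverage-per-Gbp profiles with planted uni/bimodality.

    Each vOTU's profile over a regular latitude grid is a one- or
    two-component Gaussian bump (centers jittered around the hemispheric
    defaults of 61 N and 51 S) plus truncated Gaussian noise.  A fraction
    ``frac_bimodal`` of vOTUs get one bump per hemisphere, the secondary at
    55-90% of the primary height, so the two highest peaks straddle the
    equator.  Returns (long profile table, ground-truth table).
    """
    if not 0.0 <= frac_bimodal <= 1.0:
        raise ValueError("frac_bimodal must lie in [0, 1]")
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = np.random.default_rng(seed)
    lats = np.linspace(lat_min, lat_max, n_samples)
    rows = []
    truth = []
    for i in range(n_votus):
        vid = f"V{i:04d}"
        bimodal = bool(rng.random() < frac_bimodal)
        c_n = north_center + rng.normal(0.0, center_jitter)
        c_s = south_center + rng.normal(0.0, center_jitter)
        if bimodal:
            primary_north = bool(rng.random() < 0.5)
            amp2 = rng.uniform(*secondary_amp)
            centers = [c_n, c_s]
            amps = [1.0, amp2] if primary_north else [amp2, 1.0]
        else:
            north = bool(rng.random() < 0.5)
            centers = [c_n if north else c_s]
            amps = [1.0]
        prof = np.zeros_like(lats)
        for c, a in zip(centers, amps):
            prof += a * np.exp(-((lats - c) ** 2) / (2.0 * sd**2))
        if noise_sd > 0:
            prof = prof + rng.normal(0.0, noise_sd, size=n_samples)
        prof = np.maximum(prof, 0.0)
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": [f"L{j:03d}" for j in range(n_samples)],
                    "latitude": lats,
                    "depth_m": depth_m,
                    "votu_id": vid,
                    "coverage_per_gbp": prof,
                }
            )
        )
        truth.append(
            {"votu_id": vid, "peak_latitudes": centers, "bimodal": bimodal}
        )
    return pd.concat(rows, ignore_index=True), pd.DataFrame(truth)
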