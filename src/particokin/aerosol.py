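"""Lognormal summary statistics and integral moments of binned aerosol size
distributions.

A differential-mobility sizer reports number concentrations on geometrically
spaced diameter channels.  For a nanoparticle aerosol whose number-size
distribution is lognormal, three numbers summarise it completely: the total
number concentration ``N`` (particles/cm^3), the count median diameter ``CMD``
(nm) and the geometric standard deviation ``GSD``.  Surface-area and volume
concentrations then follow from the Hatch-Choate moment relations

    S = N * pi * CMD^2 * exp(2 ln^2 GSD)          [nm^2/cm^3]
    V = N * (pi/6) * CMD^3 * exp(4.5 ln^2 GSD)    [nm^3/cm^3]

and the mass concentration from the material density,
``mass [ug/m^3] = V [nm^3/cm^3] * rho [g/cm^3] * 1e-9``.

Moments can also be accumulated bin by bin (:func:`binwise_moments`), which
serves as a model-free cross-check of the closed forms on real channel data.
Moments are computed only over the instrument range; no tail extrapolation is
performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SizeDistribution",
    "LognormalSummary",
    "AerosolConcentrations",
    "summarize_distribution",
    "hatch_choate_surface",
    "hatch_choate_volume",
    "binwise_moments",
    "mass_concentration",
    "summarize_campaign",
]

#: Mobility-sizer measurement window, nm.
DEFAULT_RANGE = (6.0, 225.0)


class InvalidDistributionError(ValueError):
    """Raised for empty, unsorted or out-of-range size distributions."""


@dataclass(frozen=True)
class LognormalSummary:
    """Three-parameter summary of a (near-)lognormal number-size distribution.

    Attributes
    ----------
    total_number : float
        Total number concentration N, particles per cm^3.
    cmd : float
        Count median diameter, nm.
    gsd : float
        Geometric standard deviation (dimensionless, >= 1; 1 = monodisperse).
    """

    total_number: float
    cmd: float
    gsd: float

    def __post_init__(self) -> None:
        if self.total_number < 0:
            raise ValueError("total_number must be >= 0")
        if self.cmd <= 0:
            raise ValueError("cmd must be > 0")
        if self.gsd < 1.0:
            raise ValueError(f"gsd must be >= 1, got {self.gsd}")


@dataclass(frozen=True)
class AerosolConcentrations:
    """Surface, volume and (density-scaled) mass concentrations of an aerosol."""

    surface_conc: float  # nm^2/cm^3
    volume_conc: float  # nm^3/cm^3
    mass_conc: float | None = None  # ug/m^3
    density: float | None = None  # g/cm^3


class SizeDistribution:
    """Binned number-size distribution: midpoint diameters and counts per bin.

    Parameters
    ----------
    diameters : array-like
        Bin representative (midpoint) diameters in nm, strictly ascending.
    counts : array-like
        Number concentration in each bin, particles per cm^3, >= 0.
    range_low, range_high : float
        Instrument measurement limits in nm; all midpoints must fall inside.
    """

    def __init__(self, diameters, counts, range_low: float = DEFAULT_RANGE[0],
                 range_high: float = DEFAULT_RANGE[1]):
        d = np.asarray(diameters, dtype=float)
        n = np.asarray(counts, dtype=float)
        if d.ndim != 1 or d.size == 0:
            raise InvalidDistributionError("need at least one size bin")
        if d.shape != n.shape:
            raise InvalidDistributionError("diameters and counts must align")
        if np.any(d <= 0):
            raise InvalidDistributionError("bin diameters must be positive")
        if np.any(np.diff(d) <= 0):
            raise InvalidDistributionError("bin diameters must be strictly ascending")
        if np.any(n < 0):
            raise InvalidDistributionError("bin counts must be non-negative")
        if d[0] < range_low or d[-1] > range_high:
            raise InvalidDistributionError(
                f"bin midpoints [{d[0]}, {d[-1]}] outside instrument range "
                f"[{range_low}, {range_high}] nm"
            )
        self.diameters = d
        self.counts = n
        self.range_low = float(range_low)
        self.range_high = float(range_high)

    def __len__(self) -> int:
        return self.diameters.size

    @classmethod
    def from_edges(cls, edges, counts, **kwargs) -> "SizeDistribution":
        """Build from bin *edges*; representative diameter is the geometric
        midpoint sqrt(lo*hi) of each channel (channels are geometrically
        spaced on a mobility sizer)."""
        e = np.asarray(edges, dtype=float)
        if np.any(e <= 0) or np.any(np.diff(e) <= 0):
            raise InvalidDistributionError("edges must be positive and ascending")
        mids = np.sqrt(e[:-1] * e[1:])
        return cls(mids, counts, **kwargs)

    @classmethod
    def from_lognormal(cls, cmd: float, gsd: float, total_number: float,
                       n_bins: int = 64, range_low: float = DEFAULT_RANGE[0],
                       range_high: float = DEFAULT_RANGE[1]) -> "SizeDistribution":
        """Discretise a lognormal(CMD, GSD) number distribution onto a
        geometric grid, allocating ``total_number`` by CDF mass per channel.

        Counts are the within-range CDF increments rescaled to sum to
        ``total_number`` (truncated-lognormal allocation), so the discrete
        distribution is exactly the instrument's view of the continuous one.
        """
        from scipy.stats import lognorm

        if gsd < 1.0:
            raise ValueError("gsd must be >= 1")
        if gsd == 1.0:
            # monodisperse: single channel at the CMD
            return cls([cmd], [total_number], range_low=range_low,
                       range_high=range_high)
        edges = np.geomspace(range_low, range_high, n_bins + 1)
        dist = lognorm(s=np.log(gsd), scale=cmd)
        cdf = dist.cdf(edges)
        mass = np.diff(cdf)
        inside = mass.sum()
        if inside <= 0:
            raise InvalidDistributionError("lognormal has no mass in range")
        counts = total_number * mass / inside
        return cls.from_edges(edges, counts, range_low=range_low,
                              range_high=range_high)

    @classmethod
    def from_csv(cls, path, diameter_col: str = "diameter_nm",
                 count_col: str = "number_per_cm3", **kwargs) -> "SizeDistribution":
        df = pd.read_csv(path)
        for col in (diameter_col, count_col):
            if col not in df.columns:
                raise InvalidDistributionError(f"missing column {col!r} in {path}")
        df = df.sort_values(diameter_col)
        return cls(df[diameter_col].to_numpy(), df[count_col].to_numpy(), **kwargs)


def summarize_distribution(dist: SizeDistribution,
                           estimator: str = "geometric_mean") -> LognormalSummary:
    """Total number, CMD and GSD of a binned distribution.

    ``estimator='geometric_mean'`` (default) takes the count-weighted geometric
    mean diameter, which equals the median for a lognormal.
    ``estimator='interpolated_median'`` locates the 50th count percentile by
    log-linear interpolation of the cumulative counts instead.
    """
    n = dist.counts
    total = float(n.sum())
    if total <= 0:
        raise InvalidDistributionError("all-zero counts: distribution is empty")
    logd = np.log(dist.diameters)
    mean_logd = float(np.sum(n * logd) / total)
    if estimator == "geometric_mean":
        cmd = float(np.exp(mean_logd))
    elif estimator == "interpolated_median":
        # cumulative count up to the *centre* of each bin; the plain cumsum
        # refers to the bin's upper edge and biases the median half a channel
        cum_mid = np.cumsum(n) - n / 2.0
        cmd = float(np.exp(np.interp(total / 2.0, cum_mid, logd)))
    else:
        raise ValueError(f"unknown CMD estimator {estimator!r}")
    var_logd = float(np.sum(n * (logd - mean_logd) ** 2) / total)
    gsd = float(np.exp(np.sqrt(var_logd)))
    return LognormalSummary(total_number=total, cmd=cmd, gsd=max(gsd, 1.0))


def hatch_choate_surface(summary: LognormalSummary) -> float:
    """Surface-area concentration N*pi*CMD^2*exp(2 ln^2 GSD), nm^2/cm^3."""
    ln2g = np.log(summary.gsd) ** 2
    return float(summary.total_number * np.pi * summary.cmd**2 * np.exp(2.0 * ln2g))


def hatch_choate_volume(summary: LognormalSummary) -> float:
    """Volume concentration N*(pi/6)*CMD^3*exp(4.5 ln^2 GSD), nm^3/cm^3."""
    ln2g = np.log(summary.gsd) ** 2
    return float(summary.total_number * np.pi / 6.0 * summary.cmd**3
                 * np.exp(4.5 * ln2g))


def binwise_moments(dist: SizeDistribution) -> AerosolConcentrations:
    """Surface and volume concentrations accumulated channel by channel,
    treating every particle in a bin as a sphere at the bin diameter."""
    d = dist.diameters
    n = dist.counts
    surface = float(np.sum(n * np.pi * d**2))
    volume = float(np.sum(n * np.pi / 6.0 * d**3))
    return AerosolConcentrations(surface_conc=surface, volume_conc=volume)


def mass_concentration(volume_conc: float, density: float) -> float:
    """Convert a volume concentration (nm^3/cm^3) to mass (ug/m^3).

    1 nm^3/cm^3 = 1e-21 cm^3/cm^3 = 1e-15 cm^3/m^3; at rho g/cm^3 that is
    rho*1e-15 g/m^3 = rho*1e-9 ug/m^3.
    """
    if volume_conc < 0 or density < 0:
        raise ValueError("volume_conc and density must be >= 0")
    return float(volume_conc * density * 1e-9)


def summarize_one(dist: SizeDistribution, density: float | None = None,
                  estimator: str = "geometric_mean") -> dict:
    """Full summary record for one distribution (keys match the CSV/JSON
    output schema)."""
    s = summarize_distribution(dist, estimator=estimator)
    surface = hatch_choate_surface(s)
    volume = hatch_choate_volume(s)
    out = {
        "total_number": s.total_number,
        "cmd_nm": s.cmd,
        "gsd": s.gsd,
        "surface_nm2_cm3": surface,
        "volume_nm3_cm3": volume,
    }
    if density is not None:
        out["density_g_cm3"] = float(density)
        out["mass_ug_m3"] = mass_concentration(volume, density)
    return out


def summarize_campaign(df: pd.DataFrame, density: float | None = None,
                       date_col: str = "date",
                       diameter_col: str = "diameter_nm",
                       count_col: str = "number_per_cm3",
                       estimator: str = "geometric_mean") -> pd.DataFrame:
    """Per-day summaries of a multi-day monitoring campaign (long format with
    a date column), plus a trailing mean/SD row across days.

    Campaign-level values are the mean +/- SD of the daily summaries, i.e. the
    convention of routine exposure-chamber reporting.
    """
    if date_col not in df.columns:
        raise InvalidDistributionError(f"campaign table needs a {date_col!r} column")
    rows = []
    for day, sub in df.groupby(date_col, sort=True):
        sub = sub.sort_values(diameter_col)
        dist = SizeDistribution(sub[diameter_col].to_numpy(),
                                sub[count_col].to_numpy())
        rec = summarize_one(dist, density=density, estimator=estimator)
        rec[date_col] = day
        rows.append(rec)
    daily = pd.DataFrame(rows).set_index(date_col)
    summary = pd.DataFrame({"mean": daily.mean(), "sd": daily.std(ddof=1)}).T
    summary.index = pd.Index(["mean", "sd"], name=date_col)
    out = pd.concat([daily, summary])
    if density is not None and "mass_ug_m3" in daily:
        # Mass here is rho * V from the size channels; filter-based gravimetric
        # or spectrometric mass can differ when the effective particle density
        # deviates from the bulk value.  Surface the assumption once.
        warnings.warn(
            "mass_ug_m3 assumes bulk material density on mobility-derived "
            "volume; independently measured mass concentrations may differ",
            stacklevel=2,
        )
    return out
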