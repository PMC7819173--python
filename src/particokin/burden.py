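"""Lung-burden tables: calibration-corrected whole-lung burdens, group
summaries, retention percentages and co-/single-exposure ratios.

The measurement chain is: lung tissue digested and analysed by ICP-MS (ng of
analyte per g of lung), corrected against a spiked-lung standard curve,
multiplied by the whole lung weight to give the whole-lung burden in ng.
Burdens are summarised per (group, analyte, timepoint) cell as mean +/- SE;
retention is expressed as a percent of the first post-exposure observation
(PEO-1) mean, and co-exposure/single-exposure burden ratios are reported
against the null expectation of 0.5 (the co-exposure aerosol carried half the
single-exposure mass concentration).

Timepoints follow the study design of a 4-week inhalation exposure: ``E-1``
(after the first 6-h exposure day, pre-baseline, excluded from kinetics) and
``PEO-1/PEO-7/PEO-28`` (1, 7 and 28 days post-exposure), mapped onto a
clearance time axis of 0, 6 and 27 days since PEO-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "DetectionLimits",
    "TIMEPOINT_DAYS",
    "recovery_percent",
    "fit_calibration",
    "correct_concentration",
    "whole_lung_burden",
    "apply_detection_limits",
    "load_burden_table",
    "group_summary",
    "retention_percent",
    "co_to_single_ratio",
]

#: Days since the PEO-1 baseline for each kinetic timepoint.
TIMEPOINT_DAYS = {"PEO-1": 0.0, "PEO-7": 6.0, "PEO-28": 27.0}

TIMEPOINT_ORDER = ["E-1", "PEO-1", "PEO-7", "PEO-28"]

REQUIRED_COLUMNS = ["animal_id", "group", "analyte", "timepoint",
                    "tissue_conc_ng_g", "lung_weight_g"]


def recovery_percent(measured: float, spiked: float) -> float:
    """Digestion/assay recovery: 100 * measured / spiked (both ng/g)."""
    if spiked <= 0:
        raise ValueError("spiked concentration must be > 0")
    if measured < 0:
        raise ValueError("measured concentration must be >= 0")
    return 100.0 * measured / spiked


@dataclass(frozen=True)
class CalibrationCurve:
    """Spiked-lung standard curve ``measured = slope * spiked + intercept``.

    ``valid_range`` is the spiked-concentration interval covered by the
    standards; corrections outside it are flagged as extrapolation.
    """

    analyte: str
    slope: float
    intercept: float
    valid_range: tuple[float, float]
    points: tuple = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be > 0")

    def correct(self, raw, clamp: bool = True):
        return correct_concentration(raw, self, clamp=clamp)


def fit_calibration(points, analyte: str = "") -> CalibrationCurve:
    """Ordinary least-squares line through (spiked, measured) standards.

    Parameters
    ----------
    points : sequence of (spiked_ng_g, measured_ng_g)
        At least two distinct spiked levels.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need >= 2 (spiked, measured) points")
    spiked, measured = pts[:, 0], pts[:, 1]
    if np.unique(spiked).size < 2:
        raise ValueError("need >= 2 distinct spiked levels to fit a line")
    res = stats.linregress(spiked, measured)
    return CalibrationCurve(
        analyte=analyte,
        slope=float(res.slope),
        intercept=float(res.intercept),
        valid_range=(float(spiked.min()), float(spiked.max())),
        points=tuple(map(tuple, pts)),
    )


def correct_concentration(raw, curve: CalibrationCurve, clamp: bool = True):
    """Invert the standard curve: corrected = (raw - intercept) / slope.

    Negative corrected values (raw below the curve intercept) are clamped to 0
    and flagged as censored.  Returns ``(corrected, flags)`` where flags is a
    DataFrame-friendly record of censoring/extrapolation, or a scalar pair for
    scalar input.
    """
    raw_arr = np.atleast_1d(np.asarray(raw, dtype=float))
    corrected = (raw_arr - curve.intercept) / curve.slope
    lo, hi = curve.valid_range
    fitted_lo = curve.slope * lo + curve.intercept
    fitted_hi = curve.slope * hi + curve.intercept
    out_of_range = (raw_arr < min(fitted_lo, fitted_hi)) | \
                   (raw_arr > max(fitted_lo, fitted_hi))
    censored = corrected < 0
    if clamp:
        corrected = np.maximum(corrected, 0.0)
    flags = pd.DataFrame({"censored": censored, "out_of_range": out_of_range})
    if np.isscalar(raw) or np.asarray(raw).ndim == 0:
        return float(corrected[0]), flags.iloc[0].to_dict()
    return corrected, flags


def whole_lung_burden(tissue_conc, lung_weight):
    """Whole-lung burden (ng) = tissue concentration (ng/g) x lung weight (g)."""
    conc = np.asarray(tissue_conc, dtype=float)
    wt = np.asarray(lung_weight, dtype=float)
    if np.any(wt <= 0):
        raise ValueError("lung weight must be > 0")
    if np.any(conc < 0):
        raise ValueError("tissue concentration must be >= 0")
    out = conc * wt
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DetectionLimits:
    """Assay limit of detection / quantification (solution scale, ug/L)."""

    analyte: str
    lod: float
    loq: float

    def __post_init__(self) -> None:
        if not (0 < self.lod < self.loq):
            raise ValueError("need 0 < LOD < LOQ")


#: Published assay limits for the two analytes, ug/L.
DEFAULT_LIMITS = {
    "Ag": DetectionLimits("Ag", lod=0.086, loq=0.260),
    "Au": DetectionLimits("Au", lod=0.027, loq=0.082),
}


def apply_detection_limits(value, limits: DetectionLimits, rule: str = "half_lod"):
    """Censor solution-scale values against the assay LOD/LOQ.

    Values below the LOD are non-detects and substituted per ``rule``
    ('half_lod' (default), 'zero' or 'lod'); values in [LOD, LOQ) are retained
    but flagged below-quantification.  Returns ``(values, flags)`` with flags
    in {'ok', 'below_loq', 'non_detect'}.
    """
    substitutes = {"half_lod": limits.lod / 2.0, "zero": 0.0, "lod": limits.lod}
    if rule not in substitutes:
        raise ValueError(f"unknown substitution rule {rule!r}")
    vals = np.atleast_1d(np.asarray(value, dtype=float)).copy()
    flags = np.full(vals.shape, "ok", dtype=object)
    below_loq = (vals >= limits.lod) & (vals < limits.loq)
    non_detect = vals < limits.lod
    flags[below_loq] = "below_loq"
    flags[non_detect] = "non_detect"
    vals[non_detect] = substitutes[rule]
    if np.isscalar(value) or np.asarray(value).ndim == 0:
        return float(vals[0]), str(flags[0])
    return vals, flags


def load_burden_table(path_or_df, curve: CalibrationCurve | None = None,
                      curves: dict | None = None) -> pd.DataFrame:
    """Read a per-animal burden CSV and derive whole-lung burdens.

    Expected columns: ``animal_id, group, analyte, timepoint,
    tissue_conc_ng_g, lung_weight_g``.  If calibration curves are supplied
    (one, or a dict keyed by analyte), tissue concentrations are corrected
    through them before the burden is formed.
    """
    df = (path_or_df.copy() if isinstance(path_or_df, pd.DataFrame)
          else pd.read_csv(path_or_df))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"burden table missing columns: {missing}")
    conc = df["tissue_conc_ng_g"].to_numpy(dtype=float)
    if curve is not None or curves is not None:
        corrected = np.empty_like(conc)
        cens = np.zeros(conc.shape, dtype=bool)
        for analyte, idx in df.groupby("analyte").groups.items():
            c = curves.get(analyte) if curves is not None else curve
            if c is None:
                corrected[df.index.get_indexer(idx)] = conc[df.index.get_indexer(idx)]
                continue
            loc = df.index.get_indexer(idx)
            vals, flags = correct_concentration(conc[loc], c)
            corrected[loc] = vals
            cens[loc] = flags["censored"].to_numpy()
        df["tissue_conc_ng_g"] = corrected
        df["censored"] = cens
    df["whole_lung_burden_ng"] = whole_lung_burden(
        df["tissue_conc_ng_g"], df["lung_weight_g"])
    return df


def group_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SE of whole-lung burden per (group, analyte, timepoint) cell.

    SE = sd / sqrt(n) with ddof=1; single-animal cells report SE 0 with an
    ``se_undefined`` flag rather than NaN.
    """
    if "whole_lung_burden_ng" not in records.columns:
        records = load_burden_table(records)
    rows = []
    for (group, analyte, tp), sub in records.groupby(
            ["group", "analyte", "timepoint"], sort=False):
        burdens = sub["whole_lung_burden_ng"].to_numpy(dtype=float)
        n = burdens.size
        mean = float(burdens.mean())
        if n > 1:
            se = float(burdens.std(ddof=1) / np.sqrt(n))
            undefined = False
        else:
            se, undefined = 0.0, True
        rows.append({"group": group, "analyte": analyte, "timepoint": tp,
                     "n": n, "mean_burden_ng": mean, "se_burden_ng": se,
                     "se_undefined": undefined})
    out = pd.DataFrame(rows)
    out["timepoint"] = pd.Categorical(out["timepoint"], TIMEPOINT_ORDER,
                                      ordered=True)
    return out.sort_values(["analyte", "group", "timepoint"]).reset_index(drop=True)


def _cell(summaries: pd.DataFrame, group: str, analyte: str, timepoint: str):
    m = summaries[(summaries["group"] == group)
                  & (summaries["analyte"] == analyte)
                  & (summaries["timepoint"] == timepoint)]
    if m.empty:
        return None
    return m.iloc[0]


def retention_percent(summaries: pd.DataFrame, group: str, analyte: str,
                      baseline: str = "PEO-1",
                      records: pd.DataFrame | None = None,
                      mode: str = "ratio_of_means") -> pd.DataFrame:
    """Retention as a percent of the baseline (PEO-1) burden.

    ``mode='ratio_of_means'`` (default) divides each timepoint's mean burden
    by the baseline mean; its SE is the timepoint SE scaled by the baseline
    mean (the baseline is treated as the fixed reference, so retention at
    baseline is exactly 100 +/- 0).  ``mode='mean_of_ratios'`` forms
    per-animal ratios against rank-matched baseline animals and averages them
    (requires ``records``); animals are destructively sampled, so the rank
    pairing is an approximation.

    The pre-baseline E-1 timepoint is excluded.
    """
    base = _cell(summaries, group, analyte, baseline)
    if base is None or base["mean_burden_ng"] <= 0:
        raise ValueError(f"baseline cell {group}/{analyte}/{baseline} missing "
                         "or non-positive")
    m0 = base["mean_burden_ng"]
    rows = []
    for tp in TIMEPOINT_DAYS:
        cell = _cell(summaries, group, analyte, tp)
        if cell is None:
            continue
        if mode == "ratio_of_means":
            pct = 100.0 * cell["mean_burden_ng"] / m0
            se = 0.0 if tp == baseline else 100.0 * cell["se_burden_ng"] / m0
        elif mode == "mean_of_ratios":
            if records is None:
                raise ValueError("mean_of_ratios mode needs per-animal records")
            ratios = _paired_ratios(records, group, analyte, tp,
                                    group, analyte, baseline)
            pct = 100.0 * float(np.mean(ratios))
            se = (0.0 if tp == baseline or ratios.size < 2
                  else 100.0 * float(np.std(ratios, ddof=1) / np.sqrt(ratios.size)))
            if tp == baseline:
                pct = 100.0
        else:
            raise ValueError(f"unknown retention mode {mode!r}")
        rows.append({"group": group, "analyte": analyte, "timepoint": tp,
                     "days": TIMEPOINT_DAYS[tp], "retention_pct": pct,
                     "se_pct": se})
    return pd.DataFrame(rows)


def _paired_ratios(records: pd.DataFrame, g_num, a_num, t_num,
                   g_den, a_den, t_den) -> np.ndarray:
    num = np.sort(records[(records["group"] == g_num)
                          & (records["analyte"] == a_num)
                          & (records["timepoint"] == t_num)]
                  ["whole_lung_burden_ng"].to_numpy(dtype=float))
    den = np.sort(records[(records["group"] == g_den)
                          & (records["analyte"] == a_den)
                          & (records["timepoint"] == t_den)]
                  ["whole_lung_burden_ng"].to_numpy(dtype=float))
    if num.size == 0 or den.size == 0:
        raise ValueError("empty cell in per-animal ratio computation")
    k = max(num.size, den.size)
    num = num[np.arange(k) % num.size]
    den = den[np.arange(k) % den.size]
    if np.any(den <= 0):
        raise ValueError("non-positive denominator burden in per-animal ratio")
    return num / den


def co_to_single_ratio(summaries: pd.DataFrame, analyte: str,
                       co_group: str = "AuNP+AgNP",
                       single_group: str | None = None,
                       records: pd.DataFrame | None = None,
                       mode: str = "ratio_of_means",
                       null_expectation: float = 0.5) -> pd.DataFrame:
    """Co-exposure/single-exposure burden ratio per timepoint.

    With equal deposition and unchanged kinetics, halving the exposure
    concentration halves the burden, so the null expectation is 0.5.  The
    default is the ratio of cell means with a delta-method SE; per-animal
    rank-paired ratios are available via ``mode='mean_of_ratios'``.
    """
    single_group = single_group or f"{analyte}NP"
    rows = []
    for tp in TIMEPOINT_ORDER:
        co = _cell(summaries, co_group, analyte, tp)
        single = _cell(summaries, single_group, analyte, tp)
        if co is None or single is None:
            continue
        if single["mean_burden_ng"] <= 0:
            raise ValueError(f"single-exposure mean is non-positive at {tp}")
        if mode == "ratio_of_means":
            ratio = co["mean_burden_ng"] / single["mean_burden_ng"]
            # first-order (delta-method) propagation of the two cell SEs
            rel = np.hypot(co["se_burden_ng"] / co["mean_burden_ng"]
                           if co["mean_burden_ng"] > 0 else 0.0,
                           single["se_burden_ng"] / single["mean_burden_ng"])
            se = float(ratio * rel)
        elif mode == "mean_of_ratios":
            if records is None:
                raise ValueError("mean_of_ratios mode needs per-animal records")
            ratios = _paired_ratios(records, co_group, analyte, tp,
                                    single_group, analyte, tp)
            ratio = float(np.mean(ratios))
            se = (float(np.std(ratios, ddof=1) / np.sqrt(ratios.size))
                  if ratios.size > 1 else 0.0)
        else:
            raise ValueError(f"unknown ratio mode {mode!r}")
        rows.append({"analyte": analyte, "timepoint": tp, "ratio": float(ratio),
                     "se_ratio": se, "null_expectation": null_expectation})
    if not rows:
        raise ValueError("no matched co/single timepoints found")
    return pd.DataFrame(rows)
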