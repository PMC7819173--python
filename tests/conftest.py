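import numpy as np
import pandas as pd
import pytest

from particokin.kinetics import LN2


@pytest.fixture
def au_single_retention():
    """Mean Au retention fractions after single exposure (days since PEO-1)."""
    return np.array([0.0, 6.0, 27.0]), np.array([1.0, 0.901, 0.785])


@pytest.fixture
def au_co_retention():
    return np.array([0.0, 6.0, 27.0]), np.array([1.0, 0.870, 0.682])


@pytest.fixture
def ag_single_retention():
    return np.array([0.0, 6.0, 27.0]), np.array([1.0, 0.694, 0.450])


@pytest.fixture
def ag_co_retention():
    return np.array([0.0, 6.0, 27.0]), np.array([1.0, 0.528, 0.274])


def make_burden_frame(cells, seed=0):
    """Build a per-animal burden DataFrame from {(group, analyte, timepoint):
    [burden, ...]} with unit lung weights (burden == concentration)."""
    rows = []
    for (group, analyte, tp), burdens in cells.items():
        for i, b in enumerate(burdens):
            rows.append({"animal_id": f"{group}-{analyte}-{tp}-{i}",
                         "group": group, "analyte": analyte, "timepoint": tp,
                         "tissue_conc_ng_g": float(b), "lung_weight_g": 1.0})
    return pd.DataFrame(rows)


@pytest.fixture
def table2_like_means():
    """Single-animal-per-cell table carrying the published group mean burdens,
    so ratio-of-means arithmetic can be checked exactly."""
    cells = {
        ("AuNP", "Au", "E-1"): [466.0],
        ("AuNP", "Au", "PEO-1"): [8930.0],
        ("AuNP", "Au", "PEO-7"): [8048.0],
        ("AuNP", "Au", "PEO-28"): [7010.0],
        ("AuNP+AgNP", "Au", "E-1"): [313.0],
        ("AuNP+AgNP", "Au", "PEO-1"): [3607.0],
        ("AuNP+AgNP", "Au", "PEO-7"): [3137.0],
        ("AuNP+AgNP", "Au", "PEO-28"): [2458.0],
        ("AgNP", "Ag", "E-1"): [47.0],
        ("AgNP", "Ag", "PEO-1"): [129.0],
        ("AgNP", "Ag", "PEO-7"): [90.0],
        ("AgNP", "Ag", "PEO-28"): [58.0],
        ("AuNP+AgNP", "Ag", "E-1"): [23.0],
        ("AuNP+AgNP", "Ag", "PEO-1"): [137.0],
        ("AuNP+AgNP", "Ag", "PEO-7"): [72.0],
        ("AuNP+AgNP", "Ag", "PEO-28"): [37.0],
    }
    return make_burden_frame(cells)


def geometric_deposition_sum(daily_deposit, lam, exposure_days, sample_day):
    """Independent closed-form burden at sample_day: each exposure day's
    deposit decayed exponentially for the elapsed days."""
    return sum(daily_deposit * np.exp(-lam * (sample_day - e))
               for e in exposure_days if e <= sample_day)


LN2 = LN2
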