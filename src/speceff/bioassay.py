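"""Bioactivity endpoint computation.

Closed-form assay statistics (DPPH/ABTS radical scavenging, alpha-glucosidase
and lipase inhibition, cellular antioxidant activity units), calibration-line
quantification, four-parameter-logistic (4PL) EC50 estimation, and assembly
of the samples x endpoints activity matrix used as the Y-block of the
spectrum-effect models.

Scavenging and inhibition values outside [0, 100] are reported as computed
(with a warning), never clamped: the formulas permit them and silent clamping
would hide assay problems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


@dataclass(frozen=True)
class CalibrationLine:
    """A linear standard curve ``absorbance = slope * concentration + intercept``."""

    slope: float
    intercept: float
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be non-zero")


# Printed standard curves for quantification of total phenolics (chlorogenic
# acid equivalents) and total flavonoids (rutin equivalents).
CHLOROGENIC_ACID_CALIBRATION = CalibrationLine(1.323, -0.0869, 0.9923)
RUTIN_CALIBRATION = CalibrationLine(0.7604, -0.2294, 0.9889)


@dataclass
class DoseResponseData:
    """Doses (mg/mL, strictly positive) with percent responses."""

    doses: np.ndarray
    responses: np.ndarray
    replicate_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.shape != self.responses.shape:
            raise ValueError("doses and responses must have equal length")
        if np.any(self.doses <= 0):
            raise ValueError("doses must be strictly positive")


@dataclass(frozen=True)
class DoseResponseFit:
    ec50: float
    hill: float
    floor: float
    ceiling: float
    residual_sse: float
    converged: bool

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("EC50 must be positive")


@dataclass
class CAAKinetics:
    """Fluorescence kinetics for the cellular antioxidant activity assay.

    ``sample_fluorescence`` is the extract-treated (SA) curve and
    ``control_fluorescence`` the oxidant-only control (CA) curve, both read
    on the same time grid (the assay records every 5 min for 1 h).
    """

    time: np.ndarray
    sample_fluorescence: np.ndarray
    control_fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.sample_fluorescence = np.asarray(self.sample_fluorescence, dtype=float)
        self.control_fluorescence = np.asarray(self.control_fluorescence, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        for arr in (self.sample_fluorescence, self.control_fluorescence):
            if arr.shape != self.time.shape:
                raise ValueError("fluorescence curves must match the time grid")
            if np.any(arr < 0):
                raise ValueError("fluorescence must be non-negative")


def radical_scavenging(a_blank: float, a_sample: float) -> float:
    """Percent radical scavenging, ``100 * (1 - B/A)``.

    ``A`` is the blank absorbance and ``B`` the sample absorbance; the same
    form applies to the DPPH (517 nm) and ABTS (734 nm) assays.
    """
    if a_blank == 0:
        raise ZeroDivisionError("blank absorbance is zero: scavenging undefined")
    value = 100.0 * (1.0 - a_sample / a_blank)
    if not 0.0 <= value <= 100.0:
        warnings.warn(
            f"scavenging {value:.2f}% outside [0, 100]; reporting as computed",
            stacklevel=2,
        )
    return value


def enzyme_inhibition(a_s: float, a_n: float, a_c: float) -> float:
    """Percent enzyme inhibition, ``[1 - (As - An)/Ac] * 100``.

    As: enzyme + extract + substrate; An: extract + substrate (no enzyme);
    Ac: enzyme + substrate (no extract).  Shared by the alpha-glucosidase
    (GIA) and pancreatic-lipase assays, which use the identical formula.
    """
    if a_c == 0:
        raise ZeroDivisionError("substrate control absorbance is zero")
    value = (1.0 - (a_s - a_n) / a_c) * 100.0
    if not 0.0 <= value <= 100.0:
        warnings.warn(
            f"inhibition {value:.2f}% outside [0, 100]; reporting as computed",
            stacklevel=2,
        )
    return value


def caa_unit(kinetics: CAAKinetics) -> float:
    """Cellular antioxidant activity, ``1 - integral(SA)/integral(CA)``.

    Areas are trapezoidal integrals of the fluorescence curves over the
    recorded time grid.  Invariant to rescaling both curves by the same
    positive constant.
    """
    ca = float(np.trapezoid(kinetics.control_fluorescence, kinetics.time))
    if ca <= 0:
        raise ValueError("control curve area is zero: CAA unit undefined")
    sa = float(np.trapezoid(kinetics.sample_fluorescence, kinetics.time))
    return 1.0 - sa / ca


def apply_calibration(absorbance, line: CalibrationLine):
    """Invert a standard curve: concentration = (absorbance - intercept)/slope."""
    return (np.asarray(absorbance, dtype=float) - line.intercept) / line.slope


def four_pl(dose, floor: float, ceiling: float, ec50: float, hill: float):
    """4PL response ``floor + (ceiling - floor) / (1 + (ec50/dose)^hill)``."""
    dose = np.asarray(dose, dtype=float)
    return floor + (ceiling - floor) / (1.0 + (ec50 / dose) ** hill)


def _interp_ec50(doses: np.ndarray, responses: np.ndarray) -> float:
    """Linear-interpolation crossing of the half-maximal response on log dose."""
    order = np.argsort(doses)
    d, r = np.log(doses[order]), responses[order]
    # average replicates at identical doses
    du, inv = np.unique(d, return_inverse=True)
    ru = np.bincount(inv, weights=r) / np.bincount(inv)
    half = (ru.min() + ru.max()) / 2.0
    sign = np.sign(ru - half)
    for i in range(len(du) - 1):
        if sign[i] == 0:
            return float(np.exp(du[i]))
        if sign[i] != sign[i + 1]:
            frac = (half - ru[i]) / (ru[i + 1] - ru[i])
            return float(np.exp(du[i] + frac * (du[i + 1] - du[i])))
    return float(np.exp(np.median(du)))


def fit_dose_response(
    data: DoseResponseData, method: str = "4pl"
) -> DoseResponseFit:
    """Estimate the EC50 from a dose-response curve.

    ``method="4pl"`` (default) fits the four-parameter logistic by nonlinear
    least squares with the EC50 parameterized on log dose, initialized from
    the linear-interpolation crossing of the half-maximal response.
    ``method="interpolate"`` returns the interpolation crossing alone (the
    "intermediate effect" reading), with hill reported as NaN.
    """
    doses, resp = data.doses, data.responses
    if np.unique(doses).size < 4:
        raise ValueError("at least 4 distinct doses are required")

    ec50_0 = _interp_ec50(doses, resp)
    if method == "interpolate":
        lo, hi = float(resp.min()), float(resp.max())
        mid = (lo + hi) / 2.0
        sse = float(np.sum((resp - mid) ** 2))
        return DoseResponseFit(ec50_0, float("nan"), lo, hi, sse, True)
    if method != "4pl":
        raise ValueError(f"unknown method {method!r}")

    log_d = np.log(doses)

    def residuals(theta):
        floor, ceiling, log_ec50, hill = theta
        pred = floor + (ceiling - floor) / (1.0 + np.exp(hill * (log_ec50 - log_d)))
        return pred - resp

    theta0 = np.array([resp.min(), resp.max(), np.log(ec50_0), 1.0])
    res = least_squares(residuals, theta0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    floor, ceiling, log_ec50, hill = res.x
    if hill < 0:  # equivalent curve with roles of floor/ceiling swapped
        floor, ceiling, hill = ceiling, floor, -hill
    if floor > ceiling:
        floor, ceiling = ceiling, floor
    return DoseResponseFit(
        ec50=float(np.exp(log_ec50)),
        hill=float(hill),
        floor=float(floor),
        ceiling=float(ceiling),
        residual_sse=float(2 * res.cost),
        converged=bool(res.success),
    )


#: endpoint orientation: does a larger raw value mean more activity?
DEFAULT_ORIENTATIONS = {
    "dpph_ec50": "lower",
    "abts_ec50": "lower",
    "caa_ec50": "lower",
    "frap": "higher",
    "caa_unit": "higher",
    "glucosidase_inhibition": "higher",
    "lipase_inhibition": "higher",
}


def build_activity_matrix(
    results: Mapping[str, Mapping[str, float]] | pd.DataFrame,
    orientations: Mapping[str, str] | None = None,
    harmonise: str = "reciprocal",
) -> pd.DataFrame:
    """Assemble the samples x endpoints Y-matrix for modeling.

    ``results`` maps sample id -> endpoint -> value (or is already a
    DataFrame).  Every sample must report every endpoint; gaps raise an error
    naming the sample and endpoint.  Endpoints declared "lower = more active"
    (EC50-type) are harmonised so that larger always means more active:
    ``reciprocal`` replaces them by 1/value, ``negate`` by -value, ``none``
    leaves them untouched.
    """
    if isinstance(results, pd.DataFrame):
        df = results.astype(float).copy()
    else:
        df = pd.DataFrame.from_dict(results, orient="index").astype(float)
    endpoints = list(df.columns)
    missing = [
        (str(s), str(e)) for s in df.index for e in endpoints if pd.isna(df.loc[s, e])
    ]
    if missing:
        gaps = ", ".join(f"{s}:{e}" for s, e in missing)
        raise ValueError(f"missing endpoint values for {gaps}")
    if orientations is None:
        orientations = DEFAULT_ORIENTATIONS
    if harmonise not in ("reciprocal", "negate", "none"):
        raise ValueError(f"unknown harmonisation {harmonise!r}")
    if harmonise != "none":
        for e in endpoints:
            if orientations.get(e, "higher") == "lower":
                df[e] = 1.0 / df[e] if harmonise == "reciprocal" else -df[e]
    return df


def read_assay_wells(path) -> pd.DataFrame:
    """Read a plate export: one row per well (sample_id, role, concentration, reading).

    ``role`` must be one of blank/control/sample.
    """
    df = pd.read_csv(path)
    required = {"sample_id", "role", "concentration", "reading"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assay CSV is missing columns: {sorted(missing)}")
    bad = set(df["role"].unique()) - {"blank", "control", "sample"}
    if bad:
        raise ValueError(f"unknown well roles: {sorted(bad)}")
    return df


def scavenging_from_wells(wells: pd.DataFrame) -> pd.DataFrame:
    """Per-sample scavenging percentages from well-level readings.

    The blank absorbance A is the mean of the blank wells; each sample well's
    reading is B.  Returns one row per (sample_id, concentration) with the
    mean scavenging over replicate wells.
    """
    blank = wells.loc[wells["role"] == "blank", "reading"].mean()
    if not np.isfinite(blank) or blank == 0:
        raise ValueError("no usable blank wells: blank absorbance undefined")
    rows = wells[wells["role"] == "sample"].copy()
    rows["scavenging_pct"] = 100.0 * (1.0 - rows["reading"] / blank)
    return (
        rows.groupby(["sample_id", "concentration"], as_index=False)[
            "scavenging_pct"
        ].mean()
    )
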