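"""Gas-chromatography quantification and rate estimation.

Covers the wet-lab arithmetic around the SIP incubations and isolate
assays: DMS calibration curves and detection limits, initial-rate
estimation from substrate/product time courses, conversion of consumed
substrate to assimilated carbon, per-protein DMS production rates, and
growth calls on OD600 triplicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DMS_HEADSPACE_DETECTION_LIMIT_PMOL",
    "DMS_DETECTION_LIMIT_NMOL",
    "MESH_DETECTION_LIMIT_NMOL",
    "MIXED_CARBON_SOURCE_MM",
    "mixed_carbon_total_mM",
    "TimeCourse",
    "CalibrationCurve",
    "RateEstimate",
    "GrowthAssay",
    "GrowthCall",
    "Quantification",
    "SingularFitError",
    "InsufficientDataError",
    "fit_calibration",
    "read_calibration",
    "read_assays",
    "quantify",
    "initial_rate",
    "assimilated_carbon",
    "production_rate",
    "growth_call",
]

#: Detection limit for DMS in vial headspace (pmol).
DMS_HEADSPACE_DETECTION_LIMIT_PMOL = 0.8
#: Detection limits for DMS and methanethiol in incubation monitoring (nmol).
DMS_DETECTION_LIMIT_NMOL = 0.15
MESH_DETECTION_LIMIT_NMOL = 4.0

#: Mixed carbon source supplement of the marine basal medium: five
#: components at 2 mM each.
MIXED_CARBON_SOURCE_MM = {
    "glucose": 2.0,
    "succinate": 2.0,
    "sucrose": 2.0,
    "pyruvate": 2.0,
    "glycerol": 2.0,
}


def mixed_carbon_total_mM() -> float:
    """Total concentration of the mixed-carbon supplement (mM)."""
    return float(sum(MIXED_CARBON_SOURCE_MM.values()))


class SingularFitError(ValueError):
    """Calibration cannot be fit or inverted (degenerate standards/slope)."""


class InsufficientDataError(ValueError):
    """Fewer usable observations than the operation requires."""


@dataclass
class TimeCourse:
    """Substrate and volatile-product concentrations over an incubation."""

    time_h: np.ndarray
    dmsp_uM: np.ndarray
    dms_uM: np.ndarray
    mesh_uM: np.ndarray | None = None
    replicate: str = "rep1"

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.dmsp_uM = np.asarray(self.dmsp_uM, dtype=float)
        self.dms_uM = np.asarray(self.dms_uM, dtype=float)
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("times must be strictly increasing")

    def series(self, analyte: str) -> np.ndarray:
        try:
            return {"dmsp": self.dmsp_uM, "dms": self.dms_uM, "mesh": self.mesh_uM}[
                analyte
            ]
        except KeyError:
            raise ValueError(f"unknown analyte {analyte!r}") from None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"time_h": self.time_h, "dmsp_uM": self.dmsp_uM, "dms_uM": self.dms_uM}
        )
        if self.mesh_uM is not None:
            df["mesh_uM"] = self.mesh_uM
        df["replicate"] = self.replicate
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, replicate: str = "rep1") -> "TimeCourse":
        return cls(
            time_h=df["time_h"].to_numpy(),
            dmsp_uM=df["dmsp_uM"].to_numpy(),
            dms_uM=df["dms_uM"].to_numpy(),
            mesh_uM=df["mesh_uM"].to_numpy() if "mesh_uM" in df else None,
            replicate=replicate,
        )


@dataclass
class CalibrationCurve:
    """OLS line through (amount, response) standards."""

    standards: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    detection_limit: float


@dataclass
class Quantification:
    amount: float
    below_detection: bool


@dataclass
class RateEstimate:
    """Regression-based rate with its standard error and fitting window."""

    value: float
    standard_error: float
    window: tuple[float, float]
    n_points: int
    direction: str  # "removal", "production" or "none"
    units: str = "uM/h"


@dataclass
class GrowthAssay:
    """OD600 readings for one strain across the three growth arms."""

    od_no_carbon: np.ndarray
    od_substrate: np.ndarray
    od_mixed_carbon: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.od_no_carbon = np.asarray(self.od_no_carbon, dtype=float)
        self.od_substrate = np.asarray(self.od_substrate, dtype=float)
        for arm in (self.od_no_carbon, self.od_substrate):
            if arm.size < 2:
                raise ValueError("each assay arm needs at least 2 observations")
            if np.any(arm < 0):
                raise ValueError("OD600 must be >= 0")


@dataclass
class GrowthCall:
    grows: bool
    p_value: float
    t_statistic: float


def fit_calibration(
    standards, detection_limit: float = DMS_HEADSPACE_DETECTION_LIMIT_PMOL
) -> CalibrationCurve:
    """Fit response = slope * amount + intercept through the standards.

    ``standards`` is an iterable of (amount_pmol, response) pairs; at
    least two distinct amounts are required.
    """
    pts = np.asarray(standards, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise SingularFitError("need at least 2 (amount, response) standards")
    if np.unique(pts[:, 0]).size < 2:
        raise SingularFitError("standards must span at least 2 distinct amounts")
    fit = stats.linregress(pts[:, 0], pts[:, 1])
    return CalibrationCurve(
        standards=pts,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        detection_limit=detection_limit,
    )


def quantify(response: float, calibration: CalibrationCurve) -> Quantification:
    """Invert the calibration line and flag below-detection amounts."""
    if calibration.slope == 0:
        raise SingularFitError("calibration slope is zero; cannot invert")
    amount = (response - calibration.intercept) / calibration.slope
    return Quantification(
        amount=float(amount), below_detection=amount < calibration.detection_limit
    )


def initial_rate(
    timecourse: TimeCourse,
    analyte: str = "dmsp",
    window: tuple[float, float] = (0.0, 48.0),
    method: str = "regression",
) -> RateEstimate:
    """Estimate the initial removal/production rate of an analyte.

    Fits an OLS slope of concentration vs time over ``window`` (default
    the first 48 h).  Rates are reported as positive magnitudes with the
    direction recorded: a negative slope is a removal, a positive slope a
    production.  ``method="endpoint"`` uses the plain first/last
    difference quotient instead (its SE is undefined and reported as
    NaN).  Missing values are dropped pairwise.
    """
    conc = timecourse.series(analyte)
    if conc is None:
        raise InsufficientDataError(f"no {analyte} data in time course")
    t = timecourse.time_h
    mask = (t >= window[0]) & (t <= window[1]) & np.isfinite(conc)
    if mask.sum() < 2:
        raise InsufficientDataError(
            f"need >= 2 points with {analyte} data in window {window}"
        )
    tw, cw = t[mask], conc[mask]
    if method == "regression":
        if np.allclose(cw, cw[0]):
            slope, se = 0.0, 0.0
        else:
            fit = stats.linregress(tw, cw)
            slope, se = float(fit.slope), float(fit.stderr)
            if not np.isfinite(se):  # 2-point fit: slope exact, SE undefined
                se = 0.0
    elif method == "endpoint":
        slope = float((cw[-1] - cw[0]) / (tw[-1] - tw[0]))
        se = float("nan")
    else:
        raise ValueError(f"unknown method {method!r}")
    if slope < 0:
        direction = "removal"
    elif slope > 0:
        direction = "production"
    else:
        direction = "none"
    return RateEstimate(
        value=abs(slope),
        standard_error=se,
        window=window,
        n_points=int(mask.sum()),
        direction=direction,
    )


def assimilated_carbon(
    delta_substrate_umol_per_L: float, labeled_atoms_per_molecule: int
) -> float:
    """Carbon assimilated (umol C / L) from consumed substrate.

    Each consumed molecule contributes its labelled-moiety carbons; for
    propionate-labelled DMSP that is 3 carbons per molecule.
    """
    if delta_substrate_umol_per_L < 0 or labeled_atoms_per_molecule < 0:
        raise ValueError("inputs must be >= 0")
    return float(delta_substrate_umol_per_L * labeled_atoms_per_molecule)


def production_rate(analyte_nmol: float, protein_mg: float, hours: float) -> float:
    """Specific production rate in nmol per mg protein per hour."""
    if protein_mg <= 0 or hours <= 0:
        raise ValueError("protein_mg and hours must be positive")
    if analyte_nmol < 0:
        raise ValueError("analyte_nmol must be >= 0")
    return float(analyte_nmol / (protein_mg * hours))


def read_calibration(path, detection_limit: float = DMS_HEADSPACE_DETECTION_LIMIT_PMOL):
    """Fit a calibration from a calibration.tsv (amount_pmol, response)."""
    df = pd.read_csv(path, sep="\t")
    return fit_calibration(
        df[["amount_pmol", "response"]].to_numpy(), detection_limit=detection_limit
    )


def read_assays(path) -> dict[str, GrowthAssay]:
    """Read assays.tsv (strain, arm, replicate, od600) into per-strain assays.

    Arms are named ``no_carbon``, ``substrate`` and ``mixed_carbon``.
    """
    df = pd.read_csv(path, sep="\t")
    assays = {}
    for strain, sub in df.groupby("strain"):
        arms = {arm: g["od600"].to_numpy() for arm, g in sub.groupby("arm")}
        assays[str(strain)] = GrowthAssay(
            od_no_carbon=arms["no_carbon"],
            od_substrate=arms["substrate"],
            od_mixed_carbon=arms.get("mixed_carbon"),
        )
    return assays


def growth_call(
    assay: GrowthAssay, alpha: float = 0.05, alternative: str = "greater"
) -> GrowthCall:
    """Test whether a strain grew on the substrate.

    Classical equal-variance two-sample t-test of the substrate arm
    against the no-carbon arm, one-sided (greater) by default since
    growth is directional.  Both arms identical with zero variance is a
    non-call (p = 1).
    """
    a, b = assay.od_substrate, assay.od_no_carbon
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return GrowthCall(grows=False, p_value=1.0, t_statistic=0.0)
    t, p = stats.ttest_ind(a, b, equal_var=True, alternative=alternative)
    if not np.isfinite(p):
        return GrowthCall(grows=False, p_value=1.0, t_statistic=0.0)
    return GrowthCall(grows=bool(p < alpha), p_value=float(p), t_statistic=float(t))
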