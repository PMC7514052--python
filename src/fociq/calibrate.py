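"""Fluorescence-intensity calibration into transcript counts.

Small sarcoplasmic foci are single transcripts, so their mean
(background-subtracted) integrated intensity is the single-transcript
unit; dividing a large nuclear focus's intensity by the unit estimates
how many nascent transcripts that nucleus carries. Quantification is
only valid on non-saturated exposures, so an exposure series is checked
for linearity first: background and single-transcript signal scale
linearly with exposure time while bright nuclear deposits clip.

Separate fluorophores preclude comparing 5' with 3' intensities;
calibration is strictly per channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class ExposureSeries:
    """Mean intensity of one ROI across an exposure ladder."""

    roi_id: str
    kind: str                       # "small_focus" | "large_focus" | "background"
    exposures_ms: np.ndarray
    intensities_au: np.ndarray
    linearity_flag: bool | None = None

    def __post_init__(self) -> None:
        self.exposures_ms = np.asarray(self.exposures_ms, dtype=float)
        self.intensities_au = np.asarray(self.intensities_au, dtype=float)
        if len(self.exposures_ms) != len(self.intensities_au):
            raise ValueError("exposures and intensities differ in length")
        if (np.diff(self.exposures_ms) <= 0).any():
            raise ValueError("exposures must be strictly increasing")
        if (self.intensities_au < 0).any():
            raise ValueError("intensities must be >= 0")


def check_linearity(series: ExposureSeries, tolerance: float = 0.2) -> bool:
    """True when the series stays linear to the highest exposure.

    A through-origin line is fitted to the two lowest exposures; the
    series is flagged saturated (False) when the highest-exposure
    observation falls below (1 − tolerance) of the linear prediction.
    Only non-saturated exposures are eligible for quantification.
    """
    if len(series.exposures_ms) < 3:
        raise ValueError("need at least 3 exposures to assess linearity")
    e, i = series.exposures_ms, series.intensities_au
    slope = float(np.mean(i[:2] / e[:2]))
    predicted = slope * e[-1]
    linear = bool(i[-1] >= (1.0 - tolerance) * predicted)
    series.linearity_flag = linear
    return linear


def max_linear_exposure(series: ExposureSeries, tolerance: float = 0.2) -> float:
    """Highest exposure at which the ROI is still within the linear fit."""
    if len(series.exposures_ms) < 3:
        raise ValueError("need at least 3 exposures")
    e, i = series.exposures_ms, series.intensities_au
    slope = float(np.mean(i[:2] / e[:2]))
    ok = i >= (1.0 - tolerance) * slope * e
    return float(e[ok].max())


@dataclass(frozen=True)
class CalibrationResult:
    """Single-transcript unit intensity with its sampling adequacy."""

    unit_intensity_mean_au: float
    unit_intensity_sd_au: float
    n_foci: int
    exposures_used_ms: tuple
    adequacy_n_required: int

    @property
    def adequate(self) -> bool:
        return self.n_foci >= self.adequacy_n_required


def required_sample_size(mean: float, sd: float, precision: float = 0.10,
                         confidence: float = 0.95) -> int:
    """Foci needed to estimate the mean to ±precision at the confidence level.

    Normal-approximation post-hoc formula n = (z·sd / (precision·mean))²,
    rounded up; depends on mean and sd only through the CV.
    """
    if mean <= 0:
        raise ValueError("mean must be > 0")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if not (0 < precision and 0 < confidence < 1):
        raise ValueError("precision must be > 0 and confidence in (0, 1)")
    if sd == 0:
        return 1
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    return max(1, math.ceil((z * sd / (precision * mean)) ** 2))


def calibrate_unit_intensity(small_foci_intensities,
                             background_intensities=0.0,
                             exposures_used_ms=(100.0, 200.0),
                             saturated_flags=None,
                             precision: float = 0.10,
                             confidence: float = 0.95) -> CalibrationResult:
    """Background-subtracted mean ± SD of single-transcript intensity.

    ``background_intensities`` may be a scalar or an array of background
    ROI values at the matched exposure (its mean is subtracted). Inputs
    flagged saturated are rejected outright.
    """
    values = np.asarray(small_foci_intensities, dtype=float)
    if saturated_flags is not None:
        saturated_flags = np.asarray(saturated_flags, dtype=bool)
        if saturated_flags.any():
            raise ValueError("saturated inputs are not quantifiable; "
                             "restrict to non-saturated exposures")
    if values.size < 2:
        raise ValueError("need at least 2 small foci to calibrate")
    bg = float(np.mean(background_intensities))
    corrected = values - bg
    mean = float(corrected.mean())
    sd = float(corrected.std(ddof=1))
    if mean <= 0:
        raise ValueError("background exceeds focus intensities")
    return CalibrationResult(
        unit_intensity_mean_au=mean,
        unit_intensity_sd_au=sd,
        n_foci=int(values.size),
        exposures_used_ms=tuple(np.atleast_1d(exposures_used_ms).tolist()),
        adequacy_n_required=required_sample_size(mean, sd, precision,
                                                 confidence),
    )


@dataclass(frozen=True)
class NucleusEstimate:
    """Nascent-transcript estimate for one large nuclear focus."""

    intensity_au: float
    transcripts: float              # continuous, intensity / unit mean
    transcripts_rounded: int

    @property
    def count(self) -> float:
        return self.transcripts


def estimate_nascent_count(large_focus_intensity_au: float,
                           calibration: CalibrationResult,
                           background_au: float = 0.0) -> NucleusEstimate:
    """Transcripts in a large nuclear focus: intensity / unit intensity.

    Reported both continuous (used for downstream totals, to avoid
    rounding bias) and rounded to the nearest integer.
    """
    if calibration.unit_intensity_mean_au <= 0:
        raise ValueError("calibration mean must be > 0")
    corrected = max(large_focus_intensity_au - background_au, 0.0)
    count = corrected / calibration.unit_intensity_mean_au
    return NucleusEstimate(intensity_au=large_focus_intensity_au,
                           transcripts=count,
                           transcripts_rounded=int(round(count)))
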