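"""Band-area integration and the organic-phosphate ratio.

The organic content of bone shows up in the C-H stretch region
(3060-2800 cm^-1); the mineral (carbonated hydroxyapatite) phase shows up in
the symmetric phosphate stretch nu1 (983-930 cm^-1) and the O-P-O bending
nu2 region (566-300 cm^-1).  The ratio of the C-H band area to the phosphate
band area is a relative proxy for surviving protein.

Integration is trapezoidal on the native grid.  The default baseline is a
local linear chord through the window endpoints, each endpoint taken as the
mean of the 5 nearest grid points (anchored at the mean of their
wavenumbers); this makes every corrected band area exactly invariant to
adding any affine function of wavenumber to the spectrum, which is the
property that protects the ratio against sloping fluorescence backgrounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .spectra_io import RamanSpectrum, SpectrumRangeError

__all__ = [
    "BandWindow",
    "BandAreas",
    "SampleRamanResult",
    "UndefinedRatioError",
    "CH_WINDOW",
    "PO4_V1_WINDOW",
    "PO4_V2_WINDOW",
    "NOISE_WINDOW",
    "integrate_band",
    "band_areas",
    "organic_phosphate_ratio",
    "aggregate_replicates",
    "detect_fluorescence",
    "ch_presence",
    "analyse_replicates",
]


class UndefinedRatioError(ValueError):
    """The phosphate denominator band is absent: the ratio is undefined and
    the spectrum unusable for organic-phosphate analysis."""


@dataclass(frozen=True)
class BandWindow:
    """A closed integration window [lo, hi] in cm^-1."""

    lo: float
    hi: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"window requires lo < hi, got [{self.lo}, {self.hi}]")

    @property
    def width(self) -> float:
        return self.hi - self.lo


#: C-H symmetric and asymmetric stretches — the organic (protein) indicator.
CH_WINDOW = BandWindow(2800.0, 3060.0, "C-H stretch")
#: Symmetric phosphate stretch nu1 of apatite, the most intense bone band.
PO4_V1_WINDOW = BandWindow(930.0, 983.0, "PO4 nu1")
#: O-P-O bending nu2 region of apatite.
PO4_V2_WINDOW = BandWindow(300.0, 566.0, "PO4 nu2")
#: Band-free region used for robust noise estimation.
NOISE_WINDOW = BandWindow(1900.0, 2200.0, "noise reference")

#: Grid points averaged per endpoint when building the local-linear chord.
CHORD_ENDPOINT_POINTS = 5

#: Default replicate-scatter threshold: sd/mean above this flags a sample as
#: spatially heterogeneous.
HETEROGENEITY_CV = 0.25

#: Default fluorescence contrast threshold: corrected-nu1-area over raw
#: intensity integral in the nu1 window below this marks the scan unusable.
FLUORESCENCE_TAU = 0.05

#: C-H signal-to-noise thresholds for the qualitative presence score.
CH_SNR_PROMINENT = 10.0
CH_SNR_WEAK = 3.0


@dataclass(frozen=True)
class BandAreas:
    """Baseline-corrected areas over the three fixed windows.

    Negative corrected areas (pure-noise organic region of a degraded bone)
    are clipped to zero and flagged via ``clipped``.
    """

    ch_area: float
    po4_v1_area: float
    po4_v2_area: float
    baseline_mode: str
    clipped: bool = False


@dataclass(frozen=True)
class SampleRamanResult:
    """Per-sample aggregate over replicate scans."""

    sample_id: str
    ratio_mean: float | None
    ratio_sd: float
    n_replicates: int
    fluorescence_failed: bool
    heterogeneity_flag: bool
    ch_presence: str  # prominent | weak | absent

    def __post_init__(self) -> None:
        usable = not self.fluorescence_failed and self.n_replicates > 0
        if (self.ratio_mean is None) == usable:
            raise ValueError(
                "ratio_mean must be missing exactly when the sample is unusable"
            )


def _window_slice(spectrum: RamanSpectrum, window: BandWindow) -> np.ndarray:
    lo, hi = spectrum.wavenumber_range
    if window.lo < lo or window.hi > hi:
        raise SpectrumRangeError(
            f"window [{window.lo}, {window.hi}] outside spectrum range [{lo}, {hi}]"
        )
    w = spectrum.wavenumbers
    return np.flatnonzero((w >= window.lo) & (w <= window.hi))


def _chord_baseline(
    w: np.ndarray, y: np.ndarray, idx: np.ndarray
) -> np.ndarray:
    """Linear chord through the window's endpoint intensities.

    Each endpoint is the mean intensity of the CHORD_ENDPOINT_POINTS grid
    points nearest the window edge (within the window), anchored at the mean
    of their wavenumbers.  Means commute with affine maps, so the chord — and
    hence the corrected area — is exactly affine-invariant.
    """
    k = min(CHORD_ENDPOINT_POINTS, idx.size)
    lo_pts, hi_pts = idx[:k], idx[-k:]
    x0, y0 = float(np.mean(w[lo_pts])), float(np.mean(y[lo_pts]))
    x1, y1 = float(np.mean(w[hi_pts])), float(np.mean(y[hi_pts]))
    if x1 == x0:
        return np.full(idx.size, y0)
    slope = (y1 - y0) / (x1 - x0)
    return y0 + slope * (w[idx] - x0)


def integrate_band(
    spectrum: RamanSpectrum,
    window: BandWindow,
    baseline_mode: str = "local_linear",
) -> float:
    """Trapezoidal area of (intensity - baseline) over ``window``.

    ``baseline_mode`` is ``"none"`` (raw integral) or ``"local_linear"``
    (chord through the window endpoints).  The window must lie inside the
    spectrum's range.  The returned value may be negative; clipping policy
    belongs to :func:`band_areas`.
    """
    idx = _window_slice(spectrum, window)
    if idx.size < 2:
        raise SpectrumRangeError(
            f"window [{window.lo}, {window.hi}] contains fewer than 2 grid points"
        )
    w = spectrum.wavenumbers
    y = spectrum.intensities
    seg = y[idx].astype(float)
    if baseline_mode == "local_linear":
        seg = seg - _chord_baseline(w, y, idx)
    elif baseline_mode != "none":
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
    return float(np.trapezoid(seg, w[idx]))


def band_areas(
    spectrum: RamanSpectrum, baseline_mode: str = "local_linear"
) -> BandAreas:
    """Corrected areas over the C-H, phosphate nu1 and nu2 windows.

    Negative corrected areas are clipped to 0 (a degraded bone legitimately
    has ~zero organic signal) and the result is flagged.
    """
    raw = [
        integrate_band(spectrum, win, baseline_mode)
        for win in (CH_WINDOW, PO4_V1_WINDOW, PO4_V2_WINDOW)
    ]
    clipped = any(a < 0 for a in raw)
    ch, v1, v2 = (max(a, 0.0) for a in raw)
    return BandAreas(
        ch_area=ch,
        po4_v1_area=v1,
        po4_v2_area=v2,
        baseline_mode=baseline_mode,
        clipped=clipped,
    )


def organic_phosphate_ratio(
    areas: BandAreas,
    denominator: str = "v1",
    min_denominator: float = 1e-12,
) -> float:
    """C-H band area divided by the phosphate band area (unitless).

    ``denominator`` is ``"v1"`` (the convention of the reference tables) or
    ``"v1_plus_v2"``.  A zero or near-zero denominator means the mineral band
    is absent — the spectrum is unusable and :class:`UndefinedRatioError` is
    raised.
    """
    if denominator == "v1":
        denom = areas.po4_v1_area
    elif denominator == "v1_plus_v2":
        denom = areas.po4_v1_area + areas.po4_v2_area
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom <= min_denominator:
        raise UndefinedRatioError(
            f"phosphate band area {denom} is zero/near-zero; ratio undefined"
        )
    return areas.ch_area / denom


def aggregate_replicates(
    ratios: Sequence[float], cv_threshold: float = HETEROGENEITY_CV
) -> tuple[float | None, float, bool]:
    """Combine per-replicate ratios: (mean, sample sd, heterogeneity flag).

    Replicates are independent sampling spots, so the mean of per-replicate
    ratios (not the ratio of mean areas) is used.  The flag is raised when
    the coefficient of variation sd/mean exceeds ``cv_threshold`` — spatially
    heterogeneous protein preservation across the bone surface.  Empty input
    yields a missing mean.
    """
    vals = np.asarray([r for r in ratios if math.isfinite(r)], dtype=float)
    if vals.size == 0:
        return None, float("nan"), False
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    flag = bool(mean > 0 and sd / mean > cv_threshold)
    return mean, sd, flag


def detect_fluorescence(
    spectrum: RamanSpectrum,
    tau: float = FLUORESCENCE_TAU,
    saturation_level: float | None = None,
) -> bool:
    """Flag a scan swamped by fluorescence (or saturated) as unusable.

    The criterion is baseline-to-band contrast: the chord-corrected phosphate
    nu1 area divided by the raw intensity integral over the same window.  A
    huge emission background inflates the raw integral without adding nu1
    band area, driving the contrast below ``tau``.  A spectrum with no bands
    at all (zero raw integral) is also unusable.
    """
    if saturation_level is not None and np.any(
        spectrum.intensities >= saturation_level
    ):
        return True
    corrected = integrate_band(spectrum, PO4_V1_WINDOW, "local_linear")
    raw = integrate_band(spectrum, PO4_V1_WINDOW, "none")
    if raw <= 0:
        return True
    return max(corrected, 0.0) / raw < tau


def ch_presence(
    spectrum: RamanSpectrum,
    snr_prominent: float = CH_SNR_PROMINENT,
    snr_weak: float = CH_SNR_WEAK,
    noise_window: BandWindow = NOISE_WINDOW,
) -> str:
    """Qualitative C-H presence score: ``prominent`` / ``weak`` / ``absent``.

    The score is the signal-to-noise ratio of the chord-corrected C-H region
    peak height against a robust noise sd (1.4826 x MAD of chord-detrended
    intensities over a band-free window, 1900-2200 cm^-1 by default).  Being
    a ratio of intensities it is invariant to rescaling the spectrum.
    """
    idx = _window_slice(spectrum, CH_WINDOW)
    w, y = spectrum.wavenumbers, spectrum.intensities
    corrected = y[idx] - _chord_baseline(w, y, idx)
    peak = float(np.max(corrected)) if idx.size else 0.0

    nidx = _window_slice(spectrum, noise_window)
    resid = y[nidx] - _chord_baseline(w, y, nidx)
    noise_sd = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))

    if peak <= 0:
        return "absent"
    snr = peak / noise_sd if noise_sd > 0 else float("inf")
    if snr >= snr_prominent:
        return "prominent"
    if snr >= snr_weak:
        return "weak"
    return "absent"


def analyse_replicates(
    spectra: Sequence[RamanSpectrum],
    baseline_mode: str = "local_linear",
    denominator: str = "v1",
    cv_threshold: float = HETEROGENEITY_CV,
    tau: float = FLUORESCENCE_TAU,
) -> SampleRamanResult:
    """Full per-sample pipeline: fluorescence rejection, per-replicate ratios,
    aggregation and C-H presence scoring over a set of replicate scans."""
    if not spectra:
        raise ValueError("need at least one replicate spectrum")
    sample_id = spectra[0].sample_id
    usable = [s for s in spectra if not detect_fluorescence(s, tau=tau)]
    ratios = []
    for s in usable:
        try:
            ratios.append(
                organic_phosphate_ratio(band_areas(s, baseline_mode), denominator)
            )
        except UndefinedRatioError:
            continue
    mean, sd, het = aggregate_replicates(ratios, cv_threshold)
    fluor_failed = len(usable) == 0
    presences = [ch_presence(s) for s in usable]
    order = {"absent": 0, "weak": 1, "prominent": 2}
    best = max(presences, key=lambda p: order[p]) if presences else "absent"
    return SampleRamanResult(
        sample_id=sample_id,
        ratio_mean=mean,
        ratio_sd=sd if mean is not None else float("nan"),
        n_replicates=len(ratios),
        fluorescence_failed=fluor_failed,
        heterogeneity_flag=het,
        ch_presence=best,
    )
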