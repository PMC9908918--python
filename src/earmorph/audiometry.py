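"""Extraction of the 11 hearing variables from audiograms, and the
ABR-to-behavioral threshold correction.

An audiogram is a threshold curve (dB SPL against tone frequency); all
interpolation happens in (log2 frequency, dB) space, the space in which
octave arithmetic is linear.  The 11 variables:

LFC / HFC   low/high frequency cut-off: where the curve crosses the 60 dB
            SPL criterion; extrapolated from the terminal slope when the
            last tested threshold is at least 45 dB SPL, otherwise missing
RO          hearing range, log2(HFC / LFC) octaves
SPL1        threshold at 1 kHz
ASL/ASM/ASH average sensitivity over half-octave steps on LFC-1, 1-8 and
            8-HFC kHz bands
MS          total mean sensitivity, half-octave steps LFC-HFC
PS          peak sensitivity: lowest threshold at the characteristic
            frequency(ies)
CF1 / CF2   characteristic frequencies: the one (V-shaped audiogram) or
            two (W-shaped) frequencies of best sensitivity; equal for a V

ABR audiograms are systematically less sensitive than behavioral ones,
particularly below 2 kHz; correction factors (behavioral minus ABR,
averaged over two reference species on an 11-frequency grid spanning
1-32 kHz) shift ABR thresholds to behavioral levels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields

import numpy as np
import scipy.signal

from .io_formats import AudiogramRecord, ContentError

CUTOFF_CRITERION_DB = 60.0
EXTRAPOLATION_FLOOR_DB = 45.0

#: default correction grid: half-octave ladder spanning 1-32 kHz, 11 points
DEFAULT_CORRECTION_GRID_KHZ = tuple(2.0 ** (0.5 * k) for k in range(11))

#: minimum prominence (dB) for a dip to count as a characteristic frequency
CF_PROMINENCE_DB = 2.0


@dataclass
class HearingVariables:
    """The 11 audiometric variables; None marks a value that could not be
    computed (untested flank, non-extrapolatable cut-off)."""

    LFC: float | None
    ASL: float | None
    ASM: float | None
    HFC: float | None
    ASH: float | None
    SPL1: float | None
    RO: float | None
    MS: float | None
    PS: float
    CF1: float
    CF2: float

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class CorrectionFactors:
    frequencies_khz: np.ndarray
    factors_db: np.ndarray  # behavioral - ABR, averaged over reference species

    def __post_init__(self):
        self.frequencies_khz = np.asarray(self.frequencies_khz, float)
        self.factors_db = np.asarray(self.factors_db, float)
        f = self.frequencies_khz
        if np.any(np.diff(f) <= 0):
            raise ContentError("correction grid frequencies must be increasing")
        if f.min() < 1.0 - 1e-9 or f.max() > 32.0 + 1e-9:
            raise ContentError("correction grid must lie within [1, 32] kHz")


def interpolate_threshold(
    audiogram: AudiogramRecord, f_khz: float, extrapolate: bool = False
) -> float:
    """Piecewise-linear threshold in (log2 f, dB); extrapolation (linear
    continuation of the terminal segments) only on request."""
    x = np.log2(audiogram.frequencies_khz)
    t = audiogram.thresholds_db
    xq = math.log2(f_khz)
    if xq < x[0] - 1e-12 or xq > x[-1] + 1e-12:
        if not extrapolate:
            raise ValueError(
                f"{f_khz} kHz outside tested range "
                f"[{audiogram.frequencies_khz[0]}, {audiogram.frequencies_khz[-1]}]"
            )
        if xq < x[0]:
            slope = (t[1] - t[0]) / (x[1] - x[0])
            return float(t[0] + slope * (xq - x[0]))
        slope = (t[-1] - t[-2]) / (x[-1] - x[-2])
        return float(t[-1] + slope * (xq - x[-1]))
    return float(np.interp(xq, x, t))


def frequency_cutoff(
    audiogram: AudiogramRecord,
    end: str,
    criterion: float = CUTOFF_CRITERION_DB,
    extrapolation_floor: float = EXTRAPOLATION_FLOOR_DB,
) -> float | None:
    """LFC or HFC: frequency (kHz) where the flank crosses ``criterion``.

    If the tested flank spans the criterion, the crossing nearest the
    audiogram minimum is interpolated.  Otherwise, when the terminal tested
    threshold is >= ``extrapolation_floor``, the line through the last two
    tested points is extended; below the floor the cut-off is missing.
    """
    if end not in ("low", "high"):
        raise ValueError("end must be 'low' or 'high'")
    x = np.log2(audiogram.frequencies_khz)
    t = audiogram.thresholds_db
    i_min = int(np.argmin(t))
    if end == "low":
        idx = range(i_min, 0, -1)  # segments (i-1, i) scanning away from min
        pairs = [(i - 1, i) for i in idx]
        terminal, inner = 0, 1
    else:
        pairs = [(i, i + 1) for i in range(i_min, len(t) - 1)]
        terminal, inner = -1, -2
    for a, b in pairs:
        lo, hi = (t[a], t[b]) if t[a] <= t[b] else (t[b], t[a])
        if lo <= criterion <= hi and t[a] != t[b]:
            xc = x[a] + (criterion - t[a]) * (x[b] - x[a]) / (t[b] - t[a])
            return float(2.0 ** xc)
    if t[terminal] >= criterion:  # flat-topped terminal at/above criterion
        return float(2.0 ** x[terminal])
    if t[terminal] >= extrapolation_floor:
        slope = (t[terminal] - t[inner]) / (x[terminal] - x[inner])
        # the flank must rise away from the tested range
        rising = slope < 0 if end == "low" else slope > 0
        if not rising:
            warnings.warn(f"{end} flank terminal slope does not rise; "
                          "cut-off not extrapolated")
            return None
        xc = x[terminal] + (criterion - t[terminal]) / slope
        return float(2.0 ** xc)
    return None


def range_octaves(lfc: float | None, hfc: float | None) -> float | None:
    """RO = log2(HFC / LFC); missing if either cut-off is."""
    if lfc is None or hfc is None:
        return None
    return float(math.log2(hfc / lfc))


def half_octave_grid(f_lo: float, f_hi: float) -> np.ndarray:
    """f_lo * 2^{0, 0.5, 1, ...} up to f_hi, with f_hi appended if absent."""
    if not f_lo < f_hi:
        raise ValueError("need f_lo < f_hi")
    n = int(math.floor(2.0 * math.log2(f_hi / f_lo) + 1e-9))
    grid = f_lo * 2.0 ** (0.5 * np.arange(n + 1))
    if grid[-1] < f_hi * (1.0 - 1e-9):
        grid = np.append(grid, f_hi)
    return grid


def average_sensitivity(
    audiogram: AudiogramRecord, f_lo: float, f_hi: float
) -> float | None:
    """Mean interpolated threshold over half-octave steps from f_lo to f_hi.

    Grid points beyond the tested range are reached by extending the
    terminal segments (the same line the cut-off extrapolation uses); a
    band that cannot be covered at all returns missing with a warning.
    """
    try:
        grid = half_octave_grid(f_lo, f_hi)
    except ValueError:
        warnings.warn(f"invalid band [{f_lo}, {f_hi}] kHz")
        return None
    vals = [interpolate_threshold(audiogram, f, extrapolate=True) for f in grid]
    return float(np.mean(vals))


def peak_and_characteristic(
    audiogram: AudiogramRecord, prominence_db: float = CF_PROMINENCE_DB
) -> tuple[float, float, float]:
    """(PS, CF1, CF2) from the audiogram's sensitivity dips.

    Local minima with prominence >= ``prominence_db`` are candidate
    characteristic frequencies: two or more retained dips make a W
    audiogram (CF1 the lowest-frequency dip, CF2 the highest, PS the lower
    of their thresholds); exactly one makes a V (CF1 = CF2).  A monotone
    audiogram falls back to the endpoint minimum with a warning.
    """
    t = audiogram.thresholds_db
    f = audiogram.frequencies_khz
    peaks, _ = scipy.signal.find_peaks(-t, prominence=prominence_db)
    if len(peaks) == 0:
        interior, _ = scipy.signal.find_peaks(-t)
        i = int(np.argmin(t))
        if len(interior) == 0:
            warnings.warn("monotone audiogram: endpoint minimum used")
        return float(t[i]), float(f[i]), float(f[i])
    if len(peaks) == 1:
        i = int(peaks[0])
        return float(t[i]), float(f[i]), float(f[i])
    i1, i2 = int(peaks[0]), int(peaks[-1])
    ps = float(min(t[i1], t[i2]))
    return ps, float(f[i1]), float(f[i2])


def compute_correction_factors(
    behav_a: AudiogramRecord,
    abr_a: AudiogramRecord,
    behav_b: AudiogramRecord,
    abr_b: AudiogramRecord,
    grid_khz: tuple[float, ...] = DEFAULT_CORRECTION_GRID_KHZ,
) -> CorrectionFactors:
    """Per-frequency mean of (behavioral - ABR) over two reference species."""
    grid = np.asarray(grid_khz, float)
    if len(grid) != 11:
        raise ContentError("correction grid must have 11 frequencies")
    for rec in (behav_a, abr_a, behav_b, abr_b):
        if grid.min() < rec.frequencies_khz[0] - 1e-9 or \
                grid.max() > rec.frequencies_khz[-1] + 1e-9:
            raise ContentError(
                f"audiogram of {rec.species!r} does not cover the "
                f"[{grid.min():g}, {grid.max():g}] kHz correction grid"
            )
    diff_a = np.array([
        interpolate_threshold(behav_a, f) - interpolate_threshold(abr_a, f)
        for f in grid
    ])
    diff_b = np.array([
        interpolate_threshold(behav_b, f) - interpolate_threshold(abr_b, f)
        for f in grid
    ])
    return CorrectionFactors(grid, 0.5 * (diff_a + diff_b))


def apply_correction(
    abr: AudiogramRecord, factors: CorrectionFactors
) -> AudiogramRecord:
    """Shift each ABR threshold by the (log2-interpolated) factor; outside
    the factor grid the nearest factor is used.  Tag becomes ABR-corrected."""
    xg = np.log2(factors.frequencies_khz)
    x = np.log2(abr.frequencies_khz)
    adj = np.interp(x, xg, factors.factors_db)  # np.interp clamps to ends
    return AudiogramRecord(
        species=abr.species,
        method="ABR-corrected",
        frequencies_khz=abr.frequencies_khz.copy(),
        thresholds_db=abr.thresholds_db + adj,
    )


def extract_all(
    audiogram: AudiogramRecord,
    factors: CorrectionFactors | None = None,
    criterion: float = CUTOFF_CRITERION_DB,
    extrapolation_floor: float = EXTRAPOLATION_FLOOR_DB,
) -> HearingVariables:
    """All 11 hearing variables, with ABR correction applied first when the
    record is tagged ABR and factors are supplied.  Missing cut-offs
    propagate to the variables that need them (ASL, ASH, RO, MS)."""
    if audiogram.method == "ABR" and factors is not None:
        audiogram = apply_correction(audiogram, factors)
    lfc = frequency_cutoff(audiogram, "low", criterion, extrapolation_floor)
    hfc = frequency_cutoff(audiogram, "high", criterion, extrapolation_floor)
    ro = range_octaves(lfc, hfc)
    f0, f1 = audiogram.frequencies_khz[0], audiogram.frequencies_khz[-1]
    spl1 = interpolate_threshold(audiogram, 1.0) if f0 <= 1.0 <= f1 else None
    asl = average_sensitivity(audiogram, lfc, 1.0) if lfc is not None and lfc < 1.0 else None
    asm = average_sensitivity(audiogram, 1.0, 8.0) if f0 <= 1.0 and f1 >= 8.0 else None
    ash = average_sensitivity(audiogram, 8.0, hfc) if hfc is not None and hfc > 8.0 else None
    ms = average_sensitivity(audiogram, lfc, hfc) if lfc is not None and hfc is not None else None
    ps, cf1, cf2 = peak_and_characteristic(audiogram)
    return HearingVariables(LFC=lfc, ASL=asl, ASM=asm, HFC=hfc, ASH=ash,
                            SPL1=spl1, RO=ro, MS=ms, PS=ps, CF1=cf1, CF2=cf2)
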