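"""Fragment-size-spectrum metrics from capillary-electrophoresis traces.

Free DNA recovered from seawater is sized on a fragment analyzer; the
instrument emits an electropherogram of relative fluorescence (RFU) against
calibrated fragment size (bp).  This module normalizes those traces to unit
integral, computes the proportion of signal in molecular-weight bands
(low-molecular-weight <1,000 bp; high-molecular-weight 1,000-40,000 bp;
the <350 bp tail), and detects peaks with a width-based classification:
a distinct peak (width < 5,000 bp) indicates intact DNA, a broad one
(width > 10,000 bp) a degraded smear.

Traces are assumed already sized in bp by the vendor software and
baseline-subtracted; an optional rolling-minimum baseline subtraction is
provided for raw traces.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy.ndimage import minimum_filter1d

#: Instrument sizing range (bp) of the genomic-DNA CE protocol.
SIZE_RANGE_BP = (75.0, 50000.0)

#: Boundary between low- and high-molecular-weight DNA (bp).
LMW_BOUNDARY_BP = 1000.0
#: Upper bound of the high-molecular-weight band (bp).
HMW_CAP_BP = 40000.0
#: Short-fragment boundary (bp) for the degradation tail.
SHORT_FRAGMENT_BP = 350.0

#: Peak-width classification thresholds (bp): distinct below the first,
#: broad above the second, intermediate between.
DISTINCT_WIDTH_BP = 5000.0
BROAD_WIDTH_BP = 10000.0

#: The standard band partition reported per sample.
DEFAULT_BANDS = (
    ("lt350", 75.0, 350.0),
    ("350_1000", 350.0, 1000.0),
    ("1000_40000", 1000.0, 40000.0),
    ("gt40000", 40000.0, 50000.0),
)


@dataclass
class Electropherogram:
    """Calibrated size (bp) vs relative-fluorescence trace."""

    size: np.ndarray
    rfu: np.ndarray

    def __post_init__(self) -> None:
        self.size = np.asarray(self.size, dtype=float)
        self.rfu = np.asarray(self.rfu, dtype=float)
        if self.size.size < 10:
            raise ValueError("trace needs at least 10 points")
        if self.size.shape != self.rfu.shape:
            raise ValueError("size and rfu vectors differ in length")
        if not (np.diff(self.size) > 0).all():
            raise ValueError("sizes must be strictly increasing")
        if (self.rfu < 0).any():
            raise ValueError("rfu must be non-negative (baseline-subtract first)")

    @property
    def total_signal(self) -> float:
        return float(np.trapezoid(self.rfu, self.size))


@dataclass
class PeakDescriptor:
    """One detected peak: apex position, width and mass share."""

    apex_bp: float
    width_bp: float
    mass_fraction: float
    classification: str  # "distinct" | "intermediate" | "broad"


def read_trace(path: str | Path) -> Electropherogram:
    """Read a two-column CSV (size_bp, rfu)."""
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["size_bp", "rfu"]:
        raise ValueError(f"{path}: expected columns size_bp,rfu")
    return Electropherogram(size=df["size_bp"].to_numpy(), rfu=df["rfu"].to_numpy())


def write_trace(trace: Electropherogram, path: str | Path) -> None:
    pd.DataFrame({"size_bp": trace.size, "rfu": trace.rfu}).to_csv(path, index=False)


def subtract_baseline(trace: Electropherogram, window: int = 101) -> Electropherogram:
    """Rolling-minimum baseline subtraction for raw traces."""
    baseline = minimum_filter1d(trace.rfu, size=window, mode="nearest")
    return Electropherogram(size=trace.size, rfu=trace.rfu - baseline)


def normalize_trace(trace: Electropherogram) -> Electropherogram:
    """Scale the trace so its trapezoidal integral over size equals 1.

    The shape is preserved; proportions computed downstream are therefore
    invariant to overall signal intensity.
    """
    total = trace.total_signal
    if total <= 0:
        raise ValueError("trace has zero total signal")
    return Electropherogram(size=trace.size, rfu=trace.rfu / total)


def _cumulative_mass(trace: Electropherogram) -> np.ndarray:
    """Cumulative trapezoidal integral of rfu over size, from the left edge."""
    seg = 0.5 * (trace.rfu[1:] + trace.rfu[:-1]) * np.diff(trace.size)
    return np.concatenate([[0.0], np.cumsum(seg)])


def fraction_in_range(trace: Electropherogram, lo_bp: float, hi_bp: float) -> float:
    """Proportion of total signal with fragment size in [lo_bp, hi_bp).

    Evaluated on the cumulative integral with linear interpolation at the
    band edges, so fractions over a partition of the size range sum to the
    full-range fraction exactly.
    """
    if not lo_bp < hi_bp:
        raise ValueError("need lo_bp < hi_bp")
    cum = _cumulative_mass(trace)
    total = cum[-1]
    if total <= 0:
        raise ValueError("trace has zero total signal")
    lo_v, hi_v = np.interp([lo_bp, hi_bp], trace.size, cum)
    return float((hi_v - lo_v) / total)


def band_fractions(trace: Electropherogram,
                   bands: tuple = DEFAULT_BANDS) -> dict[str, float]:
    """Signal proportion in each named molecular-weight band."""
    return {name: fraction_in_range(trace, lo, hi) for name, lo, hi in bands}


def classify_width(width_bp: float,
                   distinct_below: float = DISTINCT_WIDTH_BP,
                   broad_above: float = BROAD_WIDTH_BP) -> str:
    if width_bp < distinct_below:
        return "distinct"
    if width_bp > broad_above:
        return "broad"
    return "intermediate"


def detect_peaks(trace: Electropherogram, prominence: float = 0.05,
                 distinct_below: float = DISTINCT_WIDTH_BP,
                 broad_above: float = BROAD_WIDTH_BP) -> list[PeakDescriptor]:
    """Detect peaks and classify their widths.

    Peak finding operates on the mass density per log10(bp) (``rfu * size``),
    the axis on which CE sizing is approximately uniform; this keeps apex
    positions of log-symmetric bands at their true centers.  ``prominence``
    is a fraction of the maximum of that density.  Each peak's width at
    half prominence is converted back to the bp axis, and its mass fraction
    is the share of total signal between the flanking minima used by the
    prominence computation.
    """
    if not 0 < prominence <= 1:
        raise ValueError("prominence must be in (0, 1]")
    dens = trace.rfu * trace.size  # mass per unit log-size (up to ln10)
    if dens.max() <= 0:
        return []
    idx, props = _signal.find_peaks(dens, prominence=prominence * dens.max())
    if idx.size == 0:
        return []

    cum = _cumulative_mass(trace)
    total = cum[-1]
    widths, _, left_ips, right_ips = _signal.peak_widths(
        dens, idx, rel_height=0.5,
        prominence_data=(props["prominences"], props["left_bases"], props["right_bases"]),
    )
    out: list[PeakDescriptor] = []
    grid = np.arange(trace.size.size, dtype=float)
    for k, i in enumerate(idx):
        left_bp, right_bp = np.interp([left_ips[k], right_ips[k]], grid, trace.size)
        width = float(right_bp - left_bp)
        lo, hi = trace.size[props["left_bases"][k]], trace.size[props["right_bases"][k]]
        mass = float((np.interp(hi, trace.size, cum) - np.interp(lo, trace.size, cum)) / total)
        out.append(PeakDescriptor(
            apex_bp=float(trace.size[i]),
            width_bp=width,
            mass_fraction=mass,
            classification=classify_width(width, distinct_below, broad_above),
        ))
    return out
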