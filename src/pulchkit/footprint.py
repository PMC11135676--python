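"""Differential peak-height analysis of fluorescent DNase I footprinting.

A 5'-dye-labeled promoter probe is partially digested with DNase I with and
without a DNA-binding protein, and the fragment pools are resolved by
capillary electrophoresis alongside a size standard (ladder).  Positions
contacted by the protein are cleaved less (protection), while distorted
flanking positions can be cleaved more (hypersensitivity).

The analysis chain implemented here:

1.  ``detect_peaks``       - local-maxima extraction per channel
2.  ``calibrate_sizes``    - ladder-anchored scan -> bp calibration
3.  ``match_peaks``        - pair with/without peaks by fragment size
4.  ``normalize_heights``  - divide each peak height by the channel sum
5.  ``differential_profile`` - D_i = n_i(with) - n_i(without), so DNase I
    protection produces negative values and hypersensitivity positive ones
6.  ``call_regions``       - threshold runs of the differential into
    protected / hypersensitive intervals in TSS-relative coordinates

``analyze_trace_pair`` runs the whole chain on a pair of traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import peak_prominences

from .coords import CoordinateError, ProbeMap

__all__ = [
    "Trace",
    "Peak",
    "SizeCalibration",
    "MatchResult",
    "DifferentialProfile",
    "FootprintRegion",
    "CalibrationError",
    "detect_peaks",
    "calibrate_sizes",
    "normalize_heights",
    "match_peaks",
    "differential_profile",
    "call_regions",
    "analyze_trace_pair",
]


class CalibrationError(ValueError):
    """The ladder channel cannot support a monotone size calibration."""


@dataclass(frozen=True)
class Trace:
    """One electropherogram: sample and ladder channels on a shared scan grid."""

    scan: np.ndarray
    sample_signal: np.ndarray
    ladder_signal: np.ndarray
    label: str  # "with_protein" | "without_protein"

    def __post_init__(self) -> None:
        scan = np.asarray(self.scan, dtype=float)
        sam = np.asarray(self.sample_signal, dtype=float)
        lad = np.asarray(self.ladder_signal, dtype=float)
        if not (scan.size == sam.size == lad.size):
            raise ValueError("scan and signal channels differ in length")
        if not np.all(np.diff(scan) > 0):
            raise ValueError("scan indices must be strictly increasing")
        object.__setattr__(self, "scan", scan)
        object.__setattr__(self, "sample_signal", sam)
        object.__setattr__(self, "ladder_signal", lad)


@dataclass(frozen=True)
class Peak:
    """A local maximum of one channel; ``size_bp`` is set by calibration."""

    scan_pos: float
    height: float
    size_bp: float | None = None

    def __post_init__(self) -> None:
        if not self.height > 0:
            raise ValueError("peak height must be positive")


def detect_peaks(
    signal,
    min_height: float = 0.0,
    min_prominence: float = 0.0,
    scan=None,
) -> list[Peak]:
    """Extract local maxima from a signal series.

    A peak is an interior point strictly greater than both neighbors;
    plateaus of equal values are resolved to their leftmost point.  Peaks
    are filtered by ``min_height`` and topographic ``min_prominence`` and
    returned sorted by scan position.
    """
    y = np.asarray(signal, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 points to detect peaks")
    x = np.arange(y.size, dtype=float) if scan is None else np.asarray(scan, dtype=float)

    idx = []
    i = 1
    n = y.size
    while i < n - 1:
        if y[i] > y[i - 1]:
            j = i
            while j < n - 1 and y[j + 1] == y[i]:
                j += 1  # walk the plateau
            if j < n - 1 and y[j + 1] < y[i]:
                idx.append(i)  # leftmost point of the plateau
            i = j + 1
        else:
            i += 1
    if not idx:
        return []
    idx = np.asarray(idx)
    heights = y[idx]
    keep = heights >= min_height
    if min_prominence > 0:
        prom = peak_prominences(y, idx)[0]
        keep &= prom >= min_prominence
    return [Peak(scan_pos=float(x[i]), height=float(y[i])) for i in idx[keep]]


@dataclass(frozen=True)
class SizeCalibration:
    """Monotone piecewise-linear scan -> bp mapping anchored at ladder peaks."""

    anchor_scans: np.ndarray
    anchor_sizes: np.ndarray
    interpolation: str = "piecewise-linear"

    def __post_init__(self) -> None:
        s = np.asarray(self.anchor_scans, dtype=float)
        b = np.asarray(self.anchor_sizes, dtype=float)
        if s.size != b.size or s.size < 2:
            raise CalibrationError("need >= 2 anchors of matching length")
        if not (np.all(np.diff(s) > 0) and np.all(np.diff(b) > 0)):
            raise CalibrationError("anchors must increase strictly in scan and size")
        object.__setattr__(self, "anchor_scans", s)
        object.__setattr__(self, "anchor_sizes", b)

    def size_at(self, scan):
        """Interpolated fragment size (bp) at scan position(s); linear
        extrapolation beyond the terminal anchors."""
        scan = np.asarray(scan, dtype=float)
        s, b = self.anchor_scans, self.anchor_sizes
        size = np.interp(scan, s, b)
        lo_slope = (b[1] - b[0]) / (s[1] - s[0])
        hi_slope = (b[-1] - b[-2]) / (s[-1] - s[-2])
        size = np.where(scan < s[0], b[0] + (scan - s[0]) * lo_slope, size)
        size = np.where(scan > s[-1], b[-1] + (scan - s[-1]) * hi_slope, size)
        return size if size.ndim else float(size)

    def assign(self, peaks: list[Peak]) -> list[Peak]:
        """Return copies of ``peaks`` with calibrated ``size_bp``."""
        return [
            Peak(p.scan_pos, p.height, size_bp=float(self.size_at(p.scan_pos)))
            for p in peaks
        ]


def calibrate_sizes(ladder_peaks: list[Peak], ladder_sizes) -> SizeCalibration:
    """Build a size calibration from detected ladder-channel peaks.

    The N tallest candidate peaks (N = number of ladder fragments) are
    taken as the ladder, assigned the known sizes in scan order, and joined
    by a monotone piecewise-linear mapping with linear extrapolation at the
    ends.
    """
    sizes = np.sort(np.asarray(ladder_sizes, dtype=float))
    n = sizes.size
    if len(ladder_peaks) < n:
        raise CalibrationError(
            f"found {len(ladder_peaks)} ladder peaks but need {n}"
        )
    tallest = sorted(ladder_peaks, key=lambda p: p.height, reverse=True)[:n]
    scans = np.sort(np.array([p.scan_pos for p in tallest]))
    if np.any(np.diff(scans) <= 0):
        raise CalibrationError("non-monotone ladder peak assignment")
    return SizeCalibration(anchor_scans=scans, anchor_sizes=sizes)


def normalize_heights(peaks: list[Peak]) -> np.ndarray:
    """Divide each peak height by the sum of all heights; the result sums
    to 1.  Raises on empty input."""
    if not peaks:
        raise ValueError("no peaks to normalize")
    h = np.array([p.height for p in peaks], dtype=float)
    return h / h.sum()


@dataclass(frozen=True)
class MatchResult:
    """Size-matched with/without peak pairs plus the leftovers."""

    pairs: list[tuple[Peak, Peak]]  # (with_protein, without_protein)
    unmatched_with: list[Peak]
    unmatched_without: list[Peak]


def match_peaks(
    with_peaks: list[Peak],
    without_peaks: list[Peak],
    tol_bp: float = 0.5,
) -> MatchResult:
    """Pair calibrated peaks between the two traces by fragment size.

    Greedy nearest-size matching: candidate pairs within ``tol_bp`` are
    taken in order of increasing size difference, each peak used at most
    once.  Pairs are returned sorted by the without-protein size.
    """
    for p in with_peaks + without_peaks:
        if p.size_bp is None:
            raise ValueError("peaks must be calibrated to bp before matching")
    candidates = [
        (abs(w.size_bp - u.size_bp), i, j)
        for i, w in enumerate(with_peaks)
        for j, u in enumerate(without_peaks)
        if abs(w.size_bp - u.size_bp) <= tol_bp
    ]
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    used_w: set[int] = set()
    used_u: set[int] = set()
    pairs = []
    for _, i, j in candidates:
        if i in used_w or j in used_u:
            continue
        used_w.add(i)
        used_u.add(j)
        pairs.append((with_peaks[i], without_peaks[j]))
    pairs.sort(key=lambda pr: pr[1].size_bp)
    return MatchResult(
        pairs=pairs,
        unmatched_with=[p for i, p in enumerate(with_peaks) if i not in used_w],
        unmatched_without=[p for j, p in enumerate(without_peaks) if j not in used_u],
    )


@dataclass(frozen=True)
class DifferentialProfile:
    """Signed differential peak heights along the probe.

    ``values`` are differences of sum-normalized heights (normalization
    over the matched peaks only), so they sum to zero by construction.
    ``positions`` are TSS-relative promoter coordinates when a probe map
    was supplied, otherwise fragment sizes in bp.
    """

    positions: np.ndarray
    values: np.ndarray
    matched_n: int
    coordinate_system: str = "tss"  # "tss" | "size_bp"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions)
        val = np.asarray(self.values, dtype=float)
        if pos.size != val.size:
            raise ValueError("positions and values differ in length")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", val)


def differential_profile(
    match: MatchResult,
    probe: ProbeMap | None = None,
) -> DifferentialProfile:
    """Compute the differential peak-height profile from matched pairs.

    Heights of each trace are sum-normalized over the matched peaks only,
    then D_i = normalized(with) - normalized(without).  Protection (less
    cleavage with protein bound) gives D_i < 0, hypersensitivity D_i > 0.
    With a probe map, positions are converted to TSS-relative promoter
    coordinates; matched sizes that round off the probe are dropped (and
    the normalization redone over the retained pairs).
    """
    pairs = match.pairs
    if not pairs:
        raise ValueError("no matched pairs")
    if probe is not None:
        kept = []
        for w, u in pairs:
            try:
                pos = probe.position_tss_of_size(int(round(u.size_bp)))
            except CoordinateError:
                continue
            kept.append((pos, w, u))
        if not kept:
            raise ValueError("no matched pairs map onto the probe")
        kept.sort(key=lambda k: k[0])
        positions = np.array([k[0] for k in kept])
        with_n = normalize_heights([k[1] for k in kept])
        without_n = normalize_heights([k[2] for k in kept])
        return DifferentialProfile(
            positions=positions,
            values=with_n - without_n,
            matched_n=len(kept),
            coordinate_system="tss",
        )
    positions = np.array([u.size_bp for _, u in pairs])
    with_n = normalize_heights([w for w, _ in pairs])
    without_n = normalize_heights([u for _, u in pairs])
    return DifferentialProfile(
        positions=positions,
        values=with_n - without_n,
        matched_n=len(pairs),
        coordinate_system="size_bp",
    )


@dataclass(frozen=True)
class FootprintRegion:
    """A called protected or hypersensitive promoter interval (TSS coords)."""

    start_tss: int
    end_tss: int
    kind: str  # "protected" | "hypersensitive"
    mean_differential: float
    peak_count: int


def call_regions(
    profile: DifferentialProfile,
    tau: float = 0.02,
    min_run: int = 3,
) -> list[FootprintRegion]:
    """Segment a differential profile into footprint regions.

    The threshold ``tau`` is applied on the relative scale: a position
    counts as protected when ``matched_n * D_i <= -tau`` and as
    hypersensitive when ``matched_n * D_i >= +tau``.  Multiplying by the
    number of matched peaks expresses each differential as a fold
    deviation from the mean normalized height (1/matched_n), so the same
    ``tau`` works regardless of how many peaks the probe yields.  Maximal
    runs of at least ``min_run`` consecutive qualifying positions are
    reported; region bounds are the first and last positions of the run,
    ``mean_differential`` the mean of the raw (sum-normalized) D values.
    """
    rel = profile.values * profile.matched_n
    labels = np.zeros(rel.size, dtype=int)
    labels[rel <= -tau] = -1
    labels[rel >= tau] = 1
    regions = []
    i = 0
    n = rel.size
    while i < n:
        if labels[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and labels[j + 1] == labels[i]:
            j += 1
        if j - i + 1 >= min_run:
            regions.append(
                FootprintRegion(
                    start_tss=int(profile.positions[i]),
                    end_tss=int(profile.positions[j]),
                    kind="protected" if labels[i] == -1 else "hypersensitive",
                    mean_differential=float(profile.values[i : j + 1].mean()),
                    peak_count=j - i + 1,
                )
            )
        i = j + 1
    return regions


def analyze_trace_pair(
    with_trace: Trace,
    without_trace: Trace,
    probe: ProbeMap,
    ladder_sizes,
    min_height: float = 5.0,
    min_prominence: float = 2.0,
    match_tol_bp: float = 0.5,
    tau: float = 0.02,
    min_run: int = 3,
) -> tuple[DifferentialProfile, list[FootprintRegion], dict]:
    """Run the full footprinting chain on a with/without trace pair.

    Each trace is calibrated from its own ladder channel, sample peaks are
    detected and sized, matched across traces, differenced, and segmented.
    Returns (profile, regions, diagnostics).
    """
    sized = []
    n_ladder = []
    for trace in (with_trace, without_trace):
        lad_peaks = detect_peaks(
            trace.ladder_signal, min_height=min_height,
            min_prominence=min_prominence, scan=trace.scan,
        )
        cal = calibrate_sizes(lad_peaks, ladder_sizes)
        sam_peaks = detect_peaks(
            trace.sample_signal, min_height=min_height,
            min_prominence=min_prominence, scan=trace.scan,
        )
        n_ladder.append(len(lad_peaks))
        sized.append(cal.assign(sam_peaks))
    match = match_peaks(sized[0], sized[1], tol_bp=match_tol_bp)
    profile = differential_profile(match, probe=probe)
    regions = call_regions(profile, tau=tau, min_run=min_run)
    diagnostics = {
        "ladder_peaks_with": n_ladder[0],
        "ladder_peaks_without": n_ladder[1],
        "sample_peaks_with": len(sized[0]),
        "sample_peaks_without": len(sized[1]),
        "matched_pairs": len(match.pairs),
        "unmatched_with": len(match.unmatched_with),
        "unmatched_without": len(match.unmatched_without),
    }
    return profile, regions, diagnostics
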