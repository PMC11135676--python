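"""Synthetic data with known ground truth for the three assays.

Generators emulate, at desk scale:

* OD600 growth curves — logistic growth plus additive Gaussian noise;
* A410 pulcherrimin production curves — a modified-Gompertz rise above a
  background baseline plus additive Gaussian noise;
* single-channel flow-cytometry samples — a two-component log10-normal
  fluorescence mixture (GFP-negative and GFP-positive populations);
* fluorescent DNase I footprinting electropherogram pairs — one Gaussian
  peak per probe position in the sample channel, a co-run size ladder in a
  second channel, multiplicative protection/hypersensitivity applied to the
  with-protein trace, and a per-position multiplicative cutting-preference
  jitter shared between the two traces.

All generators are deterministic for a fixed seed.  The preset tables at
the bottom encode the study conditions: the wild-type A410 plateau of 0.10
reached ~18 h after the growth transition, the 69.8% GFP-positive
wild-type reporter population, and the protected windows of the three
repressors on the yvmC promoter (PchR +6..+28, AbrB -30..+60,
ScoC -10..+60, TSS-relative).  Mutant production parameters are only
ordered, not tabulated, in the source data, so the mutant presets are
chosen to reproduce the reported orderings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coords import ProbeMap
from .flow import FlowSample
from .footprint import Trace
from .kinetics import GompertzParams, GrowthCurve, ProductionCurve, gompertz_value

__all__ = [
    "LogisticOD",
    "GenotypePreset",
    "FootprintSpec",
    "FlowPreset",
    "LIZ500_SIZES",
    "PROBE_YVMC",
    "GENOTYPE_PRESETS",
    "FOOTPRINT_PRESETS",
    "FLOW_PRESETS",
    "derive_seed",
    "generate_growth_curve",
    "generate_production_curve",
    "generate_flow_sample",
    "generate_trace_pair",
]

#: GeneScan-500 LIZ size-standard fragment lengths (bp).  Configurable
#: fixture; any strictly increasing list of sizes may be substituted.
LIZ500_SIZES = (35, 50, 75, 100, 139, 150, 160, 200, 250, 300, 340, 350,
                400, 450, 490, 500)

#: The yvmC promoter probe: labeled 5' end at -244 relative to the ATG,
#: 253 bp long (-244..+9 zero-free).  The TSS offset is a synthetic-fixture
#: choice (-60 relative to ATG); real-data users must supply their own.
PROBE_YVMC = ProbeMap(label_end_atg=-244, probe_len=253, tss_offset_atg=-60)

_OD_FLOOR = 1e-4


def derive_seed(master_seed: int, offset: int) -> int:
    """Derive a per-call seed from a pipeline master seed by fixed offset."""
    return (master_seed * 100_003 + offset) % (2**31 - 1)


@dataclass(frozen=True)
class LogisticOD:
    """Logistic OD600 growth parameters."""

    od0: float  # initial OD
    od_max: float  # carrying capacity
    rate: float  # growth rate per hour

    def __post_init__(self) -> None:
        if not (self.od_max > self.od0 > 0):
            raise ValueError("need od_max > od0 > 0")
        if not self.rate > 0:
            raise ValueError("growth rate must be positive")

    def value(self, t):
        t = np.asarray(t, dtype=float)
        return (self.od_max * self.od0
                / (self.od0 + (self.od_max - self.od0) * np.exp(-self.rate * t)))


@dataclass(frozen=True)
class GenotypePreset:
    """Growth and pulcherrimin-production parameters for one strain.

    ``prod_params.y0`` equals ``baseline_a410``: the Gompertz curve is
    anchored on the background absorbance of pigment-free cultures.
    """

    name: str
    od_params: LogisticOD
    prod_params: GompertzParams
    baseline_a410: float

    def __post_init__(self) -> None:
        if abs(self.prod_params.y0 - self.baseline_a410) > 1e-12:
            raise ValueError("prod_params.y0 must equal baseline_a410")


@dataclass(frozen=True)
class FootprintSpec:
    """Ground-truth footprint of one protein on the probe.

    ``attenuation`` multiplies with-protein peak heights inside the
    zero-free TSS window (0 < attenuation < 1 = protection);
    ``hypersensitive_sites`` lists (position, amplification > 1) single
    positions cleaved more strongly with protein bound.
    """

    protein: str
    window_start_tss: int
    window_end_tss: int
    attenuation: float
    hypersensitive_sites: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.window_start_tss == 0 or self.window_end_tss == 0:
            raise ValueError("promoter coordinates have no position 0")
        if self.window_start_tss > self.window_end_tss:
            raise ValueError("window_start_tss must be <= window_end_tss")
        if not 0 < self.attenuation < 1:
            raise ValueError("attenuation must lie in (0, 1)")
        for pos, amp in self.hypersensitive_sites:
            if pos == 0 or not amp > 1:
                raise ValueError("hypersensitive sites need nonzero position, amp > 1")


@dataclass(frozen=True)
class FlowPreset:
    """Two-component log10-normal fluorescence mixture."""

    positive_fraction: float
    pos_log_mean: float
    pos_log_sd: float
    neg_log_mean: float
    neg_log_sd: float

    def __post_init__(self) -> None:
        if not 0 <= self.positive_fraction <= 1:
            raise ValueError("positive_fraction must lie in [0, 1]")
        if self.pos_log_sd <= 0 or self.neg_log_sd <= 0:
            raise ValueError("mixture SDs must be positive")
        if not self.pos_log_mean > self.neg_log_mean:
            raise ValueError("positive component must sit above the negative one")


def _check_times(times, noise_sd):
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("empty time grid")
    if not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    return times


def generate_growth_curve(
    preset: GenotypePreset,
    times,
    noise_sd: float = 0.01,
    seed: int = 0,
    replicate: str = "1",
) -> GrowthCurve:
    """Logistic OD600 trajectory with additive Gaussian noise, truncated
    below at a small positive floor."""
    times = _check_times(times, noise_sd)
    rng = np.random.default_rng(seed)
    od = preset.od_params.value(times)
    if noise_sd > 0:
        od = od + rng.normal(0.0, noise_sd, size=times.size)
    od = np.maximum(od, _OD_FLOOR)
    return GrowthCurve(strain=preset.name, replicate=replicate, times=times, od600=od)


def generate_production_curve(
    preset: GenotypePreset,
    times,
    noise_sd: float = 0.005,
    seed: int = 0,
    replicate: str = "1",
) -> ProductionCurve:
    """Baseline-anchored Gompertz A410 trajectory with additive Gaussian
    noise, truncated below at zero."""
    times = _check_times(times, noise_sd)
    rng = np.random.default_rng(seed)
    a410 = np.asarray(gompertz_value(preset.prod_params, times), dtype=float)
    if noise_sd > 0:
        a410 = a410 + rng.normal(0.0, noise_sd, size=times.size)
    a410 = np.maximum(a410, 0.0)
    return ProductionCurve(
        strain=preset.name, replicate=replicate, times=times, a410=a410
    )


def generate_flow_sample(
    preset: FlowPreset,
    n_events: int,
    seed: int = 0,
    sample_id: str = "sample",
    strain: str = "strain",
    is_control: bool = False,
) -> FlowSample:
    """Draw ``n_events`` fluorescence values from the two-component
    log10-normal mixture."""
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    positive = rng.random(n_events) < preset.positive_fraction
    log10_f = np.where(
        positive,
        rng.normal(preset.pos_log_mean, preset.pos_log_sd, n_events),
        rng.normal(preset.neg_log_mean, preset.neg_log_sd, n_events),
    )
    return FlowSample(
        sample_id=sample_id,
        strain=strain,
        events=10.0**log10_f,
        is_control=is_control,
    )


def generate_trace_pair(
    spec: FootprintSpec,
    probe: ProbeMap = PROBE_YVMC,
    peak_spacing_scans: int = 10,
    peak_width_scans: float = 2.0,
    base_height: float = 100.0,
    noise_sd: float = 0.0,
    jitter_sd: float = 0.05,
    seed: int = 0,
    ladder_sizes=LIZ500_SIZES,
    ladder_height: float = 150.0,
    scan_offset: float = 100.0,
    scan_curvature: float = 0.0,
) -> tuple[Trace, Trace]:
    """Generate a (with-protein, without-protein) electropherogram pair.

    The sample channel carries one Gaussian peak (SD ``peak_width_scans``)
    per probe position, centered at scan ``scan_offset + spacing*s +
    curvature*s**2`` for fragment size ``s``.  Without-protein heights are
    ``base_height`` times a per-position log-normal jitter (SD
    ``jitter_sd`` in log space) shared between the two traces, emulating
    sequence-dependent DNase I cutting preference; with-protein heights
    are additionally multiplied by ``spec.attenuation`` inside the
    footprint window and by the amplification at hypersensitive sites.
    The ladder channel carries peaks at the ``ladder_sizes`` fragments.
    Additive Gaussian noise (``noise_sd``) is drawn independently per
    channel and trace.
    """
    if not probe.covers_tss_window(spec.window_start_tss, spec.window_end_tss):
        raise ValueError(
            f"probe does not cover footprint window "
            f"{spec.window_start_tss}..{spec.window_end_tss}"
        )
    rng = np.random.default_rng(seed)
    sizes = np.arange(1, probe.probe_len + 1)
    jitter = (
        np.exp(rng.normal(0.0, jitter_sd, sizes.size)) if jitter_sd > 0
        else np.ones(sizes.size)
    )
    positions_tss = np.array([probe.position_tss_of_size(int(s)) for s in sizes])
    without_h = base_height * jitter
    factor = np.ones(sizes.size)
    in_window = (positions_tss >= spec.window_start_tss) & (
        positions_tss <= spec.window_end_tss
    )
    factor[in_window] = spec.attenuation
    for pos, amp in spec.hypersensitive_sites:
        factor[positions_tss == pos] *= amp
    with_h = without_h * factor

    def scan_of(s):
        s = np.asarray(s, dtype=float)
        return scan_offset + peak_spacing_scans * s + scan_curvature * s**2

    ladder_sizes = np.asarray(ladder_sizes, dtype=float)
    max_scan = float(scan_of(max(ladder_sizes.max(), sizes.max()))) + 8 * peak_width_scans
    scan = np.arange(0.0, max_scan + 1.0)

    def channel(centers, heights):
        sig = np.zeros_like(scan)
        for c, h in zip(np.atleast_1d(scan_of(centers)), np.atleast_1d(heights)):
            lo = np.searchsorted(scan, c - 6 * peak_width_scans)
            hi = np.searchsorted(scan, c + 6 * peak_width_scans)
            sig[lo:hi] += h * np.exp(-0.5 * ((scan[lo:hi] - c) / peak_width_scans) ** 2)
        return sig

    ladder = channel(ladder_sizes, np.full(ladder_sizes.size, ladder_height))
    traces = []
    for label, heights in (("with_protein", with_h), ("without_protein", without_h)):
        sample = channel(sizes, heights)
        lad = ladder.copy()
        if noise_sd > 0:
            sample = sample + rng.normal(0.0, noise_sd, scan.size)
            lad = lad + rng.normal(0.0, noise_sd, scan.size)
        traces.append(
            Trace(scan=scan, sample_signal=sample, ladder_signal=lad, label=label)
        )
    return traces[0], traces[1]


# ---------------------------------------------------------------------------
# Presets (study conditions)
# ---------------------------------------------------------------------------

_OD_SHARED = LogisticOD(od0=0.005, od_max=2.0, rate=0.5)
_BASE = 0.01  # background A410 of pigment-free cultures


def _genotype(name, K, mumax, lam):
    return GenotypePreset(
        name=name,
        od_params=_OD_SHARED,
        prod_params=GompertzParams(y0=_BASE, K=K, mumax=mumax, lam=lam),
        baseline_a410=_BASE,
    )


#: Strain panel.  WT anchors on the reported plateau (K = 0.10 reached
#: ~18 h after the transition at ~6 h); mutants reproduce the reported
#: qualitative orderings: the triple mutant produces from the first
#: sampled timepoint (>= 6 h before T0) with the longest duration, the
#: pchR deletion has the highest single-mutant plateau, and the scoC abrB
#: double has a higher rate than any single mutant.  Lag times are in
#: absolute hours since inoculation.
GENOTYPE_PRESETS = {
    "WT": _genotype("WT", K=0.10, mumax=0.005, lam=6.0),
    "scoC": _genotype("scoC", K=0.30, mumax=0.020, lam=5.0),
    "abrB": _genotype("abrB", K=0.25, mumax=0.020, lam=5.5),
    "pchR": _genotype("pchR", K=0.50, mumax=0.022, lam=6.0),
    "scoC_abrB": _genotype("scoC_abrB", K=0.80, mumax=0.060, lam=5.0),
    "pchR_scoC": _genotype("pchR_scoC", K=0.65, mumax=0.035, lam=6.5),
    "pchR_abrB": _genotype("pchR_abrB", K=0.65, mumax=0.025, lam=7.0),
    "triple": _genotype("triple", K=0.80, mumax=0.028, lam=0.5),
}

#: Protected windows read off the differential footprint profiles,
#: TSS-relative, zero-free.  Attenuation 0.3 is a generator choice.
FOOTPRINT_PRESETS = {
    "PchR": FootprintSpec("PchR", window_start_tss=6, window_end_tss=28,
                          attenuation=0.3),
    "AbrB": FootprintSpec("AbrB", window_start_tss=-30, window_end_tss=60,
                          attenuation=0.3),
    "ScoC": FootprintSpec("ScoC", window_start_tss=-10, window_end_tss=60,
                          attenuation=0.3),
}

#: Reporter mixtures.  The WT positive fraction anchors on the reported
#: 69.8% GFP-positive population; scoC and abrB sit above WT with broader
#: positive components.  The no-GFP control is pure negative component.
FLOW_PRESETS = {
    "no_gfp": FlowPreset(positive_fraction=0.0, pos_log_mean=3.0,
                         pos_log_sd=0.3, neg_log_mean=1.0, neg_log_sd=0.25),
    "WT": FlowPreset(positive_fraction=0.698, pos_log_mean=3.0,
                     pos_log_sd=0.3, neg_log_mean=1.0, neg_log_sd=0.25),
    "scoC": FlowPreset(positive_fraction=0.92, pos_log_mean=3.2,
                       pos_log_sd=0.45, neg_log_mean=1.0, neg_log_sd=0.25),
    "abrB": FlowPreset(positive_fraction=0.88, pos_log_mean=3.1,
                       pos_log_sd=0.45, neg_log_mean=1.0, neg_log_sd=0.25),
}
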