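"""Microelectrode-array activity analysis for spheroid recordings.

Raw single-electrode extracellular traces are band-pass filtered
(200 Hz - 3 kHz Butterworth, zero phase), spikes are detected as local
extrema whose absolute voltage reaches k = 6 times a robust estimate of the
noise standard deviation, and bursts are maximal runs of >= 5 spikes with no
more than 100 ms between consecutive spikes. Per-electrode activity is
summarized as the mean firing rate (total spikes / recording duration) and
burst count; the tetrodotoxin (TTX) / vehicle endpoint is expressed as the
fractional suppression of firing after dosing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

#: scale factor turning the median absolute deviation of a Gaussian sample
#: into its standard deviation (1/Phi^-1(0.75)).
MAD_TO_SD = 1.0 / 0.6745


@dataclass
class VoltageTrace:
    """Raw or filtered samples from one electrode.

    ``included`` records whether the spheroid sat centered on the electrode;
    only included electrodes enter quantification.
    """

    samples: np.ndarray          # uV
    fs_hz: float
    electrode_id: str = ""
    well_id: str = ""
    timepoint_days: int = 0
    included: bool = True

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("trace must be a non-empty 1-D array")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass corners in Hz and Butterworth order; zero-phase by default."""

    high_pass_hz: float = 200.0
    low_pass_hz: float = 3000.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.high_pass_hz < self.low_pass_hz:
            raise ValueError("need 0 < high_pass_hz < low_pass_hz")


@dataclass(frozen=True)
class DetectionConfig:
    """Spike threshold = k x estimated noise SD; k = 6 by default.

    ``dead_time_s`` suppresses secondary extrema of the same waveform
    (larger-amplitude event wins a conflict). ``polarity`` selects which
    excursions count as peaks.
    """

    k: float = 6.0
    dead_time_s: float = 0.001
    polarity: str = "both"       # both | negative | positive

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.dead_time_s < 0:
            raise ValueError("dead_time_s must be >= 0")
        if self.polarity not in ("both", "negative", "positive"):
            raise ValueError("polarity must be both|negative|positive")


@dataclass
class SpikeTrain:
    times_s: np.ndarray
    sigma_noise_uv: float
    threshold_uv: float
    duration_s: float
    electrode_id: str = ""
    well_id: str = ""

    @property
    def n_spikes(self) -> int:
        return int(self.times_s.size)


@dataclass
class Burst:
    start_s: float
    end_s: float
    spike_indices: tuple[int, int]   # half-open [first, last+1) into the train

    @property
    def n_spikes(self) -> int:
        return self.spike_indices[1] - self.spike_indices[0]


@dataclass
class ActivitySummary:
    electrode_id: str
    well_id: str
    timepoint_days: int
    n_spikes: int
    n_bursts: int
    mfr_hz: float
    duration_s: float
    included: bool = True


def bandpass_filter(trace: VoltageTrace, spec: FilterSpec = FilterSpec()) -> VoltageTrace:
    """Butterworth band-pass, forward-backward (zero phase) by default.

    Output has the same length and sampling rate as the input. Raises if a
    corner frequency reaches the Nyquist frequency.
    """
    nyq = trace.fs_hz / 2.0
    if spec.low_pass_hz >= nyq:
        raise ValueError(
            f"low-pass corner {spec.low_pass_hz} Hz >= Nyquist {nyq} Hz"
        )
    sos = signal.butter(
        spec.order,
        [spec.high_pass_hz, spec.low_pass_hz],
        btype="bandpass",
        fs=trace.fs_hz,
        output="sos",
    )
    if spec.zero_phase:
        filtered = signal.sosfiltfilt(sos, trace.samples)
    else:
        filtered = signal.sosfilt(sos, trace.samples)
    return replace(trace, samples=filtered)


def estimate_noise_sd(trace: VoltageTrace) -> float:
    """Robust noise SD: median absolute deviation / 0.6745.

    Consistent with the SD for Gaussian noise and insensitive to spikes
    occupying a small fraction of the samples, unlike the raw SD which the
    spikes themselves inflate.
    """
    x = trace.samples
    mad = np.median(np.abs(x - np.median(x)))
    sd = float(mad * MAD_TO_SD)
    if sd == 0.0:
        warnings.warn("constant trace: noise SD estimated as 0", stacklevel=2)
    return sd


def detect_spikes(
    filtered: VoltageTrace, cfg: DetectionConfig = DetectionConfig()
) -> SpikeTrain:
    """Threshold-based spike detection on a band-passed trace.

    The threshold is ``cfg.k`` times the robust noise SD. Spikes are local
    extrema with |voltage| at or above threshold (per the polarity setting);
    the spike time is the extremum sample time. Events closer than
    ``dead_time_s`` are resolved in favor of the larger amplitude.
    """
    sigma = estimate_noise_sd(filtered)
    if sigma == 0.0:
        raise ValueError("degenerate trace: noise SD is 0")
    threshold = cfg.k * sigma
    x = filtered.samples
    if cfg.polarity == "both":
        detection_signal = np.abs(x)
    elif cfg.polarity == "negative":
        detection_signal = -x
    else:
        detection_signal = x
    distance = max(1, int(round(cfg.dead_time_s * filtered.fs_hz)))
    # find_peaks with `distance` drops the smaller of two conflicting peaks
    idx, _ = signal.find_peaks(detection_signal, height=threshold, distance=distance)
    return SpikeTrain(
        times_s=idx / filtered.fs_hz,
        sigma_noise_uv=sigma,
        threshold_uv=threshold,
        duration_s=filtered.duration_s,
        electrode_id=filtered.electrode_id,
        well_id=filtered.well_id,
    )


def detect_bursts(
    spikes: SpikeTrain | np.ndarray,
    min_spikes: int = 5,
    max_isi_s: float = 0.100,
) -> list[Burst]:
    """Partition a spike train into bursts.

    A burst is a maximal run of consecutive spikes whose inter-spike
    intervals are all <= ``max_isi_s`` (the boundary is inclusive: an ISI of
    exactly 100 ms stays inside the burst) containing at least
    ``min_spikes`` spikes. Bursts are disjoint by construction.
    """
    times = spikes.times_s if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    if times.size == 0:
        return []
    isi = np.diff(times)
    # maximal runs: split after every ISI strictly greater than the cap;
    # 1 ns guard keeps an ISI of exactly 100 ms inside a burst despite
    # floating-point summation artifacts
    breaks = np.flatnonzero(isi > max_isi_s + 1e-9) + 1
    bursts: list[Burst] = []
    for start, stop in zip(np.r_[0, breaks], np.r_[breaks, times.size]):
        if stop - start >= min_spikes:
            bursts.append(
                Burst(
                    start_s=float(times[start]),
                    end_s=float(times[stop - 1]),
                    spike_indices=(int(start), int(stop)),
                )
            )
    return bursts


def summarize_activity(
    spikes: SpikeTrain,
    bursts: list[Burst] | None = None,
    duration_s: float | None = None,
    timepoint_days: int = 0,
    included: bool = True,
) -> ActivitySummary:
    """Mean firing rate (spikes / duration, Hz) and burst count."""
    if bursts is None:
        bursts = detect_bursts(spikes)
    duration = spikes.duration_s if duration_s is None else duration_s
    if duration <= 0:
        raise ValueError("duration must be positive")
    return ActivitySummary(
        electrode_id=spikes.electrode_id,
        well_id=spikes.well_id,
        timepoint_days=timepoint_days,
        n_spikes=spikes.n_spikes,
        n_bursts=len(bursts),
        mfr_hz=spikes.n_spikes / duration,
        duration_s=duration,
        included=included,
    )


def process_trace(
    trace: VoltageTrace,
    filter_spec: FilterSpec = FilterSpec(),
    detection: DetectionConfig = DetectionConfig(),
    min_spikes: int = 5,
    max_isi_s: float = 0.100,
) -> tuple[SpikeTrain, list[Burst], ActivitySummary]:
    """Full per-electrode pipeline: filter -> detect -> bursts -> summary."""
    filtered = bandpass_filter(trace, filter_spec)
    spikes = detect_spikes(filtered, detection)
    bursts = detect_bursts(spikes, min_spikes, max_isi_s)
    summary = summarize_activity(
        spikes, bursts, timepoint_days=trace.timepoint_days, included=trace.included
    )
    return spikes, bursts, summary


def ttx_contrast(
    baseline: ActivitySummary, dosed: ActivitySummary, condition: str
) -> dict:
    """Baseline vs post-dose endpoint for one electrode.

    Reports both summaries and the suppression fraction
    ``1 - dosed.mfr / baseline.mfr``. TTX abolishes sodium-channel firing,
    so an active electrode should suppress to ~1.0 under TTX and ~0 under
    vehicle. A silent baseline makes the fraction undefined (NaN).
    """
    if condition not in ("ttx", "vehicle"):
        raise ValueError("condition must be 'ttx' or 'vehicle'")
    if baseline.electrode_id != dosed.electrode_id:
        raise ValueError(
            f"electrode mismatch: {baseline.electrode_id!r} vs {dosed.electrode_id!r}"
        )
    if baseline.mfr_hz > 0:
        suppression = 1.0 - dosed.mfr_hz / baseline.mfr_hz
    else:
        suppression = float("nan")
    return {
        "electrode_id": baseline.electrode_id,
        "well_id": baseline.well_id,
        "condition": condition,
        "baseline_mfr_hz": baseline.mfr_hz,
        "dosed_mfr_hz": dosed.mfr_hz,
        "baseline_n_bursts": baseline.n_bursts,
        "dosed_n_bursts": dosed.n_bursts,
        "suppression_fraction": suppression,
    }


def longitudinal_table(
    summaries: list[ActivitySummary],
    timepoints: tuple[int, ...] = (7, 14, 21, 28),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """One row per included electrode x timepoint, flagging incomplete series.

    Electrodes whose spheroid was not centered (``included = False``) are
    dropped and counted; electrodes missing any of the requested timepoints
    are flagged ``incomplete``.
    """
    excluded = sorted({s.electrode_id for s in summaries if not s.included})
    rows = [
        {
            "well_id": s.well_id,
            "electrode_id": s.electrode_id,
            "timepoint_days": s.timepoint_days,
            "n_spikes": s.n_spikes,
            "mfr_hz": s.mfr_hz,
            "n_bursts": s.n_bursts,
            "included": s.included,
        }
        for s in summaries
        if s.included
    ]
    counts = {"excluded_electrodes": len(excluded)}
    if not rows:
        warnings.warn("all electrodes excluded from longitudinal table", stacklevel=2)
        return pd.DataFrame(
            columns=[
                "well_id", "electrode_id", "timepoint_days", "n_spikes",
                "mfr_hz", "n_bursts", "included", "incomplete",
            ]
        ), counts
    df = pd.DataFrame(rows).sort_values(["electrode_id", "timepoint_days"])
    seen = df.groupby("electrode_id")["timepoint_days"].apply(set)
    incomplete = {e for e, tps in seen.items() if not set(timepoints) <= tps}
    df["incomplete"] = df["electrode_id"].isin(incomplete)
    counts["incomplete_electrodes"] = len(incomplete)
    return df.reset_index(drop=True), counts
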