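"""Ground-truthed synthetic fixtures for the three assays.

Every generator is deterministic in its seed and returns (or carries) the
planted truth alongside the data, so downstream recovery tests consume only
the data and compare against the truth:

* bright-field well images — dark, roughly circular spheroids with a mild
  radial interior gradient on a bright background, plus sub-10-px speckle
  debris and additive Gaussian noise; ``n_spheroids > 1`` reproduces the
  failure mode where progenitors form two or more spheroids in one well;
* extracellular voltage traces — Gaussian noise with biphasic spike
  waveforms planted at known times, in tonic (homogeneous Poisson), bursty
  (Poisson burst onsets, >= 5 spikes at <= 100 ms ISI per burst) and TTX
  (noise only) regimes; defaults match the recording conditions the
  analysis assumes (300 s at 12.5 kHz);
* qPCR plates — standard dilution series and unknown wells drawn from
  Ct = intercept + slope*log10(ng) with slope = -1/log10(1+E) and Gaussian
  Ct noise; zero-quantity genes yield non-detect wells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mea import VoltageTrace
from .morphometry import BrightfieldImage

# default 4-fold dilution series: 50 ng down to 50/4**7 = 0.003052 ng
DEFAULT_STANDARD_SERIES = tuple(50.0 / 4.0**k for k in range(8))


# ---------------------------------------------------------------------------
# bright-field images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageGroundTruth:
    """Planted parameters of one synthetic well image.

    ``true_diameter_px`` is the full minor axis of the (possibly elliptical)
    spheroid, i.e. its minimum Feret diameter. ``eccentricity`` stretches
    the major axis: semi-major = semi-minor / sqrt(1 - e**2). ``noise_sd``
    is the additive Gaussian SD as a fraction of full intensity scale.
    ``n_spheroids > 1`` plants additional smaller spheroids (the
    split-spheroid failure mode).
    """

    true_diameter_px: float
    center_xy: tuple[float, float] | None = None
    eccentricity: float = 0.0
    n_speckles: int = 0
    n_spheroids: int = 1
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_diameter_px <= 0:
            raise ValueError("true_diameter_px must be positive")
        if not 0 <= self.eccentricity < 1:
            raise ValueError("eccentricity must be in [0, 1)")
        if self.n_spheroids < 1:
            raise ValueError("n_spheroids must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


BACKGROUND_LEVEL = 0.85      # fraction of full scale
SPHEROID_CORE_LEVEL = 0.25   # interior at center
SPHEROID_RIM_LEVEL = 0.45    # interior at rim (radial gradient)


def _ellipse_mask(
    shape: tuple[int, int], center: tuple[float, float], semi_x: float, semi_y: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center rasterization; returns (mask, normalized radius)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    rho = np.sqrt(
        ((xx - center[0]) / semi_x) ** 2 + ((yy - center[1]) / semi_y) ** 2
    )
    return rho <= 1.0, rho


def generate_spheroid_image(
    gt: ImageGroundTruth, size_px: tuple[int, int] = (512, 512)
) -> tuple[BrightfieldImage, np.ndarray]:
    """Render a synthetic bright-field well image and its true spheroid mask.

    The mask covers the spheroid(s) only, never the speckles. Images are
    16-bit grayscale. Raises if a spheroid would exceed the image bounds.
    """
    rng = np.random.default_rng(gt.seed)
    h, w = size_px
    center = gt.center_xy if gt.center_xy is not None else ((w - 1) / 2.0, (h - 1) / 2.0)

    semi_minor = gt.true_diameter_px / 2.0
    semi_major = semi_minor / np.sqrt(1.0 - gt.eccentricity**2)

    img = np.full((h, w), BACKGROUND_LEVEL, dtype=float)
    mask = np.zeros((h, w), dtype=bool)

    # main spheroid: minor axis along x, major along y
    specs = [(center, semi_minor, semi_major)]
    if gt.n_spheroids > 1:
        # satellites: smaller spheroids placed toward the image diagonals,
        # where a centered main spheroid leaves the most room
        sat_r = 0.35 * semi_minor
        for i in range(gt.n_spheroids - 1):
            ang = np.deg2rad(45.0 + 90.0 * i + rng.uniform(-10.0, 10.0))
            # ellipse radius of the main spheroid in that direction
            r_e = 1.0 / np.sqrt(
                (np.cos(ang) / semi_minor) ** 2 + (np.sin(ang) / semi_major) ** 2
            )
            ring = r_e + sat_r + 10.0
            c = (center[0] + ring * np.cos(ang), center[1] + ring * np.sin(ang))
            specs.append((c, sat_r, sat_r))

    for c, sx, sy in specs:
        if c[0] - sx < 0 or c[0] + sx > w - 1 or c[1] - sy < 0 or c[1] + sy > h - 1:
            raise ValueError("spheroid exceeds image bounds")
        m, rho = _ellipse_mask((h, w), c, sx, sy)
        img[m] = SPHEROID_CORE_LEVEL + (SPHEROID_RIM_LEVEL - SPHEROID_CORE_LEVEL) * rho[m]
        mask |= m

    # speckle debris: dark blobs strictly below 10 px equivalent diameter
    placed = 0
    guard = np.array(mask)
    attempts = 0
    while placed < gt.n_speckles and attempts < 200 * max(gt.n_speckles, 1):
        attempts += 1
        d = rng.uniform(2.0, 8.0)
        cx = rng.uniform(d, w - 1 - d)
        cy = rng.uniform(d, h - 1 - d)
        m, _ = _ellipse_mask((h, w), (cx, cy), d / 2.0, d / 2.0)
        # keep speckles clear of the spheroid so they stay separate objects
        if _near(guard, m, margin=4):
            continue
        img[m] = SPHEROID_CORE_LEVEL
        guard |= m
        placed += 1

    if gt.noise_sd > 0:
        img = img + rng.normal(0.0, gt.noise_sd, img.shape)

    pixels = np.clip(np.round(img * 65535.0), 0, 65535).astype(np.uint16)
    return BrightfieldImage(pixels=pixels), mask


def _near(existing: np.ndarray, candidate: np.ndarray, margin: int) -> bool:
    """True when a candidate blob's bounding box (padded) touches existing."""
    yy, xx = np.nonzero(candidate)
    y0, y1 = max(yy.min() - margin, 0), min(yy.max() + margin + 1, existing.shape[0])
    x0, x1 = max(xx.min() - margin, 0), min(xx.max() + margin + 1, existing.shape[1])
    return bool(existing[y0:y1, x0:x1].any())


# ---------------------------------------------------------------------------
# MEA traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceGroundTruth:
    """Planted spike times and noise model for one synthetic electrode.

    ``spike_amplitude_sigma`` is the (pre-filter) peak amplitude of the
    planted waveform in multiples of the noise SD. The TTX regime carries
    an empty spike list by construction.
    """

    true_spike_times_s: tuple[float, ...]
    regime: str                      # tonic | bursty | ttx
    spike_amplitude_sigma: float = 10.0
    noise_sd_uv: float = 5.0
    fs_hz: float = 12_500.0
    duration_s: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in ("tonic", "bursty", "ttx"):
            raise ValueError("regime must be tonic|bursty|ttx")
        if self.spike_amplitude_sigma < 0:
            raise ValueError("spike_amplitude_sigma must be >= 0")
        if self.regime == "ttx" and self.true_spike_times_s:
            raise ValueError("ttx regime must have no spikes")
        t = np.asarray(self.true_spike_times_s)
        if t.size and (t.min() < 0 or t.max() >= self.duration_s):
            raise ValueError("spike times must lie in [0, duration_s)")

    @classmethod
    def tonic(
        cls, rate_hz: float = 1.0, duration_s: float = 300.0, seed: int = 0, **kw
    ) -> "TraceGroundTruth":
        """Homogeneous-Poisson spike times at the given mean rate."""
        rng = np.random.default_rng(seed)
        n = rng.poisson(rate_hz * duration_s)
        margin = 0.005  # keep waveforms fully inside the trace
        times = np.sort(rng.uniform(margin, duration_s - margin, size=n))
        times = _enforce_refractory(times, 0.003)
        return cls(tuple(times), "tonic", duration_s=duration_s, seed=seed, **kw)

    @classmethod
    def bursty(
        cls,
        burst_rate_hz: float = 0.2,
        duration_s: float = 300.0,
        seed: int = 0,
        spikes_per_burst_mean: float = 8.0,
        **kw,
    ) -> "TraceGroundTruth":
        """Poisson burst onsets; each burst has >= 5 spikes at ISI <= 95 ms."""
        rng = np.random.default_rng(seed)
        times: list[float] = []
        t = rng.exponential(1.0 / burst_rate_hz)
        while t < duration_s - 1.0:
            n = max(5, int(rng.poisson(spikes_per_burst_mean)))
            isis = rng.uniform(0.005, 0.095, size=n - 1)
            burst = t + np.r_[0.0, np.cumsum(isis)]
            burst = burst[burst < duration_s - 0.005]
            if burst.size >= 5:
                times.extend(burst.tolist())
                t = burst[-1]
            # inter-burst gap well above the 100 ms ISI cap so bursts never merge
            t += 0.3 + rng.exponential(1.0 / burst_rate_hz)
        return cls(tuple(times), "bursty", duration_s=duration_s, seed=seed, **kw)

    @classmethod
    def ttx(cls, duration_s: float = 300.0, seed: int = 0, **kw) -> "TraceGroundTruth":
        return cls((), "ttx", duration_s=duration_s, seed=seed, **kw)


def _enforce_refractory(times: np.ndarray, min_gap_s: float) -> np.ndarray:
    if times.size < 2:
        return times
    keep = [times[0]]
    for t in times[1:]:
        if t - keep[-1] >= min_gap_s:
            keep.append(t)
    return np.asarray(keep)


def spike_template(fs_hz: float) -> np.ndarray:
    """Biphasic extracellular waveform, ~1 ms wide, dominant negative phase.

    Difference of two Gaussians, normalized so the negative peak is -1 and
    centered (the minimum falls on the middle sample).
    """
    half = int(round(0.6e-3 * fs_hz))
    t = (np.arange(-half, half + 1)) / fs_hz
    w = -np.exp(-(t**2) / (2 * (0.10e-3) ** 2)) + 0.45 * np.exp(
        -((t - 0.25e-3) ** 2) / (2 * (0.18e-3) ** 2)
    )
    return w / np.abs(w.min())


def generate_mea_trace(
    gt: TraceGroundTruth, electrode_id: str = "", well_id: str = "",
    timepoint_days: int = 0, included: bool = True,
) -> VoltageTrace:
    """Render Gaussian noise plus planted biphasic spikes as a voltage trace.

    Each planted spike contributes the template scaled to
    ``spike_amplitude_sigma * noise_sd_uv`` peak amplitude, with its
    negative peak at the planted time (rounded to the nearest sample).
    """
    rng = np.random.default_rng(gt.seed)
    n = int(round(gt.fs_hz * gt.duration_s))
    x = rng.normal(0.0, gt.noise_sd_uv, size=n)
    if gt.true_spike_times_s:
        tpl = spike_template(gt.fs_hz) * gt.spike_amplitude_sigma * gt.noise_sd_uv
        half = (tpl.size - 1) // 2
        for t in gt.true_spike_times_s:
            c = int(round(t * gt.fs_hz))
            lo, hi = c - half, c + half + 1
            s0, s1 = max(lo, 0), min(hi, n)
            x[s0:s1] += tpl[s0 - lo : tpl.size - (hi - s1)]
    return VoltageTrace(
        samples=x, fs_hz=gt.fs_hz, electrode_id=electrode_id, well_id=well_id,
        timepoint_days=timepoint_days, included=included,
    )


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QpcrGroundTruth:
    """Planted quantities and amplification model for a synthetic plate.

    ``true_quantities`` maps gene -> relative amount (ng-equivalents of the
    standard mix); a value may itself be a mapping stage -> amount for
    multi-stage plates. An amount of 0 plants a never-detected gene.
    ``efficiency`` is the per-cycle amplification fraction E, so the
    standard-curve slope is -1/log10(1+E). ``intercept_ct`` anchors the
    curve (Ct of a 1 ng input).
    """

    true_quantities: dict
    efficiency: float = 0.95
    ct_noise_sd: float = 0.2
    standard_amounts_ng: tuple[float, ...] = DEFAULT_STANDARD_SERIES
    intercept_ct: float = 22.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.efficiency <= 1.2:
            raise ValueError("efficiency must be in (0, 1.2]")
        s = np.asarray(self.standard_amounts_ng, dtype=float)
        if (s <= 0).any() or not np.all(np.diff(s) < 0):
            raise ValueError("standard series must be strictly decreasing and positive")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")

    @property
    def slope(self) -> float:
        return -1.0 / np.log10(1.0 + self.efficiency)


def generate_qpcr_plate(
    gt: QpcrGroundTruth,
    n_replicates: int = 3,
    n_standard_replicates: int = 1,
) -> pd.DataFrame:
    """Simulate a qPCR plate as a tidy well table.

    Standards (per gene) follow Ct = intercept + slope*log10(ng) + noise;
    unknown wells place each biological replicate's true quantity on the
    same curve. Zero/None quantities yield non-detect wells (Ct = NaN,
    empty field in CSV). Columns: well, gene, sample_id, stage, task,
    amount_ng, ct.
    """
    rng = np.random.default_rng(gt.seed)
    rows = []
    widx = 0

    def ct_of(amount: float) -> float:
        base = gt.intercept_ct + gt.slope * np.log10(amount)
        return float(base + (rng.normal(0.0, gt.ct_noise_sd) if gt.ct_noise_sd else 0.0))

    for gene in gt.true_quantities:
        for amount in gt.standard_amounts_ng:
            for _ in range(n_standard_replicates):
                widx += 1
                rows.append(
                    {
                        "well": f"W{widx:03d}", "gene": gene, "sample_id": "std_mix",
                        "stage": "", "task": "standard", "amount_ng": amount,
                        "ct": ct_of(amount),
                    }
                )

    for gene, value in gt.true_quantities.items():
        per_stage = value if isinstance(value, dict) else {"sample": value}
        for stage, q in per_stage.items():
            for rep in range(1, n_replicates + 1):
                widx += 1
                nd = q is None or q <= 0
                rows.append(
                    {
                        "well": f"W{widx:03d}", "gene": gene,
                        "sample_id": f"{stage}_b{rep}" if stage != "sample" else f"b{rep}",
                        "stage": stage if stage != "sample" else "",
                        "task": "unknown", "amount_ng": float("nan"),
                        "ct": float("nan") if nd else ct_of(float(q)),
                    }
                )
    return pd.DataFrame(rows)
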