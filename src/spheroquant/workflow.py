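"""End-to-end orchestration of the three assays on a directory tree.

``make_demo_dataset`` writes a complete synthetic study (well images, MEA
traces with a TTX/vehicle endpoint, a qPCR plate) with its ground truth;
``run_all`` executes morphometry -> growth statistics, MEA activity
analysis, and qPCR quantification as configured, isolating per-assay
failures, and writes CSV outputs plus a JSON run report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sq_io
from . import mea, morphometry, qpcr, stats, synthetic

log = logging.getLogger("spheroquant")

MEA_TIMEPOINTS = (7, 14, 21, 28)
DEMO_GENES = {
    # planted relative quantities per stage (curve units); ~flat controls,
    # pluripotency high only in iPSC, MN markers >= 10x up in spheroids,
    # GFAP never detected
    "ACTB": {"iPSC": 1.0, "MNPC": 1.0, "spheroid_d14": 1.0, "spheroid_d28": 1.0},
    "GAPDH": {"iPSC": 1.0, "MNPC": 1.0, "spheroid_d14": 1.0, "spheroid_d28": 1.0},
    "NANOG": {"iPSC": 1.0, "MNPC": 0.02, "spheroid_d14": 0.01, "spheroid_d28": 0.01},
    "OCT4": {"iPSC": 1.0, "MNPC": 0.02, "spheroid_d14": 0.01, "spheroid_d28": 0.01},
    "PAX6": {"iPSC": 0.02, "MNPC": 1.0, "spheroid_d14": 0.2, "spheroid_d28": 0.2},
    "OLIG2": {"iPSC": 0.02, "MNPC": 1.0, "spheroid_d14": 0.2, "spheroid_d28": 0.2},
    "HB9": {"iPSC": 0.01, "MNPC": 0.05, "spheroid_d14": 0.6, "spheroid_d28": 0.8},
    "ISL1": {"iPSC": 0.01, "MNPC": 0.05, "spheroid_d14": 0.6, "spheroid_d28": 0.8},
    "CHAT": {"iPSC": 0.01, "MNPC": 0.05, "spheroid_d14": 0.4, "spheroid_d28": 0.9},
    "MAP2": {"iPSC": 0.02, "MNPC": 0.08, "spheroid_d14": 1.0, "spheroid_d28": 1.2},
    "VSX2": {"iPSC": 0.02, "MNPC": 0.1, "spheroid_d14": 0.3, "spheroid_d28": 0.3},
    "SIM1": {"iPSC": 0.02, "MNPC": 0.1, "spheroid_d14": 0.3, "spheroid_d28": 0.3},
    "MBP": {"iPSC": 0.02, "MNPC": 0.05, "spheroid_d14": 0.2, "spheroid_d28": 0.3},
    "GFAP": {"iPSC": 0.0, "MNPC": 0.0, "spheroid_d14": 0.0, "spheroid_d28": 0.0},
}
DEMO_REFERENCE_OVERRIDES = {"NANOG": "iPSC", "OCT4": "iPSC"}
MN_MARKERS = ("HB9", "ISL1", "CHAT", "MAP2")


@dataclass
class RunConfig:
    """Parameters for an end-to-end run; defaults are the analysis defaults
    (ROUT Q = 0.01, spike threshold k = 6, bursts of >= 5 spikes at
    <= 100 ms ISI, 200 Hz - 3 kHz band)."""

    image_dir: str | None = None
    trace_dir: str | None = None
    plate_csv: str | None = None
    out_dir: str = "results"
    scale_um_per_px: float = 1.0
    rout_q: float = 0.01
    detection_k: float = 6.0
    burst_min_spikes: int = 5
    burst_max_isi_s: float = 0.100
    band_hz: tuple[float, float] = (200.0, 3000.0)
    controls: tuple[str, str] = qpcr.DEFAULT_CONTROLS
    reference_stage: str = "MNPC"
    reference_overrides: dict = field(default_factory=lambda: dict(DEMO_REFERENCE_OVERRIDES))
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat ``key = value`` config file."""
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key in ("band_hz", "controls"):
                parts = [p.strip() for p in value.split(",")]
                kwargs[key] = tuple(float(p) for p in parts) if key == "band_hz" else tuple(parts)
            elif key in ("image_dir", "trace_dir", "plate_csv", "out_dir", "reference_stage"):
                kwargs[key] = value
            elif key in ("burst_min_spikes", "seed"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


@dataclass
class RunReport:
    outputs: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    version: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


# ---------------------------------------------------------------------------
# demo dataset
# ---------------------------------------------------------------------------

def make_demo_dataset(
    seed: int,
    out_dir: str | Path,
    n_spheroids_per_group: int = 30,
    image_size: int = 512,
    trace_duration_s: float = 60.0,
    n_electrodes: int = 6,
) -> dict:
    """Write a full synthetic study and return its ground truth.

    Two cell lines x two timepoints (14, 28 days) x ``n_spheroids_per_group``
    well images with per-well paired growth, one planted undersized outlier
    well and one split-spheroid well per line; ``n_electrodes`` electrodes
    recorded at days 7/14/21/28 (increasingly bursty) plus a day-28
    TTX/vehicle endpoint pair; and one qPCR plate with the planted
    stage-specific expression profile.
    """
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    images_dir = out / "images"
    traces_dir = out / "traces"
    images_dir.mkdir(parents=True, exist_ok=True)
    traces_dir.mkdir(parents=True, exist_ok=True)

    truth: dict = {"images": [], "traces": [], "qpcr": {}}

    # --- bright-field images: paired growth day 14 -> day 28 -------------
    lines = {"lineA": 300.0, "lineB": 260.0}   # mean day-14 diameter, px
    wells = [f"{r}{c}" for r in "BCDEFG" for c in range(2, 12)]
    img_rows = []
    for line, mean_d14 in lines.items():
        outlier_well = wells[int(rng.integers(n_spheroids_per_group))]
        split_well = wells[int(rng.integers(n_spheroids_per_group))]
        while split_well == outlier_well:
            split_well = wells[int(rng.integers(n_spheroids_per_group))]
        for i in range(n_spheroids_per_group):
            well = wells[i]
            d14 = float(rng.normal(mean_d14, 12.0))
            growth = float(rng.normal(1.08, 0.02))     # planted ~8% growth
            d28 = d14 * growth
            for day, d in ((14, d14), (28, d28)):
                is_outlier = well == outlier_well and day == 28
                if is_outlier:
                    d = 0.4 * mean_d14              # mimics a failed segmentation
                gt = synthetic.ImageGroundTruth(
                    true_diameter_px=d,
                    eccentricity=float(rng.uniform(0.0, 0.45)),
                    n_speckles=int(rng.integers(0, 6)),
                    n_spheroids=2 if (well == split_well and day == 28) else 1,
                    noise_sd=0.02,
                    seed=int(rng.integers(2**31)),
                )
                image, _ = synthetic.generate_spheroid_image(gt, (image_size, image_size))
                image.batch_id, image.well_id, image.timepoint_days = line, well, day
                sq_io.write_brightfield(sq_io.image_path(images_dir, line, well, day), image)
                img_rows.append(
                    {
                        "batch_id": line, "well_id": well, "timepoint_days": day,
                        "true_diameter_px": gt.true_diameter_px,
                        "planted_outlier": is_outlier,
                        "n_spheroids": gt.n_spheroids,
                    }
                )
    truth["images"] = img_rows
    pd.DataFrame(img_rows).to_csv(out / "images_ground_truth.csv", index=False)

    # --- MEA traces: firing matures over the four timepoints --------------
    day_rate = {7: 0.4, 14: 0.8, 21: 1.2, 28: 1.6}
    trace_rows = []
    for e in range(n_electrodes):
        eid, wid = f"E{e + 1}", f"W{e + 1}"
        for day in MEA_TIMEPOINTS:
            if day < 21:
                gt = synthetic.TraceGroundTruth.tonic(
                    rate_hz=day_rate[day], duration_s=trace_duration_s,
                    seed=int(rng.integers(2**31)),
                )
            else:
                gt = synthetic.TraceGroundTruth.bursty(
                    burst_rate_hz=day_rate[day] / 8.0, duration_s=trace_duration_s,
                    seed=int(rng.integers(2**31)),
                )
            trace = synthetic.generate_mea_trace(
                gt, electrode_id=eid, well_id=wid, timepoint_days=day
            )
            sq_io.write_trace(traces_dir / f"{eid}_d{day:02d}.bin", trace)
            trace_rows.append(
                {
                    "electrode_id": eid, "well_id": wid, "timepoint_days": day,
                    "phase": "baseline", "condition": "",
                    "n_true_spikes": len(gt.true_spike_times_s), "regime": gt.regime,
                }
            )
        # day-28 endpoint: first half of wells dosed with TTX, rest vehicle
        condition = "ttx" if e < n_electrodes // 2 else "vehicle"
        if condition == "ttx":
            gt = synthetic.TraceGroundTruth.ttx(
                duration_s=trace_duration_s, seed=int(rng.integers(2**31))
            )
        else:
            gt = synthetic.TraceGroundTruth.bursty(
                burst_rate_hz=day_rate[28] / 8.0, duration_s=trace_duration_s,
                seed=int(rng.integers(2**31)),
            )
        trace = synthetic.generate_mea_trace(
            gt, electrode_id=eid, well_id=wid, timepoint_days=28
        )
        sq_io.write_trace(traces_dir / f"{eid}_d28_dosed_{condition}.bin", trace)
        trace_rows.append(
            {
                "electrode_id": eid, "well_id": wid, "timepoint_days": 28,
                "phase": "dosed", "condition": condition,
                "n_true_spikes": len(gt.true_spike_times_s), "regime": gt.regime,
            }
        )
    truth["traces"] = trace_rows
    pd.DataFrame(trace_rows).to_csv(out / "traces_ground_truth.csv", index=False)

    # --- qPCR plate --------------------------------------------------------
    qgt = synthetic.QpcrGroundTruth(
        true_quantities=DEMO_GENES, efficiency=0.95, ct_noise_sd=0.15,
        seed=int(rng.integers(2**31)),
    )
    plate = synthetic.generate_qpcr_plate(qgt, n_replicates=3)
    sq_io.write_plate(out / "qpcr_plate.csv", plate)
    truth["qpcr"] = {"efficiency": qgt.efficiency, "true_quantities": DEMO_GENES}
    return truth


# ---------------------------------------------------------------------------
# assay runners
# ---------------------------------------------------------------------------

def run_morphometry(
    image_dir: str | Path,
    scale_um_per_px: float = 1.0,
    rout_q: float = 0.01,
    out_dir: str | Path | None = None,
    overlay_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Segment and measure every image in a directory; screen outliers per
    batch x timepoint; run paired growth tests (day 14 vs 28) per batch.

    Returns (measurements, growth-test table, counts).
    """
    paths = sorted(
        p for p in Path(image_dir).iterdir() if sq_io.IMAGE_NAME_RE.match(p.name)
    )
    measurements: list[morphometry.SpheroidMeasurement] = []
    failures = 0
    for p in paths:
        img = sq_io.read_brightfield(p, scale_um_per_px)
        try:
            seg = morphometry.segment_spheroid(img)
        except morphometry.SegmentationError:
            log.error("segmentation failed: %s", p.name)
            failures += 1
            continue
        measurements.append(morphometry.measure_spheroid(seg))
        if overlay_dir is not None:
            import imageio.v3 as iio

            Path(overlay_dir).mkdir(parents=True, exist_ok=True)
            iio.imwrite(Path(overlay_dir) / (p.stem + "_overlay.png"), seg.overlay)

    df = morphometry.measurements_to_frame(measurements)
    counts = {"images": len(paths), "segmentation_failures": failures}
    if df.empty:
        return df, pd.DataFrame(), counts

    # ROUT on the diameter within each batch x timepoint group
    cfg = morphometry.OutlierConfig(Q=rout_q)
    for _, idx in df.groupby(["batch_id", "timepoint_days"]).groups.items():
        flags = morphometry.rout_outlier_screen(df.loc[idx, "d_um"].to_numpy(), cfg)
        df.loc[idx, "outlier_flag"] = flags
    counts["outliers_flagged"] = int(df["outlier_flag"].sum())
    counts["multi_object_wells"] = int(df["multi_object_flag"].sum())

    growth_rows = []
    days = sorted(df["timepoint_days"].unique())
    if len(days) == 2:
        t1, t2 = days
        for batch, sub in df.groupby("batch_id"):
            try:
                paired, pair_counts = morphometry.pair_timepoints(
                    sub[sub["timepoint_days"] == t1], sub[sub["timepoint_days"] == t2]
                )
            except ValueError:
                continue
            for col, name in (
                ("d_um", "diameter"), ("A_um2", "area"),
                ("V_um3", "volume"), ("circularity", "circularity"),
            ):
                s = stats.PairedSample(
                    paired[f"{col}_t2"].to_numpy(), paired[f"{col}_t1"].to_numpy(),
                    pairing_keys=list(paired["well_id"]),
                )
                r = stats.paired_t(s, label=f"{name} d{t2} vs d{t1}")
                growth_rows.append(
                    {
                        "batch_id": batch, "measure": name,
                        "n_pairs": pair_counts["paired"], "t": r.statistic,
                        "df": r.df, "p": r.p,
                    }
                )
    growth = pd.DataFrame(growth_rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "morphometry.csv", index=False)
        growth.to_csv(out / "growth_tests.csv", index=False)
    return df, growth, counts


def run_mea(
    trace_dir: str | Path,
    detection_k: float = 6.0,
    band_hz: tuple[float, float] = (200.0, 3000.0),
    burst_min_spikes: int = 5,
    burst_max_isi_s: float = 0.100,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Process every trace in a directory.

    Returns (spike table, per-electrode summary table, endpoint-contrast
    table, counts). Dosed endpoint recordings are recognized by the
    ``_dosed_<condition>`` filename suffix and contrasted against the
    matching baseline recording.
    """
    spec = mea.FilterSpec(high_pass_hz=band_hz[0], low_pass_hz=band_hz[1])
    det = mea.DetectionConfig(k=detection_k)
    paths = sorted(Path(trace_dir).glob("*.bin")) + sorted(Path(trace_dir).glob("*.csv"))
    spike_rows, summary_rows = [], []
    summaries: dict[tuple[str, int, str], mea.ActivitySummary] = {}
    dosed_conditions: dict[str, str] = {}
    for p in paths:
        trace = sq_io.read_trace(p)
        spikes, bursts, summary = mea.process_trace(
            trace, spec, det, burst_min_spikes, burst_max_isi_s
        )
        phase = "baseline"
        if "_dosed_" in p.stem:
            phase = "dosed"
            dosed_conditions[trace.electrode_id] = p.stem.rsplit("_dosed_", 1)[1]
        summaries[(trace.electrode_id, trace.timepoint_days, phase)] = summary
        for t in spikes.times_s:
            spike_rows.append(
                {"electrode_id": trace.electrode_id, "phase": phase, "spike_time_s": t}
            )
        summary_rows.append(
            {
                "well_id": summary.well_id, "electrode_id": summary.electrode_id,
                "timepoint_days": summary.timepoint_days, "phase": phase,
                "n_spikes": summary.n_spikes, "mfr_hz": summary.mfr_hz,
                "n_bursts": summary.n_bursts, "included": summary.included,
            }
        )
    spikes_df = pd.DataFrame(spike_rows)
    summary_df = pd.DataFrame(summary_rows)

    contrast_rows = []
    for eid, condition in sorted(dosed_conditions.items()):
        base = summaries.get((eid, 28, "baseline"))
        dosed = summaries.get((eid, 28, "dosed"))
        if base is not None and dosed is not None:
            contrast_rows.append(mea.ttx_contrast(base, dosed, condition))
    contrast_df = pd.DataFrame(contrast_rows)

    counts = {
        "traces": len(paths),
        "electrodes": summary_df["electrode_id"].nunique() if not summary_df.empty else 0,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        spikes_df.to_csv(out / "spikes.csv", index=False)
        summary_df.to_csv(out / "mea_summary.csv", index=False)
        contrast_df.to_csv(out / "ttx_contrast.csv", index=False)
    return spikes_df, summary_df, contrast_df, counts


def run_qpcr(
    plate_csv: str | Path,
    controls: tuple[str, str] = qpcr.DEFAULT_CONTROLS,
    reference_stage: str = "MNPC",
    reference_overrides: dict | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    plate = sq_io.read_plate(plate_csv)
    curves, expression, tests = qpcr.analyze_plate(
        plate, controls=controls, reference_stage=reference_stage,
        reference_overrides=reference_overrides, seed=seed,
    )
    counts = {
        "genes": int(plate["gene"].nunique()),
        "samples_quantified": int(expression["sample_id"].nunique()),
        "curves_with_warning": sum(c.warning for c in curves.values()),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        expression.to_csv(out / "expression.csv", index=False)
        tests.to_csv(out / "expression_tests.csv", index=False)
        pd.DataFrame(
            [
                {
                    "gene": g, "slope": c.slope, "intercept": c.intercept,
                    "r2": c.r2, "efficiency": c.efficiency, "warning": c.warning,
                }
                for g, c in sorted(curves.items())
            ]
        ).to_csv(out / "standard_curves.csv", index=False)
    return expression, tests, counts


def run_all(cfg: RunConfig) -> RunReport:
    """Execute every configured assay, isolating failures per assay."""
    from . import __version__

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=dataclasses.asdict(cfg), version=__version__)

    if cfg.image_dir is not None:
        try:
            _, _, counts = run_morphometry(
                cfg.image_dir, cfg.scale_um_per_px, cfg.rout_q, out_dir=out
            )
            report.counts["morphometry"] = counts
            report.outputs["morphometry"] = str(out / "morphometry.csv")
            report.outputs["growth_tests"] = str(out / "growth_tests.csv")
        except Exception as exc:  # per-assay isolation
            log.error("morphometry failed: %s", exc)
            report.failures["morphometry"] = "".join(
                traceback.format_exception_only(exc)
            ).strip()

    if cfg.trace_dir is not None:
        try:
            _, _, _, counts = run_mea(
                cfg.trace_dir, cfg.detection_k, cfg.band_hz,
                cfg.burst_min_spikes, cfg.burst_max_isi_s, out_dir=out,
            )
            report.counts["mea"] = counts
            report.outputs["mea_summary"] = str(out / "mea_summary.csv")
            report.outputs["spikes"] = str(out / "spikes.csv")
            report.outputs["ttx_contrast"] = str(out / "ttx_contrast.csv")
        except Exception as exc:
            log.error("mea failed: %s", exc)
            report.failures["mea"] = "".join(traceback.format_exception_only(exc)).strip()

    if cfg.plate_csv is not None:
        try:
            _, _, counts = run_qpcr(
                cfg.plate_csv, cfg.controls, cfg.reference_stage,
                cfg.reference_overrides, cfg.seed, out_dir=out,
            )
            report.counts["qpcr"] = counts
            report.outputs["expression"] = str(out / "expression.csv")
            report.outputs["expression_tests"] = str(out / "expression_tests.csv")
        except Exception as exc:
            log.error("qpcr failed: %s", exc)
            report.failures["qpcr"] = "".join(traceback.format_exception_only(exc)).strip()

    (out / "run_report.json").write_text(report.to_json())
    summary_lines = [f"spheroquant {__version__}"]
    for assay, counts in report.counts.items():
        summary_lines.append(f"  {assay}: " + ", ".join(f"{k}={v}" for k, v in counts.items()))
    for assay, err in report.failures.items():
        summary_lines.append(f"  {assay}: FAILED ({err})")
    (out / "run_report.txt").write_text("\n".join(summary_lines) + "\n")
    return report
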