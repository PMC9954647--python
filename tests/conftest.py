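import numpy as np
import pandas as pd
import pytest

from spheroquant import workflow


@pytest.fixture(scope="session")
def demo_dir(tmp_path_factory):
    """Full synthetic demo study, generated once per session."""
    out = tmp_path_factory.mktemp("demo")
    truth = workflow.make_demo_dataset(20240917, out)
    return out, truth


@pytest.fixture(scope="session")
def demo_results(demo_dir):
    """run_all output on the demo study."""
    out, truth = demo_dir
    cfg = workflow.RunConfig(
        image_dir=str(out / "images"),
        trace_dir=str(out / "traces"),
        plate_csv=str(out / "qpcr_plate.csv"),
        out_dir=str(out / "results"),
        seed=20240917,
    )
    report = workflow.run_all(cfg)
    return out / "results", truth, report


def brute_force_otsu(counts: np.ndarray) -> int:
    """Independent oracle: exhaustive scan of all split points, maximizing
    w0*w1*(mu0-mu1)^2 directly from the class definitions."""
    counts = np.asarray(counts, dtype=float)
    bins = np.arange(counts.size)
    best_t, best_v = None, -1.0
    for t in range(counts.size):
        w0 = counts[: t + 1].sum()
        w1 = counts[t + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: t + 1] * bins[: t + 1]).sum() / w0
        mu1 = (counts[t + 1 :] * bins[t + 1 :]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def projection_scan_min_feret(mask: np.ndarray, step_deg: float = 0.1) -> float:
    """Independent oracle: brute-force caliper width over a dense angle grid,
    projecting every boundary-pixel corner point."""
    from spheroquant.morphometry import _corner_hull_points

    pts = _corner_hull_points(mask)
    theta = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    dirs = np.column_stack([np.cos(theta), np.sin(theta)])
    proj = pts @ dirs.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.min())


def exhaustive_burst_scan(times, min_spikes=5, max_isi=0.100):
    """Independent oracle: assign each spike to a run id that increments at
    every ISI > max_isi, then keep runs with enough spikes."""
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return []
    run_id = np.zeros(times.size, dtype=int)
    for i in range(1, times.size):
        # same inclusive-boundary rule (1 ns float guard) as the definition
        run_id[i] = run_id[i - 1] + (1 if times[i] - times[i - 1] > max_isi + 1e-9 else 0)
    out = []
    for rid in np.unique(run_id):
        idx = np.flatnonzero(run_id == rid)
        if idx.size >= min_spikes:
            out.append((int(idx[0]), int(idx[-1] + 1)))
    return out
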