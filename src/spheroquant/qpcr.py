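"""qPCR absolute quantification with a serial-dilution standard curve.

Ct values regress linearly on log10(input mass): Ct = intercept +
slope*log10(ng), with amplification efficiency E = 10**(-1/slope) - 1
(E = 1 is perfect per-cycle doubling, slope = -1/log10(2) = -3.3219).
Unknown samples are quantified by inverting the fitted curve,
quantity = 10**((Ct - intercept)/slope), in curve-relative units
(ng-equivalents of the standard mix). Target quantities are normalized to
the mean of two endogenous controls (ACTB and GAPDH by default), and stage
differences are tested per gene with one-way ANOVA followed by Dunnett's
comparisons against a reference stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

from . import stats as sq_stats

STAGES = ("iPSC", "MNPC", "spheroid_d14", "spheroid_d28")
DEFAULT_CONTROLS = ("ACTB", "GAPDH")


class SampleError(ValueError):
    """A sample is unusable, e.g. an endogenous control was not detected."""


@dataclass
class QpcrWell:
    gene: str
    sample_id: str
    stage: str
    task: str                      # "standard" | "unknown"
    ct: float                      # NaN encodes non-detect
    amount_ng: float = float("nan")  # standards only
    well: str = ""


@dataclass
class StandardCurve:
    """Linear calibration of Ct on log10(input ng) for one gene.

    A usable curve has slope < 0; quality warnings are raised (as flags,
    not errors) when the implied efficiency leaves [0.8, 1.1] or r2 < 0.98.
    """

    gene: str
    slope: float
    intercept: float
    r2: float
    efficiency: float
    n_points: int
    warning: bool = False

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError(
                f"standard curve for {self.gene!r} has non-negative slope "
                f"({self.slope:.3f}); Ct must decrease with input amount"
            )


@dataclass
class ExpressionRecord:
    gene: str
    stage: str
    sample_id: str
    quantity: float
    control_quantity: float
    ratio: float
    detected: bool


def fit_standard_curve(standards: pd.DataFrame | list[QpcrWell], gene: str | None = None) -> StandardCurve:
    """Ordinary least squares of Ct on log10(amount_ng) over standard wells.

    Requires at least three distinct dilution levels with numeric Ct.
    Non-detect standards are dropped.
    """
    df = _as_frame(standards)
    df = df[df["task"] == "standard"]
    if gene is not None:
        df = df[df["gene"] == gene]
    df = df[np.isfinite(df["ct"])]
    if df.empty:
        raise ValueError("no numeric standard Ct values")
    gene = gene or str(df["gene"].iloc[0])
    levels = df["amount_ng"].astype(float)
    if (levels <= 0).any():
        raise ValueError("standard amounts must be positive")
    if levels.nunique() < 3:
        raise ValueError("need >= 3 distinct dilution levels")
    fit = linregress(np.log10(levels), df["ct"].astype(float))
    slope = float(fit.slope)
    efficiency = 10.0 ** (-1.0 / slope) - 1.0 if slope < 0 else float("nan")
    r2 = float(fit.rvalue**2)
    return StandardCurve(
        gene=gene,
        slope=slope,
        intercept=float(fit.intercept),
        r2=r2,
        efficiency=efficiency,
        n_points=int(len(df)),
        warning=not (0.8 <= efficiency <= 1.1) or r2 < 0.98,
    )


def quantify(ct: float, curve: StandardCurve) -> float:
    """Invert the standard curve: quantity = 10**((ct - intercept)/slope).

    A non-detect Ct (NaN) propagates to a non-detect quantity (NaN).
    """
    if not np.isfinite(ct):
        return float("nan")
    return float(10.0 ** ((ct - curve.intercept) / curve.slope))


def normalize_expression(
    quantities: dict[str, float],
    sample_id: str = "",
    stage: str = "",
    controls: tuple[str, str] = DEFAULT_CONTROLS,
    control_mean: str = "arithmetic",
) -> list[ExpressionRecord]:
    """Express each target as a ratio to the mean endogenous-control quantity.

    The control quantity is the arithmetic mean of the two control genes
    (geometric mean available via ``control_mean="geometric"``). A
    non-detect target is reported as ratio 0 with ``detected = False``; a
    non-detect control invalidates the whole sample.
    """
    for c in controls:
        if c not in quantities or not np.isfinite(quantities[c]):
            raise SampleError(
                f"endogenous control {c!r} missing or non-detect in sample {sample_id!r}"
            )
    c1, c2 = (quantities[c] for c in controls)
    if control_mean == "arithmetic":
        control_q = (c1 + c2) / 2.0
    elif control_mean == "geometric":
        control_q = math.sqrt(c1 * c2)
    else:
        raise ValueError("control_mean must be 'arithmetic' or 'geometric'")
    records = []
    for gene, q in quantities.items():
        if gene in controls:
            continue
        detected = np.isfinite(q)
        records.append(
            ExpressionRecord(
                gene=gene,
                stage=stage,
                sample_id=sample_id,
                quantity=float(q) if detected else float("nan"),
                control_quantity=float(control_q),
                ratio=float(q) / control_q if detected else 0.0,
                detected=bool(detected),
            )
        )
    return records


def stage_comparison(
    records: pd.DataFrame,
    reference_stage: str,
    alpha: float = 0.05,
    n_draws: int = 100_000,
    seed: int = 0,
    reference_overrides: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-gene one-way ANOVA across stages + Dunnett vs a reference stage.

    ``records`` is an expression table (columns gene, stage, ratio,
    detected). Non-detect ratios enter as 0 (absence of expression); genes
    never detected in any sample are skipped. ``reference_overrides`` maps
    gene -> stage for genes whose natural control condition differs (e.g.
    pluripotency markers referenced to the iPSC stage).
    """
    rows = []
    for gene, sub in records.groupby("gene", sort=True):
        if not sub["detected"].any():
            continue
        ref = (reference_overrides or {}).get(gene, reference_stage)
        stages = [s for s in STAGES if s in set(sub["stage"])]
        if ref not in stages or len(stages) < 2:
            continue
        groups = [sub.loc[sub["stage"] == s, "ratio"].to_numpy(float) for s in stages]
        if any(g.size < 2 for g in groups):
            continue
        if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
            continue  # degenerate: all values identical
        res = sq_stats.anova_dunnett(
            groups,
            reference_index=stages.index(ref),
            alpha=alpha,
            n_draws=n_draws,
            seed=seed,
            labels=stages,
        )
        for comp in res.comparisons:
            stage = comp.comparison_label.split(" vs ")[0]
            rows.append(
                {
                    "gene": gene,
                    "reference_stage": ref,
                    "stage": stage,
                    "anova_F": res.anova.statistic,
                    "anova_p": res.anova.p,
                    "t": comp.statistic,
                    "p_adj": comp.p,
                    "significant": comp.p <= alpha,
                }
            )
    return pd.DataFrame(rows)


def analyze_plate(
    plate: pd.DataFrame,
    controls: tuple[str, str] = DEFAULT_CONTROLS,
    reference_stage: str = "MNPC",
    reference_overrides: dict[str, str] | None = None,
    control_mean: str = "arithmetic",
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[dict[str, StandardCurve], pd.DataFrame, pd.DataFrame]:
    """Full plate analysis: fit curves, quantify, normalize, test stages.

    Technical replicates (same gene and sample_id) are averaged at the Ct
    level before quantification; a sample with any non-detect replicate of
    a gene is treated as non-detect for that gene only if all its
    replicates are non-detect, otherwise the detected Cts are averaged.

    Returns (per-gene standard curves, expression table, stage-test table).
    """
    plate = _as_frame(plate)
    curves = {
        g: fit_standard_curve(plate, gene=g)
        for g in sorted(plate.loc[plate["task"] == "standard", "gene"].unique())
    }

    unknowns = plate[plate["task"] == "unknown"]
    mean_ct = (
        unknowns.groupby(["sample_id", "stage", "gene"], sort=True)["ct"]
        .apply(lambda s: s.dropna().mean() if s.notna().any() else float("nan"))
        .reset_index()
    )

    records: list[ExpressionRecord] = []
    for (sample_id, stage), sub in mean_ct.groupby(["sample_id", "stage"], sort=True):
        quantities = {
            row.gene: quantify(row.ct, curves[row.gene]) for row in sub.itertuples()
        }
        records.extend(
            normalize_expression(
                quantities, sample_id=sample_id, stage=stage,
                controls=controls, control_mean=control_mean,
            )
        )
    expression = pd.DataFrame(
        [
            {
                "gene": r.gene,
                "stage": r.stage,
                "sample_id": r.sample_id,
                "quantity": r.quantity,
                "control_quantity": r.control_quantity,
                "ratio": r.ratio,
                "detected": r.detected,
            }
            for r in records
        ]
    )
    tests = stage_comparison(
        expression,
        reference_stage=reference_stage,
        alpha=alpha,
        seed=seed,
        reference_overrides=reference_overrides,
    )
    return curves, expression, tests


def _as_frame(wells: pd.DataFrame | list[QpcrWell]) -> pd.DataFrame:
    if isinstance(wells, pd.DataFrame):
        return wells
    return pd.DataFrame(
        [
            {
                "well": w.well,
                "gene": w.gene,
                "sample_id": w.sample_id,
                "stage": w.stage,
                "task": w.task,
                "amount_ng": w.amount_ng,
                "ct": w.ct,
            }
            for w in wells
        ]
    )
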