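"""Microspectrophotometry pipeline: raw traces to stage summaries.

Each photoreceptor cell contributes one absorbance trace.  The pipeline
baseline-corrects and peak-normalises the trace, estimates λ_max by
whole-limb template inversion (every usable point on the
long-wavelength limb is inverted to a λ_max estimate; their mean is the
cell's λ_max and their standard deviation is the fit quality in nm),
classifies the chromophore as A1 or A2 by whichever family gives the
lower quality SD, applies the validity filter (SD < 7.5 nm), and
aggregates accepted cells into per-stage, per-cell-type summaries with
two-sample t-tests between stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .templates import (
    CHROMOPHORES,
    LAMBDA_MAX_RANGE,
    TemplateInversionError,
    evaluate_template,
    invert_long_limb,
)

__all__ = [
    "STAGES",
    "CELL_TYPES",
    "Spectrum",
    "FitConfig",
    "TemplateFit",
    "StageSummary",
    "StageComparison",
    "ChromophoreRatio",
    "preprocess",
    "fit_spectrum",
    "grid_search_fit",
    "summarize_stage",
    "compare_stages",
    "compare_from_stats",
    "chromophore_ratio",
    "histogram",
]

STAGES = ("glass", "cultured_yellow", "wild_yellow", "other")
CELL_TYPES = ("rod", "cone")


@dataclass
class Spectrum:
    """One cell's absorbance trace plus identity metadata."""

    cell_id: str
    specimen_id: str
    stage: str
    cell_type: str
    wavelengths: np.ndarray
    absorbance: np.ndarray
    processed: bool = False
    #: ground-truth labels attached by the simulator, empty for real data
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.shape != self.absorbance.shape:
            raise ValueError(f"{self.cell_id}: vector length mismatch")
        if self.wavelengths.size < 50:
            raise ValueError(f"{self.cell_id}: need ≥ 50 points")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError(f"{self.cell_id}: wavelengths must increase")
        if np.any(~np.isfinite(self.absorbance)):
            raise ValueError(f"{self.cell_id}: non-finite absorbance")
        if self.stage not in STAGES:
            raise ValueError(f"{self.cell_id}: unknown stage {self.stage!r}")
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"{self.cell_id}: unknown cell type {self.cell_type!r}")


@dataclass(frozen=True)
class FitConfig:
    """Pipeline tunables.

    qc_threshold
        Validity filter: a fit is accepted when the SD of the per-point
        λ_max estimates is below this many nm (default 7.5).
    window
        Peak-normalised absorbance band on the long limb whose points
        are inverted (default 0.2–0.9; excludes the flat peak and the
        noise-dominated tail).
    min_limb_points
        Minimum usable limb points for a fit (default 8).
    smooth_window
        Moving-average width in points; 0 or 1 disables smoothing.
    baseline_frac
        Fraction of the wavelength span, at the long-wavelength end,
        averaged to estimate the baseline (default top 5 %).
    include_beta
        Whether template evaluation/inversion includes the β-band.
    welch
        Use Welch's unequal-variance t-test instead of Student's.
    """

    qc_threshold: float = 7.5
    window: tuple[float, float] = (0.2, 0.9)
    min_limb_points: int = 8
    smooth_window: int = 5
    baseline_frac: float = 0.05
    include_beta: bool = True
    welch: bool = False

    def __post_init__(self) -> None:
        if self.qc_threshold <= 0:
            raise ValueError("qc_threshold must be positive")
        lo, hi = self.window
        if not (0 < lo < hi < 1):
            raise ValueError("fitting window must satisfy 0 < low < high < 1")
        if self.min_limb_points < 2:
            raise ValueError("min_limb_points must be ≥ 2")
        if not (0 < self.baseline_frac < 0.5):
            raise ValueError("baseline_frac must be in (0, 0.5)")


DEFAULT_CONFIG = FitConfig()


@dataclass(frozen=True)
class TemplateFit:
    """Result of fitting one cell's spectrum."""

    cell_id: str
    lambda_max_hat: float
    chromophore: str
    quality_sd: float
    accepted: bool
    n_limb_points: int
    reason: str = ""


@dataclass(frozen=True)
class StageSummary:
    stage: str
    cell_type: str
    mean_lambda_max: float
    sd_lambda_max: float
    n_cells: int
    n_specimens: int
    detectable: bool = True


@dataclass(frozen=True)
class StageComparison:
    stage_a: str
    stage_b: str
    cell_type: str
    t_statistic: float
    dof: float
    p_value: float
    significant: bool


@dataclass(frozen=True)
class ChromophoreRatio:
    stage: str
    n_a1: int
    n_a2: int
    ratio_a1_a2: float  # inf when n_a2 == 0
    infinite: bool


# ---------------------------------------------------------------------------
# preprocessing

def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    # reflect-pad so the smoothed trace keeps its length and end slopes
    pad = window // 2
    padded = np.concatenate([y[pad:0:-1], y, y[-2:-2 - pad:-1]])
    return np.convolve(padded, kernel, mode="valid")[: y.size]


def preprocess(spectrum: Spectrum, config: FitConfig = DEFAULT_CONFIG) -> Spectrum:
    """Baseline-subtract, optionally smooth, and peak-normalise a trace.

    The baseline is the mean absorbance over the long-wavelength tail
    window (top ``baseline_frac`` of the wavelength span), where the
    pigment no longer absorbs.  Already-processed spectra are returned
    unchanged, making the operation idempotent.
    """
    if spectrum.processed:
        return spectrum
    wl = spectrum.wavelengths
    span = wl[-1] - wl[0]
    if span < 100:
        raise ValueError(f"{spectrum.cell_id}: trace spans {span:.0f} nm, need ≥ 100")
    tail_start = wl[-1] - config.baseline_frac * span
    tail = spectrum.absorbance[wl >= tail_start]
    if tail.size == 0:
        raise ValueError("baseline tail window outside trace")
    y = spectrum.absorbance - tail.mean()
    y = _moving_average(y, config.smooth_window)
    peak = y.max()
    if peak <= 0:
        raise ValueError(f"{spectrum.cell_id}: degenerate trace, no positive peak")
    return replace(spectrum, absorbance=y / peak, processed=True)


# ---------------------------------------------------------------------------
# fitting

def _limb_points(
    spectrum: Spectrum, config: FitConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Long-limb (λ past the peak) points inside the fitting window."""
    y = spectrum.absorbance
    wl = spectrum.wavelengths
    peak_idx = int(np.argmax(y))
    lo, hi = config.window
    mask = np.zeros_like(y, dtype=bool)
    mask[peak_idx + 1 :] = True
    mask &= (y >= lo) & (y <= hi)
    return wl[mask], y[mask]


def _invert_family(
    wl: np.ndarray, y: np.ndarray, chromophore: str, config: FitConfig
) -> np.ndarray:
    ests = []
    for w, a in zip(wl, y):
        try:
            ests.append(
                invert_long_limb(a, w, chromophore, include_beta=config.include_beta)
            )
        except TemplateInversionError:
            continue
    return np.asarray(ests)


def fit_spectrum(spectrum: Spectrum, config: FitConfig = DEFAULT_CONFIG) -> TemplateFit:
    """Estimate λ_max and chromophore class for one cell.

    Every long-limb point with peak-normalised absorbance inside the
    fitting window is inverted to a λ_max estimate under each template
    family.  The family with the smaller estimate SD wins (tie → A1);
    the fit is accepted when that SD is below the validity threshold.
    Too few usable limb points yields a rejected fit with a reason, not
    an exception.
    """
    spectrum = preprocess(spectrum, config)
    wl, y = _limb_points(spectrum, config)

    best: tuple[str, np.ndarray] | None = None
    for chromophore in CHROMOPHORES:  # A1 first → ties resolve to A1
        ests = _invert_family(wl, y, chromophore, config)
        if ests.size < config.min_limb_points:
            continue
        sd = ests.std(ddof=1)
        if best is None or sd < best[1].std(ddof=1):
            best = (chromophore, ests)

    if best is None:
        return TemplateFit(
            cell_id=spectrum.cell_id,
            lambda_max_hat=float("nan"),
            chromophore="A1",
            quality_sd=float("inf"),
            accepted=False,
            n_limb_points=int(wl.size),
            reason="too_few_limb_points",
        )

    chromophore, ests = best
    sd = float(ests.std(ddof=1))
    return TemplateFit(
        cell_id=spectrum.cell_id,
        lambda_max_hat=float(ests.mean()),
        chromophore=chromophore,
        quality_sd=sd,
        accepted=sd < config.qc_threshold,
        n_limb_points=int(ests.size),
    )


def grid_search_fit(
    spectrum: Spectrum,
    config: FitConfig = DEFAULT_CONFIG,
    grid_step: float = 0.1,
) -> tuple[float, str]:
    """Exhaustive least-squares fit over a dense λ_max grid.

    Independent of the limb-inversion path: for every λ_max on a
    ``grid_step`` nm grid and both chromophores, computes the sum of
    squared residuals between the full trace and the peak-normalised
    template, and returns the arg-min.  Used as an internal oracle.
    """
    spectrum = preprocess(spectrum, config)
    wl, y = spectrum.wavelengths, spectrum.absorbance
    lo, hi = LAMBDA_MAX_RANGE
    grid = np.arange(lo, hi + grid_step / 2, grid_step).clip(max=hi)
    best_sse, best = math.inf, (math.nan, "A1")
    for chromophore in CHROMOPHORES:
        for lm in grid:
            t = evaluate_template(
                lm, chromophore, wl, include_beta=config.include_beta
            ).relative_absorbance
            sse = float(np.sum((t - y) ** 2))
            if sse < best_sse:
                best_sse, best = sse, (float(lm), chromophore)
    return best


# ---------------------------------------------------------------------------
# aggregation and comparison

def summarize_stage(
    fits: Iterable[TemplateFit],
    metadata: pd.DataFrame,
) -> list[StageSummary]:
    """Aggregate accepted fits into per-stage × cell-type summaries.

    ``metadata`` must carry columns ``cell_id``, ``specimen_id``,
    ``stage``, ``cell_type``.  Cell-level estimates are pooled across
    specimens within a stage; stages present in the metadata but with
    zero accepted cells are flagged not detectable.
    """
    required = {"cell_id", "specimen_id", "stage", "cell_type"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    fit_df = pd.DataFrame(
        [
            {
                "cell_id": f.cell_id,
                "lambda_max_hat": f.lambda_max_hat,
                "accepted": f.accepted,
            }
            for f in fits
        ]
    )
    unknown = set(fit_df["cell_id"]) - set(metadata["cell_id"])
    if unknown:
        raise KeyError(f"fits without metadata rows: {sorted(unknown)[:5]}")
    merged = fit_df.merge(metadata, on="cell_id", validate="one_to_one")

    out: list[StageSummary] = []
    for (stage, cell_type), grp in merged.groupby(
        ["stage", "cell_type"], sort=False
    ):
        acc = grp[grp["accepted"]]
        if len(acc) == 0:
            out.append(
                StageSummary(stage, cell_type, math.nan, math.nan, 0,
                             grp["specimen_id"].nunique(), detectable=False)
            )
            continue
        vals = acc["lambda_max_hat"].to_numpy()
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out.append(
            StageSummary(
                stage=stage,
                cell_type=cell_type,
                mean_lambda_max=float(vals.mean()),
                sd_lambda_max=sd,
                n_cells=int(len(vals)),
                n_specimens=int(acc["specimen_id"].nunique()),
            )
        )
    return out


def compare_from_stats(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    welch: bool = False,
) -> tuple[float, float, float]:
    """Two-sample t-test from summary statistics: (t, dof, p)."""
    if n_a < 2 or n_b < 2:
        raise ValueError("need n ≥ 2 in both groups")
    if sd_a == 0.0 and sd_b == 0.0:
        # degenerate: no within-group variance
        if mean_a == mean_b:
            return 0.0, float(n_a + n_b - 2), 1.0
        return math.copysign(math.inf, mean_a - mean_b), float(n_a + n_b - 2), 0.0
    t, p = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=not welch
    )
    if welch:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        dof = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    else:
        dof = n_a + n_b - 2
    return float(t), float(dof), float(p)


def compare_stages(
    summary_a: StageSummary,
    summary_b: StageSummary,
    welch: bool = False,
    alpha: float = 0.05,
) -> StageComparison:
    """Two-sample t-test between two stage summaries (same cell type)."""
    if summary_a.cell_type != summary_b.cell_type:
        raise ValueError("summaries compare different cell types")
    t, dof, p = compare_from_stats(
        summary_a.mean_lambda_max, summary_a.sd_lambda_max, summary_a.n_cells,
        summary_b.mean_lambda_max, summary_b.sd_lambda_max, summary_b.n_cells,
        welch=welch,
    )
    return StageComparison(
        stage_a=summary_a.stage,
        stage_b=summary_b.stage,
        cell_type=summary_a.cell_type,
        t_statistic=t,
        dof=dof,
        p_value=p,
        significant=p < alpha,
    )


def chromophore_ratio(
    fits: Sequence[TemplateFit],
    metadata: pd.DataFrame | None = None,
    stage: str | None = None,
) -> ChromophoreRatio:
    """A1:A2 ratio of accepted fits, optionally restricted to one stage."""
    if stage is not None:
        if metadata is None:
            raise ValueError("stage filtering requires metadata")
        wanted = set(metadata.loc[metadata["stage"] == stage, "cell_id"])
        fits = [f for f in fits if f.cell_id in wanted]
    accepted = [f for f in fits if f.accepted]
    if not accepted:
        raise ValueError("no accepted fits to classify")
    n_a1 = sum(f.chromophore == "A1" for f in accepted)
    n_a2 = len(accepted) - n_a1
    infinite = n_a2 == 0
    ratio = math.inf if infinite else n_a1 / n_a2
    return ChromophoreRatio(stage or "all", n_a1, n_a2, ratio, infinite)


def histogram(
    fits: Iterable[TemplateFit],
    bin_width: float = 5.0,
    anchor: float = 400.0,
) -> pd.DataFrame:
    """Bin accepted λ_max estimates; bins left-closed, right-open.

    Returns a DataFrame with columns ``bin_left``, ``bin_right``,
    ``count``; empty input yields an empty frame.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    vals = np.asarray([f.lambda_max_hat for f in fits if f.accepted])
    if vals.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    left = anchor + np.floor((vals - anchor) / bin_width) * bin_width
    counts = pd.Series(left).value_counts().sort_index()
    return pd.DataFrame(
        {
            "bin_left": counts.index.to_numpy(),
            "bin_right": counts.index.to_numpy() + bin_width,
            "count": counts.to_numpy(),
        }
    )
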