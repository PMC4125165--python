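"""Stable on-disk dialects for the pipeline.

Spectra arrive as one CSV per cell (columns ``wavelength_nm``,
``absorbance``) plus a metadata TSV (``cell_id``, ``specimen_id``,
``stage``, ``cell_type``).  Fits, summaries, comparisons, histograms
and expression tables are written as TSV with fixed column sets.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .msp import (
    ChromophoreRatio,
    Spectrum,
    StageComparison,
    StageSummary,
    TemplateFit,
)

__all__ = [
    "read_spectrum_csv",
    "read_spectra_dir",
    "read_metadata",
    "write_spectra",
    "write_fits",
    "read_fits",
    "write_summaries",
    "write_comparisons",
    "write_ratio",
]

METADATA_COLUMNS = ["cell_id", "specimen_id", "stage", "cell_type"]


def read_spectrum_csv(path: Path | str, cell_id: str, meta: dict) -> Spectrum:
    df = pd.read_csv(path)
    missing = {"wavelength_nm", "absorbance"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in trace")
    return Spectrum(
        cell_id=cell_id,
        specimen_id=meta["specimen_id"],
        stage=meta["stage"],
        cell_type=meta["cell_type"],
        wavelengths=df["wavelength_nm"].to_numpy(),
        absorbance=df["absorbance"].to_numpy(),
    )


def read_metadata(path: Path | str) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"{path}: metadata missing columns {sorted(missing)}")
    dup = meta["cell_id"][meta["cell_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate cell_ids in metadata: {list(dup)[:5]}")
    return meta


def read_spectra_dir(spectra_dir: Path | str, metadata: pd.DataFrame) -> list[Spectrum]:
    """Load one ``<cell_id>.csv`` per metadata row; all must exist."""
    spectra_dir = Path(spectra_dir)
    missing_files = []
    spectra = []
    for row in metadata.to_dict("records"):
        path = spectra_dir / f"{row['cell_id']}.csv"
        if not path.exists():
            missing_files.append(row["cell_id"])
            continue
        spectra.append(read_spectrum_csv(path, row["cell_id"], row))
    if missing_files:
        raise FileNotFoundError(
            f"no spectrum file for cell_ids: {missing_files[:10]}"
        )
    return spectra


def write_spectra(spectra: Iterable[Spectrum], out_dir: Path | str) -> pd.DataFrame:
    """Write per-cell CSVs plus the metadata TSV; returns the metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in spectra:
        pd.DataFrame(
            {"wavelength_nm": s.wavelengths, "absorbance": s.absorbance}
        ).to_csv(out_dir / f"{s.cell_id}.csv", index=False)
        rows.append(
            {
                "cell_id": s.cell_id,
                "specimen_id": s.specimen_id,
                "stage": s.stage,
                "cell_type": s.cell_type,
            }
        )
    meta = pd.DataFrame(rows, columns=METADATA_COLUMNS)
    meta.to_csv(out_dir / "metadata.tsv", sep="\t", index=False)
    return meta


def fits_frame(fits: Iterable[TemplateFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": f.cell_id,
                "lambda_max_hat": f.lambda_max_hat,
                "chromophore": f.chromophore,
                "quality_sd": f.quality_sd,
                "accepted": f.accepted,
                "n_limb_points": f.n_limb_points,
                "reason": f.reason,
            }
            for f in fits
        ]
    )


def write_fits(fits: Iterable[TemplateFit], path: Path | str) -> None:
    # %.17g round-trips IEEE doubles exactly
    fits_frame(fits).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_fits(path: Path | str) -> list[TemplateFit]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip").fillna(
        {"reason": ""}
    )
    return [
        TemplateFit(
            cell_id=str(r.cell_id),
            lambda_max_hat=float(r.lambda_max_hat),
            chromophore=str(r.chromophore),
            quality_sd=float(r.quality_sd),
            accepted=bool(r.accepted),
            n_limb_points=int(r.n_limb_points),
            reason=str(r.reason),
        )
        for r in df.itertuples()
    ]


def summaries_frame(summaries: Sequence[StageSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "stage": s.stage,
                "cell_type": s.cell_type,
                "mean_lambda_max_nm": s.mean_lambda_max,
                "sd_lambda_max_nm": s.sd_lambda_max,
                "n_cells": s.n_cells,
                "n_specimens": s.n_specimens,
                "detectable": s.detectable,
            }
            for s in summaries
        ]
    )


def write_summaries(summaries: Sequence[StageSummary], path: Path | str) -> None:
    summaries_frame(summaries).to_csv(path, sep="\t", index=False)


def comparisons_frame(comparisons: Sequence[StageComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "stage_a": c.stage_a,
                "stage_b": c.stage_b,
                "cell_type": c.cell_type,
                "t_statistic": c.t_statistic,
                "dof": c.dof,
                "p_value": c.p_value,
                "significant": c.significant,
            }
            for c in comparisons
        ]
    )


def write_comparisons(comparisons: Sequence[StageComparison], path: Path | str) -> None:
    comparisons_frame(comparisons).to_csv(path, sep="\t", index=False)


def write_ratio(ratio: ChromophoreRatio, path: Path | str) -> None:
    pd.DataFrame(
        [
            {
                "stage": ratio.stage,
                "n_a1": ratio.n_a1,
                "n_a2": ratio.n_a2,
                "ratio_a1_a2": "inf" if ratio.infinite else ratio.ratio_a1_a2,
            }
        ]
    ).to_csv(path, sep="\t", index=False)
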