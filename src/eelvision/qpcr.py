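"""Efficiency-corrected relative and proportional opsin expression.

With per-cycle amplification efficiency E (amplification factor 1 + E)
and threshold cycle Ct, the initial template abundance of gene i is
proportional to (1 + E_i)^(−Ct_i).  Two quantities are derived:

* relative expression against a housekeeping gene h,
      T_i / T_h = (1 + E_h)^{Ct_h} / (1 + E_i)^{Ct_i}
* proportional expression as a fraction of total opsin expression,
      T_i / T_all = (1 + E_i)^{−Ct_i} / Σ_j (1 + E_j)^{−Ct_j}
  over the non-housekeeping genes j assayed in the same sample.

An alternative reading of the efficiency correction, with E itself as
the amplification factor (E^Ct), is available via
``amplification_base="e"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean
from typing import Iterable, Sequence

import math

import pandas as pd

__all__ = [
    "QpcrRecord",
    "ExpressionResult",
    "relative_expression",
    "proportional_expression",
    "average_replicates",
    "expression_table",
]


@dataclass(frozen=True)
class QpcrRecord:
    """One gene × sample qPCR measurement (replicates pre-averaged)."""

    gene: str
    sample_id: str
    ct: float  # NaN ⇒ not detected
    efficiency: float
    is_housekeeping: bool = False

    def __post_init__(self) -> None:
        if not math.isnan(self.ct) and self.ct <= 0:
            raise ValueError(f"{self.gene}: Ct must be positive")
        if not (0.0 < self.efficiency <= 1.0):
            raise ValueError(f"{self.gene}: efficiency must lie in (0, 1]")

    @property
    def detected(self) -> bool:
        return not math.isnan(self.ct)


@dataclass(frozen=True)
class ExpressionResult:
    gene: str
    sample_id: str
    relative_expression: float | None
    proportional_expression: float
    detected: bool = True


def _factor(efficiency: float, amplification_base: str) -> float:
    if amplification_base == "one_plus_e":
        return 1.0 + efficiency
    if amplification_base == "e":
        return efficiency
    raise ValueError("amplification_base must be 'one_plus_e' or 'e'")


def relative_expression(
    target: QpcrRecord,
    housekeeping: QpcrRecord | Sequence[QpcrRecord],
    amplification_base: str = "one_plus_e",
) -> float:
    """Expression of ``target`` relative to the housekeeping gene(s).

    When several housekeeping records are given (e.g. cytochrome b and
    ARP) their Ct values are averaged and their efficiencies averaged
    before normalisation.
    """
    if isinstance(housekeeping, QpcrRecord):
        housekeeping = [housekeeping]
    if not housekeeping:
        raise ValueError("at least one housekeeping record required")
    for h in housekeeping:
        if not h.is_housekeeping:
            raise ValueError(f"{h.gene} is not flagged as housekeeping")
        if h.sample_id != target.sample_id:
            raise ValueError(
                f"sample mismatch: {target.sample_id} vs {h.sample_id}"
            )
    if not target.detected:
        return 0.0
    cth = mean(h.ct for h in housekeeping)
    eh = mean(h.efficiency for h in housekeeping)
    num = _factor(eh, amplification_base) ** cth
    den = _factor(target.efficiency, amplification_base) ** target.ct
    return num / den


def proportional_expression(
    records: Iterable[QpcrRecord],
    amplification_base: str = "one_plus_e",
) -> list[ExpressionResult]:
    """Per-gene fraction of total opsin expression for one sample.

    Housekeeping records are used for the relative-expression column
    only; proportions are taken over the non-housekeeping genes.
    Undetected genes (Ct = NaN) get proportion 0 and are flagged.
    """
    records = list(records)
    if not records:
        raise ValueError("no records")
    sample_ids = {r.sample_id for r in records}
    if len(sample_ids) != 1:
        raise ValueError(f"records span several samples: {sorted(sample_ids)}")
    targets = [r for r in records if not r.is_housekeeping]
    housekeeping = [r for r in records if r.is_housekeeping]
    if not targets:
        raise ValueError("no non-housekeeping records")
    genes = [r.gene for r in targets]
    if len(genes) != len(set(genes)):
        raise ValueError("duplicate gene in sample; average replicates first")

    weights = {
        r.gene: _factor(r.efficiency, amplification_base) ** (-r.ct)
        if r.detected
        else 0.0
        for r in targets
    }
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("no detected genes in sample")

    out = []
    for r in targets:
        rel = (
            relative_expression(r, housekeeping, amplification_base)
            if housekeeping and r.detected
            else None
        )
        out.append(
            ExpressionResult(
                gene=r.gene,
                sample_id=r.sample_id,
                relative_expression=rel,
                proportional_expression=weights[r.gene] / total,
                detected=r.detected,
            )
        )
    return out


def average_replicates(df: pd.DataFrame) -> list[QpcrRecord]:
    """Collapse replicate rows to one record per gene × sample.

    Expects columns ``sample_id, gene, ct, efficiency, is_housekeeping``;
    Ct is averaged over replicates, efficiency and the housekeeping flag
    must be constant within a group.
    """
    required = {"sample_id", "gene", "ct", "efficiency", "is_housekeeping"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    records = []
    for (sample_id, gene), grp in df.groupby(["sample_id", "gene"], sort=False):
        if grp["efficiency"].nunique() > 1:
            raise ValueError(f"{gene}/{sample_id}: inconsistent efficiencies")
        if grp["is_housekeeping"].nunique() > 1:
            raise ValueError(f"{gene}/{sample_id}: inconsistent housekeeping flag")
        ct = grp["ct"].dropna()
        records.append(
            QpcrRecord(
                gene=gene,
                sample_id=sample_id,
                ct=float(ct.mean()) if len(ct) else float("nan"),
                efficiency=float(grp["efficiency"].iloc[0]),
                is_housekeeping=bool(grp["is_housekeeping"].iloc[0]),
            )
        )
    return records


def expression_table(
    df: pd.DataFrame, amplification_base: str = "one_plus_e"
) -> pd.DataFrame:
    """Relative + proportional expression for every sample in a table."""
    records = average_replicates(df)
    rows = []
    for sample_id in sorted({r.sample_id for r in records}):
        sample_records = [r for r in records if r.sample_id == sample_id]
        for res in proportional_expression(sample_records, amplification_base):
            rows.append(
                {
                    "sample_id": res.sample_id,
                    "gene": res.gene,
                    "relative_expression": res.relative_expression,
                    "proportional_expression": res.proportional_expression,
                    "detected": res.detected,
                }
            )
    return pd.DataFrame(rows)
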