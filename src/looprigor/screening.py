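"""Variant screen orchestration: ranking, % change and rigidity–potency
correlation.

Variants are ranked by their mean internal hydrogen-bond count (the proxy
for binding-loop rigidity), percent changes are computed against a chosen
reference variant, measured potencies (Ki, IC50) are joined where
available, and Spearman/Pearson correlations between bond counts and Ki
quantify the structure–activity relationship.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .hbond_network import INTERNAL, INTERMOLECULAR, NetworkSummary, percent_change

__all__ = [
    "VariantResult",
    "CorrelationBlock",
    "ScreenReport",
    "spearman_rho",
    "build_report",
    "export_table",
]

TABLE_COLUMNS = [
    "variant",
    "internal_mean",
    "internal_sem",
    "internal_pct_change",
    "intermolecular_mean",
    "intermolecular_sem",
    "intermolecular_pct_change",
    "ki_nM",
    "ic50_nM",
]


@dataclass(frozen=True)
class VariantResult:
    """One row of the screen: H-bond statistics plus optional potencies."""

    variant_name: str
    internal_mean: float
    internal_sem: float | None
    internal_pct_change: float
    intermolecular_mean: float
    intermolecular_sem: float | None
    intermolecular_pct_change: float
    ki_nM: float | None = None
    ic50_nM: float | None = None


@dataclass(frozen=True)
class CorrelationBlock:
    """Correlation of one bond-count class against Ki over assayed variants."""

    spearman_rho: float
    pearson_r_log_ki: float
    pearson_r_ki: float
    n: int


@dataclass(frozen=True)
class ScreenReport:
    """Ranked variant table with correlation statistics.

    Variants are sorted by internal mean descending with a stable
    name-order tie-break; correlations are present only when at least three
    variants carry a Ki.
    """

    variants: tuple[VariantResult, ...]
    reference_variant: str
    correlations: Mapping[str, CorrelationBlock] | None


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need two equal-length vectors of at least 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman correlation is undefined", stacklevel=2)
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def _means(summary) -> tuple[float, float | None, float, float | None]:
    """Coerce a summary to (internal mean, SEM, intermolecular mean, SEM)."""
    if isinstance(summary, NetworkSummary):
        return (
            summary.mean_count[INTERNAL],
            summary.sem_count[INTERNAL],
            summary.mean_count[INTERMOLECULAR],
            summary.sem_count[INTERMOLECULAR],
        )
    if isinstance(summary, Mapping):
        return (
            float(summary["internal_mean"]),
            summary.get("internal_sem"),
            float(summary["intermolecular_mean"]),
            summary.get("intermolecular_sem"),
        )
    seq = tuple(summary)
    if len(seq) != 4:
        raise TypeError(
            "summary must be a NetworkSummary, a mapping, or a 4-tuple "
            "(internal_mean, internal_sem, intermolecular_mean, intermolecular_sem)"
        )
    return (float(seq[0]), seq[1], float(seq[2]), seq[3])


def build_report(
    summaries: Mapping[str, object],
    reference: str,
    potencies: Mapping[str, float] | None = None,
    ic50s: Mapping[str, float] | None = None,
) -> ScreenReport:
    """Assemble the ranked screen from per-variant summaries.

    ``potencies`` maps variant name to Ki (nM); variants without a Ki stay
    in the ranking with empty potency cells.
    """
    if reference not in summaries:
        raise ValueError(f"reference variant {reference!r} not among the summaries")
    potencies = dict(potencies or {})
    ic50s = dict(ic50s or {})
    ref_internal, _, ref_inter, _ = _means(summaries[reference])

    def pct(mean: float, ref_mean: float) -> float:
        # A class the reference never shows has no defined % change.
        return percent_change(mean, ref_mean) if ref_mean > 0 else float("nan")

    rows = []
    for name, summary in summaries.items():
        internal_mean, internal_sem, inter_mean, inter_sem = _means(summary)
        rows.append(
            VariantResult(
                variant_name=name,
                internal_mean=internal_mean,
                internal_sem=internal_sem,
                internal_pct_change=pct(internal_mean, ref_internal),
                intermolecular_mean=inter_mean,
                intermolecular_sem=inter_sem,
                intermolecular_pct_change=pct(inter_mean, ref_inter),
                ki_nM=potencies.get(name),
                ic50_nM=ic50s.get(name),
            )
        )
    rows.sort(key=lambda r: (-r.internal_mean, r.variant_name))

    assayed = [r for r in rows if r.ki_nM is not None]
    correlations: dict[str, CorrelationBlock] | None
    if len(assayed) < 3:
        if potencies:
            warnings.warn(
                "fewer than 3 variants carry a Ki; correlation omitted", stacklevel=2
            )
        correlations = None
    else:
        ki = np.array([r.ki_nM for r in assayed])
        log_ki = np.log10(ki)
        counts = {
            INTERNAL: np.array([r.internal_mean for r in assayed]),
            INTERMOLECULAR: np.array([r.intermolecular_mean for r in assayed]),
            "total": np.array([r.internal_mean + r.intermolecular_mean for r in assayed]),
        }
        def block(values: np.ndarray) -> CorrelationBlock:
            if np.ptp(values) == 0:  # constant counts: correlation undefined
                warnings.warn(
                    "constant bond counts across variants: correlation undefined",
                    stacklevel=3,
                )
                nan = float("nan")
                return CorrelationBlock(nan, nan, nan, len(assayed))
            return CorrelationBlock(
                spearman_rho=spearman_rho(values, ki),
                pearson_r_log_ki=float(stats.pearsonr(values, log_ki).statistic),
                pearson_r_ki=float(stats.pearsonr(values, ki).statistic),
                n=len(assayed),
            )

        correlations = {cls: block(values) for cls, values in counts.items()}

    return ScreenReport(
        variants=tuple(rows), reference_variant=reference, correlations=correlations
    )


def to_dataframe(report: ScreenReport) -> pd.DataFrame:
    """Screen table as a DataFrame with display rounding applied."""
    records = []
    for r in report.variants:
        records.append(
            {
                "variant": r.variant_name,
                "internal_mean": round(r.internal_mean, 2),
                "internal_sem": None if r.internal_sem is None else float(f"{r.internal_sem:.3g}"),
                "internal_pct_change": round(r.internal_pct_change, 1),
                "intermolecular_mean": round(r.intermolecular_mean, 2),
                "intermolecular_sem": (
                    None if r.intermolecular_sem is None else float(f"{r.intermolecular_sem:.3g}")
                ),
                "intermolecular_pct_change": round(r.intermolecular_pct_change, 1),
                "ki_nM": r.ki_nM,
                "ic50_nM": r.ic50_nM,
            }
        )
    return pd.DataFrame.from_records(records, columns=TABLE_COLUMNS)


def export_table(report: ScreenReport, path: str | Path) -> None:
    """Write the ranked screen as a TSV file (UTF-8, '.' decimal)."""
    to_dataframe(report).to_csv(path, sep="\t", index=False, na_rep="")
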