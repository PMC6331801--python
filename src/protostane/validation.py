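"""Method-validation statistics and batch-level summaries.

Precision (intra-/inter-day), repeatability, stability and spike recovery are
all reported as relative standard deviations or mean ± sd, following the
conventions of analytical method validation.  Batch-level analysis summarises
a samples × analytes content matrix and compares geographic origin groups
with two-sample t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quant import ContentMatrix

__all__ = [
    "ValidationDesign",
    "RecoveryResult",
    "rsd",
    "recovery",
    "validation_report",
    "batch_summary",
    "compare_origins",
]


@dataclass(frozen=True)
class ValidationDesign:
    """Replication structure of the validation experiment.

    Six intra-day injections of the mixed standards, duplicates on three
    consecutive days for inter-day precision, six independent sample
    preparations for repeatability, seven stability timepoints over 24 h,
    and a spiked-known recovery design.
    """

    intra_day_n: int = 6
    inter_day_per_day: int = 2
    inter_day_days: int = 3
    repeatability_n: int = 6
    stability_timepoints_h: tuple[float, ...] = (0, 4, 8, 12, 16, 20, 24)
    recovery_n: int = 6

    def __post_init__(self) -> None:
        counts = (
            self.intra_day_n,
            self.inter_day_per_day * self.inter_day_days,
            self.repeatability_n,
            len(self.stability_timepoints_h),
            self.recovery_n,
        )
        if min(counts) < 2:
            raise ValueError("every validation arm needs >= 2 measurements")


@dataclass(frozen=True)
class RecoveryResult:
    detected: float
    original: float
    added: float

    @property
    def recovery_pct(self) -> float:
        return recovery(self.detected, self.original, self.added)


def rsd(values) -> float:
    """Relative standard deviation, %, with the sample (n−1) denominator."""
    x = np.asarray(list(values), dtype=float)
    if len(x) < 2:
        raise ValueError("RSD needs at least 2 values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(x.std(ddof=1) / mean * 100.0)


def recovery(detected: float, original: float, added: float) -> float:
    """Spike recovery, %: (detected − original) × 100 / added."""
    if added <= 0:
        raise ValueError("added amount must be positive")
    return (detected - original) * 100.0 / added


def validation_report(arms: dict[str, dict[str, list]]) -> pd.DataFrame:
    """Summarise the validation arms analyte by analyte.

    ``arms`` maps arm name → {analyte → measurements}; recognised arms are
    ``intra_day``, ``inter_day``, ``repeatability``, ``stability`` (lists of
    measured values) and ``recovery`` (lists of ``(detected, original,
    added)`` triples).  The output has one row per analyte with the columns
    of a standard validation table: intra-/inter-day RSD, repeatability RSD
    and mean content, stability RSD, mean recovery ± sd and recovery RSD.
    """
    analytes: list[str] = []
    for arm in arms.values():
        for analyte in arm:
            if analyte not in analytes:
                analytes.append(analyte)
    rows = []
    for analyte in analytes:
        row: dict[str, float | str] = {"analyte": analyte}
        for arm_name, col in (
            ("intra_day", "intra_day_rsd_pct"),
            ("inter_day", "inter_day_rsd_pct"),
            ("repeatability", "repeatability_rsd_pct"),
            ("stability", "stability_rsd_pct"),
        ):
            if arm_name in arms and analyte in arms[arm_name]:
                values = arms[arm_name][analyte]
                if len(values) < 2:
                    raise ValueError(f"arm {arm_name!r} needs >= 2 values for {analyte!r}")
                row[col] = rsd(values)
                if arm_name == "repeatability":
                    row["repeatability_mean_mg_g"] = float(np.mean(values))
        if "recovery" in arms and analyte in arms["recovery"]:
            triples = arms["recovery"][analyte]
            if len(triples) < 2:
                raise ValueError(f"arm 'recovery' needs >= 2 values for {analyte!r}")
            recs = [recovery(*t) for t in triples]
            row["recovery_mean_pct"] = float(np.mean(recs))
            row["recovery_sd_pct"] = float(np.std(recs, ddof=1))
            row["recovery_rsd_pct"] = rsd(recs) if np.mean(recs) != 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("analyte")


def batch_summary(matrix: ContentMatrix) -> pd.DataFrame:
    """Per-analyte min / max / mean (ND-excluded) plus ND counts.

    Also reports, per analyte, in how many samples it is the most abundant
    compound (``n_dominant``).
    """
    if matrix.values.empty:
        raise ValueError("content matrix is empty")
    v = matrix.values
    dominant = v.idxmax(axis=1, skipna=True)
    out = pd.DataFrame(
        {
            "min_mg_g": v.min(),
            "max_mg_g": v.max(),
            "mean_mg_g": v.mean(),
            "n_nd": matrix.nd_mask.sum(),
            "n_dominant": dominant.value_counts().reindex(v.columns, fill_value=0),
        }
    )
    out.index.name = "analyte"
    return out


def compare_origins(
    matrix: ContentMatrix,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sample t-test per analyte between two origin groups.

    Student's pooled-variance t by default (``equal_var=False`` gives
    Welch).  ND cells are excluded pairwise; analytes with fewer than two
    non-ND values in either group are skipped (flagged in the
    ``skipped`` column).  ``flag`` is True when p < alpha, and
    ``higher_in`` names the group with the larger mean.  No multiple-testing
    correction is applied.
    """
    rows = []
    a_idx = matrix.origins == group_a
    b_idx = matrix.origins == group_b
    for analyte in matrix.analytes:
        col = matrix.values[analyte]
        a = col[a_idx].dropna().to_numpy()
        b = col[b_idx].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            rows.append(
                {
                    "analyte": analyte,
                    "mean_a": np.nan,
                    "mean_b": np.nan,
                    "t": np.nan,
                    "p": np.nan,
                    "flag": False,
                    "higher_in": "",
                    "skipped": True,
                }
            )
            continue
        if np.ptp(np.concatenate([a, b])) == 0:
            t, p = 0.0, 1.0  # identical constant groups
        else:
            t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        flag = bool(p < alpha)
        rows.append(
            {
                "analyte": analyte,
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
                "t": float(t),
                "p": float(p),
                "flag": flag,
                "higher_in": (group_a if a.mean() > b.mean() else group_b) if flag else "",
                "skipped": False,
            }
        )
    return pd.DataFrame(rows).set_index("analyte")


def plot_origin_comparison(matrix: ContentMatrix, comparison: pd.DataFrame, path=None):
    """Grouped bar chart of per-origin mean contents, starring p < 0.05.

    Requires matplotlib; returns the figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = sorted(matrix.origins.unique())
    analytes = matrix.analytes
    width = 0.8 / len(groups)
    fig, ax = plt.subplots(figsize=(10, 4))
    xs = np.arange(len(analytes))
    for gi, g in enumerate(groups):
        sub = matrix.values[matrix.origins == g]
        means = sub.mean()
        sds = sub.std(ddof=1)
        ax.bar(xs + gi * width, means, width, yerr=sds, capsize=2, label=g)
    for i, analyte in enumerate(analytes):
        if analyte in comparison.index and comparison.loc[analyte, "flag"]:
            top = matrix.values[analyte].max()
            ax.text(i + 0.4 * width, top * 1.02, "*", ha="center")
    ax.set_xticks(xs + width / 2)
    ax.set_xticklabels(analytes, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("content (mg/g)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
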