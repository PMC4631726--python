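"""Group summaries and substage comparisons of per-nucleus metrics.

Per-nucleus measurements are aggregated per (stage, cycle) group as
mean and sample standard deviation (n-1 denominator) with group size n,
mirroring the mean (±sd) layout of a substage summary table: volume,
Pearson r and COM offset per group, early/middle/late within the
mitotic cycle (2C-4C) and the endocycle (4C-8C).

The early-vs-middle contrast (Pearson r markedly lower in early S) is
tested with Welch's two-sample t-test by default — group variances are
unequal — with a Mann-Whitney U alternative available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .colocalization import NucleusMetrics

__all__ = [
    "GroupSummary",
    "STAGE_ORDER",
    "metrics_to_frame",
    "summarize_group",
    "compare_groups",
    "reproduce_table",
    "render_table",
]

#: Display order of (cycle, stage) groups in summary tables.
STAGE_ORDER = [
    ("mitotic", "E"),
    ("mitotic", "M"),
    ("mitotic", "L"),
    ("endocycle", "En-E"),
    ("endocycle", "En-M"),
    ("endocycle", "En-L"),
]

_METRIC_COLUMNS = ("volume_um3", "pearson_r", "com_offset_um", "knob_enrichment")


@dataclass
class GroupSummary:
    """Mean (±sd) summary of one substage group.

    ``sd`` entries are sample standard deviations (n-1); for n = 1 the
    sd is undefined and reported as NaN with ``sd_defined=False``.
    """

    stage: str
    cycle: str
    n: int
    mean: dict[str, float]
    sd: dict[str, float]
    buffer: str = "PBS"
    sd_defined: bool = True
    comparisons: list[dict] = field(default_factory=list)

    def as_row(self) -> dict:
        row = {"cycle": self.cycle, "stage": self.stage, "n": self.n, "buffer": self.buffer}
        for m in _METRIC_COLUMNS:
            row[f"{m}_mean"] = self.mean.get(m, np.nan)
            row[f"{m}_sd"] = self.sd.get(m, np.nan)
        return row


def metrics_to_frame(metrics: Iterable[NucleusMetrics]) -> pd.DataFrame:
    """Tabulate NucleusMetrics records as one row per nucleus."""
    return pd.DataFrame([m.as_row() for m in metrics])


def _values(metrics: Sequence[NucleusMetrics] | pd.DataFrame, name: str) -> np.ndarray:
    if isinstance(metrics, pd.DataFrame):
        if name not in metrics.columns:
            raise KeyError(f"metric {name!r} absent from table")
        vals = metrics[name].to_numpy(dtype=float)
    else:
        if not metrics:
            raise ValueError("empty metrics list")
        if not hasattr(metrics[0], name):
            raise KeyError(f"metric {name!r} absent from NucleusMetrics")
        vals = np.array([getattr(m, name) if getattr(m, name) is not None else np.nan for m in metrics], dtype=float)
    return vals[~np.isnan(vals)]


def summarize_group(
    metrics: Sequence[NucleusMetrics] | pd.DataFrame,
    stage: str | None = None,
    cycle: str | None = None,
    buffer: str = "PBS",
) -> GroupSummary:
    """Mean and sample sd of each metric over one group of nuclei."""
    if isinstance(metrics, pd.DataFrame):
        if metrics.empty:
            raise ValueError("empty metrics table")
        stages = set(metrics.get("stage", pd.Series(dtype=object)).dropna().unique())
        n = len(metrics)
    else:
        if not metrics:
            raise ValueError("empty metrics list")
        stages = {m.stage for m in metrics if m.stage is not None}
        n = len(metrics)
    if len(stages) > 1:
        raise ValueError(f"mixed stage labels in one group: {sorted(stages)}")
    if stage is None and stages:
        stage = next(iter(stages))
    if cycle is None:
        if isinstance(metrics, pd.DataFrame):
            cycles = set(metrics.get("cycle", pd.Series(dtype=object)).dropna().unique())
        else:
            cycles = {m.cycle for m in metrics if m.cycle is not None}
        cycle = next(iter(cycles)) if len(cycles) == 1 else "?"
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for name in _METRIC_COLUMNS:
        try:
            vals = _values(metrics, name)
        except KeyError:
            continue
        if vals.size == 0:
            continue
        mean[name] = float(vals.mean())
        if vals.size == 1:
            sd[name] = float("nan")
        elif np.ptp(vals) == 0.0:  # identical values: sd exactly zero
            sd[name] = 0.0
        else:
            sd[name] = float(vals.std(ddof=1))
    return GroupSummary(
        stage=stage or "?",
        cycle=cycle,
        n=n,
        mean=mean,
        sd=sd,
        buffer=buffer,
        sd_defined=n > 1,
    )


def compare_groups(
    a: Sequence[NucleusMetrics] | pd.DataFrame,
    b: Sequence[NucleusMetrics] | pd.DataFrame,
    metric: str = "pearson_r",
    test: str = "welch",
) -> dict:
    """Two-sample comparison of one metric between two groups.

    Returns a record with the test name, statistic, two-sided p-value
    and the direction of the difference (sign of mean(a) - mean(b)).
    """
    va, vb = _values(a, metric), _values(b, metric)
    if va.size < 2 or vb.size < 2:
        raise ValueError("both groups need at least 2 values")
    if test == "welch":
        res = stats.ttest_ind(va, vb, equal_var=False)
    elif test == "mannwhitney":
        res = stats.mannwhitneyu(va, vb, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    diff = float(va.mean() - vb.mean())
    return {
        "metric": metric,
        "test": test,
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "mean_a": float(va.mean()),
        "mean_b": float(vb.mean()),
        "direction": "a>b" if diff > 0 else ("a<b" if diff < 0 else "a=b"),
    }


def reproduce_table(
    manifest: pd.DataFrame,
    metrics: pd.DataFrame,
    buffer: str = "PBS",
) -> pd.DataFrame:
    """Assemble the per-group summary table from a population run.

    ``manifest`` lists one row per generated nucleus (columns include
    ``stage`` and ``cycle``); ``metrics`` is the per-nucleus measurement
    table.  Every manifest row must have a measurement.  Groups appear
    in canonical substage order; late-S rows carry r and COM offset as
    computed but are flagged ``reference='none'`` because no published
    target exists for them (``'table'`` otherwise).  The ``sd_is``
    column records that spreads are sample standard deviations.
    """
    if manifest.empty:
        raise ValueError("empty manifest")
    if len(manifest) != len(metrics):
        raise ValueError(f"manifest has {len(manifest)} rows but metrics has {len(metrics)}")
    rows = []
    for cycle, stage in STAGE_ORDER:
        grp = metrics[(metrics["stage"] == stage) & (metrics["cycle"] == cycle)]
        if grp.empty:
            continue
        summary = summarize_group(grp, stage=stage, cycle=cycle, buffer=buffer)
        row = summary.as_row()
        row["reference"] = "none" if stage.endswith("L") else "table"
        row["sd_is"] = "sample_sd"
        rows.append(row)
    if not rows:
        raise ValueError("no recognised (stage, cycle) groups in metrics")
    return pd.DataFrame(rows)


def render_table(table: pd.DataFrame) -> str:
    """Human-readable mean (±sd) rendering of a summary table."""
    lines = [
        f"{'cycle':<10} {'stage':<6} {'n':>4}  {'volume um^3':>16}  {'Pearson r':>16}  {'COM offset um':>16}"
    ]
    for _, row in table.iterrows():
        def fmt(mean_key: str, sd_key: str, prec: int) -> str:
            m, s = row[mean_key], row[sd_key]
            if np.isnan(m):
                return "-"
            return f"{m:.{prec}f} (+/-{s:.{prec}f})" if not np.isnan(s) else f"{m:.{prec}f}"

        lines.append(
            f"{row['cycle']:<10} {row['stage']:<6} {row['n']:>4}  "
            f"{fmt('volume_um3_mean', 'volume_um3_sd', 0):>16}  "
            f"{fmt('pearson_r_mean', 'pearson_r_sd', 3):>16}  "
            f"{fmt('com_offset_um_mean', 'com_offset_um_sd', 3):>16}"
        )
    return "\n".join(lines)
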