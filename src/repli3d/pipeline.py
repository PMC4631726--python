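"""End-to-end generate -> measure -> summarize runs.

Streams nuclei one at a time (generate, measure, discard) so full
six-group runs need only one stack in memory; the CLI's ``generate``
subcommand materializes stacks on disk instead, and ``measure`` reads
them back through the same measurement path.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .colocalization import measure_nucleus
from .staging import reproduce_table
from .synthetic_nuclei import PopulationConfig, iter_population
from .voxel_core import read_stack

__all__ = ["run_population", "measure_directory"]


def run_population(
    config: PopulationConfig,
    progress: bool = False,
    **measure_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate and measure a population without touching disk.

    Returns ``(manifest, metrics, summary)`` DataFrames: one manifest
    and metrics row per nucleus, one summary row per (cycle, stage)
    group in canonical order.
    """
    rows = []
    manifest_rows = []
    iterator = iter_population(config)
    if progress:
        total = sum(n for _, n in config.groups)
        from tqdm import tqdm  # optional nicety; plain loop if absent

        iterator = tqdm(iterator, total=total, unit="nucleus")
    for img, mrow in iterator:
        metrics = measure_nucleus(img, **measure_kwargs)
        rows.append(metrics.as_row())
        manifest_rows.append(mrow)
    manifest = pd.DataFrame(manifest_rows)
    metrics_df = pd.DataFrame(rows)
    summary = reproduce_table(manifest, metrics_df)
    return manifest, metrics_df, summary


def measure_directory(path: str | Path, **measure_kwargs) -> pd.DataFrame:
    """Measure every written stack listed in a directory's manifest.

    The directory must contain ``manifest.csv`` (as written by
    ``make_population``) and the TIFF+sidecar pairs it names.
    """
    path = Path(path)
    manifest_path = path / "manifest.csv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.csv in {path}")
    manifest = pd.read_csv(manifest_path)
    rows = []
    for _, mrow in manifest.iterrows():
        img = read_stack(mrow["file"])
        metrics = measure_nucleus(img, **measure_kwargs)
        rows.append(metrics.as_row())
    return pd.DataFrame(rows)
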