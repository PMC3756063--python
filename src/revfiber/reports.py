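"""Summary report tables derived from a long-format trait table.

Produces the study's standard summary layouts: a muscle-by-group
mean +/- sd density grid, a per-group maximum cluster-size grid,
per-muscle trend tables for every trait, and a contrast summary.
Densities are rounded to one decimal in the formatted grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .core import MUSCLES, ValidationError
from .quantify import aggregate_traits

PathLike = Union[str, Path]


def _ordered_muscles(frame: pd.DataFrame) -> list[str]:
    present = set(frame["muscle"])
    return [m for m in MUSCLES if m in present] + sorted(present - set(MUSCLES))


@dataclass(frozen=True)
class Reports:
    """All report frames; ``write`` saves each as CSV."""

    density_mean: pd.DataFrame
    density_sd: pd.DataFrame
    density_grid: pd.DataFrame
    max_cluster: pd.DataFrame
    trends: pd.DataFrame
    contrast_summary: Optional[pd.DataFrame]

    def write(self, out_dir: PathLike) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("density_mean", "density_sd", "density_grid", "max_cluster", "trends"):
            path = out / f"{name}.csv"
            getattr(self, name).to_csv(path)
            paths[name] = path
        if self.contrast_summary is not None:
            path = out / "contrast_summary.csv"
            self.contrast_summary.to_csv(path, index=False)
            paths["contrast_summary"] = path
        return paths


def report_tables(
    trait_table: pd.DataFrame, contrasts: Optional[pd.DataFrame] = None
) -> Reports:
    """Build every report table from a long-format trait table.

    The density grids summarize ``rf_per_mm2`` per muscle and age group
    (mean over sections within mouse, then over mice); the max-cluster
    grid is the per-group maximum of ``max_cluster_size`` over all
    sections; trends carry per-muscle-per-group means of every trait.
    """
    if trait_table.empty:
        raise ValidationError("trait table is empty")
    agg = aggregate_traits(trait_table)
    order = _ordered_muscles(trait_table)

    density = agg.per_group[agg.per_group["trait"] == "rf_per_mm2"]
    mean = density.pivot(index="muscle", columns="age_group", values="mean").reindex(order)
    sd = density.pivot(index="muscle", columns="age_group", values="sd").reindex(order)
    grid = pd.DataFrame(
        {
            col: [
                f"{mean.loc[m, col]:.1f}±{sd.loc[m, col]:.1f}"
                if pd.notna(mean.loc[m, col])
                else ""
                for m in mean.index
            ]
            for col in mean.columns
        },
        index=mean.index,
    )
    grid.columns = [f"GROUP {c}" for c in grid.columns]

    max_rows = trait_table[trait_table["trait"] == "max_cluster_size"]
    max_cluster = (
        max_rows.groupby(["muscle", "age_group"])["value"].max().unstack().reindex(order)
    )

    trends = (
        trait_table.groupby(["muscle", "age_group", "mouse_id", "trait"])["value"]
        .mean()
        .groupby(["muscle", "age_group", "trait"])
        .mean()
        .rename("mean")
        .reset_index()
        .pivot(index=["muscle", "age_group"], columns="trait", values="mean")
    )

    return Reports(
        density_mean=mean,
        density_sd=sd,
        density_grid=grid,
        max_cluster=max_cluster,
        trends=trends,
        contrast_summary=contrasts,
    )
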