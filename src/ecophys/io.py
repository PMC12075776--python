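"""Reading and writing the delimited tables the analysis modules consume.

All readers accept CSV or TSV (delimiter sniffed from the extension or via
``sep``), require headers, and return the package's in-memory types.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ecology import RecruitmentTable
from .growth import ConditionSummary, GrowthCurve, GrowthEnvelope, InstantRateSeries
from .morphology import CellMeasurement

__all__ = [
    "read_table",
    "read_growth_table",
    "read_cell_table",
    "read_recruitment",
    "read_ani",
    "rate_series_frame",
    "condition_summary_frame",
    "envelope_frame",
]

GROWTH_ID_COLS = ("strain", "replicate")
GROWTH_VALUE_COLS = ("time_days", "density_cells_per_ml")


def _sep_for(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_table(path: str | Path, sep: str | None = None, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep_for(path, sep), **kwargs)


def read_growth_table(path: str | Path, sep: str | None = None) -> list[GrowthCurve]:
    """Long-format growth table -> one GrowthCurve per (strain, replicate,
    condition) group.

    Required columns: strain, replicate, time_days, density_cells_per_ml;
    every other column is treated as a condition variable (e.g.
    temperature_C, salinity_ppt, carbon_uM).
    """
    df = read_table(path, sep=sep)
    required = set(GROWTH_ID_COLS) | set(GROWTH_VALUE_COLS)
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"growth table missing columns: {sorted(missing)}")
    cond_cols = [c for c in df.columns if c not in required]
    curves: list[GrowthCurve] = []
    for key, grp in df.groupby(list(GROWTH_ID_COLS) + cond_cols, sort=True, dropna=False):
        key = (key,) if not isinstance(key, tuple) else key
        grp = grp.sort_values("time_days")
        condition = dict(zip(cond_cols, key[2:]))
        curves.append(
            GrowthCurve(
                strain_id=str(key[0]),
                replicate_id=str(key[1]),
                condition=condition,
                times=grp["time_days"].to_numpy(float),
                densities=grp["density_cells_per_ml"].to_numpy(float),
            )
        )
    return curves


def read_cell_table(path: str | Path, sep: str | None = None) -> list[CellMeasurement]:
    """Cell-measurement table in either of two dialects.

    Long dialect: columns cell_id, area_px2, scale_um_per_px, radius_px with
    one row per measured radius. List dialect: one row per cell with a
    ``radii_px`` column holding ';'- or ','-separated radii.
    """
    df = read_table(path, sep=sep)
    base = {"cell_id", "area_px2", "scale_um_per_px"}
    missing = base - set(df.columns)
    if missing:
        raise ValueError(f"cell table missing columns: {sorted(missing)}")
    cells: list[CellMeasurement] = []
    if "radius_px" in df.columns:
        for cell_id, grp in df.groupby("cell_id", sort=True):
            cells.append(
                CellMeasurement(
                    cell_id=str(cell_id),
                    area_px2=float(grp["area_px2"].iloc[0]),
                    radii_px=tuple(grp["radius_px"].astype(float)),
                    scale_um_per_px=float(grp["scale_um_per_px"].iloc[0]),
                )
            )
    elif "radii_px" in df.columns:
        for _, row in df.iterrows():
            raw = str(row["radii_px"]).replace(";", ",")
            radii = tuple(float(x) for x in raw.split(",") if x.strip())
            cells.append(
                CellMeasurement(
                    cell_id=str(row["cell_id"]),
                    area_px2=float(row["area_px2"]),
                    radii_px=radii,
                    scale_um_per_px=float(row["scale_um_per_px"]),
                )
            )
    else:
        raise ValueError("cell table needs a radius_px or radii_px column")
    return cells


def read_recruitment(
    counts_path: str | Path,
    lengths_path: str | Path,
    recruited_bp_path: str | Path,
    metadata_path: str | Path | None = None,
    sep: str | None = None,
) -> RecruitmentTable:
    """Assemble a RecruitmentTable from its component tables.

    counts: genomes x samples matrix with genome ids in the first column;
    lengths: columns genome, length_bp; recruited_bp: columns sample,
    recruited_bp (optional total_bp); metadata: sample-indexed covariates.
    """
    counts = read_table(counts_path, sep=sep, index_col=0)
    lengths = read_table(lengths_path, sep=sep).set_index("genome")["length_bp"]
    bp = read_table(recruited_bp_path, sep=sep).set_index("sample")
    meta = (
        read_table(metadata_path, sep=sep, index_col=0)
        if metadata_path is not None
        else None
    )
    return RecruitmentTable(
        counts=counts,
        genome_lengths=lengths,
        recruited_bp=bp["recruited_bp"],
        total_bp=bp["total_bp"] if "total_bp" in bp.columns else None,
        sample_metadata=meta,
    )


def read_ani(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Pairwise ANI as a square labeled matrix.

    Accepts either a square CSV/TSV (genome labels as first column and
    header) or fastANI-style long format with columns query, reference, ani.
    Long input is pivoted; the diagonal is set to 100 and pairs fastANI left
    unreported (below its reporting range) are filled with 0.
    """
    df = read_table(path, sep=sep)
    cols = {c.lower() for c in df.columns}
    if {"query", "reference", "ani"} <= cols:
        df.columns = [c.lower() for c in df.columns]
        wide = df.pivot_table(index="query", columns="reference", values="ani")
        genomes = sorted(set(wide.index) | set(wide.columns))
        wide = wide.reindex(index=genomes, columns=genomes)
        wide = wide.fillna(0.0)
        np.fill_diagonal(wide.values, 100.0)
        return wide
    return read_table(path, sep=sep, index_col=0)


def rate_series_frame(series: InstantRateSeries) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_days": series.times,
            "median_rate_doublings_per_day": series.median_rates,
        }
    )


def condition_summary_frame(summaries: Sequence[ConditionSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = dict(s.condition)
        row.update(
            representative_rate=s.representative_rate,
            mean_rate=s.mean_rate,
            rate_sd=s.rate_dispersion,
            rate_min=s.rate_range[0],
            rate_max=s.rate_range[1],
            max_density_cells_per_ml=s.max_density,
            fold_increase=s.fold_increase,
            growth_call=s.growth_call,
            n_replicates=s.n_replicates,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def envelope_frame(env: GrowthEnvelope) -> pd.DataFrame:
    df = condition_summary_frame(env.summaries)
    df["variable"] = env.variable
    return df
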