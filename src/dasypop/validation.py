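"""Zonal aggregation and one-to-one validation reports.

The defining property of proportional allotment is that aggregating any
output year back to countries reproduces the scenario inputs exactly, so
the headline validation is a one-to-one comparison: r-squared computed
about the identity line (residuals measured against the reference, not
against a refit regression) together with the RMSE in persons.  The
regression-based r-squared is available behind a flag for comparisons
against independent products, where a systematic level offset is expected
and only the spatial pattern is of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_grids import CountryRaster, FineGrid

__all__ = ["ValidationReport", "aggregate_by_region", "compare", "change_report"]


def aggregate_by_region(pop: FineGrid, regions: CountryRaster) -> pd.Series:
    """Sum valid pixel values per region id.

    Returns a Series indexed by region id, covering every id present on
    the region raster; the aggregation is lossless (the totals sum to the
    grid total over jointly valid pixels).
    """
    if regions.geometry != pop.geometry:
        raise ValueError("region raster geometry does not match population geometry")
    joint = pop.valid_mask & regions.valid_mask
    ids = regions.ids[joint]
    vals = pop.values[joint]
    out = {}
    all_ids = regions.country_ids()
    sums = np.bincount(ids, weights=vals, minlength=(all_ids.max() + 1) if all_ids.size else 1)
    for rid in all_ids:
        out[int(rid)] = float(sums[rid])
    return pd.Series(out, name="population").sort_index()


@dataclass
class ValidationReport:
    """Per-region comparison rows plus one-to-one summary statistics.

    ``r_squared`` is None when fewer than two regions are available or
    when the reference has zero variance (SS_tot = 0), with ``note``
    explaining why.
    """

    rows: pd.DataFrame  # region_id, aggregated, reference, difference
    n_regions: int
    r_squared: float | None
    rmse: float
    one_to_one: bool
    note: str = ""

    def summary(self) -> str:
        r2 = "undefined" if self.r_squared is None else f"{self.r_squared:.6f}"
        kind = "one-to-one" if self.one_to_one else "regression"
        lines = [
            f"regions compared: {self.n_regions}",
            f"r-squared ({kind}): {r2}",
            f"RMSE: {self.rmse:.6g} persons",
        ]
        if self.note:
            lines.append(f"note: {self.note}")
        return "\n".join(lines)


def compare(
    aggregated: pd.Series, reference: pd.Series, one_to_one: bool = True
) -> ValidationReport:
    """Compare aggregated totals against reference totals region by region.

    With ``one_to_one=True`` (default) residuals are measured against the
    reference values themselves: r2 = 1 - SS_res/SS_tot with SS_res the
    squared differences from the identity line.  With ``one_to_one=False``
    an ordinary least-squares line is fit first and r2 is the squared
    Pearson correlation, insensitive to level offsets.
    """
    agg = pd.Series(aggregated).sort_index()
    ref = pd.Series(reference).sort_index()
    if set(agg.index) != set(ref.index):
        raise ValueError("aggregated and reference region id sets differ")
    rows = pd.DataFrame(
        {
            "region_id": agg.index,
            "aggregated": agg.to_numpy(dtype=float),
            "reference": ref.to_numpy(dtype=float),
        }
    )
    rows["difference"] = rows["aggregated"] - rows["reference"]
    n = len(rows)
    diff = rows["difference"].to_numpy()
    rmse = float(np.sqrt(np.mean(diff**2))) if n else 0.0
    note = ""
    r2: float | None
    if n < 2:
        r2, note = None, "fewer than two regions: r-squared undefined"
    elif one_to_one:
        ss_tot = float(np.sum((rows["reference"] - rows["reference"].mean()) ** 2))
        if ss_tot == 0.0:
            if np.allclose(diff, 0.0):
                r2 = 1.0
            else:
                r2, note = None, "reference has zero variance: r-squared undefined"
        else:
            r2 = 1.0 - float(np.sum(diff**2)) / ss_tot
    else:
        ref_v = rows["reference"].to_numpy()
        agg_v = rows["aggregated"].to_numpy()
        if np.std(ref_v) == 0 or np.std(agg_v) == 0:
            r2, note = None, "zero variance: regression r-squared undefined"
        else:
            r2 = float(np.corrcoef(ref_v, agg_v)[0, 1] ** 2)
    return ValidationReport(rows, n, r2, rmse, one_to_one, note)


def change_report(
    pop_t0: FineGrid,
    pop_t1: FineGrid,
    regions: CountryRaster,
    ref_t0: pd.Series,
    ref_t1: pd.Series,
) -> pd.DataFrame:
    """Per-region population change pairs for a one-to-one change scatter.

    Returns columns ``region_id, aggregated_change, reference_change``:
    the grid-derived change (t1 - t0) paired with the reference change,
    ready to plot against the identity line.
    """
    agg0 = aggregate_by_region(pop_t0, regions)
    agg1 = aggregate_by_region(pop_t1, regions)
    ref0 = pd.Series(ref_t0).sort_index()
    ref1 = pd.Series(ref_t1).sort_index()
    if set(ref0.index) != set(agg0.index) or set(ref1.index) != set(agg0.index):
        raise ValueError("reference region id sets differ from the raster's")
    return pd.DataFrame(
        {
            "region_id": agg0.index,
            "aggregated_change": (agg1 - agg0).to_numpy(dtype=float),
            "reference_change": (ref1 - ref0).to_numpy(dtype=float),
        }
    )
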