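"""Anchoring scan results to the genetic map and heatmap binning.

Scaffolds carrying associated markers are placed on the linkage map through
the genome-zipper lookup table (scaffold -> linkage group + cM); scaffolds
absent from the zipper stay unanchored and are rendered "--".  For the
per-linkage-group heatmaps, the intervals between consecutive linkage-map
markers define the bins, and each bin's value is the median Kruskal-Wallis
statistic of the anchored markers falling inside it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["anchor_markers", "bin_by_map_intervals", "heatmap_matrix", "UNANCHORED"]

UNANCHORED = "--"


def anchor_markers(results: pd.DataFrame, zipper: pd.DataFrame) -> pd.DataFrame:
    """Attach (lg, pos_cm) to scan results via the scaffold zipper lookup.

    Every marker on an anchored scaffold inherits that scaffold's genetic
    position; markers on scaffolds absent from the zipper get lg = "--" and
    NaN pos_cm.  The anchored + unanchored counts are recorded in
    ``DataFrame.attrs``.
    """
    lut = zipper.set_index("scaffold")[["lg", "pos_cm"]]
    out = results.copy()
    anchored = out["scaffold"].isin(lut.index)
    out["lg"] = [
        int(lut.at[s, "lg"]) if ok else UNANCHORED
        for s, ok in zip(out["scaffold"], anchored, strict=True)
    ]
    out["pos_cm"] = [
        float(lut.at[s, "pos_cm"]) if ok else np.nan
        for s, ok in zip(out["scaffold"], anchored, strict=True)
    ]
    out.attrs["n_anchored"] = int(anchored.sum())
    out.attrs["n_unanchored"] = int((~anchored).sum())
    return out


def _intervals(gmap: pd.DataFrame, lg: int) -> np.ndarray:
    pos = gmap.loc[gmap["lg"] == lg, "pos_cm"].sort_values().to_numpy()
    if len(pos) < 2:
        raise ValueError(f"map needs >= 2 markers on LG{lg}, has {len(pos)}")
    return pos


def bin_by_map_intervals(
    anchored: pd.DataFrame, gmap: pd.DataFrame, family: str, lg: int, value_col: str = "H"
) -> pd.DataFrame:
    """Median statistic per interval between consecutive linkage-map markers.

    Intervals are half-open [m_i, m_{i+1}), the final one closed; a marker
    exactly on an interior map position joins the interval to its right.
    Markers anchored outside the map extent are clamped to the terminal
    interval with a warning.  Cells with no markers report n_markers = 0
    and a NaN median.
    """
    pos = _intervals(gmap, lg)
    sel = anchored[(anchored["lg"] == lg) & anchored["pos_cm"].notna()]
    cm = sel["pos_cm"].to_numpy(dtype=float)
    vals = sel[value_col].to_numpy(dtype=float)
    outside = (cm < pos[0]) | (cm > pos[-1])
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} markers outside the LG{lg} map extent; "
            "clamped to the terminal interval"
        )
    # side="right" puts a marker exactly on an interior boundary into the
    # right-hand interval; the final interval is closed at the top.
    which = np.searchsorted(pos, cm, side="right") - 1
    which = np.clip(which, 0, len(pos) - 2)
    rows = []
    for k in range(len(pos) - 1):
        in_cell = vals[which == k]
        rows.append(
            {
                "family_id": family,
                "lg": lg,
                "left_cm": float(pos[k]),
                "right_cm": float(pos[k + 1]),
                "median_H": float(np.median(in_cell)) if len(in_cell) else np.nan,
                "n_markers": int(len(in_cell)),
            }
        )
    return pd.DataFrame(rows)


def heatmap_matrix(cells: pd.DataFrame, families: list[str]) -> tuple[pd.DataFrame, tuple]:
    """Families x intervals matrix of median statistics plus color bounds.

    Missing cells stay NaN; the color scale runs from 0 to the largest
    median in the matrix.
    """
    lgs = cells["lg"].unique()
    if len(lgs) != 1:
        raise ValueError(f"cells span several linkage groups: {sorted(lgs)}")
    piv = cells.pivot_table(
        index="family_id", columns="left_cm", values="median_H", aggfunc="first", dropna=False
    )
    piv = piv.reindex(index=families)
    piv = piv[sorted(piv.columns)]
    vmax = float(np.nanmax(piv.to_numpy())) if np.isfinite(piv.to_numpy()).any() else 0.0
    return piv, (0.0, vmax)
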