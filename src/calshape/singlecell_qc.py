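"""Single-cell inclusion filtering for high-content micropattern imaging.

Segmentation exports four per-well delimited tables: calcium-channel
cell objects with morphology (file 1), post-stain cell objects
(file 2), nuclei with spacing statistics (file 3), and the cross-image
region match table (file 4).  These are merged per region and five
inclusion rules decide which regions hold exactly one correctly
matched, correctly shaped single cell:

1. shape window — circularity 4*pi*A/P**2 must be >= 0.9 for rounded
   ("O") patterns, or within 0.5..0.85 inclusive for elongated ("L");
2. single nucleus — exactly one nucleus in the region;
3. nucleus spacing — nearest other nucleus at least 20 px away;
4. nucleus size — nucleus area strictly below 300 um^2 (larger implies
   a merged pair of nuclei);
5. centroid agreement — the three per-region centroids (calcium,
   nucleus, post-stain) may disagree by at most 30 um, roughly one cell
   width; strictly larger gaps mean a mismatched object.

All rules are independent, so the cascade is order-free.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "shape_factor",
    "merge_object_tables",
    "apply_filters",
    "SHAPE_FACTOR_WINDOWS",
    "NUCLEUS_MIN_DIST_PX",
    "NUCLEUS_AREA_UM2",
    "CENTROID_MISMATCH_UM",
    "RULES",
]

#: Inclusive circularity windows per micropattern geometry.
SHAPE_FACTOR_WINDOWS = {"O": (0.9, np.inf), "L": (0.5, 0.85)}
#: Minimum nucleus-to-nucleus spacing (pixels), inclusive.
NUCLEUS_MIN_DIST_PX = 20.0
#: Maximum single-nucleus area (um^2), exclusive.
NUCLEUS_AREA_UM2 = 300.0
#: Maximum pairwise centroid disagreement (um), inclusive.
CENTROID_MISMATCH_UM = 30.0

RULES = ("shape_factor", "multi_nucleus", "nucleus_distance", "nucleus_area", "centroid_mismatch")

_REQUIRED = {
    "file1": ["region_id", "cal_cx_um", "cal_cy_um", "cell_area_um2", "perimeter_um"],
    "file2": ["region_id", "post_cx_um", "post_cy_um"],
    "file3": ["region_id", "hoe_cx_um", "hoe_cy_um", "nucleus_area_um2",
              "nucleus_min_dist_px", "nuclei_in_region"],
    "file4": ["region_id"],
}


def shape_factor(area, perimeter):
    """Circularity 4*pi*area/perimeter**2 (1 for a perfect circle)."""
    area = np.asarray(area, dtype=float)
    perimeter = np.asarray(perimeter, dtype=float)
    if np.any(perimeter <= 0):
        raise ValueError("perimeter must be positive")
    out = 4.0 * np.pi * area / perimeter**2
    return out if out.ndim else float(out)


def _load(table, name):
    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table, sep="\t")
    missing = set(_REQUIRED[name]) - set(df.columns)
    if missing:
        raise ValueError(f"{name} lacks columns {sorted(missing)}")
    if df["region_id"].duplicated().any():
        dup = df.loc[df["region_id"].duplicated(), "region_id"].tolist()
        raise ValueError(f"duplicate region ids in {name}: {dup}")
    return df


def merge_object_tables(file1, file2, file3, file4) -> pd.DataFrame:
    """Outer-merge the four object tables into one record per region.

    Accepts DataFrames or paths to tab-separated files.  Regions absent
    from any table keep NaN in that table's columns and are flagged
    ``complete = False`` (such records are excluded downstream).  A
    derived ``shape_factor`` column is attached.
    """
    f1 = _load(file1, "file1")
    f2 = _load(file2, "file2")
    f3 = _load(file3, "file3")
    f4 = _load(file4, "file4")
    merged = f1.merge(f2, on="region_id", how="outer")
    merged = merged.merge(f3, on="region_id", how="outer")
    merged = merged.merge(f4[["region_id"]].assign(_in_file4=True), on="region_id", how="outer")
    merged["_in_file4"] = merged["_in_file4"].fillna(False)
    need = [c for cols in _REQUIRED.values() for c in cols if c != "region_id"]
    merged["complete"] = merged["_in_file4"] & merged[need].notna().all(axis=1)
    merged = merged.drop(columns="_in_file4")
    sf = np.full(len(merged), np.nan)
    ok = merged["perimeter_um"].to_numpy(float) > 0
    sf[ok] = shape_factor(
        merged.loc[ok, "cell_area_um2"], merged.loc[ok, "perimeter_um"]
    )
    merged["shape_factor"] = sf
    return merged


def apply_filters(
    records: pd.DataFrame, shape_group: str, um_per_pixel: float | None = None
) -> pd.DataFrame:
    """Apply the five single-cell inclusion rules to merged records.

    Returns a copy of ``records`` with one boolean ``pass_<rule>`` column
    per rule, a ``failed_rules`` list column, and ``included`` (true iff
    no rule failed and the record is complete).  ``records`` must carry
    the merged-table columns; if nucleus spacing is only available in
    micrometres (column ``nucleus_min_dist_um``), ``um_per_pixel`` is
    required to convert it.
    """
    if shape_group not in SHAPE_FACTOR_WINDOWS:
        raise ValueError(f"unknown shape_group {shape_group!r}; expected one of "
                         f"{sorted(SHAPE_FACTOR_WINDOWS)}")
    df = records.copy()
    if "shape_factor" not in df:
        df["shape_factor"] = shape_factor(df["cell_area_um2"], df["perimeter_um"])
    if "nucleus_min_dist_px" not in df:
        if "nucleus_min_dist_um" not in df:
            raise ValueError("need nucleus_min_dist_px or nucleus_min_dist_um")
        if um_per_pixel is None or um_per_pixel <= 0:
            raise ValueError("um_per_pixel required to convert nucleus spacing to pixels")
        df["nucleus_min_dist_px"] = df["nucleus_min_dist_um"] / um_per_pixel

    lo, hi = SHAPE_FACTOR_WINDOWS[shape_group]
    sf = df["shape_factor"].to_numpy(float)
    df["pass_shape_factor"] = (sf >= lo) & (sf <= hi)
    df["pass_multi_nucleus"] = df["nuclei_in_region"].to_numpy(float) == 1
    df["pass_nucleus_distance"] = df["nucleus_min_dist_px"].to_numpy(float) >= NUCLEUS_MIN_DIST_PX
    df["pass_nucleus_area"] = df["nucleus_area_um2"].to_numpy(float) < NUCLEUS_AREA_UM2

    cents = df[["cal_cx_um", "cal_cy_um", "hoe_cx_um", "hoe_cy_um",
                "post_cx_um", "post_cy_um"]].to_numpy(float)
    gaps = np.stack([
        np.hypot(cents[:, 0] - cents[:, 2], cents[:, 1] - cents[:, 3]),
        np.hypot(cents[:, 0] - cents[:, 4], cents[:, 1] - cents[:, 5]),
        np.hypot(cents[:, 2] - cents[:, 4], cents[:, 3] - cents[:, 5]),
    ])
    df["max_centroid_gap_um"] = gaps.max(axis=0)
    df["pass_centroid_mismatch"] = df["max_centroid_gap_um"].to_numpy() <= CENTROID_MISMATCH_UM

    pass_cols = [f"pass_{r}" for r in RULES]
    # NaN comparisons are False already, so incomplete records fail closed
    complete = df["complete"].to_numpy(bool) if "complete" in df else np.ones(len(df), bool)
    df["failed_rules"] = [
        [r for r, ok in zip(RULES, flags) if not ok]
        for flags in df[pass_cols].to_numpy(bool)
    ]
    df["included"] = complete & df[pass_cols].all(axis=1).to_numpy()
    return df
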