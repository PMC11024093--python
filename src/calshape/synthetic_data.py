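"""Seeded generators for every input the pipeline consumes.

Three families of synthetic data are produced:

* **Calcium transients** drawn from the rise-decay model with
  group-dependent decay rates, a constant pre-stimulus baseline and
  i.i.d. Gaussian frame noise.  Default acquisition geometry mirrors a
  30-minute time lapse at 30 s per frame (61 frames including t = 0)
  with the agonist added at the tenth acquired frame, so that after the
  drop-first preprocessing rule the baseline occupies retained frames
  0..7 and the transient starts at frame 8.
* **High-content object tables**: four linked per-well tables (calcium
  objects, post-stain cell objects, nuclei, and the cross-image match
  table) with violations of each single-cell QC rule planted on demand
  and ground-truth inclusion labels computed by direct evaluation of
  the five rules on the emitted values.
* **Tumor expression matrices** with a single latent
  epithelial-mesenchymal axis loading positively on epithelial
  signature genes and negatively on mesenchymal ones, plus unstructured
  filler genes.

Fixed seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epimes import load_gene_lists
from .singlecell_qc import (
    CENTROID_MISMATCH_UM,
    NUCLEUS_AREA_UM2,
    NUCLEUS_MIN_DIST_PX,
    SHAPE_FACTOR_WINDOWS,
)
from .trace_preprocess import METADATA_COLUMNS, TraceMatrix
from .transient_model import TransientParams, _eval

__all__ = [
    "ParamRanges",
    "CohortSpec",
    "ObjectLayout",
    "ExpressionSimSpec",
    "simulate_transient",
    "simulate_cohort",
    "simulate_object_tables",
    "simulate_expression",
    "simulate_grid_family",
]

DEFAULT_BASELINE_AU = 100.0


@dataclass(frozen=True)
class ParamRanges:
    """Log-uniform sampling ranges for one group's transient kinetics.

    ``inv_tau_decay_s`` is the range of the decay *time constant*
    1/tau_decay in seconds; the other entries are in model units.
    """

    inv_tau_decay_s: tuple[float, float]
    tau_delta: tuple[float, float] = (1e-2, 1e-1)
    b: tuple[float, float] = (50.0, 200.0)
    c: tuple[float, float] = (20.0, 100.0)

    def sample(self, rng: np.random.Generator) -> TransientParams:
        def logu(lo, hi):
            return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

        return TransientParams(
            tau_decay=1.0 / logu(*self.inv_tau_decay_s),
            tau_delta=logu(*self.tau_delta),
            b=logu(*self.b),
            c=logu(*self.c),
        )


# Rounded ("O") cells decay faster than elongated ("L") cells: the group
# gap in 1/tau_decay is the condition the cohort generator reproduces.
DEFAULT_GROUP_RANGES = {
    "O": ParamRanges(inv_tau_decay_s=(30.0, 150.0)),
    "L": ParamRanges(inv_tau_decay_s=(200.0, 800.0)),
}


@dataclass
class CohortSpec:
    """Study design for a simulated two-geometry calcium imaging cohort."""

    n_cells: dict[str, int] = field(default_factory=lambda: {"O": 60, "L": 60})
    group_ranges: dict[str, ParamRanges] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_RANGES)
    )
    concentrations: tuple[float, ...] = (0.3, 1.0, 3.0)
    n_frames: int = 61
    dt: float = 30.0
    agonist_frame: int = 9  # tenth acquired frame, 0-based
    baseline: float = DEFAULT_BASELINE_AU
    noise_sd: float = 2.0
    nonresponder_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if not self.n_cells or any(n <= 0 for n in self.n_cells.values()):
            raise ValueError("every group needs a positive cell count")
        if self.agonist_frame >= self.n_frames:
            raise ValueError("agonist_frame must precede n_frames")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0 <= self.nonresponder_fraction <= 1:
            raise ValueError("nonresponder_fraction must lie in [0, 1]")
        if set(self.n_cells) - set(self.group_ranges):
            raise ValueError("missing kinetic ranges for some groups")


def simulate_transient(
    params: TransientParams,
    n_frames: int,
    dt: float,
    agonist_frame: int,
    noise_sd: float,
    seed: int | np.random.Generator,
    baseline: float = DEFAULT_BASELINE_AU,
) -> np.ndarray:
    """One raw fluorescence trace: baseline, then baseline + f(t) + noise.

    Frames before ``agonist_frame`` sit at the baseline constant; from
    ``agonist_frame`` on, the rise-decay model is evaluated at
    t = (frame - agonist_frame) * dt and added to the baseline.  Gaussian
    noise of sd ``noise_sd`` is added to every frame independently.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_frames < agonist_frame + 2:
        raise ValueError("n_frames must be at least agonist_frame + 2")
    if agonist_frame < 0:
        raise ValueError("agonist_frame must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trace = np.full(n_frames, float(baseline))
    t = (np.arange(agonist_frame, n_frames) - agonist_frame) * dt
    trace[agonist_frame:] += _eval(params.tau_decay, params.tau_delta, params.b, params.c, t)
    if noise_sd > 0:
        trace += rng.normal(0.0, noise_sd, n_frames)
    return trace


def simulate_cohort(spec: CohortSpec) -> tuple[TraceMatrix, pd.DataFrame]:
    """Simulate a full cohort; returns the trace matrix and a ground-truth table.

    Cells are assigned to agonist concentrations round-robin within each
    group.  Non-responders emit baseline plus noise only.  The truth
    table records each cell's sampled parameters and responder status.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows, meta, truth = [], [], []
    cell_idx = 0
    for group in sorted(spec.n_cells):
        ranges = spec.group_ranges[group]
        for j in range(spec.n_cells[group]):
            conc = spec.concentrations[j % len(spec.concentrations)]
            params = ranges.sample(rng)
            responder = bool(rng.uniform() >= spec.nonresponder_fraction)
            eff = params if responder else TransientParams(0.0, 0.0, 0.0, 0.0)
            trace = simulate_transient(
                eff, spec.n_frames, spec.dt, spec.agonist_frame,
                spec.noise_sd, rng, baseline=spec.baseline,
            )
            rows.append(trace)
            cid = f"{group}{cell_idx:04d}"
            meta.append(
                {
                    "cell_id": cid,
                    "shape_group": group,
                    "concentration_uM": conc,
                    "well": f"W{(j % 2) + 1}",
                    "replicate": (j % 4) + 1,
                }
            )
            truth.append(
                {
                    "cell_id": cid,
                    "shape_group": group,
                    "concentration_uM": conc,
                    "responder": responder,
                    "tau_decay": params.tau_decay,
                    "tau_delta": params.tau_delta,
                    "b": params.b,
                    "c": params.c,
                }
            )
            cell_idx += 1
    traces = TraceMatrix(
        values=np.array(rows), dt=spec.dt,
        metadata=pd.DataFrame(meta, columns=METADATA_COLUMNS),
    )
    return traces, pd.DataFrame(truth)


def simulate_grid_family(
    n_cells: int,
    n_frames: int = 52,
    dt: float = 30.0,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> np.ndarray:
    """Unit-peak transients spanning the full kinetic parameter space.

    Parameters are drawn log-uniformly across the same ranges the fitting
    grid covers (decay time constant 15-1500 s, rate gap 1e-6..1e-1,
    amplitudes 0.1..1000), each trace is rescaled to a common peak of 1,
    and Gaussian noise of sd ``noise_sd`` (in peak units) is added.
    The traces start at the transient onset (t = 0), with no baseline
    segment — this is the family the trajectory-PCA variance checks run on.
    """
    from .transient_model import GRID_B, GRID_INV_TAU_DECAY, GRID_TAU_DELTA

    if n_cells < 1 or n_frames < 2:
        raise ValueError("need at least one cell and two frames")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) * dt
    logu = lambda lo, hi, size=None: np.exp(rng.uniform(np.log(lo), np.log(hi), size))  # noqa: E731
    X = np.empty((n_cells, n_frames))
    for i in range(n_cells):
        f = _eval(
            1.0 / logu(*GRID_INV_TAU_DECAY),
            logu(*GRID_TAU_DELTA),
            logu(*GRID_B),
            logu(*GRID_B),
            t,
        )
        peak = np.abs(f).max()
        if peak > 0:
            f = f / peak
        X[i] = f
    if noise_sd > 0:
        X += rng.normal(0.0, noise_sd, X.shape)
    return X


# ---------------------------------------------------------------------------
# High-content object tables


@dataclass
class ObjectLayout:
    """Counts of planted single-cell QC cases for one simulated well.

    Each non-clean case violates exactly one inclusion rule.  With
    ``boundary_cases`` set, four extra records probe the rule boundaries
    (shape factor at the window edge, nucleus area 300 um^2, centroid
    gap 30 um, nucleus spacing 20 px).
    """

    n_clean: int = 10
    n_doublet: int = 0
    n_bad_shape: int = 0
    n_close_nuclei: int = 0
    n_big_nucleus: int = 0
    n_centroid_mismatch: int = 0
    shape_group: str = "O"
    boundary_cases: bool = False

    def validate(self) -> None:
        counts = (
            self.n_clean, self.n_doublet, self.n_bad_shape,
            self.n_close_nuclei, self.n_big_nucleus, self.n_centroid_mismatch,
        )
        if any(n < 0 for n in counts):
            raise ValueError("case counts must be non-negative")
        if self.shape_group not in SHAPE_FACTOR_WINDOWS:
            raise ValueError(f"unknown shape_group {self.shape_group!r}")


def _clean_record(rng: np.random.Generator, group: str) -> dict:
    lo, hi = SHAPE_FACTOR_WINDOWS[group]
    hi = min(hi, 1.0)
    sf = rng.uniform(lo + 0.02, hi - 0.02 if hi < 1 else 1.0)
    area = rng.uniform(900.0, 1200.0)
    perimeter = float(np.sqrt(4 * np.pi * area / sf))
    cx, cy = rng.uniform(100, 5000, 2)
    jit = lambda: rng.uniform(-8, 8, 2)
    hx, hy = np.array([cx, cy]) + jit()
    px, py = np.array([cx, cy]) + jit()
    return {
        "cell_area_um2": area,
        "perimeter_um": perimeter,
        "cal_cx_um": cx, "cal_cy_um": cy,
        "hoe_cx_um": hx, "hoe_cy_um": hy,
        "post_cx_um": px, "post_cy_um": py,
        "nucleus_area_um2": rng.uniform(80.0, 250.0),
        "nucleus_min_dist_px": rng.uniform(40.0, 200.0),
        "nuclei_in_region": 1,
    }


def _boundary_records(group: str) -> list[dict]:
    lo, hi = SHAPE_FACTOR_WINDOWS[group]
    sf_edge = hi if group == "L" else lo  # 0.85 for L, 0.90 for O: both included
    base = {
        "cal_cx_um": 1000.0, "cal_cy_um": 1000.0,
        "hoe_cx_um": 1000.0, "hoe_cy_um": 1000.0,
        "post_cx_um": 1000.0, "post_cy_um": 1000.0,
        "nucleus_area_um2": 150.0,
        "nucleus_min_dist_px": 60.0,
        "nuclei_in_region": 1,
    }
    area = 1100.0
    mid_sf = 0.95 if group == "O" else 0.7
    recs = []
    r = dict(base, cell_area_um2=area, perimeter_um=float(np.sqrt(4 * np.pi * area / sf_edge)))
    recs.append(r)  # shape factor exactly at the inclusive edge
    r = dict(base, cell_area_um2=area, perimeter_um=float(np.sqrt(4 * np.pi * area / mid_sf)))
    r["nucleus_area_um2"] = NUCLEUS_AREA_UM2  # exactly 300: excluded (strict <)
    recs.append(r)
    r = dict(base, cell_area_um2=area, perimeter_um=float(np.sqrt(4 * np.pi * area / mid_sf)))
    r["hoe_cx_um"] = base["cal_cx_um"] + CENTROID_MISMATCH_UM  # exactly 30 um: retained
    recs.append(r)
    r = dict(base, cell_area_um2=area, perimeter_um=float(np.sqrt(4 * np.pi * area / mid_sf)))
    r["nucleus_min_dist_px"] = NUCLEUS_MIN_DIST_PX  # exactly 20 px: retained
    recs.append(r)
    return recs


def simulate_object_tables(
    layout: ObjectLayout, seed: int
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Emit the four linked object tables plus ground-truth inclusion labels.

    Returns ``(tables, truth)`` where ``tables`` maps ``file1``..``file4``
    to DataFrames (calcium objects; post-stain cell objects; nuclei;
    cross-image region matches) and ``truth`` holds one row per region
    with the planted case name and the inclusion label obtained by
    evaluating all five QC rules directly on the emitted numbers.
    """
    layout.validate()
    rng = np.random.default_rng(seed)
    group = layout.shape_group
    lo, hi = SHAPE_FACTOR_WINDOWS[group]
    records: list[dict] = []
    cases: list[str] = []

    for _ in range(layout.n_clean):
        records.append(_clean_record(rng, group))
        cases.append("clean")
    for _ in range(layout.n_doublet):
        r = _clean_record(rng, group)
        r["nuclei_in_region"] = int(rng.integers(2, 4))
        records.append(r); cases.append("doublet")
    for _ in range(layout.n_bad_shape):
        r = _clean_record(rng, group)
        bad_sf = rng.uniform(0.2, lo - 0.03) if rng.uniform() < 0.5 or hi >= 1.0 \
            else rng.uniform(min(hi + 0.03, 0.99), 1.0)
        r["perimeter_um"] = float(np.sqrt(4 * np.pi * r["cell_area_um2"] / bad_sf))
        records.append(r); cases.append("bad_shape")
    for _ in range(layout.n_close_nuclei):
        r = _clean_record(rng, group)
        r["nucleus_min_dist_px"] = rng.uniform(1.0, 15.0)
        records.append(r); cases.append("close_nuclei")
    for _ in range(layout.n_big_nucleus):
        r = _clean_record(rng, group)
        r["nucleus_area_um2"] = rng.uniform(310.0, 600.0)
        records.append(r); cases.append("big_nucleus")
    for _ in range(layout.n_centroid_mismatch):
        r = _clean_record(rng, group)
        angle = rng.uniform(0, 2 * np.pi)
        off = rng.uniform(35.0, 90.0)
        r["hoe_cx_um"] = r["cal_cx_um"] + off * np.cos(angle)
        r["hoe_cy_um"] = r["cal_cy_um"] + off * np.sin(angle)
        records.append(r); cases.append("centroid_mismatch")
    if layout.boundary_cases:
        for r in _boundary_records(group):
            records.append(r); cases.append("boundary")

    region_ids = [f"R{i:04d}" for i in range(len(records))]
    df = pd.DataFrame(records)
    df.insert(0, "region_id", region_ids)

    tables = {
        "file1": df[["region_id", "cal_cx_um", "cal_cy_um", "cell_area_um2", "perimeter_um"]].copy(),
        "file2": df[["region_id", "post_cx_um", "post_cy_um"]].copy(),
        "file3": df[["region_id", "hoe_cx_um", "hoe_cy_um", "nucleus_area_um2",
                     "nucleus_min_dist_px", "nuclei_in_region"]].copy(),
        "file4": pd.DataFrame({"region_id": region_ids,
                               "calcium_region_id": region_ids,
                               "post_region_id": region_ids}),
    }

    # Ground truth: evaluate the five rules directly on the emitted values.
    sf = 4 * np.pi * df["cell_area_um2"] / df["perimeter_um"] ** 2
    cents = df[["cal_cx_um", "cal_cy_um", "hoe_cx_um", "hoe_cy_um",
                "post_cx_um", "post_cy_um"]].to_numpy()
    d_ch = np.hypot(cents[:, 0] - cents[:, 2], cents[:, 1] - cents[:, 3])
    d_cp = np.hypot(cents[:, 0] - cents[:, 4], cents[:, 1] - cents[:, 5])
    d_hp = np.hypot(cents[:, 2] - cents[:, 4], cents[:, 3] - cents[:, 5])
    max_gap = np.maximum(np.maximum(d_ch, d_cp), d_hp)
    included = (
        (sf >= lo) & (sf <= hi)
        & (df["nuclei_in_region"] == 1)
        & (df["nucleus_min_dist_px"] >= NUCLEUS_MIN_DIST_PX)
        & (df["nucleus_area_um2"] < NUCLEUS_AREA_UM2)
        & (max_gap <= CENTROID_MISMATCH_UM)
    )
    truth = pd.DataFrame(
        {"region_id": region_ids, "case": cases, "included": included.to_numpy()}
    )
    return tables, truth


# ---------------------------------------------------------------------------
# Tumor expression matrices


@dataclass
class ExpressionSimSpec:
    """Latent-axis tumor expression generator settings.

    The latent scalar per tumor is standard normal; positive values are
    epithelial-like.  Signature genes load on the axis with per-gene
    magnitudes drawn from ``loading_range`` (positive for epithelial
    genes, negative for mesenchymal); subtype-marker and filler genes
    carry no structure.  Values are log2 expression units.
    """

    n_tumors: int = 400
    loading_range: tuple[float, float] = (0.8, 1.5)
    noise_sd: float = 0.5
    extra_genes: int = 50
    baseline_mean_range: tuple[float, float] = (4.0, 12.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_tumors < 2:
            raise ValueError("need at least 2 tumors")
        if self.noise_sd < 0 or self.extra_genes < 0:
            raise ValueError("noise_sd and extra_genes must be non-negative")


def simulate_expression(spec: ExpressionSimSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a tumors x genes log2 expression matrix with a latent EPI-MES axis.

    Returns ``(matrix, latent)``; the matrix columns are every unique
    signature gene (epithelial, mesenchymal, subtype markers) followed by
    ``GENE0001``-style filler genes.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lists = load_gene_lists()
    latent = rng.normal(0.0, 1.0, spec.n_tumors)
    tumors = [f"TUMOR{i:04d}" for i in range(spec.n_tumors)]

    cols: dict[str, np.ndarray] = {}

    def add(genes, sign):
        for g in genes:
            base = rng.uniform(*spec.baseline_mean_range)
            load = sign * rng.uniform(*spec.loading_range)
            noise = rng.normal(0.0, spec.noise_sd, spec.n_tumors) if spec.noise_sd > 0 else 0.0
            cols[g] = base + load * latent + noise

    add(lists.epithelial, +1.0)
    add(lists.mesenchymal, -1.0)
    add(lists.subtype_markers, 0.0)
    for i in range(spec.extra_genes):
        base = rng.uniform(*spec.baseline_mean_range)
        cols[f"GENE{i:04d}"] = base + rng.normal(0.0, 1.0, spec.n_tumors)

    matrix = pd.DataFrame(cols, index=pd.Index(tumors, name="tumor"))
    return matrix, pd.Series(latent, index=matrix.index, name="latent_axis")
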