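"""End-point organoid morphometrics and group statistics.

Per-organoid parameters (pixel units unless noted):

- Area: segmented pixel count.
- Roundness: 4*pi*Area / Perimeter^2 (isoperimetric ratio, 1 for a disc;
  loss of roundness marks loss of the round organoid phenotype).
- FiltRound: Roundness after a morphological opening that strips appendages.
- Density: mean intensity of the measured channel over the object.
- AppNumber / MaxApp / MedApp: count, maximum and median geodesic length of
  appendages (invasive protrusions) — skeleton branches protruding beyond
  the opened organoid body.
- CellNumber: calibrated proxy, Area / mean single-cell area.

Group comparisons use two-sided Mann-Whitney U or Welch t-tests against a
control group, Bonferroni-corrected across all comparisons in the call, with
log2 fold-change-of-medians heatmap matrices. Growth curves are normalized
pointwise to the vehicle (DMSO) control with the final control time point
set to 100%; inhibition at time T is 100 * (1 - treated/control).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from scipy.sparse import csgraph, coo_matrix
from skimage.measure import perimeter_crofton
from skimage.morphology import disk, skeletonize

from .config import MorphometricsConfig

logger = logging.getLogger("organotrack")

__all__ = [
    "OrganoidRecord",
    "GroupComparison",
    "measure_organoid",
    "measure_field",
    "compare_groups",
    "heatmap_matrix",
    "normalize_growth_to_control",
    "inhibition_percent",
    "smooth_curve",
    "PARAMETERS",
]

PARAMETERS = ("Area", "Roundness", "FiltRound", "Density", "AppNumber",
              "MaxApp", "MedApp", "CellNumber")


@dataclass
class OrganoidRecord:
    id: int
    Area: float
    Roundness: float
    FiltRound: float
    Density: float
    AppNumber: int
    MaxApp: float
    MedApp: float
    CellNumber: float

    def __post_init__(self) -> None:
        if self.Area <= 0:
            raise ValueError("Area must be > 0")
        if not (0 < self.Roundness <= 1):
            raise ValueError("Roundness must be in (0, 1]")
        if self.AppNumber == 0:
            assert self.MaxApp == 0 and self.MedApp == 0
        assert self.MaxApp >= self.MedApp >= 0


def _roundness(mask: np.ndarray) -> float:
    area = float(mask.sum())
    per = perimeter_crofton(mask, directions=4)
    if per <= 0:
        return 1.0
    return float(min(4 * np.pi * area / per ** 2, 1.0))


def _skeleton_branch_lengths(mask: np.ndarray, body: np.ndarray,
                             min_length: float = 2.0) -> list[float]:
    """Geodesic lengths of skeleton branches protruding beyond the body."""
    skel = skeletonize(mask)
    outside = skel & ~body
    labels, n = ndi.label(outside, structure=np.ones((3, 3), bool))
    lengths: list[float] = []
    for lab in range(1, n + 1):
        ys, xs = np.nonzero(labels == lab)
        if len(ys) < 2:
            continue
        length = _geodesic_diameter(ys, xs)
        if length >= min_length:
            lengths.append(length)
    return lengths


def _geodesic_diameter(ys: np.ndarray, xs: np.ndarray) -> float:
    """Longest shortest path within an 8-connected pixel set (diagonal sqrt 2)."""
    n = len(ys)
    pts = np.stack([ys, xs], axis=1)
    index = {tuple(p): i for i, p in enumerate(pts)}
    rows, cols, w = [], [], []
    for i, (y, x) in enumerate(pts):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == 0 and dx == 0:
                    continue
                j = index.get((y + dy, x + dx))
                if j is not None and j > i:
                    rows.append(i)
                    cols.append(j)
                    w.append(np.hypot(dy, dx))
    g = coo_matrix((w, (rows, cols)), shape=(n, n))
    d0 = csgraph.dijkstra(g, directed=False, indices=0)
    far = int(np.argmax(np.where(np.isfinite(d0), d0, -1)))
    d1 = csgraph.dijkstra(g, directed=False, indices=far)
    return float(np.max(d1[np.isfinite(d1)]))


def measure_organoid(object_mask: np.ndarray, intensity_img: np.ndarray,
                     config: MorphometricsConfig | None = None,
                     object_id: int = 0) -> OrganoidRecord:
    """Morphometric vector of one connected segmented object."""
    config = config or MorphometricsConfig()
    mask = np.asarray(object_mask).astype(bool)
    if not mask.any():
        raise ValueError("empty object mask")
    if mask.shape != np.asarray(intensity_img).shape:
        raise ValueError("mask and intensity image shapes differ")
    _, n = ndi.label(mask, structure=np.ones((3, 3), bool))
    if n != 1:
        raise ValueError(f"expected a single connected object, found {n}")
    area = float(mask.sum())
    roundness = _roundness(mask)
    density = float(np.asarray(intensity_img, float)[mask].mean())
    body = ndi.binary_opening(mask, structure=disk(config.appendage_open_radius))
    if not body.any():
        body = mask
    lengths = _skeleton_branch_lengths(mask, body)
    filt_round = _roundness(body)
    return OrganoidRecord(
        id=object_id,
        Area=area,
        Roundness=roundness,
        FiltRound=filt_round,
        Density=density,
        AppNumber=len(lengths),
        MaxApp=float(max(lengths)) if lengths else 0.0,
        MedApp=float(np.median(lengths)) if lengths else 0.0,
        CellNumber=area / config.mean_cell_area,
    )


def measure_field(mask: np.ndarray, intensity_img: np.ndarray,
                  config: MorphometricsConfig | None = None,
                  min_area: int = 50) -> pd.DataFrame:
    """Measure every connected object in a field mask; one row per organoid."""
    labels, n = ndi.label(np.asarray(mask).astype(bool),
                          structure=np.ones((3, 3), bool))
    records = []
    for lab in range(1, n + 1):
        obj = labels == lab
        if obj.sum() < min_area:
            continue
        records.append(asdict(measure_organoid(obj, intensity_img, config,
                                               object_id=lab)))
    return pd.DataFrame.from_records(records)


@dataclass
class GroupComparison:
    parameter: str
    group: str
    direction: str        # increased | decreased | none
    p_raw: float
    p_adjusted: float
    test: str             # mannwhitney | ttest


def compare_groups(records_by_group: dict[str, pd.DataFrame],
                   control_name: str, test: str = "mannwhitney",
                   params: list[str] | None = None) -> list[GroupComparison]:
    """Two-sided tests of every group against the control, per parameter.

    Bonferroni correction multiplies each raw p by the total number of
    comparisons performed in this call. Effect direction comes from the
    median (Mann-Whitney) or mean (t-test) relative to control.
    """
    if test not in ("mannwhitney", "ttest"):
        raise ValueError(f"unknown test '{test}'")
    if control_name not in records_by_group:
        raise ValueError(f"control group '{control_name}' not present")
    params = list(params or PARAMETERS)
    for name, df in records_by_group.items():
        if len(df) < 3:
            raise ValueError(f"group '{name}' has fewer than 3 records")
    groups = [g for g in records_by_group if g != control_name]
    m = len(groups) * len(params)
    ctrl = records_by_group[control_name]
    out: list[GroupComparison] = []
    for g in groups:
        df = records_by_group[g]
        for p in params:
            x = np.asarray(df[p], float)
            y = np.asarray(ctrl[p], float)
            if test == "mannwhitney":
                if np.array_equal(np.sort(x), np.sort(y)):
                    praw, direction = 1.0, "none"
                else:
                    praw = float(stats.mannwhitneyu(
                        x, y, alternative="two-sided", method="auto").pvalue)
                    delta = np.median(x) - np.median(y)
                    direction = ("increased" if delta > 0
                                 else "decreased" if delta < 0 else "none")
            else:
                if np.array_equal(np.sort(x), np.sort(y)):
                    praw, direction = 1.0, "none"
                else:
                    praw = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
                    delta = x.mean() - y.mean()
                    direction = ("increased" if delta > 0
                                 else "decreased" if delta < 0 else "none")
            out.append(GroupComparison(p, g, direction, praw,
                                       min(1.0, praw * m), test))
    return out


def heatmap_matrix(comparisons: list[GroupComparison],
                   records_by_group: dict[str, pd.DataFrame],
                   control_name: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parameter x group matrices: log2 fold change of group median over
    control median, and the aligned adjusted p-values."""
    params = sorted({c.parameter for c in comparisons},
                    key=lambda p: PARAMETERS.index(p) if p in PARAMETERS else 99)
    groups = sorted({c.group for c in comparisons})
    ctrl = records_by_group[control_name]
    fold = pd.DataFrame(index=params, columns=groups, dtype=float)
    pmat = pd.DataFrame(index=params, columns=groups, dtype=float)
    for c in comparisons:
        pmat.loc[c.parameter, c.group] = c.p_adjusted
        cm = float(np.median(ctrl[c.parameter]))
        gm = float(np.median(records_by_group[c.group][c.parameter]))
        if cm == 0:
            logger.warning("zero control median for %s: fold change undefined",
                           c.parameter)
            fold.loc[c.parameter, c.group] = np.nan
        elif gm <= 0:
            fold.loc[c.parameter, c.group] = np.nan
        else:
            fold.loc[c.parameter, c.group] = np.log2(gm / cm)
    return fold, pmat


def normalize_growth_to_control(treated_curves: dict[str, np.ndarray],
                                control_curve: np.ndarray) -> dict[str, np.ndarray]:
    """Normalize growth curves to the control, control final point = 100%.

    Each treated curve is divided pointwise by the control curve and scaled
    to percent, so the control itself maps to a flat 100% line. Curves must
    share the control's time base.
    """
    control = np.asarray(control_curve, float)
    if control[-1] <= 0:
        raise ValueError("control final value must be > 0")
    if np.any(control <= 0):
        raise ValueError("control curve must be positive throughout")
    out: dict[str, np.ndarray] = {}
    for name, curve in treated_curves.items():
        c = np.asarray(curve, float)
        if c.shape != control.shape:
            raise ValueError(f"curve '{name}' does not share the control time base")
        out[name] = 100.0 * c / control
    return out


def inhibition_percent(treated_curve: np.ndarray,
                       control_curve: np.ndarray) -> float:
    """Growth inhibition at the final time point: 100 * (1 - treated/control)."""
    norm = normalize_growth_to_control({"t": treated_curve}, control_curve)
    return float(100.0 - norm["t"][-1])


def smooth_curve(curve: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average (window truncated at the ends); raw data should
    be retained alongside the smoothed curve."""
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be an odd integer >= 1")
    c = np.asarray(curve, float)
    half = window // 2
    out = np.empty_like(c)
    for i in range(len(c)):
        lo, hi = max(0, i - half), min(len(c), i + half + 1)
        out[i] = c[lo:hi].mean()
    return out
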