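"""Filtering and segmentation of high-frequency localization tracks.

Raw fix streams are cleaned with a covariance-based quality filter and a
20 m/s speed filter, then each bat-night is segmented into tree visits
and commuting flights with a first-passage rule: a visit opens when a
run of fixes stays within a fixed radius of the (iteratively refined)
centre of its "cloud of fixes".  Visits are annotated with the nearest
mapped tree and flagged as flyovers when the pass is both straight and
brief.  Nights are indexed by noon-to-noon boundaries so one foraging
night shares a single index.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .synth import VISIT_COLUMNS

logger = logging.getLogger(__name__)

DAY = 86400.0


class IngestionError(ValueError):
    """Raised when fixes violate ingestion preconditions (e.g. unsorted)."""


@dataclasses.dataclass
class SegmenterParams:
    """Tunable parameters of the filter/segmentation stage.

    fp_radius: first-passage cloud radius (m).
    min_fixes: consecutive fixes required to open a cloud.
    min_duration: shortest emitted visit (s); also the flyover duration cap.
    speed_max: speed filter threshold (m/s).
    quality_var_max: bound on the larger covariance eigenvalue (m^2).
    match_radius: max centroid-to-tree distance for annotation (m).
    straightness_max: net/cumulative displacement ratio above which a
        brief pass counts as a flyover.
    """

    fp_radius: float = 50.0
    min_fixes: int = 5
    min_duration: float = 4.0
    speed_max: float = 20.0
    quality_var_max: float = 400.0
    match_radius: float = 50.0
    straightness_max: float = 0.9

    def __post_init__(self) -> None:
        for name in (
            "fp_radius",
            "min_fixes",
            "min_duration",
            "speed_max",
            "quality_var_max",
            "match_radius",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.straightness_max <= 1.0:
            raise ValueError("straightness_max must be in (0, 1]")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_fixes(fixes: pd.DataFrame, params: SegmenterParams) -> pd.DataFrame:
    """Quality filter then causal speed filter, per tag, order preserved.

    A fix is dropped when the larger eigenvalue of its localization
    covariance exceeds ``quality_var_max``; then a single forward pass
    drops any fix whose speed relative to the last *retained* fix
    exceeds ``speed_max``.
    """
    if fixes.empty:
        return fixes.copy()
    grouped = fixes.groupby("tag_id", sort=False)["t"]
    if not (grouped.diff().dropna() > 0).all():
        raise IngestionError("fixes must be strictly increasing in t per tag")

    vx = fixes["var_x"].to_numpy(float)
    vy = fixes["var_y"].to_numpy(float)
    cxy = fixes["cov_xy"].to_numpy(float)
    lam_max = 0.5 * (vx + vy) + np.sqrt((0.5 * (vx - vy)) ** 2 + cxy**2)
    fixes = fixes.loc[lam_max <= params.quality_var_max]
    n_quality = len(fixes)
    logger.debug("quality filter kept %d fixes", n_quality)

    keep_parts = []
    for _, grp in fixes.groupby("tag_id", sort=False):
        t = grp["t"].to_numpy(float)
        x = grp["x"].to_numpy(float)
        y = grp["y"].to_numpy(float)
        keep = np.zeros(len(grp), dtype=bool)
        last = -1
        for i in range(len(grp)):
            if last < 0:
                keep[i] = True
                last = i
                continue
            speed = np.hypot(x[i] - x[last], y[i] - y[last]) / (t[i] - t[last])
            if speed <= params.speed_max:
                keep[i] = True
                last = i
        keep_parts.append(pd.Series(keep, index=grp.index))
    keep_all = pd.concat(keep_parts)
    out = fixes.loc[keep_all.reindex(fixes.index, fill_value=False)]
    logger.debug("speed filter kept %d of %d fixes", len(out), n_quality)
    return out.copy()


# ---------------------------------------------------------------------------
# first-passage segmentation
# ---------------------------------------------------------------------------


def _find_clouds(
    x: np.ndarray, y: np.ndarray, params: SegmenterParams
) -> list[tuple[int, int, float, float]]:
    """Forward scan for fix clouds: (lo, hi, centre_x, centre_y)."""
    n = len(x)
    m = params.min_fixes
    r2 = params.fp_radius**2
    out = []
    i = 0
    while i + m <= n:
        sx = x[i : i + m]
        sy = y[i : i + m]
        cx, cy = sx.mean(), sy.mean()
        if np.max((sx - cx) ** 2 + (sy - cy) ** 2) > r2:
            i += 1
            continue
        lo, hi = i, i + m - 1
        for _ in range(200):
            prev = (lo, hi)
            # extend forward while fixes stay in the cloud
            while hi + 1 < n and (x[hi + 1] - cx) ** 2 + (y[hi + 1] - cy) ** 2 <= r2:
                hi += 1
            # re-test membership at the edges against the current centre
            while lo < hi and (x[lo] - cx) ** 2 + (y[lo] - cy) ** 2 > r2:
                lo += 1
            while hi > lo and (x[hi] - cx) ** 2 + (y[hi] - cy) ** 2 > r2:
                hi -= 1
            ncx = x[lo : hi + 1].mean()
            ncy = y[lo : hi + 1].mean()
            moved = (ncx - cx) ** 2 + (ncy - cy) ** 2
            cx, cy = ncx, ncy
            if prev == (lo, hi) and moved < 1e-12:
                break
        if hi - lo + 1 >= m:
            out.append((lo, hi, cx, cy))
            i = hi + 1
        else:
            i += 1
    return out


def classify_flyover(visit_fixes: pd.DataFrame, params: SegmenterParams) -> bool:
    """Straight, brief pass over a point of interest?

    straightness = net displacement / cumulative path length; a flyover
    is a pass with straightness above ``straightness_max`` *and*
    duration below ``min_duration`` (a bat circling a tree, however
    briefly, is a visit).
    """
    if len(visit_fixes) < 2:
        raise ValueError("classify_flyover needs at least 2 fixes")
    x = visit_fixes["x"].to_numpy(float)
    y = visit_fixes["y"].to_numpy(float)
    t = visit_fixes["t"].to_numpy(float)
    path = float(np.sum(np.hypot(np.diff(x), np.diff(y))))
    net = float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
    straightness = net / path if path > 0 else 0.0
    duration = t[-1] - t[0]
    return bool(
        straightness > params.straightness_max and duration < params.min_duration
    )


def segment_visits(
    track: pd.DataFrame,
    trees: pd.DataFrame | None,
    params: SegmenterParams,
) -> pd.DataFrame:
    """Segment one bat's filtered fixes into tree visits.

    Emits one row per cloud with duration >= ``min_duration``; remaining
    fixes are commuting flight.  If a tree table is given, visits are
    annotated with the nearest tree within ``match_radius``.
    """
    if track.empty:
        return _empty_visits()
    if track["tag_id"].nunique() != 1:
        raise IngestionError("segment_visits expects fixes of a single bat")
    t = track["t"].to_numpy(float)
    x = track["x"].to_numpy(float)
    y = track["y"].to_numpy(float)
    bat = track["tag_id"].iloc[0]

    rows = []
    for lo, hi, cx, cy in _find_clouds(x, y, params):
        duration = t[hi] - t[lo]
        if duration < params.min_duration:
            continue
        flyover = classify_flyover(track.iloc[lo : hi + 1], params)
        rows.append(
            {
                "bat_id": bat,
                "night_index": 0,
                "tree_id": pd.NA,
                "centroid_x": cx,
                "centroid_y": cy,
                "t_start": t[lo],
                "t_end": t[hi],
                "duration": duration,
                "n_fixes": hi - lo + 1,
                "flyover": flyover,
            }
        )
    visits = pd.DataFrame(rows, columns=VISIT_COLUMNS)
    visits["tree_id"] = visits["tree_id"].astype("Int64")
    if trees is not None:
        visits = annotate_visits(visits, trees, params)
    return visits


def _empty_visits() -> pd.DataFrame:
    v = pd.DataFrame(columns=VISIT_COLUMNS)
    return v.astype({"tree_id": "Int64"})


def annotate_visits(
    visits: pd.DataFrame, trees: pd.DataFrame, params: SegmenterParams
) -> pd.DataFrame:
    """Attribute each visit to the nearest tree within ``match_radius``.

    Ties in distance resolve to the smallest tree_id; centroids farther
    than ``match_radius`` from every tree stay unmatched.
    """
    visits = visits.copy()
    if len(trees) == 0:
        logger.warning("empty tree table: all %d visits unmatched", len(visits))
        visits["tree_id"] = pd.array([pd.NA] * len(visits), dtype="Int64")
        return visits
    if visits.empty:
        return visits
    trees = trees.sort_values("tree_id")
    txy = trees[["x", "y"]].to_numpy(float)
    ids = trees["tree_id"].to_numpy()
    cxy = visits[["centroid_x", "centroid_y"]].to_numpy(float)
    d2 = ((cxy[:, None, :] - txy[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)  # first minimum -> smallest tree_id on ties
    dist = np.sqrt(d2[np.arange(len(visits)), nearest])
    matched = dist <= params.match_radius
    visits["tree_id"] = pd.array(
        [ids[j] if ok else pd.NA for j, ok in zip(nearest, matched)], dtype="Int64"
    )
    return visits


# ---------------------------------------------------------------------------
# night indexing
# ---------------------------------------------------------------------------


def assign_nights(
    times: np.ndarray | pd.Series,
    t0: float | None = None,
    boundary_hour: float = 12.0,
) -> np.ndarray:
    """Night index per timestamp: number of boundary crossings since start.

    The boundary defaults to 12:00 local so an entire foraging night
    (sunset through the following sunrise) shares one index.  ``t0``
    is the local-midnight epoch of the study's first day (default: the
    midnight preceding the earliest timestamp).
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        return np.zeros(0, dtype=np.int64)
    if t0 is None:
        t0 = np.floor(t.min() / DAY) * DAY
    return np.floor((t - t0 - boundary_hour * 3600.0) / DAY).astype(np.int64)


# ---------------------------------------------------------------------------
# whole-dataset convenience
# ---------------------------------------------------------------------------


def segment_all(
    fixes: pd.DataFrame,
    trees: pd.DataFrame | None,
    params: SegmenterParams,
    t0: float | None = None,
) -> pd.DataFrame:
    """Filter and segment a multi-bat fix table into an annotated visit table."""
    filtered = filter_fixes(fixes, params)
    if filtered.empty:
        return _empty_visits()
    if t0 is None:
        t0 = np.floor(filtered["t"].min() / DAY) * DAY
    parts = []
    for _, grp in filtered.groupby("tag_id", sort=True):
        v = segment_visits(grp, trees, params)
        if len(v):
            parts.append(v)
    if not parts:
        return _empty_visits()
    visits = pd.concat(parts, ignore_index=True)
    visits["night_index"] = assign_nights(visits["t_start"], t0=t0)
    logger.info(
        "segmented %d fixes into %d visits (%d tree-matched)",
        len(filtered),
        len(visits),
        int(visits["tree_id"].notna().sum()),
    )
    return visits
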