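"""Synthetic telemetry for a central-place foraging fruit-bat colony.

This module generates everything the downstream stages consume, with known
ground truth: a fruit-tree landscape (mostly seasonal species, a small
unpredictable *Ficus* fraction, and a handful of focal trees), nightly
roost-to-trees-to-roost itineraries driven by per-bat spatial memory,
noisy localization ("fix") streams at tag sampling rate, and odour-cue
manipulation scenarios in which a configurable fraction of naive bats
responds by visiting a focal tree 1-6 nights later.

The simulated landscape emulates a ~19,000 ha valley: trees are placed
uniformly over a ~13.8 km square, the roost sits just outside the tree
extent, and bats commute in straight constant-speed legs between dwell
episodes on trees.  Dwell durations are log-normal (median 9 min,
truncated to 4 s - 50 min).  All event times are quantized to the
sampling grid so that ground-truth episodes are directly comparable with
fix-level segmentation output.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

DAY = 86400.0

SEASONAL_SPECIES = (
    "Phoenix dactylifera",
    "Morus alba",
    "Persea americana",
    "Melia azedarach",
    "Eriobotrya japonica",
)
UNPREDICTABLE_SPECIES = ("Ficus sycomorus", "Ficus religiosa", "Ficus microcarpa")
FOCAL_SPECIES = "Ficus sycomorus"

FIX_COLUMNS = ["tag_id", "t", "x", "y", "var_x", "var_y", "cov_xy"]
TREE_COLUMNS = ["tree_id", "x", "y", "species", "predictability", "is_focal"]
TRUTH_COLUMNS = ["bat_id", "night_index", "tree_id", "t_start", "t_end"]
VISIT_COLUMNS = [
    "bat_id",
    "night_index",
    "tree_id",
    "centroid_x",
    "centroid_y",
    "t_start",
    "t_end",
    "duration",
    "n_fixes",
    "flyover",
]
MANIFEST_COLUMNS = ["night_index", "roost", "bat_id", "role"]
ROSTER_COLUMNS = ["bat_id", "roost", "track_start", "track_end"]


class InvalidConfigError(ValueError):
    """A simulation configuration violates one of its invariants."""


@dataclasses.dataclass
class SimConfig:
    """Parameters of the synthetic colony and the manipulation scenario.

    Distances are metres, times seconds, rates probabilities.  The
    defaults are the study conditions: 72 manipulation-tagged bats of
    which 16 are smeared, ~7% temporally unpredictable tree species,
    exactly two focal trees, 0.25 Hz sampling with 5 m localization
    noise, and a naive response probability of 0.18 with most responses
    arriving within the first four nights.
    """

    n_bats: int = 72
    n_nights: int = 14
    n_trees: int = 1000
    n_focal: int = 2
    extent: tuple[float, float] = (13800.0, 13800.0)
    unpredictable_frac: float = 0.07
    two_roosts: bool = False
    sampling_interval: float = 4.0
    noise_sd: float = 5.0
    commute_speed: float = 18.0
    trees_per_night: tuple[int, int] = (1, 5)
    repertoire_size: tuple[int, int] = (1, 5)
    revisit_prob: float = 0.8
    dwell_median_s: float = 540.0
    dwell_sigma: float = 1.0
    dwell_min_s: float = 4.0
    dwell_max_s: float = 3000.0
    routine_focal_window_rate: float = 0.012
    routine_focal_window_nights: int = 6
    night_start_hour: float = 20.0
    night_end_hour: float = 6.0
    n_manipulated: int = 16
    response_prob: float = 0.18
    manipulated_response_prob: float = 0.25
    lag_pmf: tuple[float, ...] = (0.3, 0.2, 0.2, 0.2, 0.0, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_focal < 0 or self.n_trees < 0:
            raise InvalidConfigError("tree counts must be non-negative")
        if self.n_focal > self.n_trees:
            raise InvalidConfigError(
                f"n_focal={self.n_focal} exceeds n_trees={self.n_trees}"
            )
        if self.extent[0] <= 0 or self.extent[1] <= 0:
            raise InvalidConfigError("extent must be positive")
        for name in (
            "unpredictable_frac",
            "revisit_prob",
            "routine_focal_window_rate",
            "response_prob",
            "manipulated_response_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name}={v} outside [0, 1]")
        if any(p < 0 for p in self.lag_pmf) or not math.isclose(
            sum(self.lag_pmf), 1.0, abs_tol=1e-9
        ):
            raise InvalidConfigError("lag_pmf must be non-negative and sum to 1")
        if self.sampling_interval <= 0 or self.noise_sd < 0:
            raise InvalidConfigError("sampling_interval must be > 0, noise_sd >= 0")
        if self.n_manipulated > self.n_bats:
            raise InvalidConfigError("n_manipulated exceeds n_bats")

    # -- derived quantities -------------------------------------------------

    @property
    def roosts(self) -> dict[str, tuple[float, float]]:
        """Roost name -> planar coordinates, outside the tree extent."""
        r = {"Gershom": (-500.0, self.extent[1] / 2.0)}
        if self.two_roosts:
            r["Zemer"] = (self.extent[0] + 500.0, self.extent[1] / 2.0)
        return r

    def bat_roost(self, bat_id: int) -> str:
        names = sorted(self.roosts)
        return names[bat_id % len(names)]

    @property
    def p_focal_night(self) -> float:
        """Per-night routine focal-visit probability implied by the
        per-window rate (1 - (1-rate)^(1/window))."""
        w = self.routine_focal_window_nights
        return 1.0 - (1.0 - self.routine_focal_window_rate) ** (1.0 / w)

    def night_anchor(self, night: int) -> float:
        return night * DAY + self.night_start_hour * 3600.0

    def night_end(self, night: int) -> float:
        return night * DAY + (24.0 + self.night_end_hour) * 3600.0


def _rng(config: SimConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(config.seed)


def _quantize_up(x: float, step: float) -> float:
    return math.ceil(round(x / step, 9)) * step


def _draw_dwell(config: SimConfig, rng: np.random.Generator) -> float:
    """Truncated log-normal dwell duration, quantized to the fix grid."""
    mu = math.log(config.dwell_median_s)
    for _ in range(1000):
        d = float(rng.lognormal(mu, config.dwell_sigma))
        if config.dwell_min_s <= d <= config.dwell_max_s:
            break
    else:  # pragma: no cover - essentially unreachable
        d = config.dwell_median_s
    return max(_quantize_up(d, config.sampling_interval), config.sampling_interval)


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------


def generate_landscape(
    config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Place ``n_trees`` uniformly in the extent.

    A fraction ``unpredictable_frac`` of trees belongs to temporally
    unpredictable (*Ficus*) species; exactly ``n_focal`` trees are focal
    and these are forced to be unpredictable *F. sycomorus*.
    """
    rng = _rng(config, rng)
    n = config.n_trees
    x = rng.uniform(0.0, config.extent[0], n)
    y = rng.uniform(0.0, config.extent[1], n)
    unpredictable = rng.random(n) < config.unpredictable_frac
    species = np.where(
        unpredictable,
        rng.choice(UNPREDICTABLE_SPECIES, n),
        rng.choice(SEASONAL_SPECIES, n),
    )
    is_focal = np.zeros(n, dtype=bool)
    if config.n_focal:
        focal_idx = rng.choice(n, config.n_focal, replace=False)
        is_focal[focal_idx] = True
        unpredictable[focal_idx] = True
        species[focal_idx] = FOCAL_SPECIES
    return pd.DataFrame(
        {
            "tree_id": np.arange(n, dtype=np.int64),
            "x": x,
            "y": y,
            "species": species,
            "predictability": np.where(unpredictable, "unpredictable", "seasonal"),
            "is_focal": is_focal,
        }
    )


# ---------------------------------------------------------------------------
# itineraries and ground truth
# ---------------------------------------------------------------------------


def plan_itineraries(
    trees: pd.DataFrame, config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw per-bat-night tree itineraries and dwell times.

    Each bat owns a fixed repertoire of 1-5 remembered (non-focal) trees;
    each night it strings together 1-5 dwells, drawing each tree from its
    repertoire with probability ``revisit_prob`` and exploring a random
    tree otherwise.  Focal trees enter routine itineraries only through
    the small per-night routine rate.  Returns the ground-truth episode
    log (bat_id, night_index, tree_id, t_start, t_end), with planned
    per-night episode counts stored in ``.attrs['episodes_per_night']``.
    """
    rng = _rng(config, rng)
    step = config.sampling_interval
    tx = trees.set_index("tree_id")["x"]
    ty = trees.set_index("tree_id")["y"]
    focal_ids = trees.loc[trees["is_focal"], "tree_id"].to_numpy()
    nonfocal_ids = trees.loc[~trees["is_focal"], "tree_id"].to_numpy()
    if len(nonfocal_ids) == 0 and config.n_bats > 0:
        raise InvalidConfigError("need at least one non-focal tree to forage on")

    repertoires: dict[int, np.ndarray] = {}
    lo, hi = config.repertoire_size
    for bat in range(config.n_bats):
        k = int(rng.integers(lo, hi + 1))
        k = min(k, len(nonfocal_ids))
        repertoires[bat] = rng.choice(nonfocal_ids, k, replace=False)

    rows: list[tuple[int, int, int, float, float]] = []
    per_night: dict[tuple[int, int], int] = {}
    t_lo, t_hi = config.trees_per_night
    for bat in range(config.n_bats):
        rx, ry = config.roosts[config.bat_roost(bat)]
        rep = repertoires[bat]
        for night in range(config.n_nights):
            k = int(rng.integers(t_lo, t_hi + 1))
            chosen: list[int] = []
            for _ in range(k):
                tree = -1
                if rng.random() < config.revisit_prob:
                    cand = [t for t in rep if t not in chosen]
                    if cand:
                        tree = int(cand[rng.integers(0, len(cand))])
                if tree < 0:
                    # exploration: rejection-sample an unused tree
                    for _ in range(20):
                        t_try = int(nonfocal_ids[rng.integers(0, len(nonfocal_ids))])
                        if t_try not in chosen:
                            tree = t_try
                            break
                    if tree < 0:
                        break
                chosen.append(tree)
            if len(focal_ids) and rng.random() < config.p_focal_night:
                pos = int(rng.integers(0, len(chosen) + 1))
                chosen.insert(pos, int(rng.choice(focal_ids)))

            t = config.night_anchor(night) + int(rng.integers(0, 450)) * step
            end = config.night_end(night)
            px, py = rx, ry
            count = 0
            for tree in chosen:
                dist = math.hypot(tx[tree] - px, ty[tree] - py)
                commute = max(_quantize_up(dist / config.commute_speed, step), step)
                dwell = _draw_dwell(config, rng)
                if t + commute + dwell > end:
                    break
                t_start = t + commute
                rows.append((bat, night, tree, t_start, t_start + dwell))
                t = t_start + dwell
                px, py = tx[tree], ty[tree]
                count += 1
            per_night[(bat, night)] = count

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    truth = truth.astype(
        {"bat_id": np.int64, "night_index": np.int64, "tree_id": np.int64}
    )
    truth.sort_values(["bat_id", "t_start"], inplace=True, ignore_index=True)
    truth.attrs["episodes_per_night"] = per_night
    return truth


def episodes_to_fixes(
    truth: pd.DataFrame,
    trees: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Render a ground-truth episode log into a noisy fix stream.

    Fixes are emitted on the sampling grid from roost departure to roost
    return each night; positions interpolate linearly along commute legs
    and sit on the tree during dwells, then receive isotropic Gaussian
    noise of sd ``noise_sd`` with a matching per-fix covariance.
    """
    rng = _rng(config, rng)
    step = config.sampling_interval
    if truth.empty:
        return pd.DataFrame(columns=FIX_COLUMNS).astype(
            {"tag_id": np.int64, "t": float}
        )
    tx = trees.set_index("tree_id")["x"]
    ty = trees.set_index("tree_id")["y"]

    parts = []
    for (bat, night), grp in truth.groupby(["bat_id", "night_index"], sort=True):
        grp = grp.sort_values("t_start")
        rx, ry = config.roosts[config.bat_roost(int(bat))]
        wt: list[float] = []
        wx: list[float] = []
        wy: list[float] = []
        first = grp.iloc[0]
        d0 = math.hypot(tx[first.tree_id] - rx, ty[first.tree_id] - ry)
        dep = first.t_start - max(_quantize_up(d0 / config.commute_speed, step), step)
        wt.append(dep), wx.append(rx), wy.append(ry)
        for ep in grp.itertuples():
            wt.extend([ep.t_start, ep.t_end])
            wx.extend([tx[ep.tree_id]] * 2)
            wy.extend([ty[ep.tree_id]] * 2)
        last = grp.iloc[-1]
        dn = math.hypot(tx[last.tree_id] - rx, ty[last.tree_id] - ry)
        ret = last.t_end + max(_quantize_up(dn / config.commute_speed, step), step)
        wt.append(ret), wx.append(rx), wy.append(ry)

        ts = np.arange(dep, ret + step / 2.0, step)
        xs = np.interp(ts, wt, wx)
        ys = np.interp(ts, wt, wy)
        if config.noise_sd > 0:
            xs = xs + rng.normal(0.0, config.noise_sd, len(ts))
            ys = ys + rng.normal(0.0, config.noise_sd, len(ts))
        parts.append(
            pd.DataFrame(
                {
                    "tag_id": np.int64(bat),
                    "t": ts,
                    "x": xs,
                    "y": ys,
                    "var_x": config.noise_sd**2,
                    "var_y": config.noise_sd**2,
                    "cov_xy": 0.0,
                }
            )
        )
    fixes = pd.concat(parts, ignore_index=True)
    fixes.sort_values(["tag_id", "t"], inplace=True, ignore_index=True)
    return fixes


def simulate_tracks(
    trees: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    truth: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate nightly trips for every bat: (fix table, truth episode log)."""
    rng = _rng(config, rng)
    if truth is None:
        truth = plan_itineraries(trees, config, rng)
    fixes = episodes_to_fixes(truth, trees, config, rng)
    return fixes, truth


# ---------------------------------------------------------------------------
# manipulation
# ---------------------------------------------------------------------------


def inject_manipulation(
    truth: pd.DataFrame,
    trees: pd.DataFrame,
    config: SimConfig,
    manipulation_night: int,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Designate smeared/naive bats and inject odour-cue responses.

    Each naive bat independently responds with probability
    ``response_prob`` (smeared bats with ``manipulated_response_prob``);
    a responder gains exactly one focal-tree dwell at a night lag drawn
    from ``lag_pmf``, appended after its last episode of that night so
    itineraries stay commute-consistent and non-overlapping.

    Returns ``(manifest, truth)`` where the manifest has one row per
    tagged bat (night_index, roost, bat_id, role) and the truth log
    carries the injected rows in ``.attrs['injected']``.
    """
    rng = _rng(config, rng)
    if not 0 <= manipulation_night < config.n_nights:
        raise InvalidConfigError("manipulation_night outside simulated range")
    max_lag = len(config.lag_pmf)
    if manipulation_night + max_lag > config.n_nights - 1:
        raise InvalidConfigError(
            "simulation too short for responses up to "
            f"{max_lag} nights after night {manipulation_night}"
        )
    focal_ids = trees.loc[trees["is_focal"], "tree_id"].to_numpy()
    if len(focal_ids) == 0:
        raise InvalidConfigError("no focal trees in landscape")
    tx = trees.set_index("tree_id")["x"]
    ty = trees.set_index("tree_id")["y"]
    step = config.sampling_interval

    bats = np.arange(config.n_bats, dtype=np.int64)
    manipulated = rng.choice(bats, config.n_manipulated, replace=False)
    manipulated_set = set(int(b) for b in manipulated)
    manifest = pd.DataFrame(
        {
            "night_index": np.int64(manipulation_night),
            "roost": [config.bat_roost(int(b)) for b in bats],
            "bat_id": bats,
            "role": ["manipulated" if int(b) in manipulated_set else "naive" for b in bats],
        }
    )

    lags = np.arange(1, max_lag + 1)
    new_rows = []
    for bat in bats:
        p = (
            config.manipulated_response_prob
            if int(bat) in manipulated_set
            else config.response_prob
        )
        if rng.random() >= p:
            continue
        lag = int(rng.choice(lags, p=config.lag_pmf))
        night = manipulation_night + lag
        tree = int(rng.choice(focal_ids))
        prior = truth[(truth["bat_id"] == bat) & (truth["night_index"] == night)]
        if len(prior):
            last = prior.loc[prior["t_end"].idxmax()]
            px, py, t0 = tx[last.tree_id], ty[last.tree_id], float(last.t_end)
        else:
            px, py = config.roosts[config.bat_roost(int(bat))]
            t0 = config.night_anchor(night)
        dist = math.hypot(tx[tree] - px, ty[tree] - py)
        commute = max(_quantize_up(dist / config.commute_speed, step), step)
        dwell = _draw_dwell(config, rng)
        t_start = t0 + commute
        t_end = min(t_start + dwell, config.night_end(night))
        if t_end <= t_start:  # pragma: no cover - nights always have room
            continue
        new_rows.append((int(bat), night, tree, t_start, t_end, lag))

    injected = pd.DataFrame(
        new_rows, columns=TRUTH_COLUMNS + ["lag"]
    )
    if len(injected) and len(truth):
        out = pd.concat([truth, injected[TRUTH_COLUMNS]], ignore_index=True)
    elif len(injected):
        out = injected[TRUTH_COLUMNS].copy()
    else:
        out = truth.copy()
    out = out.astype({"bat_id": np.int64, "night_index": np.int64, "tree_id": np.int64})
    out.sort_values(["bat_id", "t_start"], inplace=True, ignore_index=True)
    out.attrs["injected"] = injected
    return manifest, out


def make_roster(config: SimConfig) -> pd.DataFrame:
    """Tracking roster: every simulated bat tracked over the whole run."""
    bats = np.arange(config.n_bats, dtype=np.int64)
    return pd.DataFrame(
        {
            "bat_id": bats,
            "roost": [config.bat_roost(int(b)) for b in bats],
            "track_start": np.int64(0),
            "track_end": np.int64(max(config.n_nights - 1, 0)),
        }
    )


def episodes_to_visits(
    truth: pd.DataFrame, trees: pd.DataFrame, sampling_interval: float = 4.0
) -> pd.DataFrame:
    """Convert a ground-truth episode log into the visit-table schema.

    Used to run the visit-level statistics without rendering and
    re-segmenting fixes (exact centroids, no flyovers).
    """
    tx = trees.set_index("tree_id")["x"]
    ty = trees.set_index("tree_id")["y"]
    v = pd.DataFrame(
        {
            "bat_id": truth["bat_id"],
            "night_index": truth["night_index"],
            "tree_id": truth["tree_id"].astype("Int64"),
            "centroid_x": truth["tree_id"].map(tx).astype(float),
            "centroid_y": truth["tree_id"].map(ty).astype(float),
            "t_start": truth["t_start"],
            "t_end": truth["t_end"],
        }
    )
    v["duration"] = v["t_end"] - v["t_start"]
    v["n_fixes"] = (v["duration"] / sampling_interval).round().astype(np.int64) + 1
    v["flyover"] = False
    return v


# ---------------------------------------------------------------------------
# routine-interval cohorts for the resampling null
# ---------------------------------------------------------------------------


def simulate_routine_blocks(
    n_intervals: int = 60,
    bats_per_interval: int = 56,
    window_nights: int = 6,
    visit_rate: float = 0.012,
    focal_tree_ids: Sequence[int] = (0, 1),
    rng: np.random.Generator | None = None,
    seed: int = 0,
    bat_id_offset: int = 100_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Routine (non-fruiting period) interval cohorts for the null.

    Emulates tracking campaigns: ``n_intervals`` consecutive six-night
    blocks, each with its own cohort of ``bats_per_interval`` tagged
    bats, where each bat independently visits a focal tree during its
    block with probability ``visit_rate`` (the routine per-window rate).
    Returns ``(visits, roster)`` ready for the null sampler.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    focal_tree_ids = np.asarray(list(focal_tree_ids), dtype=np.int64)
    visit_rows = []
    roster_rows = []
    for j in range(n_intervals):
        start = j * window_nights
        for i in range(bats_per_interval):
            bat = bat_id_offset + j * bats_per_interval + i
            roster_rows.append((bat, "routine", start, start + window_nights - 1))
            if rng.random() < visit_rate:
                night = int(rng.integers(start, start + window_nights))
                tree = int(rng.choice(focal_tree_ids))
                t0 = night * DAY + 22 * 3600.0
                visit_rows.append(
                    (bat, night, tree, np.nan, np.nan, t0, t0 + 540.0, 540.0, 136, False)
                )
    visits = pd.DataFrame(visit_rows, columns=VISIT_COLUMNS)
    if len(visits):
        visits = visits.astype({"bat_id": np.int64, "night_index": np.int64})
        visits["tree_id"] = visits["tree_id"].astype("Int64")
    else:
        visits["tree_id"] = visits["tree_id"].astype("Int64")
    roster = pd.DataFrame(roster_rows, columns=ROSTER_COLUMNS)
    return visits, roster


def simulate_discovery_records(
    n_met: int,
    n_control: int,
    p_met: float,
    p_control: float,
    rng: np.random.Generator | None = None,
    seed: int = 0,
    lags: Sequence[int] = (1, 2, 3, 4, 5, 6),
) -> pd.DataFrame:
    """Dyadic discovery records at known group response probabilities.

    Direct fixture generator for the lag-model stage: one record per
    (dyad, lag) with Bernoulli responses at ``p_met`` / ``p_control``.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    rows = []
    for lag in lags:
        for i in range(n_met):
            rows.append((2 * i, 2 * i + 1, True, lag, bool(rng.random() < p_met)))
        for i in range(n_control):
            rows.append(
                (10_000 + 2 * i, 10_001 + 2 * i, False, lag, bool(rng.random() < p_control))
            )
    return pd.DataFrame(
        rows, columns=["focal_id", "partner_id", "met", "lag", "response"]
    )


# ---------------------------------------------------------------------------
# one-call experiment
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SimResult:
    trees: pd.DataFrame
    truth: pd.DataFrame
    visits: pd.DataFrame
    manifest: pd.DataFrame | None
    roster: pd.DataFrame
    fixes: pd.DataFrame | None


def simulate_experiment(
    config: SimConfig,
    manipulation_night: int | None = None,
    render_fixes: bool = False,
    rng: np.random.Generator | None = None,
) -> SimResult:
    """Full scenario: landscape, itineraries, optional manipulation, fixes.

    All randomness flows from one generator seeded by ``config.seed``
    (or the supplied ``rng``).  With ``render_fixes=False`` the visit
    table is derived directly from ground truth, which is the fast path
    for the statistical stages.
    """
    rng = _rng(config, rng)
    trees = generate_landscape(config, rng)
    truth = plan_itineraries(trees, config, rng)
    manifest = None
    if manipulation_night is not None:
        manifest, truth = inject_manipulation(
            truth, trees, config, manipulation_night, rng
        )
    visits = episodes_to_visits(truth, trees, config.sampling_interval)
    fixes = episodes_to_fixes(truth, trees, config, rng) if render_fixes else None
    return SimResult(trees, truth, visits, manifest, make_roster(config), fixes)
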