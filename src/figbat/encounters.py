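"""Dyadic tree encounters and new-tree discovery after meetings.

Two bats "meet" when their non-flyover visits to the same tree overlap
in time.  For each meeting, the partner's trees are those it visited in
the three nights before; the focal bat's new trees are those it visits
in a three-night window after the meeting (shifted by lag-1 nights for
lags 1-6), excluding every tree it had visited before.  A binary
response records whether the focal's new trees include any of the
partner's.  Never-met control dyads, month-matched to the meetings, give
the comparison group, and one logistic regression per lag estimates the
effect of having met on the discovery probability.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

ENCOUNTER_COLUMNS = [
    "bat_a",
    "bat_b",
    "tree_id",
    "overlap_start",
    "overlap_end",
    "night_index",
]
RECORD_COLUMNS = ["focal_id", "partner_id", "met", "lag", "response", "meeting_night"]


class InsufficientControlsError(ValueError):
    def __init__(self, shortfall: dict[int, int]):
        self.shortfall = shortfall
        super().__init__(
            "not enough never-met co-tracked dyads; shortfall by month: "
            + ", ".join(f"{m}: {k}" for m, k in sorted(shortfall.items()))
        )


def default_month_of_night(night: int) -> int:
    """Synthetic calendar: 30-night months."""
    return int(night) // 30


# ---------------------------------------------------------------------------
# encounter detection
# ---------------------------------------------------------------------------


def detect_encounters(visits: pd.DataFrame) -> pd.DataFrame:
    """All same-tree visit-interval overlaps of positive length.

    One row per overlapping visit pair (dyad unordered, bat_a < bat_b);
    zero-length contact (one visit ending exactly when the other starts)
    does not count.
    """
    v = visits[visits["tree_id"].notna()]
    if "flyover" in v:
        v = v[~v["flyover"].astype(bool)]
    rows = []
    for tree, grp in v.groupby("tree_id", sort=True):
        grp = grp.sort_values("t_start")
        starts = grp["t_start"].to_numpy(float)
        ends = grp["t_end"].to_numpy(float)
        bats = grp["bat_id"].to_numpy()
        nights = grp["night_index"].to_numpy()
        for i in range(len(grp)):
            for j in range(i + 1, len(grp)):
                if starts[j] >= ends[i]:
                    break
                if bats[i] == bats[j]:
                    continue
                lo = max(starts[i], starts[j])
                hi = min(ends[i], ends[j])
                a, b = sorted((bats[i], bats[j]))
                rows.append((a, b, tree, lo, hi, min(nights[i], nights[j])))
    enc = pd.DataFrame(rows, columns=ENCOUNTER_COLUMNS)
    if len(enc):
        enc.sort_values(["overlap_start", "bat_a", "bat_b"], inplace=True, ignore_index=True)
    return enc


def meetings_from_encounters(encounters: pd.DataFrame) -> pd.DataFrame:
    """Unique (dyad, night) meetings with met=True."""
    if encounters.empty:
        return pd.DataFrame(columns=["bat_a", "bat_b", "meeting_night", "met"])
    m = (
        encounters.rename(columns={"night_index": "meeting_night"})[
            ["bat_a", "bat_b", "meeting_night"]
        ]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    m["met"] = True
    return m


# ---------------------------------------------------------------------------
# sharing rate
# ---------------------------------------------------------------------------


def dyad_sharing_rate(
    visits: pd.DataFrame,
    roster: pd.DataFrame,
    window_nights: int = 6,
) -> dict[str, float]:
    """Fraction of co-tracked dyads sharing a tree within a six-night window.

    The denominator contains every dyad with at least one simultaneous
    tracked night; the window examined is the ``window_nights`` nights
    starting at the dyad's first co-tracked night.  Returns overall and
    same-/different-roost rates (NaN where a stratum is empty).
    """
    enc = detect_encounters(visits)
    info = roster.set_index("bat_id")
    bats = list(info.index)
    if len(bats) < 2:
        raise UndefinedRateError("need at least two tracked bats")
    enc_nights: dict[tuple, set[int]] = {}
    for r in enc.itertuples():
        enc_nights.setdefault((r.bat_a, r.bat_b), set()).add(int(r.night_index))
    num = {"overall": 0, "same_roost": 0, "diff_roost": 0}
    den = {"overall": 0, "same_roost": 0, "diff_roost": 0}
    for i in range(len(bats)):
        for j in range(i + 1, len(bats)):
            a, b = bats[i], bats[j]
            lo = max(info.at[a, "track_start"], info.at[b, "track_start"])
            hi = min(info.at[a, "track_end"], info.at[b, "track_end"])
            if hi < lo:
                continue
            window = range(int(lo), int(lo) + window_nights)
            key = tuple(sorted((a, b)))
            shared = bool(enc_nights.get(key, set()) & set(window))
            strat = (
                "same_roost"
                if info.at[a, "roost"] == info.at[b, "roost"]
                else "diff_roost"
            )
            for k in ("overall", strat):
                den[k] += 1
                num[k] += shared
    if den["overall"] == 0:
        raise UndefinedRateError("no co-tracked dyads")
    return {k: (num[k] / den[k] if den[k] else float("nan")) for k in den}


class UndefinedRateError(ValueError):
    """Sharing rate requested with no co-tracked dyads."""


# ---------------------------------------------------------------------------
# discovery records
# ---------------------------------------------------------------------------


def sample_control_dyads(
    roster: pd.DataFrame,
    meetings: pd.DataFrame,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    month_of_night: Callable[[int], int] = default_month_of_night,
) -> pd.DataFrame:
    """Never-met co-tracked dyads, month-matched to the meetings.

    Draws, without replacement, as many control dyads as there are
    distinct met dyads in each calendar month, assigning each control a
    pseudo-meeting night uniformly among its co-tracked nights in that
    month.  Raises with the per-month shortfall when impossible.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    met_pairs = set(
        tuple(sorted((a, b))) for a, b in meetings[["bat_a", "bat_b"]].itertuples(index=False)
    )
    need: dict[int, int] = {}
    for r in meetings.drop_duplicates(["bat_a", "bat_b"]).itertuples():
        need[month_of_night(r.meeting_night)] = (
            need.get(month_of_night(r.meeting_night), 0) + 1
        )

    info = roster.set_index("bat_id")
    bats = list(info.index)
    candidates: dict[int, list[tuple[tuple, list[int]]]] = {m: [] for m in need}
    for i in range(len(bats)):
        for j in range(i + 1, len(bats)):
            pair = tuple(sorted((bats[i], bats[j])))
            if pair in met_pairs:
                continue
            lo = max(info.at[pair[0], "track_start"], info.at[pair[1], "track_start"])
            hi = min(info.at[pair[0], "track_end"], info.at[pair[1], "track_end"])
            if hi < lo:
                continue
            for m in need:
                nights = [n for n in range(int(lo), int(hi) + 1) if month_of_night(n) == m]
                if nights:
                    candidates[m].append((pair, nights))

    shortfall = {m: need[m] - len(candidates[m]) for m in need if len(candidates[m]) < need[m]}
    if shortfall:
        raise InsufficientControlsError(shortfall)

    rows = []
    for m in sorted(need):
        pick = rng.choice(len(candidates[m]), need[m], replace=False)
        for k in pick:
            pair, nights = candidates[m][int(k)]
            night = int(nights[int(rng.integers(0, len(nights)))])
            rows.append((pair[0], pair[1], night, False))
    return pd.DataFrame(rows, columns=["bat_a", "bat_b", "meeting_night", "met"])


def build_discovery_records(
    visits: pd.DataFrame,
    dyads: pd.DataFrame,
    trees: pd.DataFrame | None = None,
    pre_window: int = 3,
    post_window: int = 3,
    lags: Sequence[int] = (1, 2, 3, 4, 5, 6),
    ficus_only: bool = False,
) -> pd.DataFrame:
    """One binary record per (dyad member as focal, lag).

    ``dyads`` holds met and control rows (bat_a, bat_b, meeting_night,
    met).  The partner's tree set is what it visited in the
    ``pre_window`` nights before the meeting; the focal's candidate new
    trees are its visits in the ``post_window`` nights whose anchor is
    shifted by (lag - 1) nights past the meeting, minus every tree the
    focal visited up to and including the meeting night.  ``ficus_only``
    restricts the partner's trees to unpredictable species (requires a
    tree table).
    """
    if ficus_only and trees is None:
        raise ValueError("ficus_only requires a tree table")
    v = visits[visits["tree_id"].notna()]
    if "flyover" in v:
        v = v[~v["flyover"].astype(bool)]
    unpredictable: set | None = None
    if ficus_only:
        unpredictable = set(
            trees.loc[trees["predictability"] == "unpredictable", "tree_id"]
        )

    by_bat: dict = {}
    for bat, grp in v.groupby("bat_id"):
        by_bat[bat] = grp[["night_index", "tree_id"]].to_numpy()

    def trees_in(bat, lo, hi) -> set:
        arr = by_bat.get(bat)
        if arr is None:
            return set()
        sel = (arr[:, 0] >= lo) & (arr[:, 0] <= hi)
        return set(arr[sel, 1])

    rows = []
    for d in dyads.itertuples():
        n0 = int(d.meeting_night)
        for focal, partner in ((d.bat_a, d.bat_b), (d.bat_b, d.bat_a)):
            partner_trees = trees_in(partner, n0 - pre_window, n0 - 1)
            if unpredictable is not None:
                partner_trees &= unpredictable
            already = trees_in(focal, -(10**9), n0)
            for lag in lags:
                anchor = n0 + (lag - 1)
                new_trees = trees_in(focal, anchor + 1, anchor + post_window) - already
                rows.append(
                    (focal, partner, bool(d.met), int(lag), bool(new_trees & partner_trees), n0)
                )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


# ---------------------------------------------------------------------------
# per-lag logistic models
# ---------------------------------------------------------------------------


def fit_lag_models(records: pd.DataFrame, lags: Sequence[int] | None = None) -> pd.DataFrame:
    """Logistic regression of response on met, one model per lag.

    Emits coefficient (log odds ratio of meeting), SE, Wald p and the
    fitted group probabilities; degenerate inputs (single-class response
    or a group at 0/1, i.e. complete separation) are flagged instead of
    fitted.
    """
    if lags is None:
        lags = sorted(records["lag"].unique())
    rows = []
    for lag in lags:
        sub = records[records["lag"] == lag]
        met = sub[sub["met"]]
        ctl = sub[~sub["met"]]
        row = {
            "lag": int(lag),
            "n_met": len(met),
            "n_control": len(ctl),
            "coef": np.nan,
            "se": np.nan,
            "p": np.nan,
            "p_met": met["response"].mean() if len(met) else np.nan,
            "p_control": ctl["response"].mean() if len(ctl) else np.nan,
            "flag": "",
        }
        if len(met) == 0 or len(ctl) == 0:
            row["flag"] = "missing-group"
        elif sub["response"].nunique() < 2:
            row["flag"] = "degenerate"
        elif row["p_met"] in (0.0, 1.0) or row["p_control"] in (0.0, 1.0):
            row["flag"] = "separation"
        else:
            X = sm.add_constant(sub["met"].astype(float).to_numpy())
            model = sm.GLM(sub["response"].astype(float).to_numpy(), X,
                           family=sm.families.Binomial())
            res = model.fit()
            row["coef"] = float(res.params[1])
            row["se"] = float(res.bse[1])
            row["p"] = float(res.pvalues[1])
            fitted = res.predict(sm.add_constant(np.array([1.0, 0.0])))
            row["p_met"], row["p_control"] = float(fitted[0]), float(fitted[1])
        rows.append(row)
    return pd.DataFrame(rows)


def run_encounter_analysis(
    visits: pd.DataFrame,
    roster: pd.DataFrame,
    trees: pd.DataFrame | None = None,
    lags: Sequence[int] = (1, 2, 3, 4, 5, 6),
    ficus_only: bool = False,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    month_of_night: Callable[[int], int] = default_month_of_night,
) -> dict[str, pd.DataFrame]:
    """Encounters -> met + control dyads -> records -> per-lag models."""
    if rng is None:
        rng = np.random.default_rng(seed)
    enc = detect_encounters(visits)
    meetings = meetings_from_encounters(enc)
    if meetings.empty:
        empty = pd.DataFrame(columns=RECORD_COLUMNS)
        return {"encounters": enc, "records": empty, "models": fit_lag_models(empty, lags)}
    controls = sample_control_dyads(roster, meetings, rng=rng, month_of_night=month_of_night)
    dyads = pd.concat([meetings, controls], ignore_index=True)
    records = build_discovery_records(
        visits, dyads, trees=trees, lags=lags, ficus_only=ficus_only
    )
    return {"encounters": enc, "records": records, "models": fit_lag_models(records, lags)}
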