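"""Post-manipulation visitation proportions versus a routine-movement null.

The observed statistic is the cumulative proportion of naive bats that
visited a focal tree within 1-6 nights of the odour-cue manipulation.
The null is built by resampling 1-6-night intervals of routine movement
(when the focal trees bore no fruit), pooling randomly drawn intervals
until at least ``min_cohort`` tracked bats accumulate, and recording the
pooled visitation proportion; 200-230 such iterations form the null
distribution, against which a one-tailed exceedance p-value is computed.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class UndefinedProportionError(ValueError):
    """Proportion requested over an empty cohort."""


class InfeasibleNullError(ValueError):
    """Routine data cannot ever pool ``min_cohort`` tracked bats."""


@dataclasses.dataclass
class VisitProportion:
    n_visitors: int
    n_cohort: int

    @property
    def proportion(self) -> float:
        return self.n_visitors / self.n_cohort


@dataclasses.dataclass
class NullDistribution:
    """Resampled routine visitation proportions for one window length."""

    window_nights: int
    proportions: np.ndarray
    n_iterations: int
    min_cohort: int = 70

    def mean(self) -> float:
        return float(np.mean(self.proportions))

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        a = 100.0 * (1.0 - level) / 2.0
        lo, hi = np.percentile(self.proportions, [a, 100.0 - a])
        return float(lo), float(hi)


def _focal_visit_mask(
    visits: pd.DataFrame, focal_tree_ids: Iterable[int]
) -> pd.Series:
    focal = pd.array(list(focal_tree_ids), dtype="Int64")
    mask = visits["tree_id"].isin(focal)
    if "flyover" in visits:
        mask &= ~visits["flyover"].astype(bool)
    return mask


def cumulative_visit_proportion(
    visits: pd.DataFrame,
    cohort_ids: Iterable[int],
    focal_tree_ids: Iterable[int],
    start_night: int,
    window_nights: int,
) -> VisitProportion:
    """Distinct cohort bats with >=1 non-flyover focal visit in nights
    (start, start + window], over the cohort size."""
    cohort = list(cohort_ids)
    if not cohort:
        raise UndefinedProportionError("empty cohort")
    if window_nights < 1:
        raise ValueError("window_nights must be >= 1")
    m = _focal_visit_mask(visits, focal_tree_ids)
    m &= visits["bat_id"].isin(cohort)
    m &= (visits["night_index"] > start_night) & (
        visits["night_index"] <= start_night + window_nights
    )
    return VisitProportion(int(visits.loc[m, "bat_id"].nunique()), len(cohort))


def pooled_visit_proportion(
    visits: pd.DataFrame,
    manifest: pd.DataFrame,
    focal_tree_ids: Iterable[int],
    window_nights: int,
    role: str = "naive",
) -> VisitProportion:
    """Pool the per-campaign counts across manipulation events.

    Each manifest night contributes its own cohort counted over its own
    post-manipulation window; numerators and denominators are summed.
    """
    sel = manifest[manifest["role"] == role]
    if sel.empty:
        raise UndefinedProportionError(f"no bats with role {role!r} in manifest")
    n_vis = 0
    n_coh = 0
    for night, grp in sel.groupby("night_index"):
        p = cumulative_visit_proportion(
            visits, grp["bat_id"], focal_tree_ids, int(night), window_nights
        )
        n_vis += p.n_visitors
        n_coh += p.n_cohort
    return VisitProportion(n_vis, n_coh)


def baseline_proportion(
    visits: pd.DataFrame,
    cohort_ids: Iterable[int],
    focal_tree_ids: Iterable[int],
    baseline_window: tuple[int, int],
) -> VisitProportion:
    """Same counting rule over a pre-manipulation night range [lo, hi]."""
    cohort = list(cohort_ids)
    if not cohort:
        raise UndefinedProportionError("empty cohort")
    lo, hi = baseline_window
    m = _focal_visit_mask(visits, focal_tree_ids)
    m &= visits["bat_id"].isin(cohort)
    m &= (visits["night_index"] >= lo) & (visits["night_index"] <= hi)
    return VisitProportion(int(visits.loc[m, "bat_id"].nunique()), len(cohort))


# ---------------------------------------------------------------------------
# resampling null
# ---------------------------------------------------------------------------


def sample_routine_null(
    visits: pd.DataFrame,
    roster: pd.DataFrame,
    focal_tree_ids: Iterable[int],
    window_nights: int,
    min_cohort: int = 70,
    n_iterations: int = 215,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    exclude_nights: Iterable[int] = (),
) -> NullDistribution:
    """Resample routine intervals and pool to at least ``min_cohort`` bats.

    Per iteration, candidate start nights of ``window_nights``-night
    intervals are drawn without replacement; each drawn interval
    contributes its tracked-bat count (bats whose tracking covers the
    whole interval) to the denominator and its distinct focal-visiting
    bats to the numerator, until the pooled denominator reaches
    ``min_cohort``.  A bat appearing in several pooled intervals counts
    once per interval (interval-bat exposures).  Intervals touching
    ``exclude_nights`` (fruiting / manipulation periods) are never drawn.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    w = int(window_nights)
    if w < 1:
        raise ValueError("window_nights must be >= 1")
    excl = set(int(n) for n in exclude_nights)

    ts = roster["track_start"].to_numpy(np.int64)
    te = roster["track_end"].to_numpy(np.int64)
    bat_ids = roster["bat_id"].to_numpy()
    night_lo = int(ts.min())
    night_hi = int(te.max())
    starts = np.array(
        [
            s
            for s in range(night_lo, night_hi - w + 2)
            if not any((s + k) in excl for k in range(w))
        ],
        dtype=np.int64,
    )
    if len(starts) == 0:
        raise InfeasibleNullError("no candidate intervals outside excluded nights")

    # coverage[b, s]: bat b tracked over the whole interval starting at s
    coverage = (ts[:, None] <= starts[None, :]) & (te[:, None] >= starts[None, :] + w - 1)

    # visited[b, s]: bat b has >=1 non-flyover focal visit in the interval
    m = _focal_visit_mask(visits, focal_tree_ids)
    fv = visits.loc[m, ["bat_id", "night_index"]]
    bat_index = {b: i for i, b in enumerate(bat_ids)}
    visited = np.zeros_like(coverage)
    for bat, night in fv.itertuples(index=False):
        i = bat_index.get(bat)
        if i is None:
            continue
        lo = max(int(night) - w + 1, night_lo)
        sel = (starts >= lo) & (starts <= night)
        visited[i, sel] = True

    cohort_count = coverage.sum(axis=0)
    visitor_count = (visited & coverage).sum(axis=0)
    if int(cohort_count.sum()) < min_cohort:
        raise InfeasibleNullError(
            f"routine data can pool at most {int(cohort_count.sum())} "
            f"interval-bat exposures (< min_cohort={min_cohort})"
        )

    props = np.empty(n_iterations)
    idx = np.arange(len(starts))
    for it in range(n_iterations):
        order = rng.permutation(idx)
        cum = np.cumsum(cohort_count[order])
        stop = int(np.searchsorted(cum, min_cohort))
        take = order[: stop + 1]
        denom = int(cohort_count[take].sum())
        numer = int(visitor_count[take].sum())
        props[it] = numer / denom
    return NullDistribution(w, props, n_iterations, min_cohort)


def permutation_pvalue(observed: float, null: NullDistribution) -> float:
    """One-tailed exceedance p = (#{null_i >= observed} + 1) / (n + 1)."""
    props = np.asarray(null.proportions)
    if props.size == 0:
        raise ValueError("empty null distribution")
    return float((np.sum(props >= observed) + 1) / (props.size + 1))


# ---------------------------------------------------------------------------
# full test
# ---------------------------------------------------------------------------


def run_manipulation_test(
    visits: pd.DataFrame,
    manifest: pd.DataFrame,
    roster: pd.DataFrame,
    focal_tree_ids: Iterable[int],
    windows: Sequence[int] = (1, 2, 3, 4, 5, 6),
    min_cohort: int = 70,
    n_iterations: int = 215,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    exclude_nights: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Observed naive proportion, null summary and p per window length.

    ``exclude_nights`` defaults to two weeks before through the longest
    window after each manipulation night, so the null never samples the
    experimental periods.  CIs are empirical 2.5/97.5 percentiles.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    focal = list(focal_tree_ids)
    w_max = max(windows)
    if exclude_nights is None:
        excl: set[int] = set()
        for night in manifest["night_index"].unique():
            excl.update(range(int(night) - 14, int(night) + w_max + 1))
        exclude_nights = excl
    rows = []
    for w in windows:
        obs = pooled_visit_proportion(visits, manifest, focal, w, role="naive")
        null = sample_routine_null(
            visits,
            roster,
            focal,
            w,
            min_cohort=min_cohort,
            n_iterations=n_iterations,
            rng=rng,
            exclude_nights=exclude_nights,
        )
        lo, hi = null.ci()
        rows.append(
            {
                "window": w,
                "n_visitors": obs.n_visitors,
                "n_cohort": obs.n_cohort,
                "observed": obs.proportion,
                "null_mean": null.mean(),
                "null_lo": lo,
                "null_hi": hi,
                "p": permutation_pvalue(obs.proportion, null),
            }
        )
    return pd.DataFrame(rows)


def plot_report(report: pd.DataFrame, baseline: float | None = None, ax=None):
    """Observed vs null proportions per window, with null CIs."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(
        report["window"],
        report["null_mean"],
        yerr=[
            report["null_mean"] - report["null_lo"],
            report["null_hi"] - report["null_mean"],
        ],
        fmt="o-",
        color="tab:blue",
        capsize=3,
        label="routine movement (null)",
    )
    ax.plot(
        report["window"],
        report["observed"],
        "o-",
        color="tab:red",
        label="manipulation (naive bats)",
    )
    if baseline is not None:
        ax.axhline(baseline, color="grey", lw=1, label="pre-manipulation baseline")
    ax.set_xlabel("nights after manipulation")
    ax.set_ylabel("proportion of bats visiting focal trees")
    ax.legend(frameon=False)
    return ax
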