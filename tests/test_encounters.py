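"""Dyadic encounter detection, sharing rates, discovery records and the
per-lag logistic models, checked against brute-force oracles and exact
contingency-table algebra."""

import numpy as np
import pandas as pd
import pytest

from figbat import encounters as enc
from figbat import synth


def _visits(rows):
    v = pd.DataFrame(rows, columns=synth.VISIT_COLUMNS)
    v["tree_id"] = v["tree_id"].astype("Int64")
    return v


def _vrow(bat, night, tree, t0, t1, flyover=False):
    return (bat, night, tree, np.nan, np.nan, float(t0), float(t1), float(t1 - t0),
            10, flyover)


def _roster(bats, start=0, end=20, roost="A"):
    if isinstance(roost, str):
        roost = [roost] * len(bats)
    return pd.DataFrame(
        {"bat_id": bats, "roost": roost, "track_start": start, "track_end": end}
    )


class TestDetectEncounters:
    def test_partial_overlap_on_same_tree(self):
        v = _visits([_vrow(1, 0, 7, 0, 600), _vrow(2, 0, 7, 300, 900)])
        out = enc.detect_encounters(v)
        assert len(out) == 1
        r = out.iloc[0]
        assert (r.bat_a, r.bat_b, r.tree_id) == (1, 2, 7)
        assert (r.overlap_start, r.overlap_end) == (300.0, 600.0)

    def test_zero_length_contact_does_not_count(self):
        v = _visits([_vrow(1, 0, 7, 0, 600), _vrow(2, 0, 7, 600, 900)])
        assert enc.detect_encounters(v).empty

    def test_different_trees_never_meet(self):
        v = _visits([_vrow(1, 0, 7, 0, 600), _vrow(2, 0, 8, 0, 600)])
        assert enc.detect_encounters(v).empty

    def test_flyovers_and_unmatched_visits_ignored(self):
        v = _visits(
            [
                _vrow(1, 0, 7, 0, 600),
                _vrow(2, 0, 7, 100, 500, flyover=True),
                (3, 0, pd.NA, np.nan, np.nan, 0.0, 600.0, 600.0, 10, False),
            ]
        )
        assert enc.detect_encounters(v).empty

    def test_matches_all_pairs_brute_force(self, rng):
        rows = [
            _vrow(
                int(rng.integers(0, 12)),
                0,
                int(rng.integers(0, 6)),
                t0 := float(rng.integers(0, 5000)),
                t0 + float(rng.integers(1, 800)),
            )
            for _ in range(200)
        ]
        v = _visits(rows)
        out = enc.detect_encounters(v)
        got = set(
            (r.bat_a, r.bat_b, r.tree_id, r.overlap_start, r.overlap_end)
            for r in out.itertuples()
        )
        expected = set()
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                bi, _, ti, _, _, si, ei, *_ = rows[i]
                bj, _, tj, _, _, sj, ej, *_ = rows[j]
                if ti != tj or bi == bj:
                    continue
                lo, hi = max(si, sj), min(ei, ej)
                if hi > lo:
                    a, b = sorted((bi, bj))
                    expected.add((a, b, ti, lo, hi))
        assert got == expected

    def test_symmetric_in_bat_order(self):
        v1 = _visits([_vrow(5, 0, 7, 0, 600), _vrow(2, 0, 7, 300, 900)])
        v2 = _visits([_vrow(2, 0, 7, 300, 900), _vrow(5, 0, 7, 0, 600)])
        a = enc.detect_encounters(v1)
        b = enc.detect_encounters(v2)
        pd.testing.assert_frame_equal(a, b)
        assert (a["bat_a"] < a["bat_b"]).all()


class TestSharingRate:
    def test_single_shared_visit_gives_rate_one(self):
        v = _visits([_vrow(1, 0, 7, 0, 600), _vrow(2, 0, 7, 300, 900)])
        out = enc.dyad_sharing_rate(v, _roster([1, 2]))
        assert out["overall"] == 1.0

    def test_disjoint_tracking_excluded_from_denominator(self):
        v = _visits([_vrow(1, 0, 7, 0, 600)])
        roster = pd.DataFrame(
            {
                "bat_id": [1, 2],
                "roost": ["A", "A"],
                "track_start": [0, 10],
                "track_end": [5, 20],
            }
        )
        with pytest.raises(enc.UndefinedRateError):
            enc.dyad_sharing_rate(v, roster)

    def test_five_bat_colony_matches_hand_enumeration(self):
        # bats 1-4 tracked nights 0-19, bat 5 nights 30-49; encounters:
        # (1,2) on night 1 (in their first window) and (3,4) on night 9
        # (outside their first 6-night window). 7 co-tracked dyads
        # (the 6 among bats 1-4 and none with bat 5), 1 sharing.
        day = synth.DAY
        v = _visits(
            [
                _vrow(1, 1, 7, 1 * day, 1 * day + 600),
                _vrow(2, 1, 7, 1 * day + 100, 1 * day + 700),
                _vrow(3, 9, 8, 9 * day, 9 * day + 600),
                _vrow(4, 9, 8, 9 * day + 100, 9 * day + 700),
            ]
        )
        roster = pd.DataFrame(
            {
                "bat_id": [1, 2, 3, 4, 5],
                "roost": ["A", "A", "B", "B", "A"],
                "track_start": [0, 0, 0, 0, 30],
                "track_end": [19, 19, 19, 19, 49],
            }
        )
        out = enc.dyad_sharing_rate(v, roster, window_nights=6)
        assert out["overall"] == pytest.approx(1 / 6)
        assert out["same_roost"] == pytest.approx(1 / 2)  # (1,2) of {(1,2),(3,4)}
        assert out["diff_roost"] == pytest.approx(0 / 4)


class TestControlDyads:
    def _meetings(self, pairs, nights):
        return pd.DataFrame(
            {
                "bat_a": [p[0] for p in pairs],
                "bat_b": [p[1] for p in pairs],
                "meeting_night": nights,
                "met": True,
            }
        )

    def test_all_dyads_met_is_an_error(self):
        meetings = self._meetings([(1, 2)], [3])
        with pytest.raises(enc.InsufficientControlsError):
            enc.sample_control_dyads(_roster([1, 2]), meetings, seed=0)

    def test_counts_match_and_controls_never_met(self):
        meetings = self._meetings([(1, 2), (3, 4), (1, 3), (2, 5)], [2, 3, 4, 5])
        roster = _roster(list(range(1, 11)))
        out = enc.sample_control_dyads(roster, meetings, seed=0)
        assert len(out) == 4
        met = {(1, 2), (3, 4), (1, 3), (2, 5)}
        got = set(map(tuple, out[["bat_a", "bat_b"]].to_numpy()))
        assert got.isdisjoint(met)
        assert not out["met"].any()

    def test_fixed_seed_reproducible(self):
        meetings = self._meetings([(1, 2), (3, 4)], [2, 35])
        roster = _roster(list(range(1, 9)), end=40)
        a = enc.sample_control_dyads(roster, meetings, seed=7)
        b = enc.sample_control_dyads(roster, meetings, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_month_matching(self):
        # one meeting in month 1 (night 35); controls must get a
        # pseudo-meeting night in the same 30-night month
        meetings = self._meetings([(1, 2)], [35])
        roster = _roster([1, 2, 3, 4], end=59)
        out = enc.sample_control_dyads(roster, meetings, seed=1)
        assert (out["meeting_night"] // 30 == 1).all()


class TestDiscoveryRecords:
    def _dyads(self, a, b, night, met=True):
        return pd.DataFrame(
            {"bat_a": [a], "bat_b": [b], "meeting_night": [night], "met": [met]}
        )

    def test_partner_tree_discovered_two_nights_later(self):
        # partner 2 visited tree 50 before meeting at night 10; focal 1
        # visits it on night 12 (meeting + 2)
        v = _visits(
            [
                _vrow(2, 8, 50, 100, 700),
                _vrow(1, 12, 50, 200, 800),
            ]
        )
        rec = enc.build_discovery_records(v, self._dyads(1, 2, 10))
        r1 = rec[rec["focal_id"] == 1].set_index("lag")["response"]
        # 3-night post windows anchored at meeting+lag-1: lags 1 and 2
        # cover night 12, later lags do not
        assert bool(r1[1]) and bool(r1[2])
        assert not (r1[3] or r1[4] or r1[5] or r1[6])
        # the partner discovered nothing of the focal's
        assert not rec[rec["focal_id"] == 2]["response"].any()

    def test_previously_known_tree_is_not_a_discovery(self):
        v = _visits(
            [
                _vrow(2, 8, 50, 100, 700),
                _vrow(1, 5, 50, 100, 700),  # focal already knew tree 50
                _vrow(1, 12, 50, 200, 800),
            ]
        )
        rec = enc.build_discovery_records(v, self._dyads(1, 2, 10))
        assert not rec[rec["focal_id"] == 1]["response"].any()

    def test_ficus_only_restricts_partner_trees(self):
        trees = pd.DataFrame(
            {
                "tree_id": [50, 60],
                "x": 0.0,
                "y": 0.0,
                "species": ["Morus alba", "Ficus religiosa"],
                "predictability": ["seasonal", "unpredictable"],
                "is_focal": False,
            }
        )
        v = _visits([_vrow(2, 8, 50, 100, 700), _vrow(1, 12, 50, 200, 800)])
        rec = enc.build_discovery_records(
            v, self._dyads(1, 2, 10), trees=trees, ficus_only=True
        )
        assert not rec["response"].any()  # tree 50 is seasonal

    def test_matches_set_algebra_oracle(self, rng):
        # 10-bat random fixture vs an independent plain-python oracle
        rows = [
            _vrow(
                int(rng.integers(0, 10)),
                int(rng.integers(0, 25)),
                int(rng.integers(0, 8)),
                0,
                600,
            )
            for _ in range(300)
        ]
        v = _visits(rows)
        dyads = pd.DataFrame(
            {
                "bat_a": [0, 2, 4, 6],
                "bat_b": [1, 3, 5, 7],
                "meeting_night": [10, 12, 8, 15],
                "met": [True, True, False, False],
            }
        )
        rec = enc.build_discovery_records(v, dyads)

        visited = {}
        for b, n, tr, *_ in rows:
            visited.setdefault(b, []).append((n, tr))

        def tset(bat, lo, hi):
            return {tr for n, tr in visited.get(bat, []) if lo <= n <= hi}

        for d in dyads.itertuples():
            for focal, partner in ((d.bat_a, d.bat_b), (d.bat_b, d.bat_a)):
                ptrees = tset(partner, d.meeting_night - 3, d.meeting_night - 1)
                known = tset(focal, -(10**9), d.meeting_night)
                for lag in range(1, 7):
                    lo = d.meeting_night + lag
                    new = tset(focal, lo, lo + 2) - known
                    expect = bool(new & ptrees)
                    got = rec[
                        (rec["focal_id"] == focal)
                        & (rec["partner_id"] == partner)
                        & (rec["lag"] == lag)
                    ]["response"]
                    assert len(got) == 1 and bool(got.iloc[0]) == expect


class TestLagModels:
    def test_two_by_two_fit_equals_exact_log_odds_ratio(self):
        rows = []
        for i in range(100):
            rows.append((2 * i, 2 * i + 1, True, 1, i < 30))
            rows.append((500 + 2 * i, 501 + 2 * i, False, 1, i < 10))
        rec = pd.DataFrame(
            rows, columns=["focal_id", "partner_id", "met", "lag", "response"]
        )
        out = enc.fit_lag_models(rec, lags=[1]).iloc[0]
        assert out["coef"] == pytest.approx(np.log(27 / 7), abs=1e-6)
        assert out["p_met"] == pytest.approx(0.30, abs=1e-9)
        assert out["p_control"] == pytest.approx(0.10, abs=1e-9)

    def test_recovers_generating_log_odds_within_two_se(self):
        rec = synth.simulate_discovery_records(500, 500, 0.30, 0.10, seed=21, lags=[1])
        out = enc.fit_lag_models(rec, lags=[1]).iloc[0]
        target = np.log((0.30 / 0.70) / (0.10 / 0.90))  # 1.3499
        assert abs(out["coef"] - target) <= 2 * out["se"]

    def test_fitted_probabilities_equal_group_frequencies(self):
        rec = synth.simulate_discovery_records(80, 120, 0.4, 0.2, seed=5, lags=[1, 2])
        out = enc.fit_lag_models(rec)
        for lag in (1, 2):
            sub = rec[rec["lag"] == lag]
            row = out[out["lag"] == lag].iloc[0]
            assert row["p_met"] == pytest.approx(
                sub[sub["met"]]["response"].mean(), abs=1e-9
            )
            assert row["p_control"] == pytest.approx(
                sub[~sub["met"]]["response"].mean(), abs=1e-9
            )

    def test_null_effect_rarely_significant(self):
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rec = synth.simulate_discovery_records(60, 60, 0.2, 0.2, seed=seed, lags=[1])
            out = enc.fit_lag_models(rec, lags=[1]).iloc[0]
            if out["flag"] == "" and out["p"] < 0.05:
                hits += 1
        assert 0.005 <= hits / n_seeds <= 0.12

    def test_copying_strength_increases_fitted_met_probability(self):
        means = []
        for p_met in (0.12, 0.22, 0.35):
            fitted = [
                enc.fit_lag_models(
                    synth.simulate_discovery_records(150, 150, p_met, 0.1,
                                                     seed=seed, lags=[1]),
                    lags=[1],
                ).iloc[0]["p_met"]
                for seed in range(10)
            ]
            means.append(np.mean(fitted))
        assert means[0] < means[1] < means[2]

    def test_single_class_response_is_flagged(self):
        rec = synth.simulate_discovery_records(30, 30, 0.0, 0.0, seed=0, lags=[1])
        out = enc.fit_lag_models(rec, lags=[1]).iloc[0]
        assert out["flag"] == "degenerate"
        assert np.isnan(out["coef"])

    def test_complete_separation_is_flagged(self):
        rec = synth.simulate_discovery_records(30, 30, 0.5, 0.0, seed=1, lags=[1])
        out = enc.fit_lag_models(rec, lags=[1]).iloc[0]
        assert out["flag"] == "separation"
        assert np.isnan(out["coef"])
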