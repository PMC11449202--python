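import numpy as np
import pandas as pd
import pytest

from figbat import synth

FOCAL_A, FOCAL_B = 900, 901


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    return synth.SimConfig(
        n_bats=6,
        n_manipulated=2,
        n_nights=9,
        n_trees=80,
        extent=(4000.0, 4000.0),
        seed=1,
    )


def _campaign_visits(rows, bats, n_visitors, night):
    """Give the first n_visitors of `bats` one focal visit in (night, night+6]."""
    for k, bat in enumerate(bats[:n_visitors]):
        vn = night + 1 + (k % 6)
        t0 = vn * synth.DAY + 22 * 3600.0
        rows.append(
            (bat, vn, FOCAL_A if k % 2 == 0 else FOCAL_B, np.nan, np.nan,
             t0, t0 + 540.0, 540.0, 136, False)
        )


@pytest.fixture
def campaign_tables():
    """Manifest + visit table encoding the three manipulation campaigns.

    Six roost-release events: per event (night, roost) the numbers of
    smeared and naive bats, and how many of each visited a focal tree
    within six nights: (3,9 -> 2,4), (4,6 -> 1,2), (4,15 -> 1,2),
    (1,7 -> 0,1), (4,19 -> 0,1), (0,0 -> 0,0).  Totals: 16 smeared with
    4 visitors, 56 naive with 10 visitors, 72 tagged bats.
    """
    events = [
        # night, roost, n_manip, n_naive, manip_visitors, naive_visitors
        (10, "Gershom", 3, 9, 2, 4),
        (10, "Zemer", 4, 6, 1, 2),
        (40, "Gershom", 4, 15, 1, 2),
        (40, "Zemer", 1, 7, 0, 1),
        (70, "Gershom", 4, 19, 0, 1),
        (70, "Zemer", 0, 0, 0, 0),
    ]
    manifest_rows = []
    visit_rows = []
    bat = 0
    for night, roost, n_m, n_n, vis_m, vis_n in events:
        manip_bats = list(range(bat, bat + n_m))
        bat += n_m
        naive_bats = list(range(bat, bat + n_n))
        bat += n_n
        for b in manip_bats:
            manifest_rows.append((night, roost, b, "manipulated"))
        for b in naive_bats:
            manifest_rows.append((night, roost, b, "naive"))
        _campaign_visits(visit_rows, manip_bats, vis_m, night)
        _campaign_visits(visit_rows, naive_bats, vis_n, night)
    manifest = pd.DataFrame(
        manifest_rows, columns=["night_index", "roost", "bat_id", "role"]
    )
    visits = pd.DataFrame(visit_rows, columns=synth.VISIT_COLUMNS)
    visits["tree_id"] = visits["tree_id"].astype("Int64")
    return manifest, visits
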