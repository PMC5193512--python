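"""The generative twin of the change-rating experiments."""

import numpy as np
import pytest
from scipy import stats

from discaug import (
    Condition,
    SimConfig,
    Theory,
    read_trials,
    records_to_frame,
    simulate_experiment,
    write_trials,
)
from discaug.simulate import EXPT2_ITEMS, frame_to_records


def cell_means(records):
    frame = records_to_frame(records)
    frame["condition"] = frame.causal_direction + frame.consequent
    return frame.groupby("condition").rating.mean()


class TestGenerator:
    def test_same_seed_reproduces_exactly(self):
        cfg = SimConfig(n_participants=8, seed=5)
        assert simulate_experiment(cfg) == simulate_experiment(cfg)

    def test_design_layout(self):
        records = simulate_experiment(SimConfig(n_participants=3, seed=0))
        frame = records_to_frame(records)
        assert len(frame) == 3 * 17  # 10 causal + 7 diagnostic scenarios each
        per_cell = frame.groupby(["causal_direction", "consequent"]).item_id.nunique()
        assert per_cell[("CE", "C")] == 5 and per_cell[("CE", "NC")] == 5
        assert per_cell[("EC", "C")] == 4 and per_cell[("EC", "NC")] == 3
        # items are nested: no item appears in two cells
        cells_per_item = frame.groupby("item_id")[["causal_direction", "consequent"]].nunique()
        assert (cells_per_item == 1).all().all()

    def test_null_category_proportions_follow_thresholds(self):
        cfg = SimConfig(
            n_participants=300, seed=11, theory=Theory.IM,
            sigma_participant=0.0, sigma_item=0.0,
        )
        ratings = records_to_frame(simulate_experiment(cfg)).rating
        expected_low = stats.norm.cdf(-0.43)
        assert np.mean(ratings == -1) == pytest.approx(expected_low, abs=0.02)
        assert np.mean(ratings == 1) == pytest.approx(expected_low, abs=0.02)

    def test_huge_effect_saturates_cell(self):
        cfg = SimConfig(n_participants=50, seed=2, theory=Theory.CM, effect_scale=5.0)
        frame = records_to_frame(simulate_experiment(cfg))
        ecnc = frame[(frame.causal_direction == "EC") & (frame.consequent == "NC")]
        assert (ecnc.rating == 1).mean() > 0.97

    def test_cell_means_order_by_generating_signs(self):
        cfg = SimConfig(n_participants=250, seed=13, theory=Theory.CM, effect_scale=1.0)
        means = cell_means(simulate_experiment(cfg))
        assert means["CEC"] < means["CENC"] - 0.3
        assert abs(means["CENC"]) < 0.1 and abs(means["ECC"]) < 0.1
        assert means["ECNC"] > means["ECC"] + 0.3

    def test_participant_sd_increases_between_participant_variance(self):
        spreads = []
        for sigma in (0.2, 0.6, 1.0):
            cfg = SimConfig(
                n_participants=220, seed=17, theory=Theory.IM,
                sigma_participant=sigma, sigma_item=0.0,
            )
            frame = records_to_frame(simulate_experiment(cfg))
            spreads.append(frame.groupby("participant_id").rating.mean().var())
        assert spreads[0] < spreads[1] < spreads[2]

    @pytest.mark.parametrize(
        "kw",
        [
            dict(n_participants=0),
            dict(sigma_participant=-0.1),
            dict(thresholds=(0.5, 0.5)),
            dict(items_per_direction={"CE": 0, "EC": 6}),
            dict(experiment=3),
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            SimConfig(**kw)

    def test_cell_mean_override(self):
        means = {Condition.CEC: 3.0}
        cfg = SimConfig(n_participants=60, seed=4, cell_means=means,
                        items_per_direction=dict(EXPT2_ITEMS), experiment=2)
        got = cell_means(simulate_experiment(cfg))
        assert got["CEC"] > 0.9 and abs(got["ECNC"]) < 0.25


class TestCsvRoundTrip:
    def test_write_read_identity(self, tmp_path):
        records = simulate_experiment(SimConfig(n_participants=5, seed=9))
        path = tmp_path / "trials.csv"
        write_trials(records, path)
        assert read_trials(path) == records

    def test_out_of_range_rating_rejected_with_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "participant_id,item_id,causal_direction,consequent,rating\n"
            "P1,CE01,CE,C,1\nP1,CE02,CE,C,2\n"
        )
        with pytest.raises(ValueError, match="row 2"):
            read_trials(path)

    def test_schema_adapter_remaps_columns_and_ratings(self, tmp_path):
        path = tmp_path / "foreign.csv"
        path.write_text(
            "Subject,Scenario,Direction,Cons,Resp\n"
            "s1,i1,CE,C,less\ns1,i2,EC,NC,more\ns2,i1,CE,C,same\n"
        )
        records = read_trials(
            path,
            column_map={
                "participant_id": "Subject",
                "item_id": "Scenario",
                "causal_direction": "Direction",
                "consequent": "Cons",
                "rating": "Resp",
            },
            rating_map={"less": -1, "same": 0, "more": 1},
        )
        assert [r.rating for r in records] == [-1, 1, 0]

    def test_missing_columns_reported(self, tmp_path):
        path = tmp_path / "short.csv"
        path.write_text("participant_id,rating\nP1,0\n")
        with pytest.raises(ValueError, match="missing required columns"):
            read_trials(path)

    def test_duplicate_trials_rejected(self):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "participant_id": ["P1", "P1"],
                "item_id": ["i1", "i1"],
                "causal_direction": ["CE", "CE"],
                "consequent": ["C", "C"],
                "rating": [0, 1],
            }
        )
        with pytest.raises(ValueError, match="duplicate"):
            frame_to_records(frame)
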