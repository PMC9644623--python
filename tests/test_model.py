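import numpy as np
import pandas as pd
import pytest

from lexhaz import (
    Covariate,
    ModelSpec,
    TimeScale,
    build_bases,
    design_matrix,
    expand_tvc_rows,
    validate_episodes,
)
from lexhaz.model import coefficient_names


def subjects_frame(rows):
    return pd.DataFrame(rows)


class TestExpandTvcRows:
    def test_two_rows_with_gate_flip_at_event_time(self):
        subj = subjects_frame(
            [{"id": 1, "entry": 0.0, "exit": 10.0, "event": 1, "r": 2.43}]
        )
        ep = expand_tvc_rows(subj)
        assert len(ep) == 2
        first, second = ep.iloc[0], ep.iloc[1]
        assert (first.entry, first.exit, first.event, first.I_RM) == (0.0, 2.43, 0, 0)
        assert (second.entry, second.exit, second.event, second.I_RM) == (2.43, 10.0, 1, 1)

    def test_no_intermediate_event_keeps_single_ungated_row(self):
        subj = subjects_frame(
            [{"id": 1, "entry": 0.0, "exit": 10.0, "event": 0, "r": np.nan}]
        )
        ep = expand_tvc_rows(subj)
        assert len(ep) == 1 and ep.I_RM.iloc[0] == 0

    def test_person_time_and_events_conserved(self):
        rng = np.random.default_rng(5)
        n = 200
        exit_ = rng.uniform(1, 10, n)
        r = np.where(rng.random(n) < 0.5, exit_ * rng.random(n), np.nan)
        r = np.where(r <= 0, np.nan, r)
        subj = pd.DataFrame(
            {"id": np.arange(n), "entry": 0.0, "exit": exit_,
             "event": rng.integers(0, 2, n), "r": r}
        )
        ep = expand_tvc_rows(subj)
        assert (ep.exit - ep.entry).sum() == pytest.approx(exit_.sum(), abs=1e-12)
        assert ep.event.sum() == subj.event.sum()

    def test_event_after_follow_up_errors(self):
        subj = subjects_frame([{"id": 1, "entry": 0.0, "exit": 5.0, "event": 1, "r": 6.0}])
        with pytest.raises(ValueError, match="after exit"):
            expand_tvc_rows(subj)

    def test_event_at_exit_stays_ungated(self):
        subj = subjects_frame([{"id": 1, "entry": 0.0, "exit": 5.0, "event": 1, "r": 5.0}])
        ep = expand_tvc_rows(subj)
        assert len(ep) == 1 and ep.I_RM.iloc[0] == 0

    def test_event_at_or_before_entry_warns_and_gates_whole_episode(self):
        subj = subjects_frame([{"id": 1, "entry": 1.0, "exit": 5.0, "event": 0, "r": 0.5}])
        with pytest.warns(UserWarning, match="at or before"):
            ep = expand_tvc_rows(subj)
        assert len(ep) == 1 and ep.I_RM.iloc[0] == 1


class TestDesign:
    def test_gated_columns_zero_when_gate_off(self, tvc_spec, tvc_episodes):
        bases = build_bases(tvc_spec, tvc_episodes)
        names = coefficient_names(tvc_spec, bases)
        off = tvc_episodes[tvc_episodes.I_RM == 0]
        Z = design_matrix(tvc_spec, bases, off, off["exit"].to_numpy())
        cols = [i for i, n in enumerate(names) if n.startswith("t2") or n == "I_RM"]
        assert np.all(Z[:, cols] == 0.0)

    def test_construction_is_pure(self, tvc_spec, tvc_episodes):
        bases = build_bases(tvc_spec, tvc_episodes)
        t = tvc_episodes["exit"].to_numpy()
        Z1 = design_matrix(tvc_spec, bases, tvc_episodes, t)
        Z2 = design_matrix(tvc_spec, bases, tvc_episodes, t)
        assert np.array_equal(Z1, Z2)

    def test_collapses_to_single_scale_when_gates_off(self, tvc_episodes):
        spec2 = ModelSpec(
            scales=(TimeScale("t1", log=True, n_knots=4),
                    TimeScale("t2", offset="r", gate="I_RM", n_knots=4)),
        )
        spec1 = ModelSpec(scales=(TimeScale("t1", log=True, n_knots=4),))
        off = tvc_episodes[tvc_episodes.I_RM == 0].reset_index(drop=True)
        # same knots: secondary scale built from the full table
        bases2 = build_bases(spec2, tvc_episodes)
        bases1 = build_bases(spec1, tvc_episodes)
        t = off["exit"].to_numpy()
        Z2 = design_matrix(spec2, bases2, off, t)
        Z1 = design_matrix(spec1, bases1, off, t)
        names2 = coefficient_names(spec2, bases2)
        keep = [i for i, n in enumerate(names2) if not (n.startswith("t2") or n == "I_RM")]
        assert np.allclose(Z2[:, keep], Z1)

    def test_breast_cancer_style_block_width(self):
        """Gate jump + 5 age-spline + treatment + 3 + 3 time splines + 1 = 14."""
        spec = ModelSpec(
            scales=(TimeScale("t1", log=True, n_knots=4),
                    TimeScale("t2", offset="r", gate="I_RM", n_knots=4)),
            covariates=(Covariate("age", n_knots=6), Covariate("hormon")),
        )
        rng = np.random.default_rng(0)
        n = 300
        ep = pd.DataFrame(
            {"id": np.arange(n), "entry": 0.0, "exit": rng.uniform(1, 10, n),
             "event": 1, "r": np.nan, "age": rng.uniform(30, 80, n),
             "hormon": rng.integers(0, 2, n), "I_RM": 0}
        )
        ep.loc[: n // 2, "I_RM"] = 1
        ep.loc[: n // 2, "r"] = ep.loc[: n // 2, "exit"] * 0.5
        bases = build_bases(spec, ep)
        assert len(coefficient_names(spec, bases)) == 14

    def test_matched_cohort_style_block_width(self):
        """Exposure jump + sex + 4 + 4 time splines + intercept = 11."""
        spec = ModelSpec(
            scales=(TimeScale("t1", n_knots=5),
                    TimeScale("t2", offset="a0", gate="I_MPN", n_knots=5)),
            covariates=(Covariate("I_sex"),),
        )
        rng = np.random.default_rng(1)
        n = 400
        a0 = rng.uniform(50, 80, n)
        ep = pd.DataFrame(
            {"id": np.arange(n), "entry": a0 + 0.1, "exit": a0 + rng.uniform(0.5, 10, n),
             "event": 1, "a0": a0, "I_MPN": rng.integers(0, 2, n),
             "I_sex": rng.integers(0, 2, n)}
        )
        bases = build_bases(spec, ep)
        assert len(coefficient_names(spec, bases)) == 11

    def test_gated_log_scale_requires_positive_values(self):
        spec = ModelSpec(
            scales=(TimeScale("t1", n_knots=2),
                    TimeScale("t2", offset="r", gate="g", n_knots=3, log=True)),
        )
        ep = pd.DataFrame(
            {"id": [0, 1, 2, 3], "entry": [0.0] * 4, "exit": [4.0, 5.0, 6.0, 7.0],
             "event": 1, "r": [1.0, 1.5, 2.0, 2.5], "g": 1}
        )
        bases = build_bases(spec, ep)
        with pytest.raises(ValueError, match="positive"):
            design_matrix(spec, bases, ep, np.array([0.5, 5.0, 6.0, 7.0]))


class TestModelSpec:
    def test_reference_scale_cannot_have_offset(self):
        with pytest.raises(ValueError, match="reference"):
            ModelSpec(scales=(TimeScale("t1", offset="a0"),))

    def test_secondary_scale_needs_offset(self):
        with pytest.raises(ValueError, match="offset"):
            ModelSpec(scales=(TimeScale("t1"), TimeScale("t2")))

    def test_dict_round_trip(self, tvc_spec):
        assert ModelSpec.from_dict(tvc_spec.to_dict()) == tvc_spec

    def test_unknown_config_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown keys"):
            ModelSpec.from_dict({"scales": [{"name": "t", "knotz": 3}]})


def test_validate_episodes_rejects_gated_nonpositive_scale_value():
    spec = ModelSpec(
        scales=(TimeScale("t1", n_knots=2),
                TimeScale("t2", offset="r", gate="g", n_knots=3)),
    )
    ep = pd.DataFrame(
        {"id": [0], "entry": [0.0], "exit": [2.0], "event": [1], "r": [3.0], "g": [1]}
    )
    with pytest.raises(ValueError, match="non-positive"):
        validate_episodes(ep, spec)
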