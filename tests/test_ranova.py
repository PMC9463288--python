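import numpy as np
import pandas as pd
import pytest

from endoeval.ranova import (
    SIGNIFICANCE_TICKS,
    SessionModel,
    _orthonormal_contrasts,
    _pooled_within_cov,
    gg_epsilon,
    hf_epsilon,
    neglog10_summary,
    ranova_session,
    ranova_table,
    sessions_of,
)
from .oracles import gg_epsilon_eigen_oracle

GROUPS_12 = np.array(["2D"] * 6 + ["3D"] * 6)


class TestEpsilon:
    def test_compound_symmetry_gives_one(self, rng):
        # exact CS covariance: shared subject effect + iid noise, large n limit
        # checked exactly by constructing a CS matrix and synthetic data spectrum
        subj = rng.standard_normal((2000, 1))
        Y = subj + rng.standard_normal((2000, 3))
        g = np.array(["2D"] * 1000 + ["3D"] * 1000)
        assert gg_epsilon(Y, g) == pytest.approx(1.0, abs=0.01)
        assert hf_epsilon(Y, g) == 1.0

    def test_hf_clipped_to_one(self, rng):
        # mild non-sphericity: HF overshoots 1 and is clipped
        Y = rng.standard_normal((12, 3))
        assert hf_epsilon(Y, GROUPS_12) <= 1.0

    def test_k2_analogue_is_identity(self, rng):
        Y = rng.standard_normal((12, 2))
        assert gg_epsilon(Y, GROUPS_12) == pytest.approx(1.0, abs=1e-12)

    def test_matches_eigenvalue_oracle(self, rng):
        C = _orthonormal_contrasts(3)
        for _ in range(20):
            Y = rng.standard_normal((12, 3)) @ rng.standard_normal((3, 3))
            M = C @ _pooled_within_cov(Y, GROUPS_12) @ C.T
            assert gg_epsilon(Y, GROUPS_12) == pytest.approx(
                gg_epsilon_eigen_oracle(M), abs=1e-10
            )

    def test_bounds(self, rng):
        for _ in range(50):
            Y = rng.standard_normal((12, 3)) @ rng.standard_normal((3, 3))
            e = gg_epsilon(Y, GROUPS_12)
            assert 1 / 2 - 1e-12 <= e <= 1 + 1e-12
            assert 1 / 2 < hf_epsilon(Y, GROUPS_12) <= 1.0

    def test_constant_data_degenerates_to_one(self):
        Y = np.ones((12, 3))
        assert hf_epsilon(Y, GROUPS_12) == 1.0


class TestRanovaSession:
    def test_identical_columns_no_time_effect(self, rng):
        Y = np.tile(rng.standard_normal((12, 1)), (1, 3))
        res = ranova_session(SessionModel(Y=Y, group=GROUPS_12))
        assert res.F_time == 0.0 and res.p_time == 1.0

    def test_matches_mixed_anova_oracle_balanced(self, rng):
        pg = pytest.importorskip("pingouin")
        for _ in range(3):
            Y = rng.standard_normal((12, 3)) @ rng.standard_normal((3, 3))
            Y += rng.standard_normal((12, 1))
            df = pd.DataFrame({
                "y": Y.ravel(),
                "time": np.tile([1, 2, 3], 12),
                "subj": np.repeat(np.arange(12), 3),
                "grp": np.repeat(GROUPS_12, 3),
            })
            aov = pg.mixed_anova(df, dv="y", within="time", subject="subj",
                                 between="grp")
            res = ranova_session(SessionModel(Y=Y, group=GROUPS_12))
            assert res.F_time == pytest.approx(
                aov.loc[aov.Source == "time", "F"].item(), rel=1e-9)
            assert res.F_int == pytest.approx(
                aov.loc[aov.Source == "Interaction", "F"].item(), rel=1e-9)

    def test_epsilon_one_reduces_to_uncorrected(self, rng):
        from scipy import stats
        Y = rng.standard_normal((12, 1)) + rng.standard_normal((12, 3))
        res = ranova_session(SessionModel(Y=Y, group=GROUPS_12))
        if res.eps_hf == 1.0:
            df_t, df_e = res.df_time
            assert res.p_time == pytest.approx(
                float(stats.f.sf(res.F_time, 2, 20)))
            assert (df_t, df_e) == (2, 20)

    def test_null_type_one_error_calibrated(self):
        """Empirical time-effect rejection rate under the null is nominal."""
        rng = np.random.default_rng(123)
        rej = 0
        n_reps = 1000
        for _ in range(n_reps):
            Y = rng.standard_normal((12, 3)) + rng.standard_normal((12, 1))
            res = ranova_session(SessionModel(Y=Y, group=GROUPS_12))
            rej += res.p_time < 0.05
        assert 0.03 <= rej / n_reps <= 0.07

    def test_small_group_rejected(self, rng):
        Y = rng.standard_normal((3, 3))
        with pytest.raises(ValueError):
            SessionModel(Y=Y, group=np.array(["2D", "2D", "3D"]))


class TestSummary:
    def test_ticks(self):
        assert SIGNIFICANCE_TICKS[0] == pytest.approx(-np.log10(0.05), abs=5e-5)
        assert round(-np.log10(0.05), 4) == 1.3010
        assert -np.log10(0.01) == pytest.approx(2.0)
        assert -np.log10(0.001) == pytest.approx(3.0)

    def test_boxplot_stats_and_outliers(self):
        p = np.full(40, 0.5)
        p[0] = 1e-6  # one strongly significant feature
        res = pd.DataFrame({
            "feature": [f"m{i}" for i in range(40)],
            "session": 1,
            "p_time": p,
            "p_time_endo": np.full(40, 0.5),
        })
        s = neglog10_summary(res)
        entry = s["sessions"][1]["time"]
        assert entry["outliers"] == ["m0"]
        assert entry["median"] == pytest.approx(-np.log10(0.5))
        assert s["ticks"] == list(SIGNIFICANCE_TICKS)


def test_sessions_built_from_table(toy_tables):
    tbl = toy_tables[1]
    models = sessions_of(tbl, "V_RMS@ch1")
    assert set(models) == {1, 2, 3}
    for m in models.values():
        assert m.Y.shape == (4, 3)
        assert set(np.unique(m.group)) == {"2D", "3D"}


def test_ranova_table_covers_all_features(toy_tables):
    tbl = toy_tables[1]
    feats = ["V_RMS@ch1", "Velocity@Hand_R"]
    rt = ranova_table(tbl, feats)
    assert len(rt) == len(feats) * 3
    assert ((rt.p_time > 0) & (rt.p_time <= 1)).all()
    assert ((rt.eps_hf > 0.5) & (rt.eps_hf <= 1)).all()
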