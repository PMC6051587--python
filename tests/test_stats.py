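"""Well-mean aggregation and the mixed ANOVA + Dunnett comparison."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from axoquant import (
    ExplantMeta,
    radial_density,
    rm_anova_dunnett,
    well_means,
)
from axoquant.pipeline import profiles_from_specs
from axoquant.stats import WELL_MEAN, _mixed_anova

from conftest import small_field_spec


def _profile(embryo, treatment, rep, explant, densities, scale=10.0, width=30.0):
    shape = (6, 6)  # 3 nonempty bins at this scale/width
    prof = radial_density(np.zeros(shape, dtype=bool), scale, width)
    prof.density = np.asarray(densities, dtype=float)[: prof.density.size]
    prof.meta = ExplantMeta(embryo, treatment, rep, explant)
    return prof


class TestWellMeans:
    def test_single_explant_well_mean_duplicates_it(self):
        table = well_means([_profile("e1", "ngf", "1", "drg01", [0.5, 0.25, 0.1])])
        wm = table.well_mean_rows().sort_values("bin_start_um")
        ex = table.explant_rows().sort_values("bin_start_um")
        assert np.array_equal(wm["density"].to_numpy(), ex["density"].to_numpy())
        assert set(wm["explant_id"]) == {WELL_MEAN}

    def test_two_explants_average(self):
        table = well_means([
            _profile("e1", "ngf", "1", "drg01", [0.1, 0.1, 0.1]),
            _profile("e1", "ngf", "1", "drg02", [0.3, 0.5, 0.7]),
        ])
        wm = table.well_mean_rows().sort_values("bin_start_um")
        assert wm["density"].to_numpy() == pytest.approx([0.2, 0.3, 0.4])

    def test_matches_independent_groupby_mean_exactly(self):
        profiles = profiles_from_specs({
            ("e1", "a", "1"): [small_field_spec(seed=0), small_field_spec(seed=1)],
            ("e1", "a", "2"): [small_field_spec(seed=2)],
            ("e2", "b", "1"): [small_field_spec(seed=3), small_field_spec(seed=4)],
        })
        table = well_means(profiles)
        oracle = (
            table.explant_rows()
            .groupby(["embryo_id", "treatment", "rep", "bin_start_um"])["density"]
            .mean()
        )
        wm = table.well_mean_rows().set_index(
            ["embryo_id", "treatment", "rep", "bin_start_um"]
        )["density"]
        assert len(oracle) == len(wm)
        assert np.array_equal(oracle.sort_index().to_numpy(), wm.sort_index().to_numpy())

    def test_inconsistent_bin_geometry_rejected(self):
        p1 = _profile("e1", "a", "1", "d1", [0.1, 0.1, 0.1], width=30.0)
        p2 = _profile("e1", "a", "1", "d2", [0.1, 0.1, 0.1], width=20.0)
        with pytest.raises(ValueError, match="geometry"):
            well_means([p1, p2])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no profiles"):
            well_means([])


def _toy_experiment_table(effect=0.0, n_embryos=3, treatments=("ctrl", "tx"), seed=0):
    """Direct Gaussian well-mean profiles: n_embryos per treatment, 3 fine bins."""
    rng = np.random.default_rng(seed)
    profiles = []
    for ti, t in enumerate(treatments):
        for e in range(n_embryos):
            base = rng.normal(0.5, 0.05, size=3) + (effect * ti)
            profiles.append(_profile(f"e{e}", t, "1", "drg01", base))
    return well_means(profiles)


class TestRmAnovaDunnett:
    def test_matches_pingouin_mixed_anova(self):
        pg = pytest.importorskip("pingouin")
        table = _toy_experiment_table(effect=0.08, n_embryos=5, seed=3)
        res = rm_anova_dunnett(table, coarse_width_um=30.0, control_treatment="ctrl")
        wm = table.well_mean_rows().copy()
        wm["subject"] = wm["embryo_id"] + "|" + wm["treatment"]
        ref = pg.mixed_anova(
            wm, dv="density", within="bin_start_um", between="treatment", subject="subject"
        )
        row = ref[ref["Source"] == "treatment"].iloc[0]
        assert res.F_treatment == pytest.approx(row["F"], rel=1e-10)
        assert (res.df_num, res.df_den) == (row["DF1"], row["DF2"])
        assert res.p_treatment == pytest.approx(row["p_unc"], rel=1e-10)

    def test_hand_sized_two_by_two_design(self):
        """2 treatments x 2 bins with hand-picked numbers vs explicit sums of squares."""
        # subjects (rows) x bins (cols); first 3 rows group a, last 3 group b
        Y = np.array([
            [1.0, 2.0], [2.0, 3.0], [3.0, 4.0],
            [3.0, 5.0], [4.0, 6.0], [5.0, 7.0],
        ])
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        out = _mixed_anova(Y, groups).set_index("effect")
        # grand mean 3.75; group means 2.5 and 5.0 -> SS_treat = 2*3*(1.25^2)*2
        assert out.loc["treatment", "SS"] == pytest.approx(18.75)
        assert out.loc["treatment", "df"] == 1
        # subject means (1.5,2.5,3.5 | 4,5,6): SS_subj_within = 2 * (1+0+1+1+0+1)
        assert out.loc["subjects_within_groups", "SS"] == pytest.approx(8.0)
        assert out.loc["treatment", "F"] == pytest.approx(18.75 / (8.0 / 4))
        # bins differ by +1 (group a) and +2 (group b) uniformly: zero residual
        assert out.loc["residual", "SS"] == pytest.approx(0.0, abs=1e-12)

    def test_requires_three_embryos_per_treatment(self):
        table = _toy_experiment_table(n_embryos=2)
        with pytest.raises(ValueError, match="at least 3 embryos"):
            rm_anova_dunnett(table, 30.0, "ctrl")

    def test_requires_two_treatments(self):
        table = _toy_experiment_table(treatments=("ctrl",))
        with pytest.raises(ValueError, match="at least 2 treatments"):
            rm_anova_dunnett(table, 30.0, "ctrl")

    def test_unknown_control_rejected(self):
        table = _toy_experiment_table()
        with pytest.raises(ValueError, match="nope"):
            rm_anova_dunnett(table, 30.0, "nope")

    def test_unbalanced_interior_bins_rejected_naming_subject(self):
        table = _toy_experiment_table()
        data = table.data
        drop = (
            (data["embryo_id"] == "e0")
            & (data["treatment"] == "ctrl")
            & (data["bin_start_um"] == 30.0)
        )
        table.data = data[~drop]
        with pytest.raises(ValueError, match="e0"):
            rm_anova_dunnett(table, 30.0, "ctrl")

    def test_extra_distal_bins_dropped_listwise(self):
        """One subject reaching farther bins does not unbalance the design."""
        table = _toy_experiment_table()
        extra = table.well_mean_rows().iloc[[0]].copy()
        extra["bin_start_um"], extra["bin_end_um"] = 90.0, 120.0
        table.data = pd.concat([table.data, extra], ignore_index=True)
        res = rm_anova_dunnett(table, 30.0, "ctrl")
        assert res.dunnett["bin_start_um"].max() == 60.0

    def test_dunnett_adjusted_at_least_unadjusted(self):
        table = _toy_experiment_table(effect=0.04, n_embryos=4, treatments=("ctrl", "t1", "t2"), seed=9)
        res = rm_anova_dunnett(table, 30.0, "ctrl")
        d = res.dunnett.dropna(subset=["p_unadjusted"])
        assert len(d) == 6  # 2 comparisons x 3 bins
        assert np.all(d["p_adjusted"].to_numpy() >= d["p_unadjusted"].to_numpy() - 1e-12)

    def test_gg_correction_reported_and_within_bounds(self):
        table = _toy_experiment_table(n_embryos=5, seed=2)
        res = rm_anova_dunnett(table, 30.0, "ctrl", gg=True)
        assert 1.0 / (3 - 1) <= res.gg_epsilon <= 1.0

    def test_reps_collapse_to_one_subject_record(self):
        profiles = []
        for rep, shift in (("1", 0.0), ("2", 0.2)):
            profiles.append(_profile("e1", "a", rep, "d1", [0.3 + shift] * 3))
        for e in ("e1", "e2", "e3"):
            profiles.append(_profile(e, "a", "9", "d1", [0.4] * 3))
            profiles.append(_profile(e, "b", "1", "d1", [0.5] * 3))
        table = well_means(profiles)
        from axoquant.stats import _balance, _coarse_subject_table

        subj = _balance(_coarse_subject_table(table, 30.0))
        assert subj.groupby(["embryo_id", "treatment", "coarse_bin"]).size().max() == 1

    def test_null_p_values_are_uniform(self):
        """Calibration of the between-treatment F test on Gaussian nulls."""
        from scipy.stats import kstest

        ps = []
        rng = np.random.default_rng(123)
        for _ in range(500):
            Y = rng.normal(size=(9, 4))
            groups = np.repeat(["a", "b", "c"], 3)
            out = _mixed_anova(Y, groups).set_index("effect")
            ps.append(out.loc["treatment", "p"])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_power_to_flag_strong_fragmentation(self):
        """Dunnett flags a 0 vs 0.5 fragmentation contrast distally in >90% of sims."""
        rng = np.random.default_rng(2024)
        hits = 0
        n_sims = 40
        for _ in range(n_sims):
            specs = {}
            for t, frag in (("intact", 0.0), ("frag", 0.5)):
                for e in range(3):
                    specs[(f"e{e}", t, "1")] = [
                        small_field_spec(
                            seed=int(rng.integers(2**31)),
                            fragmentation_fraction=frag,
                        )
                    ]
            table = well_means(profiles_from_specs(specs))
            res = rm_anova_dunnett(table, 500.0, "intact")
            distal = res.dunnett[res.dunnett["bin_start_um"].isin([500.0, 1000.0])]
            if (distal["p_adjusted"] < 0.05).any():
                hits += 1
        assert hits / n_sims > 0.9
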