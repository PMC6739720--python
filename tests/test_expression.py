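import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lncsalt.core import ExpressionMatrix, PipelineConfig, SampleMeta, ValidationError
from lncsalt.expression import (
    call_de,
    class_correlation_contrast,
    contrast_test,
    log2_fold_change,
    salt_responsive_ids,
    specificity_sets,
    tau_index,
    tau_table,
)


class TestLog2FoldChange:
    def test_fourfold(self):
        assert log2_fold_change(4, 1, 0) == pytest.approx(2.0)

    def test_identity(self):
        assert log2_fold_change(5, 5, 0.01) == 0.0

    def test_hand_value(self):
        assert log2_fold_change(3, 6, 0.01) == pytest.approx(math.log2(3.01 / 6.01), abs=1e-12)
        assert log2_fold_change(3, 6, 0.01) == pytest.approx(-0.998, abs=1e-3)

    def test_zero_pseudocount_zero_mean_error(self):
        with pytest.raises(ValidationError):
            log2_fold_change(0, 0, 0)


class TestContrastTest:
    def test_identical_groups_p_one(self):
        assert contrast_test([2, 2, 2], [2, 2, 2]) == 1.0

    def test_closed_form_oracle(self):
        # hand-computed pooled two-sample t statistic referred to t(4)
        a_raw, b_raw = [1, 1.1, 0.9], [8, 8.2, 7.9]
        pc = 0.01
        a = np.log2(np.array(a_raw) + pc)
        b = np.log2(np.array(b_raw) + pc)
        sp2 = (2 * a.var(ddof=1) + 2 * b.var(ddof=1)) / 4
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        expected = 2 * stats.t.sf(abs(t), 4)
        assert contrast_test(a_raw, b_raw, pc) == pytest.approx(expected, rel=1e-10)

    def test_requires_replicates(self):
        with pytest.raises(ValidationError):
            contrast_test([1], [2, 3])

    def test_type_one_error_calibration(self):
        # null: both groups from the same log-normal; nominal 5% level
        rng = np.random.default_rng(42)
        n = 10_000
        A = np.power(2.0, rng.normal(3, 0.5, size=(n, 3)))
        B = np.power(2.0, rng.normal(3, 0.5, size=(n, 3)))
        p = stats.ttest_ind(np.log2(A + 0.01), np.log2(B + 0.01), axis=1, equal_var=True).pvalue
        frac = float(np.mean(p < 0.05))
        assert abs(frac - 0.05) <= 0.01


def _design_matrix(values_by_tid, tissues=("leaf",), salts=(0, 150, 300), reps=3, seed=0):
    rng = np.random.default_rng(seed)
    samples, cols = {}, {}
    for t in tissues:
        for s in salts:
            for r in range(1, reps + 1):
                sid = f"{t}_{s}_{r}"
                samples[sid] = SampleMeta(t, s, r)
                cols[sid] = [values_by_tid[tid](t, s, r) for tid in values_by_tid]
    df = pd.DataFrame(cols, index=list(values_by_tid))
    return ExpressionMatrix(df, samples)


class TestCallDe:
    def test_boundary_inclusive_fc(self, config):
        # planted exact 2x change, tiny noise: |log2fc| ~= 1 counts as DE
        m = _design_matrix(
            {"t": lambda t, s, r: (4.0 + 0.001 * r) * (2.0 if s == 300 else 1.0)},
            seed=1,
        )
        de = call_de(m, PipelineConfig(pseudocount=0.0))
        row = de[(de.salt_a == 0) & (de.salt_b == 300)].iloc[0]
        assert row.log2fc == pytest.approx(1.0, abs=1e-3)
        assert bool(row.is_de)

    def test_high_significance_low_fc_not_de(self):
        m = _design_matrix(
            {"t": lambda t, s, r: 4.0 * (1.9 if s == 300 else 1.0) + 0.0001 * r}
        )
        de = call_de(m, PipelineConfig(pseudocount=0.0))
        row = de[(de.salt_a == 0) & (de.salt_b == 300)].iloc[0]
        assert row.p < 1e-6 and abs(row.log2fc) < 1.0 and not bool(row.is_de)

    def test_three_contrasts_per_tissue(self):
        m = _design_matrix({"t": lambda t, s, r: 2.0 + r * 0.01}, tissues=("leaf", "root"))
        de = call_de(m, PipelineConfig())
        assert len(de) == 2 * 3  # 1 transcript x 2 tissues x 3 contrasts
        assert set(zip(de.salt_a, de.salt_b)) == {(0, 150), (0, 300), (150, 300)}

    def test_missing_group_skipped_with_warning(self, caplog):
        m = _design_matrix({"t": lambda t, s, r: 2.0 + 0.1 * r}, salts=(0, 300))
        with caplog.at_level("WARNING"):
            de = call_de(m, PipelineConfig())
        assert set(zip(de.salt_a, de.salt_b)) == {(0, 300)}
        assert "skipping contrast" in caplog.text

    def test_de_flag_monotone_in_thresholds(self):
        rng = np.random.default_rng(5)
        m = _design_matrix(
            {
                f"t{i}": (lambda eff: lambda t, s, r: float(
                    2 ** (2.0 + (eff if s == 300 else 0.0) + rng.normal(0, 0.3))
                ))(rng.normal(0, 1.5))
                for i in range(50)
            }
        )
        loose = call_de(m, PipelineConfig(log2fc_cut=0.5, p_cut=0.1))
        tight = call_de(m, PipelineConfig(log2fc_cut=1.0, p_cut=0.05))
        assert set(salt_responsive_ids(tight)) <= set(salt_responsive_ids(loose))

    def test_recovery_of_planted_effects(self):
        # 10-seed average recall >= 0.9 and FPR <= 0.05 at noise_sd 0.2
        from lncsalt.simulate import SimTruth, plan_expression, simulate_expression

        recalls, fprs = [], []
        for seed in range(10):
            truth = SimTruth(lncrna_class={f"A_L{i:04d}": "lincRNA" for i in range(60)})
            plan_expression(truth, "A", seed, de_fraction=0.5, ts_fraction=0.0, hk_fraction=0.0)
            ids = truth.lnc_ids("A")
            m = simulate_expression(ids, truth, noise_sd=0.2, seed=seed + 100)
            de = call_de(m, PipelineConfig())
            called = salt_responsive_ids(de)
            planted = set(truth.de_effects)
            null = set(ids) - planted
            recalls.append(len(called & planted) / len(planted))
            fprs.append(len(called & null) / len(null))
        assert np.mean(recalls) >= 0.9
        assert np.mean(fprs) <= 0.05


class TestTau:
    def test_single_tissue_profile(self):
        r = tau_index([0, 0, 10, 0], ["leaf", "phloem", "xylem", "root"])
        assert r.tau == 1.0 and r.max_tissue == "xylem"

    def test_uniform_profile(self):
        assert tau_index([5, 5, 5, 5]).tau == 0.0

    def test_hand_arithmetic(self):
        assert tau_index([8, 2, 4, 1]).tau == pytest.approx(17 / 24)

    def test_all_zero_excluded(self, caplog):
        with caplog.at_level("WARNING"):
            assert tau_index([0, 0, 0, 0]) is None

    @given(
        st.lists(
            st.one_of(st.just(0.0), st.floats(1e-6, 1e6, allow_nan=False)),
            min_size=2,
            max_size=8,
        ).filter(lambda xs: max(xs) > 0),
        st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, profile, scale):
        t1 = tau_index(profile).tau
        t2 = tau_index([scale * x for x in profile]).tau
        assert t1 == pytest.approx(t2, abs=1e-9)

    @given(st.lists(st.floats(0, 1e4, allow_nan=False), min_size=2, max_size=8).filter(
        lambda xs: max(xs) > 0
    ))
    def test_range(self, profile):
        assert 0.0 <= tau_index(profile).tau <= 1.0

    def test_strictly_decreases_as_zero_tissue_rises(self):
        base = [10.0, 0.0, 2.0, 3.0]
        taus = [tau_index([10.0, v, 2.0, 3.0]).tau for v in (0.0, 2.0, 5.0, 9.0)]
        assert all(a > b for a, b in zip(taus, taus[1:]))


class TestSpecificitySets:
    def _tau_df(self, d):
        return pd.DataFrame(
            [{"transcript_id": k, "tau": v, "max_tissue": "leaf"} for k, v in d.items()]
        )

    def _de_df(self, flags):
        # flags: list of (tid, tissue, is_de)
        return pd.DataFrame(
            [
                {"transcript_id": t, "tissue": tis, "salt_a": 0, "salt_b": 300,
                 "log2fc": 2.0, "p": 0.001, "p_adj_BH": 0.01, "is_de": f}
                for t, tis, f in flags
            ]
        )

    def test_tau_boundary_strict(self, config):
        ts, hk, tsde = specificity_sets(
            self._tau_df({"a": 0.9, "b": 0.90001}), self._de_df([]), config
        )
        assert ts == {"b"}  # tau exactly 0.9 is NOT tissue-specific

    def test_housekeeping_requires_no_de(self, config):
        tau_df = self._tau_df({"a": 0.05, "b": 0.05})
        de = self._de_df([("a", "leaf", True), ("b", "leaf", False)])
        _, hk, _ = specificity_sets(tau_df, de, config)
        assert hk == {"b"}

    def test_tissue_specific_de_exactly_one_tissue(self, config):
        de = self._de_df(
            [("a", "leaf", True), ("b", "leaf", True), ("b", "root", True)]
        )
        _, _, tsde = specificity_sets(self._tau_df({}), de, config)
        assert tsde == {"a"}


class TestClassCorrelation:
    def _matrix(self, seed=0, n_uniform=10, n_varying=10):
        rng = np.random.default_rng(seed)
        vals = {}
        for i in range(n_uniform):
            base = 2.0 + i * 0.5
            vals[f"u{i}"] = lambda t, s, r, b=base: b
        for i in range(n_varying):
            offs = dict(zip(("leaf", "phloem", "xylem", "root"), rng.uniform(0, 64, 4)))
            vals[f"v{i}"] = lambda t, s, r, o=offs: 1.0 + o[t]
        return _design_matrix(vals, tissues=("leaf", "phloem", "xylem", "root"))

    def test_uniform_set_rho_one(self):
        m = self._matrix()
        rho_u, _ = class_correlation_contrast(m, [f"u{i}" for i in range(10)],
                                              [f"v{i}" for i in range(10)])
        assert rho_u == pytest.approx(1.0)

    def test_varying_below_uniform(self):
        m = self._matrix(seed=3)
        rho_u, rho_v = class_correlation_contrast(
            m, [f"u{i}" for i in range(10)], [f"v{i}" for i in range(10)]
        )
        assert rho_v < rho_u

    def test_spearman_rank_formula_oracle(self):
        # 5-point vectors, no ties: rho = 1 - 6*sum(d^2)/(n(n^2-1))
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
        y = np.array([2.0, 0.5, 9.0, 2.5, 6.0])
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        d2 = np.sum((rx - ry) ** 2)
        expected = 1 - 6 * d2 / (5 * 24)
        assert stats.spearmanr(x, y).statistic == pytest.approx(expected, abs=1e-12)

    def test_directional_on_fixture(self, sim_dir, config):
        from lncsalt import io
        from lncsalt.pipeline import SPECIES_FILES

        d, truth = sim_dir
        m = io.read_expression(
            d / SPECIES_FILES["expression"].format(s="a"),
            d / SPECIES_FILES["samples"].format(s="a"),
        )
        lnc = truth.lnc_ids("A")
        mrna = [g for g in truth.coding_ids if g.startswith("A")]
        rho_lnc, rho_mrna = class_correlation_contrast(m, lnc, mrna)
        assert rho_lnc < rho_mrna


def test_tau_table_on_fixture(sim_dir, config):
    from lncsalt import io
    from lncsalt.pipeline import SPECIES_FILES

    d, truth = sim_dir
    m = io.read_expression(
        d / SPECIES_FILES["expression"].format(s="a"),
        d / SPECIES_FILES["samples"].format(s="a"),
    )
    df = tau_table(m.subset(truth.lnc_ids("A")), PipelineConfig())
    taus = df.set_index("transcript_id")["tau"]
    for tid, tissue in truth.tissue_specific.items():
        if not tid.startswith("A"):
            continue
        assert taus[tid] > 0.9
        assert df.set_index("transcript_id").loc[tid, "max_tissue"] == tissue
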