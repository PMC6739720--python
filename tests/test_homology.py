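import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncsalt.core import ExpressionMatrix, PipelineConfig, SampleMeta, ValidationError
from lncsalt.homology import (
    HomologPair,
    find_homologs,
    high_expression_pairs,
    homolog_concordance,
    species_specific_de,
    tissue_specific_homolog_patterns,
)
from lncsalt.simulate import SimTruth, simulate_genome, simulate_sister_species

CFG = PipelineConfig()


def _random_seqs(n, seed, lo=250, hi=600):
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    return {
        f"s{i}": "".join(bases[rng.integers(0, 4, int(rng.integers(lo, hi)))])
        for i in range(n)
    }


class TestFindHomologs:
    def test_identical_sets_all_self_pairs(self):
        seqs = _random_seqs(8, 0)
        pairs, spec_a, spec_b = find_homologs(seqs, dict(seqs), CFG)
        assert {(p.id_a, p.id_b) for p in pairs} == {(k, k) for k in seqs}
        assert all(p.identity == 1.0 for p in pairs)
        assert spec_a == set() and spec_b == set()

    def test_disjoint_random_sets_no_pairs(self):
        a = _random_seqs(6, 1)
        b = {f"b{i}": s for i, s in enumerate(_random_seqs(6, 2).values())}
        pairs, spec_a, spec_b = find_homologs(a, b, CFG)
        assert pairs == []
        assert spec_a == set(a) and spec_b == set(b)

    def test_each_id_in_at_most_one_pair(self):
        tx, truth = simulate_genome(6, 4, seed=3)
        tx_b = simulate_sister_species(tx, truth, 0.02, 0.5, seed=4)
        seqs_a = {t.id: t.sequence for t in tx if t.id in truth.lncrna_class}
        seqs_b = {t.id: t.sequence for t in tx_b if t.id in truth.lncrna_class}
        pairs, _, _ = find_homologs(seqs_a, seqs_b, CFG)
        assert len({p.id_a for p in pairs}) == len(pairs)
        assert len({p.id_b for p in pairs}) == len(pairs)

    def test_symmetry_of_direction(self):
        tx, truth = simulate_genome(6, 3, seed=5)
        tx_b = simulate_sister_species(tx, truth, 0.02, 0.5, seed=6)
        seqs_a = {t.id: t.sequence for t in tx if t.id in truth.lncrna_class}
        seqs_b = {t.id: t.sequence for t in tx_b if t.id in truth.lncrna_class}
        fwd, _, _ = find_homologs(seqs_a, seqs_b, CFG)
        rev, _, _ = find_homologs(seqs_b, seqs_a, CFG)
        assert {(p.id_a, p.id_b) for p in fwd} == {(p.id_b, p.id_a) for p in rev}

    def test_zero_divergence_identity_one(self):
        tx, truth = simulate_genome(4, 3, seed=9)
        tx_b = simulate_sister_species(tx, truth, 0.0, 1.0, seed=10)
        seqs_a = {t.id: t.sequence for t in tx if t.id in truth.lncrna_class}
        seqs_b = {t.id: t.sequence for t in tx_b if t.id in truth.lncrna_class}
        pairs, _, _ = find_homologs(seqs_a, seqs_b, CFG)
        planted = truth.homolog_map
        got = {p.id_a: p.id_b for p in pairs}
        assert got == planted
        assert all(p.identity == 1.0 for p in pairs)

    def test_recall_monotone_in_divergence(self):
        recalls = []
        for div in (0.0, 0.02, 0.1):
            tx, truth = simulate_genome(6, 4, seed=20)
            tx_b = simulate_sister_species(tx, truth, div, 0.5, seed=21)
            seqs_a = {t.id: t.sequence for t in tx if t.id in truth.lncrna_class}
            seqs_b = {t.id: t.sequence for t in tx_b if t.id in truth.lncrna_class}
            pairs, _, _ = find_homologs(seqs_a, seqs_b, CFG)
            got = {(p.id_a, p.id_b) for p in pairs}
            planted = set(truth.homolog_map.items())
            recalls.append(len(got & planted) / len(planted))
        assert recalls[0] >= recalls[1] >= recalls[2]


def _design(ids, values, tissues=("leaf", "phloem", "xylem", "root")):
    samples, cols = {}, {}
    for t in tissues:
        for s in (0, 300):
            for r in (1, 2):
                sid = f"{t}_{s}_{r}"
                samples[sid] = SampleMeta(t, s, r)
                cols[sid] = [values[i][t] for i in ids]
    return ExpressionMatrix(pd.DataFrame(cols, index=ids), samples)


class TestConcordance:
    def _matrices(self):
        prof_a = {"x": {"leaf": 1, "phloem": 2, "xylem": 3, "root": 4}}
        prof_same = {"y": {"leaf": 10, "phloem": 20, "xylem": 30, "root": 40}}
        prof_anti = {"y": {"leaf": 4, "phloem": 3, "xylem": 2, "root": 1}}
        return prof_a, prof_same, prof_anti

    def test_same_rank_order_similar(self):
        a, same, _ = self._matrices()
        ma = _design(["x"], a)
        mb = _design(["y"], same)
        (p,) = homolog_concordance([HomologPair("x", "y", 1.0, 0.0, 10)], ma, mb, CFG)
        assert p.rho == pytest.approx(1.0) and p.similar_pattern

    def test_reversed_ranks_not_similar(self):
        a, _, anti = self._matrices()
        (p,) = homolog_concordance(
            [HomologPair("x", "y", 1.0, 0.0, 10)], _design(["x"], a), _design(["y"], anti), CFG
        )
        assert p.rho == pytest.approx(-1.0) and not p.similar_pattern

    def test_tied_ranks_match_average_rank_oracle(self):
        a = {"x": {"leaf": 1, "phloem": 1, "xylem": 3, "root": 4}}
        b = {"y": {"leaf": 2, "phloem": 3, "xylem": 3, "root": 9}}
        (p,) = homolog_concordance(
            [HomologPair("x", "y", 1.0, 0.0, 10)], _design(["x"], a), _design(["y"], b), CFG
        )
        ra = stats.rankdata([1, 1, 3, 4])
        rb = stats.rankdata([2, 3, 3, 9])
        expected = np.corrcoef(ra, rb)[0, 1]
        assert p.rho == pytest.approx(expected, abs=1e-12)

    def test_constant_profile_warns_not_similar(self, caplog):
        a = {"x": {"leaf": 5, "phloem": 5, "xylem": 5, "root": 5}}
        b = {"y": {"leaf": 1, "phloem": 2, "xylem": 3, "root": 4}}
        with caplog.at_level("WARNING"):
            (p,) = homolog_concordance(
                [HomologPair("x", "y", 1.0, 0.0, 10)], _design(["x"], a), _design(["y"], b), CFG
            )
        assert p.rho is None and not p.similar_pattern

    def test_tissue_vocabulary_mismatch_rejected(self):
        a = {"x": {"leaf": 1, "phloem": 2, "xylem": 3, "root": 4}}
        ma = _design(["x"], a)
        mb = _design(["x"], {"x": {"shoot": 1, "stem": 2}}, tissues=("shoot", "stem"))
        with pytest.raises(ValidationError):
            homolog_concordance([HomologPair("x", "x", 1.0, 0.0, 1)], ma, mb, CFG)


class TestSpeciesSpecificDe:
    def _de(self, rows):
        return pd.DataFrame(
            [
                {"transcript_id": t, "tissue": tis, "salt_a": 0, "salt_b": 300,
                 "log2fc": 2.0, "p": 0.01, "p_adj_BH": 0.02, "is_de": f}
                for t, tis, f in rows
            ]
        )

    def test_unpaired_de_included(self):
        ids = {"a1", "a2", "a3"}
        pairs = [HomologPair("a1", "b1", 1.0, 0.0, 10)]
        de = self._de([("a1", "leaf", True), ("a2", "leaf", True), ("a3", "leaf", False)])
        result, per_tissue = species_specific_de(ids, pairs, de)
        assert result == {"a2"}
        assert per_tissue == {"leaf": 1}

    def test_no_de_empty(self):
        result, per_tissue = species_specific_de({"a1"}, [], self._de([("a1", "leaf", False)]))
        assert result == set() and per_tissue == {}

    def test_subset_of_unpaired(self):
        ids = {"a1", "a2"}
        pairs = [HomologPair("a1", "b1", 1.0, 0.0, 10)]
        de = self._de([("a1", "leaf", True), ("a2", "root", True)])
        result, _ = species_specific_de(ids, pairs, de)
        assert result <= (ids - {"a1"})


class TestHighExpressionPairs:
    def _mats(self, a_val, b_val):
        prof_a = {"x": {t: a_val for t in ("leaf", "phloem", "xylem", "root")}}
        prof_b = {"y": {t: b_val for t in ("leaf", "phloem", "xylem", "root")}}
        return _design(["x"], prof_a), _design(["y"], prof_b)

    def test_flagged_above_fc(self):
        ma, mb = self._mats(10.0, 2.0)
        (p,) = high_expression_pairs([HomologPair("x", "y", 1.0, 0.0, 1)], ma, mb, 4.0)
        assert set(p.high_in_a_tissues) == {"leaf", "phloem", "xylem", "root"}

    def test_boundary_strict(self):
        ma, mb = self._mats(8.0, 2.0)
        (p,) = high_expression_pairs([HomologPair("x", "y", 1.0, 0.0, 1)], ma, mb, 4.0)
        assert p.high_in_a_tissues == ()  # 8 == 4*2 is not >

    def test_zero_b_mean(self):
        ma, mb = self._mats(1.0, 0.0)
        (p,) = high_expression_pairs([HomologPair("x", "y", 1.0, 0.0, 1)], ma, mb, 4.0)
        assert len(p.high_in_a_tissues) == 4

    def test_fc_must_exceed_one(self):
        ma, mb = self._mats(1.0, 1.0)
        with pytest.raises(ValidationError):
            high_expression_pairs([], ma, mb, 1.0)

    def test_planted_pairs_recovered_at_4_not_6(self, config):
        # 5x-planted pairs: all flagged at fc 4, none at fc 6 (low noise)
        from lncsalt.simulate import (
            copy_expression_plan,
            plan_expression,
            simulate_expression,
        )

        tx, truth = simulate_genome(6, 4, seed=31)
        tx_b = simulate_sister_species(tx, truth, 0.0, 0.8, seed=32)
        plan_expression(truth, "A", 33)
        copy_expression_plan(truth, n_high_pairs=4, seed=34)
        plan_expression(truth, "B", 35)
        ids_a = [t.id for t in tx]
        ids_b = [t.id for t in tx_b]
        ma = simulate_expression(ids_a, truth, noise_sd=0.05, seed=36)
        mb = simulate_expression(ids_b, truth, noise_sd=0.05, seed=37)
        pairs = [
            HomologPair(a, b, 1.0, 0.0, 1) for a, b in sorted(truth.homolog_map.items())
        ]
        at4 = high_expression_pairs(pairs, ma, mb, 4.0)
        flagged4 = {p.id_a for p in at4 if p.high_in_a_tissues}
        assert flagged4 == set(truth.high_pair_ids)
        at6 = high_expression_pairs(pairs, ma, mb, 6.0)
        assert all(not p.high_in_a_tissues for p in at6)


def test_tissue_specific_homolog_patterns():
    tau_a = pd.DataFrame(
        [
            {"transcript_id": "a1", "tau": 0.95, "max_tissue": "leaf"},
            {"transcript_id": "a2", "tau": 0.95, "max_tissue": "root"},
            {"transcript_id": "a3", "tau": 0.5, "max_tissue": "leaf"},
        ]
    )
    tau_b = pd.DataFrame(
        [
            {"transcript_id": "b1", "tau": 0.99, "max_tissue": "leaf"},
            {"transcript_id": "b2", "tau": 0.99, "max_tissue": "xylem"},
            {"transcript_id": "b3", "tau": 0.99, "max_tissue": "leaf"},
        ]
    )
    pairs = [
        HomologPair("a1", "b1", 1.0, 0.0, 1),  # both specific, same tissue
        HomologPair("a2", "b2", 1.0, 0.0, 1),  # both specific, different tissue
        HomologPair("a3", "b3", 1.0, 0.0, 1),  # a3 not tissue-specific
    ]
    same, diff = tissue_specific_homolog_patterns(pairs, tau_a, tau_b, CFG)
    assert (same, diff) == (1, 1)
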