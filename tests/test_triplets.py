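"""Pearson statistics, pair selection and triplet assembly."""

import math

import numpy as np
import pytest

from cernet import (
    SyntheticSpec,
    ValidationError,
    build_triplets,
    pearson,
    score_cerna,
    select_lnc_mrna_pairs,
    simulate_dataset,
)
from cernet.containers import InteractionPair
from cernet.diffexpr import passing_ids, select_de

from conftest import expr_matrix


class TestPearson:
    def test_identity_and_anti_identity(self):
        x = [1.0, 4.0, 2.0, 7.0]
        res = pearson(x, x)
        assert res.r == 1.0 and res.p_value == 0.0 and res.n == 4
        res = pearson(x, [-v for v in x])
        assert res.r == -1.0 and res.p_value == 0.0

    def test_direct_formula_oracle(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 6])
        # oracle: covariance / (sigma_x sigma_y), p from the t transform
        xc, yc = x - x.mean(), y - y.mean()
        r_expected = (xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc))
        t = r_expected * math.sqrt(3 / (1 - r_expected**2))
        from scipy import stats

        p_expected = 2 * stats.t.sf(abs(t), df=3)
        res = pearson(x, y)
        assert res.r == pytest.approx(r_expected, abs=1e-12)
        assert res.p_value == pytest.approx(p_expected, abs=1e-12)

    def test_constant_vector_error_names_side(self):
        with pytest.raises(ValidationError, match="vector y"):
            pearson([1, 2, 3], [5, 5, 5])

    def test_needs_three_points(self):
        with pytest.raises(ValidationError, match="n >= 3"):
            pearson([1, 2], [3, 4])


class TestPairSelection:
    def test_proportional_pair_retained(self):
        lnc = expr_matrix({"l1": [1, 2, 3, 4]}, feature_class="lncRNA")
        mrna = expr_matrix({"g1": [2, 4, 6, 8]}, feature_class="mRNA")
        pairs = select_lnc_mrna_pairs(lnc, mrna)
        assert [(l, g) for l, g, _ in pairs] == [("l1", "g1")]
        assert pairs[0][2].r == pytest.approx(1.0)

    def test_r_0983_rejected_at_099(self):
        lnc = expr_matrix({"l1": [1, 2, 3, 4]}, feature_class="lncRNA")
        mrna = expr_matrix({"g1": [1, 2, 3, 5]}, feature_class="mRNA")
        assert select_lnc_mrna_pairs(lnc, mrna) == []
        kept = select_lnc_mrna_pairs(lnc, mrna, pcc_threshold=0.9)
        assert kept and kept[0][2].r == pytest.approx(0.98270763, abs=1e-6)

    def test_sample_mismatch_is_error(self):
        lnc = expr_matrix({"l1": [1, 2, 3, 4]}, feature_class="lncRNA")
        mrna = expr_matrix(
            {"g1": [1, 2, 3, 4]}, samples=["a", "b", "c", "d"],
            feature_class="mRNA",
        )
        with pytest.raises(ValidationError, match="sample-aligned"):
            select_lnc_mrna_pairs(lnc, mrna)

    def test_planted_zero_noise_pair_always_retained(self, zero_noise_dataset):
        ds = zero_noise_dataset
        pairs = select_lnc_mrna_pairs(ds.lncrna, ds.mrna)
        assert ("lnc-0001", "mrna-0001") in [(l, g) for l, g, _ in pairs]

    def test_sorted_by_descending_r(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=8)
        lnc = expr_matrix(
            {"l1": base, "l2": base + rng.normal(0, 0.01, 8)},
            feature_class="lncRNA",
        )
        mrna = expr_matrix(
            {"g1": base + rng.normal(0, 0.02, 8)}, feature_class="mRNA"
        )
        pairs = select_lnc_mrna_pairs(lnc, mrna, pcc_threshold=0.5)
        rs = [c.r for _, _, c in pairs]
        assert rs == sorted(rs, reverse=True)


class TestBuildTriplets:
    def _pipeline(self, ds, interactions=None, **kwargs):
        pairs = select_lnc_mrna_pairs(ds.lncrna, ds.mrna)
        return build_triplets(
            pairs,
            ds.interactions if interactions is None else interactions,
            ds.mirna,
            ds.lncrna,
            ds.mrna,
            **kwargs,
        )

    def test_zero_noise_triplet_recovered_exactly(self, zero_noise_dataset):
        trips = self._pipeline(zero_noise_dataset)
        assert [t.ids for t in trips] == [("lnc-0001", "mir-0001", "mrna-0001")]
        t = trips[0]
        assert t.lnc_mrna.r == pytest.approx(1.0)
        assert t.mir_lnc.r == pytest.approx(-1.0)
        assert t.mir_mrna.r == pytest.approx(-1.0)

    def test_interaction_support_is_required(self, zero_noise_dataset):
        ds = zero_noise_dataset
        pruned = [
            p for p in ds.interactions
            if p.key != ("mir-0001", "mrna-0001")
        ]
        assert self._pipeline(ds, interactions=pruned) == []

    def test_mirna_missing_from_matrix_is_skipped_with_warning(
        self, zero_noise_dataset, caplog
    ):
        ds = zero_noise_dataset
        extra = ds.interactions + [
            InteractionPair("mir-ghost", "lnc-0001", "lncRNA"),
            InteractionPair("mir-ghost", "mrna-0001", "mRNA"),
        ]
        import logging

        with caplog.at_level(logging.WARNING, logger="cernet.triplets"):
            trips = self._pipeline(ds, interactions=extra)
        assert [t.ids for t in trips] == [("lnc-0001", "mir-0001", "mrna-0001")]
        assert any("mir-ghost" in rec.message for rec in caplog.records)

    def test_pcc_threshold_monotonicity(self, benchmark_spec):
        ds = simulate_dataset(benchmark_spec(5))
        counts = []
        for pcc in (0.5, 0.9, 0.99, 0.999999):
            pairs = select_lnc_mrna_pairs(
                ds.lncrna, ds.mrna, pcc_threshold=pcc
            )
            counts.append(
                len(build_triplets(
                    pairs, ds.interactions, ds.mirna, ds.lncrna, ds.mrna
                ))
            )
        assert counts == sorted(counts, reverse=True)

    def test_invariant_to_sample_column_order(self, benchmark_spec):
        from dataclasses import replace

        ds = simulate_dataset(benchmark_spec(6))
        perm = np.random.default_rng(0).permutation(ds.lncrna.sample_ids)
        shuffled = {
            cls: replace(m, values=m.values[list(perm)])
            for cls, m in ds.matrices.items()
        }
        a = build_triplets(
            select_lnc_mrna_pairs(ds.lncrna, ds.mrna),
            ds.interactions, ds.mirna, ds.lncrna, ds.mrna,
        )
        b = build_triplets(
            select_lnc_mrna_pairs(shuffled["lncRNA"], shuffled["mRNA"]),
            ds.interactions, shuffled["miRNA"], shuffled["lncRNA"], shuffled["mRNA"],
        )
        assert [t.ids for t in a] == [t.ids for t in b]

    def test_de_restricted_pipeline_recovers_planted(self, benchmark_spec):
        ds = simulate_dataset(benchmark_spec(7))
        de = {cls: passing_ids(select_de(m)) for cls, m in ds.matrices.items()}
        pairs = select_lnc_mrna_pairs(
            ds.lncrna, ds.mrna, de_lnc=de["lncRNA"], de_mrna=de["mRNA"]
        )
        trips = build_triplets(
            pairs, ds.interactions, ds.mirna, ds.lncrna, ds.mrna,
            de_mirna=de["miRNA"],
        )
        assert {t.ids for t in trips} >= ds.true_triplet_ids


class TestScoreCerna:
    def test_exact_enumeration_oracle(self):
        from math import comb

        shared, p = score_cerna({"m1", "m2", "m3"}, {"m2", "m3", "m4"}, 11)
        assert shared == 2
        # oracle: sum_k C(3,k) C(8,3-k) / C(11,3) for k >= 2
        expected = sum(
            comb(3, k) * comb(8, 3 - k) for k in (2, 3)
        ) / comb(11, 3)
        assert p == pytest.approx(expected, abs=1e-12)
        assert p == pytest.approx(25 / 165, abs=1e-12)

    def test_disjoint_sets(self):
        shared, p = score_cerna({"a"}, {"b"}, 10)
        assert (shared, p) == (0, 1.0)

    def test_identical_sets_filling_universe(self):
        s = {f"m{i}" for i in range(4)}
        shared, p = score_cerna(s, s, 4)
        assert shared == 4 and p == pytest.approx(1.0)

    def test_set_exceeding_universe(self):
        with pytest.raises(ValidationError, match="universe"):
            score_cerna({"a", "b", "c"}, {"a"}, 2)
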