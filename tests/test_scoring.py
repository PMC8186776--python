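import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirstab.data_io import PercentileWindow, subtype_groups
from mirstab.params import DEFAULT_COMPONENT_PARAMS, PAIRED_FAMILIES, ComponentParams
from mirstab.scoring import (
    ComponentInstance,
    component_values_multigroup,
    component_values_two_group,
    overall_score,
    paired_log_fc,
    pooled_log_fc,
    score_genes,
    sigmoid_score,
)
from tests.conftest import make_cpm, make_meta
from tests.oracle import naive_sigmoid

SDP = DEFAULT_COMPONENT_PARAMS["S_DP"]


def _inst(score, w=1.0, ca=0.0):
    p = ComponentParams(iv=0.0, ip=1.0, cs=1.0, sq=1.0, ca=ca, w=w)
    return ComponentInstance("S_DP", "x", p, 0.0, score, w)


class TestSigmoid:
    def test_ideal_value_scores_100(self):
        assert sigmoid_score(0.05, SDP) == 100.0
        assert sigmoid_score(-1.0, SDP) == 100.0

    def test_inflection_point_scores_half(self):
        assert sigmoid_score(0.25, SDP) == pytest.approx(50.0)

    def test_closed_form_beyond_inflection(self):
        assert sigmoid_score(0.45, SDP) == pytest.approx(100.0 / (1 + 2**2.5))

    @pytest.mark.parametrize("family", sorted(DEFAULT_COMPONENT_PARAMS))
    def test_matches_naive_form_for_every_family(self, family):
        p = DEFAULT_COMPONENT_PARAMS[family]
        for x in np.linspace(p.iv - 1, p.ip + 5, 40):
            assert sigmoid_score(float(x), p) == pytest.approx(
                naive_sigmoid(float(x), p.iv, p.ip, p.cs, p.sq)
            )

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.sampled_from(sorted(DEFAULT_COMPONENT_PARAMS)),
        st.floats(-5, 50),
        st.floats(0.0, 10.0),
    )
    def test_monotone_nonincreasing(self, family, x, dx):
        p = DEFAULT_COMPONENT_PARAMS[family]
        assert sigmoid_score(x + dx, p) <= sigmoid_score(x, p) + 1e-12
        if x <= p.iv:
            assert sigmoid_score(x, p) == 100.0
        elif x > p.iv + 1e-3:  # float rounding returns 100.0 just past IV
            assert sigmoid_score(x, p) < 100.0


class TestOverallScore:
    def test_constant_components_identity(self):
        insts = [_inst(80.0, w) for w in (1.0, 2.0, 0.5)]
        assert overall_score(insts) == pytest.approx(80.0)

    def test_two_component_sqrt_product(self):
        assert overall_score([_inst(100.0), _inst(25.0)]) == pytest.approx(50.0)

    def test_constant_add_floors_zero_score(self):
        assert overall_score([_inst(0.0, ca=5.0)]) == pytest.approx(5.0)

    def test_weight_scale_free(self):
        a = [_inst(90.0, 1.0), _inst(40.0, 2.0)]
        b = [_inst(90.0, 10.0), _inst(40.0, 20.0)]
        assert overall_score(a) == pytest.approx(overall_score(b))

    def test_bounded_by_extremes_without_ca(self):
        insts = [_inst(s, w) for s, w in [(90, 1), (40, 2), (70, 0.3)]]
        got = overall_score(insts)
        assert 40 <= got <= 90

    def test_zero_factor_errors(self):
        with pytest.raises(ValueError, match="non-positive factor"):
            overall_score([_inst(0.0, ca=0.0)])


class TestFoldChanges:
    def test_identical_groups_zero(self):
        cpm = make_cpm([[100, 120, 100, 120]], ["a1", "a2", "b1", "b2"])
        assert pooled_log_fc(cpm, "g0", ["a1", "a2"], ["b1", "b2"]) == 0.0

    def test_doubling_is_one(self):
        cpm = make_cpm([[200, 200, 100, 100]], ["a1", "a2", "b1", "b2"])
        assert pooled_log_fc(cpm, "g0", ["a1", "a2"], ["b1", "b2"]) == pytest.approx(1.0)

    def test_antisymmetry(self):
        cpm = make_cpm([[250, 130, 80, 95]], ["a1", "a2", "b1", "b2"])
        ab = pooled_log_fc(cpm, "g0", ["a1", "a2"], ["b1", "b2"])
        ba = pooled_log_fc(cpm, "g0", ["b1", "b2"], ["a1", "a2"])
        assert ab == pytest.approx(-ba)

    def test_both_silent_groups_give_zero(self):
        cpm = make_cpm([[0, 0, 0, 0]], ["a1", "a2", "b1", "b2"])
        assert pooled_log_fc(cpm, "g0", ["a1", "a2"], ["b1", "b2"]) == 0.0

    def test_paired_examples(self):
        cpm = make_cpm([[8, 2, 4, 4]], ["t1", "n1", "t2", "n2"])
        got = paired_log_fc(cpm, "g0", [("t1", "n1"), ("t2", "n2")])
        np.testing.assert_allclose(got, [2.0, 0.0])

    def test_planted_pair_fold_changes_recovered(self, small_cpm):
        # paired log2FC of planted unstable genes should track the planted
        # tumor/normal shift within biological+count noise
        from mirstab.data_io import complete_pairs

        cpm, meta, truth = small_cpm
        pairs = complete_pairs(meta)
        subtype_of = meta[meta["tissue"] == "tumor"].set_index("sample_id")["subtype"]
        genes = truth.index[(truth["class"] == "unstable") & (truth["tn_log2fc"].abs() > 0.5)]
        err = []
        for g in list(genes)[:10]:
            lfc = paired_log_fc(cpm, g, pairs)
            # a tumor sample's planted shift is tn effect + its subtype effect
            planted = np.array(
                [
                    truth.loc[g, "tn_log2fc"]
                    + truth.loc[g, f"subtype_log2fc_{subtype_of[t]}"]
                    for t, _ in pairs
                ]
            )
            err.append(np.mean(lfc - planted))
        assert np.median(np.abs(err)) < 0.25


class TestTwoGroupComponents:
    def test_ideal_constant_gene_all_components_100(self):
        meta = make_meta(n_pairs=8, n_tumor_only=8)
        samples = list(meta["sample_id"])
        cpm = make_cpm(np.full((1, len(samples)), 50.0), samples)
        inst = component_values_two_group(cpm, "g0", meta)
        assert all(i.score == 100.0 for i in inst)
        assert overall_score(inst) == pytest.approx(100.0)
        # correlation slices are undefined on a constant vector: skipped
        assert not any(i.family in ("S_Cp", "S_Cr") for i in inst)

    def test_ea_inflection_at_5_cpm(self):
        meta = make_meta(n_pairs=4, n_tumor_only=4)
        samples = list(meta["sample_id"])
        cpm = make_cpm(np.full((1, len(samples)), 5.0), samples)
        inst = {i.family: i for i in component_values_two_group(cpm, "g0", meta)}
        assert inst["S_EA"].x == pytest.approx(1 / math.log2(5))
        assert inst["S_EA"].score == pytest.approx(50.0)

    def test_two_fold_pooled_shift_scores_closed_form(self):
        # 12 tumor samples at 200 CPM, their 12 paired normals at 100 CPM
        meta2 = make_meta(n_pairs=12, n_tumor_only=0)
        samples = list(meta2["sample_id"])
        vals = [200.0 if s.endswith("-T") else 100.0 for s in samples]
        cpm = make_cpm([vals], samples)
        inst = {i.family: i for i in component_values_two_group(cpm, "g0", meta2)}
        sdp = inst["S_DP"]
        assert sdp.x == pytest.approx(1.0)
        expect = 100.0 / (1 + 1.0 * ((1.0 - 0.05) / 0.2) ** 2.5)
        assert sdp.score == pytest.approx(expect)

    def test_instance_multiset_matches_published_counts(self, small_cpm):
        # 1 pooled FC, 4 paired, 2 of each per-tissue family, 1 S_EA,
        # 15 S_Cp and 15 S_Cr (complete-data gene)
        cpm, meta, truth = small_cpm
        gene = truth.index[truth["class"] == "stable"][0]
        inst = component_values_two_group(cpm, gene, meta)
        counts = pd.Series([i.family for i in inst]).value_counts().to_dict()
        assert counts["S_DP"] == 1
        for fam in PAIRED_FAMILIES:
            assert counts[fam] == 1
        for fam in ("S_EStD", "S_EoH", "S_EoL"):
            assert counts[fam] == 2
        assert counts["S_EA"] == 1
        assert counts["S_Cp"] <= 15 and counts["S_Cr"] <= 15


class TestMultigroup:
    def test_three_subgroups_give_three_pair_instances(self, small_cpm):
        cpm, meta, truth = small_cpm
        groups = subtype_groups(meta)
        gene = truth.index[0]
        inst = component_values_multigroup(cpm, gene, groups, meta)
        sdp = [i for i in inst if i.family == "S_DP"]
        assert len(sdp) == 3
        assert all(i.weight == pytest.approx(4 / 3) for i in sdp)
        assert not any(i.family in PAIRED_FAMILIES for i in inst)

    def test_weight_conservation_per_family(self, small_cpm):
        cpm, meta, truth = small_cpm
        groups = subtype_groups(meta)
        inst = component_values_multigroup(cpm, truth.index[0], groups, meta)
        by_fam = {}
        for i in inst:
            by_fam.setdefault(i.family, 0.0)
            by_fam[i.family] += i.weight
        assert by_fam["S_DP"] == pytest.approx(4.0)
        assert by_fam["S_EStD"] == pytest.approx(1.5)
        assert by_fam["S_EoH"] == pytest.approx(0.75)
        assert by_fam["S_EoL"] == pytest.approx(0.75)
        assert by_fam["S_EA"] == pytest.approx(6.0)

    def test_identical_subgroup_distribution_scores_100(self):
        meta = make_meta(n_pairs=0, n_tumor_only=30, subtypes=("A", "B", "C"))
        samples = list(meta["sample_id"])
        cpm = make_cpm(np.full((1, len(samples)), 400.0), samples)
        groups = subtype_groups(meta)
        inst = component_values_multigroup(cpm, "g0", groups, meta)
        sdp = [i for i in inst if i.family == "S_DP"]
        assert all(i.score == 100.0 for i in sdp)


class TestScoreGenes:
    def test_sample_permutation_invariance(self, small_cpm):
        cpm, meta, truth = small_cpm
        genes = list(truth.index[:20])
        st1 = score_genes(cpm, meta, genes=genes)
        rng = np.random.default_rng(3)
        perm = rng.permutation(cpm.cpm.columns)
        cpm2 = make_cpm(cpm.cpm[perm].to_numpy(), list(perm), gene_ids=cpm.gene_ids)
        meta2 = meta.sample(frac=1, random_state=5).reset_index(drop=True)
        st2 = score_genes(cpm2, meta2, genes=genes)
        pd.testing.assert_series_equal(st1.table["S_exp"], st2.table["S_exp"])

    def test_single_gene_gets_rank_one(self, small_cpm):
        cpm, meta, truth = small_cpm
        st1 = score_genes(cpm, meta, genes=[truth.index[0]])
        assert list(st1.table["rank"]) == [1]

    def test_scores_reproducible_from_instances(self, small_cpm):
        cpm, meta, truth = small_cpm
        genes = list(truth.index[:5])
        st1 = score_genes(cpm, meta, genes=genes)
        for g in genes:
            assert st1.table.loc[g, "S_exp"] == pytest.approx(
                overall_score(st1.instances[g])
            )
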