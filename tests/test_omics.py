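"""Stage effects, monotonic calling, scores, ssGSEA, enrichment, concordance."""

import numpy as np
import pandas as pd
import pytest

from fieldmap import omics as om
from fieldmap.io_formats import FieldMap, GROUPS, OmicsMatrix
from fieldmap.synthetic_organ import generate_organ, plant_histology

from conftest import small_config


@pytest.fixture(scope="module")
def fmap():
    # 24 fields: 2 UC, 10 HGIN ring, 12 NU/LGIN
    return plant_histology(4, 6, 1, 2, 1, n_lgin=2)


def _matrix(values: np.ndarray, field_map: FieldMap, n_ctrl=3, analytes=None):
    ctrl_ids = [f"CTRL{i+1}" for i in range(n_ctrl)]
    cols = field_map.field_ids + ctrl_ids
    idx = analytes or [f"A{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=pd.Index(idx, name="analyte_id"), columns=cols)
    return OmicsMatrix(df, tuple(ctrl_ids))


class TestStageEffects:
    def test_flat_analyte_zero_effect_p_one(self, fmap):
        n = fmap.n_fields + 3
        m = _matrix(np.full((3, n), 5.0), fmap)
        eff = om.stage_effects(m, fmap)
        for g in GROUPS:
            assert (eff[f"effect_{g}"] == 0).all()
            assert (eff[f"q_{g}"] == 1.0).all()

    def test_noiseless_shift_recovered_exactly(self, fmap):
        n = fmap.n_fields
        vals = np.full((2, n + 3), 1.0)
        vals[0, :n] = 3.0  # +2 in every map sample
        m = _matrix(vals, fmap)
        eff = om.stage_effects(m, fmap)
        for g in GROUPS:
            assert eff.loc["A0", f"effect_{g}"] == pytest.approx(2.0)
        assert eff.loc["A1", f"effect_UC"] == 0.0

    def test_missing_group_reported(self):
        fm = plant_histology(2, 2, 0, 0, 0, n_lgin=0)  # all NU
        vals = np.random.default_rng(0).normal(size=(3, 4 + 3))
        m = _matrix(vals, fm)
        with pytest.raises(ValueError, match="UC"):
            om.stage_effects(m, fm)

    def test_exact_p_floor_matches_combinatorics(self, fmap):
        # perfectly separated, tie-free analyte: p = 2 / C(n_uc + 3, 3)
        n = fmap.n_fields
        uc = [i for i, g in enumerate(fmap.group_of()) if g == "UC"]
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 0.1, size=(1, n + 3))  # distinct low values
        vals[0, uc] = [10.0 + k for k in range(len(uc))]
        m = _matrix(vals, fmap)
        eff = om.stage_effects(m, fmap)
        from math import comb

        expected = 2 / comb(len(uc) + 3, 3)
        assert eff.loc["A0", "p_UC"] == pytest.approx(expected, abs=1e-12)

    def test_pairwise_deletion_missing_values(self, fmap):
        n = fmap.n_fields
        rng = np.random.default_rng(1)
        vals = rng.normal(5, 0.1, size=(4, n + 3))
        vals[0, 0] = np.nan
        vals[1, n] = np.nan  # a control missing
        m = _matrix(vals, fmap)
        eff = om.stage_effects(m, fmap)
        assert np.isfinite(eff[[f"p_{g}" for g in GROUPS]].to_numpy()).all()

    def test_low_coverage_flagged_not_dropped(self, fmap):
        n = fmap.n_fields
        vals = np.random.default_rng(2).normal(size=(2, n + 3))
        vals[0, : (n + 3) * 3 // 4] = np.nan
        m = _matrix(vals, fmap)
        eff = om.stage_effects(m, fmap)
        assert bool(eff.loc["A0", "low_coverage"])
        assert "A0" in eff.index


def _effects_frame(rows: dict) -> pd.DataFrame:
    cols = {}
    for g_i, g in enumerate(GROUPS):
        cols[f"effect_{g}"] = [v[0][g_i] for v in rows.values()]
        cols[f"q_{g}"] = [v[1][g_i] for v in rows.values()]
    return pd.DataFrame(cols, index=list(rows))


class TestCallMonotonic:
    def test_strictly_increasing_wave1(self):
        eff = _effects_frame({"a": ((1, 2, 3), (0.01, 0.01, 0.01))})
        call = om.call_monotonic(eff)
        assert bool(call.loc["a", "monotone"])
        assert call.loc["a", "direction"] == "up"
        assert call.loc["a", "wave"] == 1

    def test_non_monotone_dip_rejected(self):
        eff = _effects_frame({"a": ((1, 2, 1.5), (0.01, 0.01, 0.01))})
        call = om.call_monotonic(eff, tau=0.0)
        assert not bool(call.loc["a", "monotone"])

    def test_wave2_down(self):
        eff = _effects_frame({"a": ((0.1, -2, -3), (0.8, 0.01, 0.01))})
        call = om.call_monotonic(eff)
        assert bool(call.loc["a", "monotone"])
        assert call.loc["a", "direction"] == "down"
        assert call.loc["a", "wave"] == 2

    def test_insignificant_uc_not_called(self):
        eff = _effects_frame({"a": ((1, 2, 3), (0.01, 0.01, 0.5))})
        assert not bool(om.call_monotonic(eff).loc["a", "monotone"])

    def test_tau_tolerance_allows_small_dip(self):
        eff = _effects_frame({"a": ((1, 2, 1.9), (0.01, 0.01, 0.01))})
        assert not bool(om.call_monotonic(eff, tau=0.0).loc["a", "monotone"])
        assert bool(om.call_monotonic(eff, tau=0.2).loc["a", "monotone"])

    def test_idempotent_and_order_invariant(self):
        rows = {
            f"x{i}": ((i * 0.1, i * 0.2, i * 0.3), (0.01, 0.2, 0.01))
            for i in range(1, 8)
        }
        eff = _effects_frame(rows)
        c1 = om.call_monotonic(eff)
        c2 = om.call_monotonic(c1)  # idempotent on its own output
        pd.testing.assert_frame_equal(
            c1[["monotone", "direction", "wave"]],
            c2[["monotone", "direction", "wave"]],
        )
        shuffled = eff.sample(frac=1, random_state=0)
        c3 = om.call_monotonic(shuffled)
        pd.testing.assert_frame_equal(
            c1.sort_index()[["monotone", "direction", "wave"]],
            c3.sort_index()[["monotone", "direction", "wave"]],
        )


class TestSignatureScore:
    def test_control_equal_sample_scores_zero(self, fmap):
        n = fmap.n_fields
        rng = np.random.default_rng(0)
        base = rng.normal(5, 1, size=(4, 1))
        ctrl = base + rng.normal(0, 0.3, size=(4, 3))
        samp = np.repeat(ctrl.mean(axis=1, keepdims=True), n, axis=1)
        m = _matrix(np.concatenate([samp, ctrl], axis=1), fmap,
                    analytes=["g1", "g2", "g3", "g4"])
        s = om.signature_score(m, ["g1", "g2"], ["g3"])
        np.testing.assert_allclose(s[fmap.field_ids].to_numpy(), 0, atol=1e-12)

    def test_one_sd_shift_scores_one(self, fmap):
        n = fmap.n_fields
        ctrl = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        sd = ctrl.std(axis=1, ddof=1)
        samp = np.repeat((ctrl.mean(axis=1) + sd)[:, None], n, axis=1)
        m = _matrix(np.concatenate([samp, ctrl], axis=1), fmap,
                    analytes=["u1", "u2"])
        s = om.signature_score(m, ["u1", "u2"])
        np.testing.assert_allclose(s[fmap.field_ids].to_numpy(), 1.0, atol=1e-12)

    def test_absent_members_rejected(self, fmap):
        m = _matrix(np.ones((2, fmap.n_fields + 3)), fmap)
        with pytest.raises(ValueError, match="present"):
            om.signature_score(m, ["nope"], ["also_nope"])

    def test_energy_score_declines_with_stage(self):
        org = generate_organ(small_config(), seed=4)
        st = om.score_table(org.omics["protein"])
        g = org.field_map.group_of()
        means = st.join(g, how="inner").groupby("group")["energy"].mean()
        assert means["NU_LGIN"] > means["HGIN"] > means["UC"]


class TestSsgsea:
    def _vec(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        return pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])

    def test_top_set_positive_bottom_negative(self):
        v = self._vec()
        top = list(v.sort_values(ascending=False).index[:20])
        bottom = list(v.sort_values().index[:20])
        assert om.ssgsea_es(v, top) > 0.5
        assert om.ssgsea_es(v, bottom) < -0.5

    def test_null_mean_near_zero(self):
        rng = np.random.default_rng(3)
        es = []
        for i in range(1000):
            v = pd.Series(rng.normal(size=100), index=[f"g{j}" for j in range(100)])
            members = rng.choice(v.index, size=15, replace=False)
            es.append(om.ssgsea_es(v, members))
        assert abs(np.mean(es)) < 0.02

    def test_monotone_transform_invariance(self):
        v = self._vec(seed=5)
        members = [f"g{i}" for i in range(0, 60, 3)]
        a = om.ssgsea_es(v, members)
        b = om.ssgsea_es(np.exp(v * 2) + 7, members)
        assert a == pytest.approx(b, abs=1e-12)

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="intersect"):
            om.ssgsea_es(self._vec(), ["zzz"])

    def test_bounded_in_unit_interval(self):
        v = self._vec(seed=6)
        for k in (5, 50, 150):
            es = om.ssgsea_es(v, list(v.index[:k]))
            assert -1.0 <= es <= 1.0


def _hypergeom_tail_oracle(k, M, K, n):
    from math import comb

    return sum(
        comb(K, x) * comb(M - K, n - x) for x in range(k, min(K, n) + 1)
    ) / comb(M, n)


class TestEnrichment:
    def test_full_overlap_closed_form(self):
        from math import comb

        uni = [f"g{i}" for i in range(100)]
        hits = uni[:10]
        res = om.pathway_enrichment(hits, uni, {"S": uni[:10]})
        assert res.loc["S", "p"] == pytest.approx(1 / comb(100, 10), rel=1e-9)

    def test_disjoint_set_p_one(self):
        uni = [f"g{i}" for i in range(50)]
        res = om.pathway_enrichment(uni[:5], uni, {"S": uni[40:]})
        assert res.loc["S", "p"] == pytest.approx(1.0)

    def test_matches_bruteforce_tail(self):
        rng = np.random.default_rng(7)
        uni = [f"g{i}" for i in range(1000)]
        hits = list(rng.choice(uni, size=20, replace=False))
        members = list(rng.choice(uni, size=50, replace=False))
        res = om.pathway_enrichment(hits, uni, {"S": members})
        k = len(set(hits) & set(members))
        assert res.loc["S", "p"] == pytest.approx(
            _hypergeom_tail_oracle(k, 1000, 50, 20), abs=1e-12
        )

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            om.pathway_enrichment(["x"], ["a", "b"], {"S": ["a"]})


class TestConcordance:
    def _call_frame(self, spec: dict) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "monotone": [v is not None for v in spec.values()],
                "direction": [v or "none" for v in spec.values()],
                "wave": [1 if v else 0 for v in spec.values()],
            },
            index=list(spec),
        )

    def test_identical_calls_full_intersection(self):
        calls = self._call_frame({"a": "up", "b": "down", "c": None})
        out = om.rna_protein_concordance(calls, calls.copy())
        assert sorted(out.index) == ["a", "b"]

    def test_opposite_directions_empty(self):
        r = self._call_frame({"a": "up"})
        p = self._call_frame({"a": "down"})
        assert len(om.rna_protein_concordance(r, p)) == 0

    def test_no_shared_ids_rejected(self):
        r = self._call_frame({"a": "up"})
        p = self._call_frame({"b": "up"})
        p.index = ["b"]
        with pytest.raises(ValueError, match="shared"):
            om.rna_protein_concordance(r, p)

    def test_planted_concordant_set_recovered_noiseless(self):
        from dataclasses import replace

        cfg = small_config(noise_sigma=0.0, concordant_proteins=50)
        cfg = replace(
            cfg,
            rna=replace(cfg.rna, n_analytes=200, n_up=40, n_down=60),
            protein=replace(cfg.protein, missing_fraction=0.0),
        )
        org = generate_organ(cfg, seed=9)
        calls = {}
        for plat in ("rna", "protein"):
            eff = om.stage_effects(org.omics[plat], org.field_map)
            calls[plat] = om.call_monotonic(eff)
        out = om.rna_protein_concordance(calls["rna"], calls["protein"])
        assert len(out) == 50
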