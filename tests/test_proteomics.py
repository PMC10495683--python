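"""Top-3 rollup, global normalization, differential filtering and the
localization summary, each checked against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from simplemux.proteomics import (
    ProteinQuantMatrix,
    differential_expression,
    global_normalize,
    localization_summary,
    rollup_top3,
)


from oracles import brute_force_rollup, random_precursor_table


def _table(records):
    return pd.DataFrame(records, columns=["protein", "peptide", "precursor",
                                          "sample", "intensity"])


class TestRollup:
    def test_top3_precursor_sum(self):
        tbl = _table([("P1", "pepA", f"z{i}", "s1", v) for i, v in enumerate([40, 30, 20, 10])]
                     + [("P1", "pepB", "z0", "s1", 7.0)])
        m = rollup_top3(tbl)
        # pepA contributes 40+30+20=90, pepB contributes 7; protein = mean
        assert m.peptide_quantities.loc[("P1", "pepA"), "s1"] == 90.0
        assert m.quantities.loc["P1", "s1"] == pytest.approx((90 + 7) / 2)

    def test_single_hit_protein_excluded(self):
        tbl = _table([("P1", "pepA", "z1", "s1", 100.0),
                      ("P1", "pepA", "z2", "s1", 50.0),
                      ("P2", "pepB", "z1", "s1", 10.0),
                      ("P2", "pepC", "z1", "s1", 20.0)])
        m = rollup_top3(tbl)
        assert list(m.quantities.index) == ["P2"]

    def test_max_ten_peptides_cap(self, rng):
        rows = []
        for j in range(12):
            # cross-sample mean rank j: intensity grows with j
            rows.append(("P1", f"pep{j:02d}", "z1", "s1", float(100 + 10 * j)))
            rows.append(("P1", f"pep{j:02d}", "z1", "s2", float(110 + 10 * j)))
        m = rollup_top3(_table(rows))
        assert m.n_peptides["P1"] == 10
        oracle = brute_force_rollup(_table(rows))
        assert m.quantities.loc["P1", "s1"] == pytest.approx(oracle["P1"]["s1"])
        # the two lowest-mean peptides (pep00, pep01) must not contribute
        assert m.quantities.loc["P1", "s1"] == pytest.approx(np.mean([100 + 10 * j for j in range(2, 12)]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        tbl = random_precursor_table(np.random.default_rng(seed))
        m = rollup_top3(tbl)
        oracle = brute_force_rollup(tbl)
        assert set(m.quantities.index) == set(oracle)
        for protein, row in oracle.items():
            assert m.n_peptides[protein] == row["__n"]
            for s in m.quantities.columns:
                got = m.quantities.loc[protein, s]
                want = row[s]
                if np.isnan(want):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(want, rel=1e-12)

    def test_empty_table_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            m = rollup_top3(_table([]))
        assert m.quantities.empty

    def test_duplicate_records_rejected(self):
        tbl = _table([("P1", "pepA", "z1", "s1", 1.0), ("P1", "pepA", "z1", "s1", 2.0)])
        with pytest.raises(ValueError, match="duplicate"):
            rollup_top3(tbl)

    def test_idempotent_on_own_peptide_output(self, rng):
        tbl = random_precursor_table(rng)
        m = rollup_top3(tbl)
        pep = m.peptide_quantities.stack().rename("intensity").reset_index()
        pep["precursor"] = pep["peptide"] + "_only"
        m2 = rollup_top3(pep)
        pd.testing.assert_frame_equal(
            m.quantities.sort_index(), m2.quantities.sort_index(),
            check_like=True,
        )


class TestGlobalNormalize:
    def _matrix(self, arr, samples=None):
        samples = samples or [f"s{i}" for i in range(arr.shape[1])]
        q = pd.DataFrame(arr, columns=samples,
                         index=[f"P{i}" for i in range(arr.shape[0])])
        return ProteinQuantMatrix(q, pd.Series(2, index=q.index))

    def test_fixed_point(self, rng):
        col = rng.lognormal(10, 1, 50)
        m = self._matrix(np.column_stack([col, col, col]))
        out = global_normalize(m)
        assert np.allclose(out.quantities.to_numpy(), m.quantities.to_numpy(), rtol=1e-12)

    def test_restores_scaled_sample(self, rng):
        # scaling one sample by 4 is exactly undone: the normalized matrix
        # is identical to the normalized unscaled matrix
        base = rng.lognormal(10, 1, (100, 4))
        scaled = base.copy()
        scaled[:, 2] *= 4.0
        out_base = global_normalize(self._matrix(base))
        out_scaled = global_normalize(self._matrix(scaled))
        # up to one global factor (the grand median target itself moved)
        ratio = out_scaled.quantities.to_numpy() / out_base.quantities.to_numpy()
        assert np.allclose(ratio, ratio.flat[0], rtol=1e-12)
        # and the scaled sample's quantities sit back in line with the others
        med = np.log2(out_scaled.quantities).median(axis=0)
        assert np.ptp(med.to_numpy()) < 1e-9

    def test_equalizes_log2_medians(self, rng):
        arr = rng.lognormal(8, 2, (200, 6))
        arr[rng.random(arr.shape) < 0.1] = np.nan
        out = global_normalize(self._matrix(arr))
        med = np.log2(out.quantities).median(axis=0, skipna=True)
        assert np.ptp(med.to_numpy()) < 1e-9

    def test_missing_untouched(self, rng):
        arr = rng.lognormal(8, 1, (30, 3))
        arr[0, 0] = np.nan
        out = global_normalize(self._matrix(arr))
        assert np.isnan(out.quantities.iloc[0, 0])

    def test_all_missing_sample_named_in_error(self):
        arr = np.full((5, 2), 10.0)
        arr[:, 1] = np.nan
        with pytest.raises(ValueError, match="s1"):
            global_normalize(self._matrix(arr))


def _quant(arr, groups, n_pep=3):
    samples = [f"{g}{i}" for i, g in enumerate(groups)]
    q = pd.DataFrame(arr, columns=samples, index=[f"P{i}" for i in range(len(arr))])
    return ProteinQuantMatrix(q, pd.Series(n_pep, index=q.index),
                              groups=pd.Series(groups, index=samples))


class TestDifferentialExpression:
    def test_identical_groups_null(self):
        vals = np.array([[100.0, 120, 110, 100, 120, 110]])
        m = _quant(vals, ["A", "A", "A", "B", "B", "B"])
        res = differential_expression(m, "A", "B")
        assert res["log2_fc"].iloc[0] == pytest.approx(0.0)
        assert not res["significant"].iloc[0]
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_fourfold_change(self, rng):
        a = 400.0 * (1 + rng.normal(0, 1e-4, 5))
        b = 100.0 * (1 + rng.normal(0, 1e-4, 5))
        m = _quant(np.concatenate([a, b])[None, :], ["A"] * 5 + ["B"] * 5)
        res = differential_expression(m, "A", "B")
        assert res["log2_fc"].iloc[0] == pytest.approx(2.0, abs=1e-3)
        assert res["significant"].iloc[0]

    def test_antisymmetry_under_group_swap(self, rng):
        arr = rng.lognormal(8, 1, (50, 10))
        groups = ["A"] * 5 + ["B"] * 5
        m = _quant(arr, groups)
        ab = differential_expression(m, "A", "B")
        ba = differential_expression(m, "B", "A")
        assert np.allclose(ab["log2_fc"], -ba["log2_fc"], atol=1e-12)
        assert np.allclose(ab["p_value"], ba["p_value"], atol=1e-12)

    def test_scale_invariance_after_normalization(self, rng):
        arr = rng.lognormal(8, 1, (80, 10))
        groups = ["A"] * 5 + ["B"] * 5
        res1 = differential_expression(global_normalize(_quant(arr, groups)), "A", "B")
        scaled = arr.copy()
        scaled[:, 3] *= 37.5
        res2 = differential_expression(global_normalize(_quant(scaled, groups)), "A", "B")
        assert np.allclose(res1["log2_fc"], res2["log2_fc"], atol=1e-9)
        assert np.allclose(res1["p_value"], res2["p_value"], atol=1e-9)

    def test_insufficient_observations_reported_untested(self, rng):
        arr = rng.lognormal(8, 1, (2, 10))
        arr[1, :4] = np.nan  # one observed value left in group A
        m = _quant(arr, ["A"] * 5 + ["B"] * 5)
        res = differential_expression(m, "A", "B")
        assert res["tested"].tolist() == [True, False]
        assert np.isnan(res["p_value"].iloc[1])
        assert not res["significant"].iloc[1]

    def test_fdr_is_bh_step_up(self, rng):
        arr = rng.lognormal(8, 1, (60, 10))
        m = _quant(arr, ["A"] * 5 + ["B"] * 5)
        res = differential_expression(m, "A", "B").dropna(subset=["p_value"])
        p = res["p_value"].to_numpy()
        # independent BH recomputation
        order = np.argsort(p)
        n = len(p)
        adj = p[order] * n / np.arange(1, n + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        expected = np.empty(n)
        expected[order] = np.minimum(adj, 1.0)
        assert np.allclose(res["fdr"].to_numpy(), expected, atol=1e-12)

    def test_unknown_group_rejected(self, rng):
        m = _quant(rng.lognormal(8, 1, (5, 10)), ["A"] * 5 + ["B"] * 5)
        with pytest.raises(ValueError, match="unknown group"):
            differential_expression(m, "A", "C")


class TestLocalizationSummary:
    def test_hand_counted_example(self):
        loc = {"p1": {"nuclear"}, "p2": {"nuclear", "cytosol"},
               "p3": {"cytosol", "plasma_membrane"}, "p4": set()}
        out = localization_summary(["p1", "p2", "p3", "p4"], loc)
        assert out["nuclear"] == 50.0
        assert out["cytosol"] == 50.0
        assert out["plasma_membrane"] == 25.0
        assert out["extracellular_matrix"] == 0.0
        assert out["multi_local_percent"] == 50.0

    def test_empty_input(self):
        out = localization_summary([], {})
        assert all(out[c] == 0.0 for c in
                   ("nuclear", "cytosol", "plasma_membrane", "extracellular_matrix"))
        assert out["multi_local_percent"] == 0.0

    def test_unannotated_counted_separately(self):
        out = localization_summary(["p1", "p2"], {"p1": {"nuclear"}})
        assert out["n_unannotated"] == 1
        assert out["nuclear"] == 50.0

    def test_matches_set_counting_oracle(self, rng):
        cats = ("nuclear", "cytosol", "plasma_membrane", "extracellular_matrix")
        proteins = [f"p{i}" for i in range(500)]
        loc = {}
        for p in proteins:
            if rng.random() < 0.9:
                loc[p] = {c for c in cats if rng.random() < 0.4}
        out = localization_summary(proteins, loc)
        for c in cats:
            want = 100.0 * sum(1 for p in proteins if c in loc.get(p, set())) / len(proteins)
            assert out[c] == pytest.approx(want)
        want_multi = 100.0 * sum(1 for p in proteins if len(loc.get(p, set())) >= 2) / len(proteins)
        assert out["multi_local_percent"] == pytest.approx(want_multi)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="unknown categories"):
            localization_summary(["p1"], {"p1": {"mitochondrial"}})
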