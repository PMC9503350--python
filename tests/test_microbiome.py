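import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adipoquant import (
    AbundanceTable,
    bh_fdr,
    prevalence_filter,
    spearman_assoc,
    tss_normalize,
)
from adipoquant.microbiome import _spearman_exact_p


def brute_force_bh(p):
    """Literal step-up definition: q_i = min over {j : p_j >= p_i} of m*p_j/rank_j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    ranks = np.array([(p <= pj).sum() for pj in p])
    q = np.empty(m)
    for i in range(m):
        candidates = [m * p[j] / ranks[j] for j in range(m) if p[j] >= p[i]]
        q[i] = min(1.0, min(candidates))
    return q


class TestTssNormalize:
    def test_equal_counts_split_evenly(self):
        df = pd.DataFrame({"a": [2.0], "b": [2.0]})
        out = tss_normalize(df, "caecum", "genus")
        assert np.allclose(out.data.to_numpy(), [[0.5, 0.5]])

    def test_proportions(self):
        df = pd.DataFrame({"a": [1.0], "b": [3.0], "c": [6.0]})
        out = tss_normalize(df, "caecum", "genus")
        assert np.allclose(out.data.to_numpy(), [[0.1, 0.3, 0.6]])

    def test_idempotent(self):
        df = pd.DataFrame({"a": [0.25, 0.4], "b": [0.75, 0.6]})
        once = tss_normalize(df, "caecum", "genus")
        twice = tss_normalize(once)
        assert np.allclose(once.data.to_numpy(), twice.data.to_numpy())

    def test_all_zero_sample_named_in_error(self):
        df = pd.DataFrame({"a": [1.0, 0.0], "b": [1.0, 0.0]}, index=["s1", "s2"])
        with pytest.raises(ValueError, match="s2"):
            tss_normalize(df, "caecum", "genus")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.lists(st.floats(min_value=0.01, max_value=100.0), min_size=3, max_size=3),
            min_size=1,
            max_size=6,
        )
    )
    def test_rows_always_sum_to_one(self, rows):
        df = pd.DataFrame(rows, columns=["a", "b", "c"])
        out = tss_normalize(df, "caecum", "genus")
        assert np.allclose(out.data.sum(axis=1), 1.0)


class TestAbundanceTable:
    def test_duplicate_features_rejected(self):
        df = pd.DataFrame([[0.5, 0.5]], columns=["a", "a"])
        with pytest.raises(ValueError, match="duplicate"):
            AbundanceTable("caecum", "genus", df)

    def test_unnormalized_rows_rejected(self):
        df = pd.DataFrame({"a": [0.5], "b": [0.7]})
        with pytest.raises(ValueError, match="sum"):
            AbundanceTable("caecum", "genus", df)

    def test_tsv_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {"a": [0.25, 0.5], "b": [0.75, 0.5]},
            index=pd.Index(["m1", "m2"], name="animal_id"),
        )
        table = AbundanceTable("caecum", "genus", df)
        path = tmp_path / "t.tsv"
        table.to_tsv(path)
        loaded = AbundanceTable.from_tsv(path, "caecum", "genus")
        assert np.allclose(loaded.data.to_numpy(), df.to_numpy())


class TestPrevalenceFilter:
    def _table(self):
        rng = np.random.default_rng(0)
        data = rng.random((10, 3))
        data[:9, 2] = 0.0  # rare feature: present in 1/10 samples
        df = pd.DataFrame(data, columns=["common", "mid", "rare"])
        return tss_normalize(df, "caecum", "genus")

    def test_zero_thresholds_identity(self):
        table = self._table()
        out = prevalence_filter(table, 0.0, 0.0)
        assert list(out.features) == list(table.features)
        assert np.allclose(out.data.to_numpy(), table.data.to_numpy())

    def test_low_prevalence_feature_removed(self):
        out = prevalence_filter(self._table(), min_prevalence=0.2, min_mean_abund=0.0)
        assert "rare" not in out.features
        assert {"common", "mid"} <= set(out.features)

    def test_kept_values_unchanged(self):
        table = self._table()
        out = prevalence_filter(table, 0.2, 1e-4)
        assert np.allclose(out.data["common"], table.data["common"])

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            prevalence_filter(self._table(), min_prevalence=1.5)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.05])[0] == pytest.approx(0.05)

    def test_evenly_spaced_collapse(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_all_ones_stay_one(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, np.nan])

    def test_matches_brute_force_step_up_on_random_vectors(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=25)
    )
    def test_q_at_least_p_and_monotone(self, p):
        q = bh_fdr(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestSpearmanAssoc:
    def _table(self, values: dict, ids):
        df = pd.DataFrame(values, index=pd.Index(ids, name="animal_id"))
        return AbundanceTable("caecum", "genus", df.div(df.sum(axis=1), axis=0))

    def test_monotone_pairs_hit_plus_minus_one(self):
        ids = [f"m{i}" for i in range(8)]
        x = np.arange(8, dtype=float)
        table = self._table({"up": 1 + x, "down": 100 - x}, ids)
        imaging = pd.DataFrame({"param": x}, index=ids)
        res = spearman_assoc(table, imaging).set_index("feature")
        assert res.loc["up", "rho"] == pytest.approx(1.0)
        assert res.loc["down", "rho"] == pytest.approx(-1.0)

    def test_exact_permutation_p_for_monotone_small_n(self):
        # n=5 distinct values: only identity and reversal reach |rho| = 1
        x = np.arange(5, dtype=float)
        p = _spearman_exact_p(x, 2 * x + 1, 1.0)
        assert p == pytest.approx(2 / 120)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.sampled_from(["exp", "cube", "affine"]))
    def test_rho_invariant_under_monotone_transforms(self, kind):
        rng = np.random.default_rng(5)
        ids = [f"m{i}" for i in range(12)]
        base = rng.random(12)
        transform = {
            "exp": np.exp(base),
            "cube": base**3,
            "affine": 3 * base + 1,
        }[kind]
        imaging = pd.DataFrame({"param": rng.random(12)}, index=ids)
        t1 = self._table({"f": base, "pad": np.full(12, 5.0)}, ids)
        t2 = self._table({"f": transform, "pad": np.full(12, 5.0)}, ids)
        r1 = spearman_assoc(t1, imaging).set_index("feature").loc["f", "rho"]
        r2 = spearman_assoc(t2, imaging).set_index("feature").loc["f", "rho"]
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_mean_abundance_reported_in_percent(self):
        ids = [f"m{i}" for i in range(6)]
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        table = self._table({"a": a, "b": 10.0 - a}, ids)
        imaging = pd.DataFrame({"param": np.arange(6.0)}, index=ids)
        res = spearman_assoc(table, imaging).set_index("feature")
        for feat in ("a", "b"):
            assert res.loc[feat, "mean_abund"] == pytest.approx(
                table.data[feat].mean() * 100.0
            )

    def test_fewer_than_four_pairs_skipped(self):
        ids = ["m0", "m1", "m2"]
        table = self._table({"a": [1.0, 2.0, 3.0], "b": [3.0, 2.0, 1.0]}, ids)
        imaging = pd.DataFrame({"param": [1.0, 2.0, 3.0]}, index=ids)
        res = spearman_assoc(table, imaging)
        assert res.empty

    def test_planted_signals_recovered_at_study_scale(self):
        # every caecum genus-level planted |rho| >= 0.6 should reach q <= 0.05
        # in >= 80% of replicate cohorts at the study's age-group size (20)
        import dataclasses

        from adipoquant import CohortConfig, generate_cohort

        hits = total = 0
        for seed in range(12):
            cfg = dataclasses.replace(CohortConfig(), n_per_cell=5, seed=300 + seed)
            bundle = generate_cohort(cfg)
            truth = bundle.truth.set_index("animal_id")
            age = bundle.animals.set_index("animal_id")["age_group"]
            table = bundle.abundances[("caecum", "genus")]
            planted = [
                t
                for t in cfg.taxa
                if (t.site, t.level) == ("caecum", "genus")
                and t.assoc is not None
                and abs(t.assoc[1]) >= 0.6
            ]
            for age_group in ("1mo", "6mo"):
                ids = age.index[age == age_group]
                params = sorted(
                    {t.assoc[0] for t in planted if t.assoc[2] == age_group}
                )
                if not params:
                    continue
                sub = AbundanceTable("caecum", "genus", table.data.loc[ids])
                res = spearman_assoc(sub, truth.loc[ids, params]).set_index(
                    ["parameter", "feature"]
                )
                for taxon in planted:
                    if taxon.assoc[2] != age_group:
                        continue
                    total += 1
                    if res.loc[(taxon.assoc[0], taxon.name), "q"] <= 0.05:
                        hits += 1
        assert total > 0
        assert hits / total >= 0.8

    def test_q_within_parameter_family_matches_bh_of_raw_p(self):
        rng = np.random.default_rng(9)
        ids = [f"m{i}" for i in range(20)]
        values = {f"t{k}": rng.random(20) + 0.01 for k in range(6)}
        table = self._table(values, ids)
        imaging = pd.DataFrame(
            {"p1": rng.random(20), "p2": rng.random(20)}, index=ids
        )
        res = spearman_assoc(table, imaging)
        for _, fam in res.groupby("parameter"):
            assert np.allclose(np.sort(fam["q"]), np.sort(bh_fdr(fam["p"])))
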