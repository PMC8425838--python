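from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sevmir import (
    GroupDesign,
    ValidationError,
    call_differential,
    fold_change,
    housekeeping_normalize,
    permutation_t_test,
    sample_clustergram,
    tpm_normalize,
)

from conftest import make_count_matrix, make_sheet


def design_4v4():
    return GroupDesign(
        pd.Series(
            ["control"] * 4 + ["case"] * 4,
            index=[f"c{i}" for i in range(4)] + [f"t{i}" for i in range(4)],
        )
    )


def frame(rows: dict, design: GroupDesign) -> pd.DataFrame:
    return pd.DataFrame(rows, index=list(design.labels.index)).T


def brute_force_perm_p(values, n1):
    """Independent oracle: enumerate every labeling, Welch t via scipy."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    obs = abs(
        stats.ttest_ind(values[n1:], values[:n1], equal_var=False).statistic
    )
    count = 0
    total = 0
    for combo in combinations(range(n), n - n1):
        case = values[list(combo)]
        ctrl = values[[i for i in range(n) if i not in combo]]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = stats.ttest_ind(case, ctrl, equal_var=False).statistic
        t = 0.0 if np.isnan(t) else abs(t)
        total += 1
        if t >= obs - 1e-12 * (1 + obs):
            count += 1
    return count / total


class TestHousekeepingNormalize:
    def base_em(self, hk_values, probe_values):
        cm = make_count_matrix(
            {"hk1": [1], "hk2": [1], "p": [1]},
            classes={"hk1": "housekeeping", "hk2": "housekeeping"},
        )
        em = tpm_normalize(cm)
        em.values.loc["hk1"] = hk_values[0]
        em.values.loc["hk2"] = hk_values[1]
        em.values.loc["p"] = probe_values
        return em

    def test_single_hk_divides_everything(self):
        em = self.base_em([100.0, 100.0], [250.0])
        out = housekeeping_normalize(em)
        assert out.values.at["p", "s1"] == pytest.approx(2.5)

    def test_geometric_mean_divisor(self):
        em = self.base_em([10.0, 1000.0], [500.0])
        out = housekeeping_normalize(em)
        assert out.values.at["p", "s1"] == pytest.approx(5.0)  # divisor sqrt(10*1000)=100

    def test_hk_aggregate_is_one_after_normalization(self, default_run):
        norm = default_run["norm"]
        hk = norm.probe_ids("housekeeping")
        aggregate = np.exp(np.log(norm.values.loc[hk]).mean(axis=0))
        np.testing.assert_allclose(aggregate, 1.0, rtol=1e-12)

    def test_zero_housekeeping_requires_pseudocount(self):
        em = self.base_em([0.0, 100.0], [1.0])
        with pytest.raises(ValidationError, match="pseudocount"):
            housekeeping_normalize(em)
        out = housekeeping_normalize(em, pseudocount=1.0)
        assert np.isfinite(out.values.to_numpy()).all()


class TestFoldChange:
    def norm_em(self, rows: dict, design: GroupDesign):
        probes = {**rows, "hk": [1.0] * len(design.labels)}
        cm = make_count_matrix(
            {p: [1] * len(design.labels) for p in probes}, classes={"hk": "housekeeping"}
        )
        cm.counts.columns = list(design.labels.index)
        em = tpm_normalize(cm)
        for p, vals in probes.items():
            em.values.loc[p] = vals
        return housekeeping_normalize(em)

    def test_identical_groups_fc_one(self):
        design = design_4v4()
        norm = self.norm_em({"p": [2.0] * 8}, design)
        assert fold_change(norm, design).at["p"] == pytest.approx(1.0)

    def test_log_difference(self):
        design = GroupDesign(
            pd.Series(["control", "control", "case", "case"], index=["a", "b", "c", "d"])
        )
        norm = self.norm_em({"p": [2.0, 2.0, 8.0, 8.0]}, design)
        assert fold_change(norm, design).at["p"] == pytest.approx(4.0)

    def test_geometric_means(self):
        # case values 2 and 4 -> geometric mean sqrt(8); control 1,1 -> FC = 2.828...
        design = GroupDesign(
            pd.Series(["control", "control", "case", "case"], index=["a", "b", "c", "d"])
        )
        norm = self.norm_em({"p": [1.0, 1.0, 2.0, 4.0]}, design)
        assert fold_change(norm, design).at["p"] == pytest.approx(np.sqrt(8.0))

    def test_reciprocity(self, default_run):
        """FC(case/control) * FC(control/case) = 1 for every probe."""
        norm, design = default_run["norm"], default_run["design"]
        forward = fold_change(norm, design)
        backward = fold_change(norm, GroupDesign(design.labels, reference="case"))
        np.testing.assert_allclose(forward * backward, 1.0, rtol=1e-9)


class TestPermutationTTest:
    def test_identical_groups_p_one(self):
        design = design_4v4()
        data = frame({"p": [3.0] * 8}, design)
        with pytest.warns(UserWarning, match="constant"):
            p = permutation_t_test(data, design, scheme="exhaustive")
        assert p.at["p"] == 1.0

    def test_complete_separation_exhaustive(self):
        """[1..4] vs [5..8]: only the observed split and its mirror reach max |t|."""
        design = design_4v4()
        data = frame({"p": [1, 2, 3, 4, 5, 6, 7, 8]}, design)
        p = permutation_t_test(data, design, scheme="exhaustive")
        assert p.at["p"] == pytest.approx(2 / 70)

    def test_exhaustive_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        design = design_4v4()
        rows = {f"p{i}": rng.normal(size=8) for i in range(6)}
        p = permutation_t_test(frame(rows, design), design, scheme="exhaustive")
        for name, values in rows.items():
            assert p.at[name] == pytest.approx(brute_force_perm_p(values, 4))

    def test_exhaustive_p_on_grid(self):
        """Exhaustive p-values live on the k/70 grid with minimum 1/70."""
        rng = np.random.default_rng(3)
        design = design_4v4()
        rows = {f"p{i}": rng.normal(size=8) for i in range(20)}
        p = permutation_t_test(frame(rows, design), design, scheme="exhaustive")
        np.testing.assert_allclose((p * 70) % 1, 0.0, atol=1e-9)
        assert (p >= 1 / 70 - 1e-12).all()

    def test_monte_carlo_close_to_exhaustive(self):
        design = design_4v4()
        data = frame({"p": [1, 2, 3, 4, 5, 6, 7, 8]}, design)
        p = permutation_t_test(data, design, scheme="monte_carlo", n_permutations=9999, seed=11)
        truth = 2 / 70
        se = np.sqrt(truth * (1 - truth) / 9999)
        assert abs(p.at["p"] - truth) <= 3 * se

    def test_affine_invariance(self):
        """p is unchanged by a shared affine transform of a probe's values."""
        rng = np.random.default_rng(5)
        design = design_4v4()
        base = rng.normal(size=8)
        rows = {"raw": base, "scaled": 3.5 * base + 11.0}
        p = permutation_t_test(frame(rows, design), design, scheme="exhaustive")
        assert p.at["raw"] == p.at["scaled"]

    def test_pooled_resolution_below_per_probe_floor(self):
        """Pooling across probes yields p below the per-probe 1/70 floor for a
        strong effect embedded among null probes."""
        rng = np.random.default_rng(13)
        design = design_4v4()
        rows = {f"null{i}": rng.normal(size=8) for i in range(200)}
        rows["de"] = np.array([0, 0.1, -0.1, 0.05, 5.0, 5.1, 4.9, 5.05])
        p = permutation_t_test(frame(rows, design), design, scheme="pooled")
        assert p.at["de"] < 1 / 70

    def test_unknown_scheme_rejected(self):
        design = design_4v4()
        with pytest.raises(ValidationError, match="scheme"):
            permutation_t_test(frame({"p": range(8)}, design), design, scheme="bogus")


class TestCallDifferential:
    def make_maps(self, entries):
        idx = [e[0] for e in entries]
        fc = pd.Series([e[1] for e in entries], index=idx)
        p = pd.Series([e[2] for e in entries], index=idx)
        return fc, p

    def test_threshold_logic(self):
        fc, p = self.make_maps(
            [("hit_up", 2.5, 0.005), ("weak_fc", 1.8, 0.005), ("weak_p", 3.0, 0.02),
             ("hit_down", 0.4, 0.004)]
        )
        de = call_differential(fc, p)
        assert de.table.at["hit_up", "de_call"] and de.table.at["hit_up", "direction"] == "up"
        assert not de.table.at["weak_fc", "de_call"]
        assert not de.table.at["weak_p", "de_call"]
        assert de.table.at["hit_down", "de_call"] and de.table.at["hit_down", "direction"] == "down"

    def test_sorted_by_p(self):
        fc, p = self.make_maps([("a", 2, 0.5), ("b", 2, 0.001), ("c", 2, 0.01)])
        assert call_differential(fc, p).table.index.tolist() == ["b", "c", "a"]

    def test_bh_family_excludes_housekeeping(self):
        fc, p = self.make_maps([("m1", 2, 0.01), ("m2", 2, 0.02), ("hk", 2, 0.001)])
        ann = pd.DataFrame(
            {"probe_class": ["mirna", "mirna", "housekeeping"], "length_kb": 1.0},
            index=["m1", "m2", "hk"],
        )
        de = call_differential(fc, p, annotation=ann)
        assert np.isnan(de.table.at["hk", "p_adj"])
        # BH over the two mirna probes only: [0.01, 0.02] -> [0.02, 0.02]
        assert de.table.at["m1", "p_adj"] == pytest.approx(0.02)
        assert de.table.at["m2", "p_adj"] == pytest.approx(0.02)


class TestClustergram:
    def test_identical_samples_merge_at_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        df = pd.DataFrame({"a": x, "b": x})
        gram = sample_clustergram(df)
        assert gram.distances.at["a", "b"] == pytest.approx(0.0, abs=1e-12)
        assert gram.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_distance_two(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        df = pd.DataFrame({"a": x, "b": -x})
        gram = sample_clustergram(df)
        assert gram.distances.at["a", "b"] == pytest.approx(2.0)

    def test_correlated_pair_merges_first(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": x + rng.normal(scale=0.01, size=50), "c": rng.normal(size=50)})
        gram = sample_clustergram(df)
        # first merge joins leaves 0 and 1 (a and b)
        assert set(gram.linkage[0, :2].astype(int)) == {0, 1}
        assert gram.newick.startswith("((a:")

    def test_constant_sample_is_error(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValidationError, match="flat"):
            sample_clustergram(df)

    def test_newick_parses_with_dendropy(self, default_run):
        import dendropy

        gram = sample_clustergram(default_run["log_norm"])
        tree = dendropy.Tree.get(data=gram.newick, schema="newick", preserve_underscores=True)
        labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert labels == set(default_run["log_norm"].columns)
        assert sorted(gram.leaf_order) == sorted(default_run["log_norm"].columns)
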