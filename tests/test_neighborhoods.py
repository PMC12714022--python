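"""Sub-domain ranking, composition filtering, k-selection, neighbor calling."""

import numpy as np
import pandas as pd
import pytest

from plastmap import neighborhoods as nb


class TestSelectKByAri:
    def test_hand_worked_sweep(self):
        ks = range(4, 11)
        ari = [0.5, 0.7, 0.7, 0.8, 0.66, 0.7, 0.4]
        sel = nb.select_k_by_ari(list(ks), ari, threshold=0.65, window=5)
        assert sel.run_ks == (5, 6, 7, 8, 9)
        assert sel.chosen_k == 7

    def test_no_qualifying_run_raises(self):
        with pytest.raises(nb.NoStableRangeError):
            nb.select_k_by_ari(list(range(2, 9)), [0.5] * 7, threshold=0.65, window=5)

    def test_constant_sweep_ties_to_smallest_k(self):
        sel = nb.select_k_by_ari(list(range(2, 9)), [0.9] * 7, window=4)
        assert sel.run_ks == tuple(range(2, 9))
        assert sel.chosen_k == 2

    def test_invariant_to_candidates_after_first_run(self):
        ks = [2, 3, 4, 5, 6, 7]
        ari = [0.7, 0.7, 0.8, 0.7, 0.7, 0.3]
        base = nb.select_k_by_ari(ks, ari, window=5)
        extended = nb.select_k_by_ari(ks + [8, 9], ari + [0.9, 0.9], window=5)
        assert base == extended or (
            base.run_ks == extended.run_ks and base.chosen_k == extended.chosen_k
        )

    def test_validates_inputs(self):
        with pytest.raises(ValueError):
            nb.select_k_by_ari([2, 2, 3, 4, 5], [0.7] * 5)
        with pytest.raises(ValueError):
            nb.select_k_by_ari([2, 3, 4, 5, 6], [0.7, 0.7, 1.5, 0.7, 0.7])
        with pytest.raises(ValueError):
            nb.select_k_by_ari([2, 3], [0.7, 0.7], window=5)


class TestRegionalPlasticity:
    def test_mean_rank_and_relabel(self):
        labels = pd.Series({"s1": "d1", "s2": "d1", "s3": "d2"})
        scores = pd.Series({"s1": 0.2, "s2": 0.4, "s3": 0.8})
        out = nb.regional_plasticity(labels, scores).set_index("subdomain")
        assert out.loc["d1", "score"] == pytest.approx(0.3)
        assert out.loc["d2", "rank"] == 1 and out.loc["d1", "rank"] == 2

    def test_equal_scores_tie_broken_by_id(self):
        labels = pd.Series({"s1": "b", "s2": "a"})
        scores = pd.Series({"s1": 0.5, "s2": 0.5})
        out = nb.regional_plasticity(labels, scores).set_index("subdomain")
        assert out.loc["a", "rank"] == 1

    def test_missing_score_rejected(self):
        with pytest.raises(ValueError):
            nb.regional_plasticity(pd.Series({"s1": "d1"}), pd.Series(dtype=float))

    def test_rank_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(0)
        labels = pd.Series(rng.choice(["a", "b", "c"], size=60),
                           index=[f"s{i}" for i in range(60)])
        scores = pd.Series(rng.uniform(size=60), index=labels.index)
        r1 = nb.regional_plasticity(labels, scores).set_index("subdomain")["rank"]
        # ranking is by per-group means, so order preservation is guaranteed
        # for affine transforms (nonlinear ones need not commute with means)
        r2 = nb.regional_plasticity(labels, 5 * scores + 2).set_index("subdomain")["rank"]
        assert (r1 == r2).all()


class TestCompositionSummary:
    @staticmethod
    def _labels_types(fracs: dict[str, float], n=200, sub="d1"):
        spots, types = [], []
        i = 0
        for t, f in fracs.items():
            for _ in range(int(round(f * n))):
                spots.append(f"s{i}")
                types.append(t)
                i += 1
        labels = pd.Series(sub, index=spots)
        return labels, pd.Series(types, index=spots)

    def test_cumulative_walk_includes_crossing_type(self):
        labels, types = self._labels_types({"A": 0.50, "B": 0.30, "C": 0.15, "D": 0.05})
        comp = nb.composition_summary(labels, types)
        included = set(comp.loc[comp["included"], "cell_type"])
        assert included == {"A", "B", "C"}

    def test_single_type(self):
        labels, types = self._labels_types({"A": 1.0})
        comp = nb.composition_summary(labels, types)
        assert set(comp.loc[comp["included"], "cell_type"]) == {"A"}

    def test_eligibility_exhausted_below_threshold(self):
        labels, types = self._labels_types(
            {"A": 0.85, **{f"m{i}": 0.025 for i in range(6)}}, n=400
        )
        comp = nb.composition_summary(labels, types)
        assert set(comp.loc[comp["included"], "cell_type"]) == {"A"}

    def test_thresholds_off_returns_full_composition(self):
        labels, types = self._labels_types({"A": 0.5, "B": 0.3, "C": 0.2})
        comp = nb.composition_summary(labels, types, cum_threshold=1.0, min_frac=0.0)
        assert comp["included"].all()
        assert comp["fraction"].sum() == pytest.approx(1.0)

    def test_included_fractions_respect_min_frac_and_sorting(self):
        rng = np.random.default_rng(4)
        labels = pd.Series(rng.choice(["d1", "d2"], size=300),
                           index=[f"s{i}" for i in range(300)])
        types = pd.Series(rng.choice(list("ABCDEFG"), size=300,
                                     p=[0.4, 0.2, 0.15, 0.1, 0.07, 0.05, 0.03]),
                          index=labels.index)
        comp = nb.composition_summary(labels, types)
        inc = comp[comp["included"]]
        assert (inc["fraction"] >= 0.05).all()
        for _, grp in comp.groupby("subdomain"):
            assert (grp["fraction"].diff().dropna() <= 1e-12).all()  # sorted descending
            assert grp["fraction"].sum() == pytest.approx(1.0)

    def test_invalid_thresholds_rejected(self):
        labels, types = self._labels_types({"A": 1.0})
        with pytest.raises(ValueError):
            nb.composition_summary(labels, types, cum_threshold=1.5)
        with pytest.raises(ValueError):
            nb.composition_summary(labels, types, min_frac=1.0)


class TestTwoRoundSubdomains:
    def test_valve_domain_maximizes_valve_cell_fraction(self):
        spots = [f"s{i}" for i in range(9)]
        dom = pd.Series(
            ["vCM"] * 3 + ["Valve-immature", "Valve-mature", "vCM"] + ["Endo"] * 3,
            index=spots,
        )
        calls = []

        def cluster(ids):
            calls.append(list(ids))
            if len(ids) == 9:  # round 1: three spatial domains
                return pd.Series(["d0"] * 3 + ["d1"] * 3 + ["d2"] * 3, index=ids)
            return pd.Series(["sub0", "sub0", "sub1"], index=ids)  # round 2

        label, subs = nb.two_round_subdomains(
            cluster, spots, dom, valve_types={"Valve-immature", "Valve-mature"}
        )
        assert label == "d1"  # 2/3 valve cells beats 0/3 elsewhere
        assert calls[1] == ["s3", "s4", "s5"]
        assert set(subs.unique()) == {"sub0", "sub1"}


def _comp(included_by_sub: dict[str, list[str]]) -> pd.DataFrame:
    rows = []
    for sub, types in included_by_sub.items():
        for t in types:
            rows.append({"subdomain": sub, "cell_type": t, "fraction": 0.2, "included": True})
    return pd.DataFrame(rows)


class TestNeighborCelltypes:
    def test_type_in_two_subdomains_across_two_days_is_neighbor(self):
        samples = [
            nb.SampleComposition("normal", 7, _comp({"d1": ["VEC"], "d2": ["VEC"]})),
            nb.SampleComposition("normal", 10, _comp({"d1": ["VEC"], "d2": ["VEC"], "d3": ["VEC"]})),
        ]
        assert nb.neighbor_celltypes(samples)["normal"] == {"VEC"}

    def test_single_subdomain_per_sample_is_not_enough(self):
        samples = [
            nb.SampleComposition("normal", 7, _comp({"d1": ["Epi"]})),
            nb.SampleComposition("normal", 10, _comp({"d1": ["Epi"]})),
        ]
        assert nb.neighbor_celltypes(samples).get("normal", set()) == set()

    def test_single_timepoint_is_not_enough(self):
        samples = [
            nb.SampleComposition("LAL", 7, _comp({"d1": ["Endo"], "d2": ["Endo"], "d3": ["Endo"]})),
        ]
        assert nb.neighbor_celltypes(samples).get("LAL", set()) == set()

    def test_conditions_evaluated_independently(self):
        samples = [
            nb.SampleComposition("normal", 7, _comp({"d1": ["VEC"], "d2": ["VEC"]})),
            nb.SampleComposition("normal", 10, _comp({"d1": ["VEC"], "d2": ["VEC"]})),
            nb.SampleComposition("LAL", 7, _comp({"d1": ["VEC"], "d2": ["VEC"]})),
        ]
        out = nb.neighbor_celltypes(samples)
        assert out["normal"] == {"VEC"}
        assert out.get("LAL", set()) == set()
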