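import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memoryprime import (
    ContrastBundle,
    class_a,
    class_b,
    classify_memory,
    fisher_exact_2x2,
    inversion_fisher_test,
    label_memory,
    label_percentages,
    orientation_breakdown,
    replicate_ratios,
    simulate_experiment,
    venn_counts,
)
from memoryprime.diffexpr import analyze_contrast

from conftest import make_contrast_table


def _bundle(**tables) -> ContrastBundle:
    return ContrastBundle(tables={k: make_contrast_table(v) for k, v in tables.items()})


def _sim_bundle(config):
    arrays, ann, truth = simulate_experiment(config)
    ratios = replicate_ratios(arrays, ann, span=None)
    tables = {
        cid: analyze_contrast(sub) for cid, sub in ratios.groupby("contrast_id")
    }
    return ContrastBundle(tables=tables), ann, truth


class TestVenn:
    def test_two_overlapping_sets(self):
        regions = venn_counts({"s1": {1, 2}, "s2": {2, 3}, "s3": set(), "s4": set()})
        assert regions[frozenset({"s1"})] == 1
        assert regions[frozenset({"s2"})] == 1
        assert regions[frozenset({"s1", "s2"})] == 1
        assert sum(regions.values()) == 3

    def test_identical_sets_fill_only_the_center(self):
        s = set(range(17))
        regions = venn_counts({f"s{i}": s for i in range(4)})
        center = frozenset({f"s{i}" for i in range(4)})
        assert regions[center] == 17
        assert all(v == 0 for k, v in regions.items() if k != center)

    def test_matches_per_element_pattern_oracle(self):
        rng = np.random.default_rng(17)
        universe = np.arange(1000)
        sets = {f"c{i}": set(universe[rng.random(1000) < 0.3]) for i in range(4)}
        regions = venn_counts(sets)
        names = list(sets)
        for r in range(1, 5):
            for inc in itertools.combinations(names, r):
                exc = [n for n in names if n not in inc]
                members = set.intersection(*(sets[n] for n in inc))
                for n in exc:
                    members -= sets[n]
                assert regions[frozenset(inc)] == len(members)
        union = set().union(*sets.values())
        assert sum(regions.values()) == len(union)

    def test_requires_exactly_four_sets(self):
        with pytest.raises(ValueError, match="exactly 4"):
            venn_counts({"a": set(), "b": set(), "c": set()})


class TestClassA:
    def test_intersection_and_concordance(self):
        bundle = _bundle(
            ww_bw={"a": (0.01, "up"), "b": (0.01, "down")},
            ww_wf={"a": (0.01, "up"), "c": (0.01, "up")},
        )
        ca = class_a(bundle)
        assert list(ca.index) == ["a"]
        assert not ca.loc["a", "transgressive"]

    def test_discordant_directions_are_transgressive(self):
        bundle = _bundle(
            ww_bw={"a": (0.01, "up")}, ww_wf={"a": (0.01, "down")}
        )
        ca = class_a(bundle)
        assert bool(ca.loc["a", "transgressive"])
        assert ca.loc["a", "subcategory"] == "up_by_BTH"

    def test_zero_noise_recovers_planted_class_a(self, zero_noise_config):
        bundle, _, truth = _sim_bundle(zero_noise_config)
        ca = class_a(bundle)
        planted = set(
            truth.loc[truth["memory_class"] == "classA_concordant", "transcript_id"]
        )
        assert set(ca.index) == planted
        assert not ca["transgressive"].any()  # planted Class A is concordant


class TestClassB:
    def test_intersection(self):
        bundle = _bundle(
            ww_bw={"a": (0.01, "up"), "b": (0.01, "up")},
            bw_bf={"b": (0.01, "down")},
        )
        assert list(class_b(bundle).index) == ["b"]

    def test_disjoint_sets_empty(self):
        bundle = _bundle(ww_bw={"a": (0.01, "up")}, bw_bf={"b": (0.01, "down")})
        assert class_b(bundle).empty

    def test_zero_noise_recovers_planted_memory_classes(self, zero_noise_config):
        bundle, _, truth = _sim_bundle(zero_noise_config)
        cb = class_b(bundle)
        planted = set(
            truth.loc[
                truth["memory_class"].isin(
                    ["deprimed", "persistent_primed", "transgressive"]
                ),
                "transcript_id",
            ]
        )
        assert set(cb.index) == planted


class TestClassifyMemory:
    # (dir in ww_bw, dir in bw_bf, significant in ww_bf) -> label; the full
    # 8-way truth table: same direction => transgressive regardless of the
    # ww_bf outcome; inverted direction splits on the ww_bf significance
    CASES = [
        ("up", "up", False, "transgressive"),
        ("up", "up", True, "transgressive"),
        ("up", "down", False, "deprimed"),
        ("up", "down", True, "primed"),
        ("down", "down", False, "transgressive"),
        ("down", "down", True, "transgressive"),
        ("down", "up", False, "deprimed"),
        ("down", "up", True, "primed"),
    ]

    @pytest.mark.parametrize("dir_bw,dir_bwbf,sig,expected", CASES)
    def test_exhaustive_rule_table(self, dir_bw, dir_bwbf, sig, expected):
        p = 0.01 if sig else 0.50
        labels = label_memory([dir_bw], [dir_bwbf], [p], alpha=0.05)
        assert labels[0] == expected

    def test_classify_via_bundle_matches_rule_table(self):
        ids = [f"t{i}" for i in range(len(self.CASES))]
        bundle = _bundle(
            ww_bw={t: (0.01, c[0]) for t, c in zip(ids, self.CASES)},
            bw_bf={t: (0.01, c[1]) for t, c in zip(ids, self.CASES)},
            ww_bf={t: (0.01 if c[2] else 0.5, "up") for t, c in zip(ids, self.CASES)},
        )
        labels = classify_memory(class_b(bundle), bundle)
        for t, (dir_bw, _, _, expected) in zip(ids, self.CASES):
            assert labels.loc[t, "label"] == expected
            assert labels.loc[t, "subcategory"] == (
                "up_by_BTH" if dir_bw == "up" else "down_by_BTH"
            )

    def test_missing_wwbf_transcript_is_an_error(self):
        bundle = _bundle(
            ww_bw={"a": (0.01, "up")},
            bw_bf={"a": (0.01, "down")},
            ww_bf={"other": (0.5, "up")},
        )
        with pytest.raises(KeyError, match="a"):
            classify_memory(class_b(bundle), bundle)

    def test_label_stability_under_permutation(self):
        rng = np.random.default_rng(3)
        n = 50
        ids = [f"t{i}" for i in range(n)]
        dirs = rng.choice(["up", "down"], n)
        dirs2 = rng.choice(["up", "down"], n)
        ps = rng.uniform(0, 1, n)
        base = label_memory(dirs, dirs2, ps, 0.05)
        perm = rng.permutation(n)
        permuted = label_memory(dirs[perm], dirs2[perm], ps[perm], 0.05)
        assert (permuted == base[perm]).all()

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.data())
    def test_partition_property(self, data):
        n = data.draw(st.integers(1, 60))
        dirs = data.draw(
            st.lists(st.sampled_from(["up", "down"]), min_size=n, max_size=n)
        )
        dirs2 = data.draw(
            st.lists(st.sampled_from(["up", "down"]), min_size=n, max_size=n)
        )
        ps = data.draw(
            st.lists(st.floats(0.0001, 1.0), min_size=n, max_size=n)
        )
        labels = label_memory(dirs, dirs2, ps, 0.05)
        counts = pd.Series(labels).value_counts()
        assert counts.sum() == n  # mutually exclusive and exhaustive


class TestOrientationBreakdown:
    def _annotation(self, ids, antisense_ids):
        return pd.DataFrame(
            {
                "probe_id": [f"P{t}" for t in ids],
                "transcript_id": ids,
                "gene_id": [f"G{t}" for t in ids],
                "orientation": [
                    "antisense" if t in antisense_ids else "sense" for t in ids
                ],
            }
        )

    def test_sense_antisense_split(self):
        ids = [f"t{i}" for i in range(10)]
        table = pd.DataFrame(
            {"subcategory": "up_by_BTH", "transgressive": False},
            index=pd.Index(ids, name="transcript_id"),
        )
        bd = orientation_breakdown(table, self._annotation(ids, set(ids[:4])))
        assert bd.loc["up_by_BTH", "nontransgressive_sense"] == pytest.approx(60.0)
        assert bd.loc["up_by_BTH", "nontransgressive_antisense"] == pytest.approx(40.0)
        assert bd.loc["up_by_BTH"].sum() == pytest.approx(100.0)

    def test_empty_table_has_no_rows(self):
        table = pd.DataFrame(
            {"subcategory": [], "transgressive": []},
            index=pd.Index([], name="transcript_id"),
        )
        bd = orientation_breakdown(table, self._annotation(["x"], set()))
        assert bd.empty

    def test_unannotated_transcript_errors(self):
        table = pd.DataFrame(
            {"subcategory": ["up_by_BTH"], "transgressive": [False]},
            index=pd.Index(["mystery"], name="transcript_id"),
        )
        with pytest.raises(KeyError, match="mystery"):
            orientation_breakdown(table, self._annotation(["x"], set()))

    def test_antisense_share_tracks_planted_fraction(self, zero_noise_config):
        """No orientation-class coupling in the generator: the antisense share
        of each Class B subcategory stays within 3 sigma of 25%."""
        bundle, ann, _ = _sim_bundle(zero_noise_config.with_seed(19))
        cb = class_b(bundle)
        labels = classify_memory(cb, bundle)
        bd = orientation_breakdown(labels, ann)
        for subcat, row in bd.iterrows():
            n = (labels["subcategory"] == subcat).sum()
            share = (
                row["nontransgressive_antisense"] + row["transgressive_antisense"]
            ) / 100.0
            sigma = math.sqrt(0.25 * 0.75 / n)
            assert abs(share - 0.25) <= 3 * sigma


def _fisher_oracle(table) -> float:
    """Exact two-sided Fisher p by integer-weight enumeration over all
    tables sharing the margins (minimum-likelihood rule)."""
    (a, b), (c, d) = table
    r1, c1, N = a + b, a + c, a + b + c + d
    lo, hi = max(0, c1 - (N - r1)), min(r1, c1)
    weights = {
        x: math.comb(r1, x) * math.comb(N - r1, c1 - x) for x in range(lo, hi + 1)
    }
    total = sum(weights.values())
    obs = weights[a]
    return float(Fraction(sum(w for w in weights.values() if w <= obs), total))


class TestInversionFisher:
    def test_flat_table_p_one(self):
        _, p = fisher_exact_2x2([[1, 1], [1, 1]])
        assert p == pytest.approx(1.0)

    def test_diagonal_2_2(self):
        # margins (2,2)/(2,2) admit 3 tables with weights 1,4,1: p = 2/6
        _, p = fisher_exact_2x2([[2, 0], [0, 2]])
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_diagonal_10_10_matches_enumeration(self):
        _, p = fisher_exact_2x2([[10, 0], [0, 10]])
        assert p == pytest.approx(_fisher_oracle([[10, 0], [0, 10]]), abs=1e-12)

    def test_zero_margin_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="zero margin"):
            _, p = fisher_exact_2x2([[0, 0], [3, 4]])
        assert p == 1.0

    def test_random_tables_match_scipy(self):
        from scipy.stats import fisher_exact

        import warnings

        rng = np.random.default_rng(11)
        for _ in range(200):
            t = rng.integers(0, 12, (2, 2))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)  # zero margins
                _, p1 = fisher_exact_2x2(t)
            p2 = fisher_exact(t)[1]
            assert p1 == pytest.approx(p2, abs=1e-12), t

    def test_doubling_rule_variant(self):
        t = [[8, 2], [3, 9]]
        _, p_min = fisher_exact_2x2(t)
        _, p_dbl = fisher_exact_2x2(t, two_sided_rule="double")
        assert p_dbl >= p_min  # doubling is never smaller for these tables

    def test_inversion_pattern_is_detected(self):
        cb = pd.DataFrame(
            {
                "dir_bw": ["up"] * 20 + ["down"] * 20,
                "dir_bwbf": ["down"] * 19 + ["up"] + ["up"] * 19 + ["down"],
            },
            index=pd.Index([f"t{i}" for i in range(40)], name="transcript_id"),
        )
        table, odds, p = inversion_fisher_test(cb)
        assert table.tolist() == [[1, 19], [19, 1]]
        assert odds < 1 and p < 1e-5

    def test_empty_class_b_rejected(self):
        cb = pd.DataFrame(columns=["dir_bw", "dir_bwbf"])
        with pytest.raises(ValueError, match="empty"):
            inversion_fisher_test(cb)


def test_label_percentages_sum_to_100():
    labels = pd.DataFrame({"label": ["deprimed"] * 8 + ["primed"] * 1 + ["transgressive"] * 1})
    pct = label_percentages(labels)
    assert sum(pct.values()) == pytest.approx(100.0)
    assert pct["deprimed"] == pytest.approx(80.0)
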