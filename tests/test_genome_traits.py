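import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from denitscape.data_io import DataError
from denitscape.genome_traits import (
    DenitrifierType,
    GeneRepertoire,
    apply_quality_filter,
    bin_growth_rate,
    classify_denitrifier,
    classify_table,
    compare_counts_ks,
    compare_groups_ranked,
    nosz_clade_cross_table,
    summarize_types,
    trait_density,
)


def oracle_type(nirK, nirS, nor, nosZ, anammox, archaeal):
    """Truth table coded independently from the pathway framework:
    nitrite reduction (nir) starts denitrification, N2O reduction (nosZ)
    ends it, nor links them; anammox / archaeal-nitrifier nitrite
    reductases are not respiratory denitrification enzymes."""
    if anammox or archaeal:
        return "non_denitrifier"
    nir = nirK or nirS
    if nir and nosZ and nor:
        return "complete"
    if nir and nosZ:
        return "initiator_terminator"
    if nir:
        return "initiator"
    if nosZ:
        return "terminator"
    return "non_denitrifier"


class TestClassification:
    def test_exhaustive_truth_table(self):
        """All 2^4 presence combinations x exclusion flags match the oracle."""
        cases = 0
        for nirK, nirS, nor, nosZ, anammox, archaeal in itertools.product(
            [False, True], repeat=6
        ):
            rep = GeneRepertoire(
                has_nirK=nirK,
                has_nirS=nirS,
                has_nor=nor,
                has_nosZ=nosZ,
                nosZ_clade="I" if nosZ else "none",
                is_anammox=anammox,
                is_archaeal_nitrifier=archaeal,
            )
            expected = oracle_type(nirK, nirS, nor, nosZ, anammox, archaeal)
            assert classify_denitrifier(rep).value == expected
            cases += 1
        assert cases == 64

    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(has_nirS=True, has_nor=True, has_nosZ=True, nosZ_clade="I"),
             "complete"),
            (dict(has_nor=True), "non_denitrifier"),  # nor-only: detox
            (dict(has_nirS=True, is_anammox=True), "non_denitrifier"),
            (dict(has_nirK=True, has_nosZ=True, nosZ_clade="II"),
             "initiator_terminator"),
            (dict(has_nirK=True, has_nor=True), "initiator"),
            (dict(has_nosZ=True, nosZ_clade="II", has_nor=True), "terminator"),
        ],
    )
    def test_named_cases(self, kwargs, expected):
        assert classify_denitrifier(GeneRepertoire(**kwargs)).value == expected

    def test_clade_presence_consistency_enforced(self):
        with pytest.raises(ValueError, match="nosZ_clade"):
            GeneRepertoire(has_nosZ=True, nosZ_clade="none")

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(0)
        n = 200
        table = pd.DataFrame(
            {
                "has_nirK": rng.random(n) < 0.5,
                "has_nirS": rng.random(n) < 0.5,
                "has_nor": rng.random(n) < 0.5,
                "has_nosZ": rng.random(n) < 0.5,
                "is_anammox": rng.random(n) < 0.1,
                "is_archaeal_nitrifier": rng.random(n) < 0.1,
            }
        )
        expected = [
            oracle_type(*row)
            for row in table.itertuples(index=False)
        ]
        assert list(classify_table(table)) == expected


class TestQualityFilter:
    def table(self, **overrides):
        base = {
            "genome_id": ["A", "B", "C", "D"],
            "completeness": [79.9, 80.0, 95.0, 99.0],
            "contamination": [1.0, 5.0, 5.1, 0.5],
            "gunc_pass": [True, True, True, False],
        }
        base.update(overrides)
        return pd.DataFrame(base)

    def test_boundary_semantics(self):
        kept, report = apply_quality_filter(self.table())
        # 79.9 excluded (strictly less than 80), 80.0 and 5.0 retained,
        # 5.1 excluded (more than 5), GUNC failure excluded
        assert list(kept["genome_id"]) == ["B"]
        assert report["low_completeness"] == 1
        assert report["high_contamination"] == 1
        assert report["gunc_fail"] == 1

    def test_gunc_optional(self):
        kept, _ = apply_quality_filter(self.table(), require_gunc=False)
        assert list(kept["genome_id"]) == ["B", "D"]

    def test_empty_result_allowed(self):
        kept, report = apply_quality_filter(
            self.table(completeness=[10, 20, 30, 40])
        )
        assert kept.empty
        assert report["retained"] == 0


class TestSummaries:
    def four_types_table(self):
        return pd.DataFrame(
            {
                "denitrifier_type": [
                    "complete",
                    "initiator",
                    "terminator",
                    "initiator_terminator",
                ],
                "group": ["x"] * 4,
                "has_nosZ": [True, False, True, True],
                "nosZ_clade": ["I", "none", "II", "II"],
            }
        )

    def test_one_of_each_gives_quarter_shares(self):
        summary = summarize_types(self.four_types_table())
        for t in ("complete", "initiator", "terminator", "initiator_terminator"):
            assert summary[f"prop_{t}"][0] == pytest.approx(0.25)
        assert summary["denitrifier_fraction"][0] == pytest.approx(1.0)

    def test_constant_grouping_equals_ungrouped(self):
        table = self.four_types_table()
        grouped = summarize_types(table, group_by="group")
        ungrouped = summarize_types(table)
        for col in grouped.columns:
            if col != "group":
                assert grouped[col][0] == pytest.approx(ungrouped[col][0])

    def test_permutation_invariance_and_unit_sum(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(
            {
                "denitrifier_type": rng.choice(
                    [t.value for t in DenitrifierType], 100
                )
            }
        )
        a = summarize_types(table)
        b = summarize_types(table.sample(frac=1.0, random_state=1))
        pd.testing.assert_frame_equal(a, b)
        prop_cols = [c for c in a.columns if c.startswith("prop_")]
        assert a[prop_cols].to_numpy().sum() == pytest.approx(1.0, abs=1e-9)

    def test_unknown_group_column(self):
        with pytest.raises(KeyError):
            summarize_types(self.four_types_table(), group_by="no_such")

    def test_clade_cross_table_reports_both_conditionals(self):
        table = self.four_types_table()
        cross = nosz_clade_cross_table(table).set_index("clade")
        assert cross.loc["I", "p_complete_given_clade"] == pytest.approx(1.0)
        assert cross.loc["II", "p_complete_given_clade"] == pytest.approx(0.0)
        assert cross.loc["I", "p_clade_given_complete"] == pytest.approx(1.0)


class TestScalarTraits:
    def test_density_arithmetic(self):
        assert trait_density(340, 5_000_000) == pytest.approx(68.0)
        assert trait_density(0, 123) == 0.0

    def test_density_domain_error(self):
        with pytest.raises(DataError):
            trait_density(10, 0)

    @pytest.mark.parametrize(
        "rate,expected", [(0.46, "fast"), (0.1, "slow"), (0.2, "fast")]
    )
    def test_growth_binning(self, rate, expected):
        assert bin_growth_rate(rate) == expected

    def test_negative_rate_rejected(self):
        with pytest.raises(DataError):
            bin_growth_rate(-0.1)


def oracle_rank_stats(values, groups):
    """Brute-force Kruskal-Wallis + Dunn from the textbook formulas."""
    values = list(map(float, values))
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    labels = sorted(set(groups), key=list(groups).index)
    sums = {g: 0.0 for g in labels}
    sizes = {g: 0 for g in labels}
    for r, g in zip(ranks, groups):
        sums[g] += r
        sizes[g] += 1
    h = 12 / (n * (n + 1)) * sum(
        sums[g] ** 2 / sizes[g] for g in labels
    ) - 3 * (n + 1)
    ties = {}
    for v in values:
        ties[v] = ties.get(v, 0) + 1
    tie_sum = sum(t**3 - t for t in ties.values())
    correction = 1 - tie_sum / (n**3 - n)
    h_corrected = h / correction if correction > 0 else 0.0
    dunn = {}
    for a, b in itertools.combinations(labels, 2):
        se = math.sqrt(
            (n * (n + 1) / 12 - tie_sum / (12 * (n - 1)))
            * (1 / sizes[a] + 1 / sizes[b])
        )
        mean_a = sums[a] / sizes[a]
        mean_b = sums[b] / sizes[b]
        z = (mean_a - mean_b) / se if se > 0 else 0.0
        dunn[(a, b)] = (z, 2 * stats.norm.sf(abs(z)))
    return h_corrected, dunn


class TestRankComparison:
    def test_identical_groups_share_letter(self):
        result = compare_groups_ranked([1, 2, 3, 1, 2, 3], list("aaabbb"))
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.letters["a"] == result.letters["b"]

    def test_tie_floor_collapses_subthreshold_ranks(self):
        result = compare_groups_ranked(
            [0.05, 0.10, 0.15, 0.19], list("aabb"), tie_floor=0.2
        )
        assert result.statistic == 0.0
        assert result.p_value == 1.0

    def test_matches_rank_oracle_on_random_batteries(self):
        rng = np.random.default_rng(8)
        for _ in range(40):
            k = rng.integers(2, 5)
            sizes = rng.integers(2, 5, k)
            values, groups = [], []
            for gi, size in enumerate(sizes):
                # integer values force ties
                values.extend(rng.integers(0, 6, size).tolist())
                groups.extend([f"g{gi}"] * size)
            if np.ptp(values) == 0:
                continue
            result = compare_groups_ranked(values, groups)
            h_oracle, dunn_oracle = oracle_rank_stats(values, groups)
            assert result.statistic == pytest.approx(h_oracle, abs=1e-9)
            for row in result.pairwise.itertuples():
                z, p = dunn_oracle[(row.group_a, row.group_b)]
                assert row.z == pytest.approx(z, abs=1e-9)
                assert row.p_raw == pytest.approx(p, abs=1e-9)

    def test_matches_scipy_without_tie_floor(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=30)
        groups = np.repeat(["a", "b", "c"], 10)
        result = compare_groups_ranked(values, groups)
        expected = stats.kruskal(*(values[groups == g] for g in "abc"))
        assert result.statistic == pytest.approx(expected.statistic, abs=1e-9)
        assert result.p_value == pytest.approx(expected.pvalue, abs=1e-9)

    def test_bh_adjustment_monotone_and_ordered(self):
        rng = np.random.default_rng(10)
        values = np.concatenate(
            [rng.normal(0, 1, 8), rng.normal(3, 1, 8), rng.normal(6, 1, 8)]
        )
        groups = np.repeat(["a", "b", "c"], 8)
        result = compare_groups_ranked(values, groups)
        assert (result.pairwise["p_adjusted"] >= result.pairwise["p_raw"]).all()
        from statsmodels.stats.multitest import multipletests

        _, expected, _, _ = multipletests(
            result.pairwise["p_raw"], method="fdr_bh"
        )
        np.testing.assert_allclose(result.pairwise["p_adjusted"], expected)

    def test_well_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(11)
        values = np.concatenate([rng.normal(0, 0.1, 20), rng.normal(10, 0.1, 20)])
        groups = np.repeat(["lo", "hi"], 20)
        result = compare_groups_ranked(values, groups)
        assert set(result.letters["lo"]).isdisjoint(result.letters["hi"])

    def test_letters_partition_every_group(self):
        rng = np.random.default_rng(12)
        values = rng.normal(size=24)
        groups = np.repeat(["a", "b", "c", "d"], 6)
        result = compare_groups_ranked(values, groups)
        assert all(result.letters[g] for g in "abcd")

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups_ranked([1, 2, 3], ["a", "a", "a"])


class TestOneSidedKS:
    def test_identical_samples(self):
        d, p = compare_counts_ks([1, 2, 3, 4], [1, 2, 3, 4])
        assert d == 0.0
        assert p == 1.0

    def test_shifted_sample_detected(self):
        a = list(range(10, 30))
        b = [x - 10 for x in a]  # stochastically smaller
        d, p = compare_counts_ks(a, b)
        assert d > 0.4
        assert p < 0.01

    def test_matches_ecdf_enumeration(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            a = rng.integers(0, 8, rng.integers(3, 12)).tolist()
            b = rng.integers(0, 8, rng.integers(3, 12)).tolist()
            d, _ = compare_counts_ks(a, b)
            support = sorted(set(a) | set(b))
            d_oracle = max(
                max(
                    sum(x <= s for x in b) / len(b)
                    - sum(x <= s for x in a) / len(a)
                    for s in support
                ),
                0.0,
            )
            assert d == pytest.approx(d_oracle, abs=1e-12)

    def test_matches_scipy_one_sided_statistic(self):
        rng = np.random.default_rng(14)
        a = rng.poisson(5, 25).tolist()
        b = rng.poisson(3, 30).tolist()
        d, _ = compare_counts_ks(a, b)
        expected = stats.ks_2samp(b, a, alternative="greater")
        assert d == pytest.approx(expected.statistic, abs=1e-12)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_counts_ks([1], [1, 2])
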