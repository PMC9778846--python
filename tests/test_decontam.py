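"""QC gates, the four decontamination steps and their exact-test oracle."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from calcmicro import (
    FeatureTable,
    SampleMetadata,
    SimConfig,
    abundance_zero_filter,
    contaminant_list_filter,
    decontaminate,
    estimate_source_proportions_nnls,
    filter_low_oral_samples,
    filter_low_read_samples,
    museum_exceedance_filter,
    partition_reads_by_reference,
    prevalence_contaminant_score,
    prevalence_contaminants,
    simulate_profiles,
)


def meta_frame(rows):
    return SampleMetadata(pd.DataFrame.from_dict(rows, orient="index"))


class TestReadCountGate:
    def test_thresholds_and_control_exemption(self):
        meta = meta_frame(
            {
                "below": dict(role="calculus", read_count=299_999),
                "at": dict(role="calculus", read_count=300_000),
                "blank": dict(role="extraction_blank", read_count=19),
                "ctrl": dict(role="museum_control", read_count=5),
            }
        )
        kept = set(filter_low_read_samples(meta))
        assert kept == {"at", "blank", "ctrl"}

    def test_missing_read_count_names_sample(self):
        meta = meta_frame(
            {"a": dict(role="calculus", read_count=1e6),
             "b": dict(role="calculus", read_count=np.nan)}
        )
        with pytest.raises(ValueError, match="b"):
            filter_low_read_samples(meta)


class TestOralProportionGate:
    def test_three_percent_rule(self):
        props = pd.DataFrame(
            {
                "oral": [0.029, 0.031, 0.0],
                "soil": [0.5, 0.5, 0.2],
                "unknown": [0.471, 0.469, 0.8],
            },
            index=["low", "ok", "none"],
        )
        assert list(filter_low_oral_samples(props)) == ["ok"]

    def test_simplex_violation_rejected(self):
        props = pd.DataFrame({"oral": [0.5], "soil": [0.2]}, index=["x"])
        with pytest.raises(ValueError, match="sum to 1"):
            filter_low_oral_samples(props)


class TestSourceProportionsNnls:
    def _refs(self, rng):
        taxa = [f"t{i}" for i in range(40)]
        refs = pd.DataFrame(
            {
                "oral": rng.dirichlet(np.ones(40)),
                "soil": rng.dirichlet(np.ones(40)),
            },
            index=taxa,
        )
        return taxa, refs

    def test_self_recovery(self):
        rng = np.random.default_rng(0)
        taxa, refs = self._refs(rng)
        counts = pd.DataFrame({"s": (refs["oral"] * 1e6).round().astype(int)})
        props = estimate_source_proportions_nnls(counts, refs)
        assert props.loc["s", "oral"] >= 0.99

    def test_fifty_fifty_mixture(self):
        rng = np.random.default_rng(1)
        taxa, refs = self._refs(rng)
        mix = 0.5 * refs["oral"] + 0.5 * refs["soil"]
        counts = pd.DataFrame({"s": (mix * 1e6).round().astype(int)})
        props = estimate_source_proportions_nnls(counts, refs)
        assert props.loc["s", "oral"] == pytest.approx(0.5, abs=0.01)
        assert props.loc["s", "soil"] == pytest.approx(0.5, abs=0.01)

    def test_orthogonal_profile_reported_unknown(self):
        rng = np.random.default_rng(2)
        taxa, refs = self._refs(rng)
        refs.iloc[20:, :] = 0.0  # references live on the first 20 taxa
        refs = refs / refs.sum(axis=0)
        noise = np.zeros(40)
        noise[20:] = rng.dirichlet(np.ones(20))
        counts = pd.DataFrame({"s": (pd.Series(noise, index=taxa) * 1e6).astype(int)})
        props = estimate_source_proportions_nnls(counts, refs)
        assert props.loc["s", "unknown"] >= 0.9

    def test_empty_overlap_rejected(self):
        refs = pd.DataFrame({"oral": [1.0]}, index=["only_ref"])
        counts = pd.DataFrame({"s": [5]}, index=["only_sample"])
        with pytest.raises(ValueError, match="shared"):
            estimate_source_proportions_nnls(counts, refs)


class TestPrevalenceScore:
    def test_worked_hypergeometric_example(self):
        """3/3 blanks and 1/10 samples: P(X >= 3) = C(4,3)/C(13,3)."""
        counts = pd.DataFrame(
            {**{f"b{i}": [1] for i in range(3)},
             **{f"s{i}": [1 if i == 0 else 0] for i in range(10)}},
            index=["taxon"],
        )
        score = prevalence_contaminant_score(
            counts, [f"b{i}" for i in range(3)], [f"s{i}" for i in range(10)]
        )
        expected = comb(4, 3) / comb(13, 3)
        assert score["taxon"] == pytest.approx(expected)
        assert expected < 0.2  # called a contaminant at the 0.2 threshold

    def test_absent_from_blanks_scores_one(self):
        counts = pd.DataFrame(
            {"b1": [0], "b2": [0], "s1": [9], "s2": [0]}, index=["taxon"]
        )
        score = prevalence_contaminant_score(counts, ["b1", "b2"], ["s1", "s2"])
        assert score["taxon"] == pytest.approx(1.0)

    def test_exhaustive_hypergeometric_oracle(self):
        """Score equals the exact tail sum of the hypergeometric pmf for every
        2x2 table with both margins <= 12."""
        for nb, ns in itertools.product(range(1, 7), range(1, 7)):
            for b in range(nb + 1):
                for s in range(ns + 1):
                    cols = {f"b{i}": [1 if i < b else 0] for i in range(nb)}
                    cols.update({f"s{i}": [1 if i < s else 0] for i in range(ns)})
                    counts = pd.DataFrame(cols, index=["t"])
                    score = prevalence_contaminant_score(
                        counts, [f"b{i}" for i in range(nb)],
                        [f"s{i}" for i in range(ns)],
                    )["t"]
                    n, k = nb + ns, b + s
                    oracle = sum(
                        comb(k, x) * comb(n - k, nb - x) / comb(n, nb)
                        for x in range(b, min(k, nb) + 1)
                    )
                    assert score == pytest.approx(oracle, abs=1e-12), (nb, ns, b, s)

    def test_union_across_datasets(self):
        """A taxon flagged in one dataset is removed from the full table."""
        counts = pd.DataFrame(
            {
                # dataset A: 3/3 blanks, 0/6 samples -> strongly blank-enriched
                **{f"ab{i}": [1, 0] for i in range(3)},
                **{f"as{i}": [0, 1] for i in range(6)},
                # dataset B: absent from blanks
                **{f"bb{i}": [0, 0] for i in range(2)},
                **{f"bs{i}": [1, 1] for i in range(6)},
            },
            index=["flagged_in_A", "clean"],
        )
        rows = {}
        for c in counts.columns:
            rows[c] = dict(
                role="extraction_blank" if c[1] == "b" else "calculus",
                dataset="A" if c[0] == "a" else "B",
            )
        meta = meta_frame(rows)
        contaminants, scores = prevalence_contaminants(
            FeatureTable(counts), meta, thresholds={"A": 0.2, "B": 0.2}
        )
        assert contaminants == {"flagged_in_A"}
        assert set(scores.columns) == {"A", "B"}

    def test_dataset_without_blanks_skipped_with_warning(self):
        counts = pd.DataFrame({"s1": [1], "s2": [1]}, index=["t"])
        meta = meta_frame(
            {"s1": dict(role="calculus", dataset="A"),
             "s2": dict(role="calculus", dataset="A")}
        )
        with pytest.warns(UserWarning, match="no blanks"):
            contaminants, _ = prevalence_contaminants(FeatureTable(counts), meta)
        assert contaminants == set()


class TestAbundanceZeroFilter:
    def test_boundary_cases(self):
        counts = pd.DataFrame(
            {"s": [4, 5, 99_991]}, index=["below", "at", "big"]
        )  # total 100,000: 4e-5 zeroed, 5e-5 kept (strict "<")
        out = abundance_zero_filter(FeatureTable(counts))
        assert out.counts.loc["below", "s"] == 0
        assert out.counts.loc["at", "s"] == 5
        assert out.counts.loc["big", "s"] == 99_991

    def test_no_cell_below_threshold_is_identity(self):
        counts = pd.DataFrame({"s": [50, 50]}, index=["a", "b"])
        out = abundance_zero_filter(FeatureTable(counts))
        pd.testing.assert_frame_equal(out.counts, counts)


class TestMuseumExceedance:
    def _table_meta(self, ctrl, samp):
        counts = pd.DataFrame(
            {"c1": [ctrl[0], 100], "c2": [ctrl[1], 100],
             "s1": [samp[0], 100], "s2": [samp[1], 100]},
            index=["taxon", "filler"],
        )
        meta = meta_frame(
            {"c1": dict(role="museum_control"), "c2": dict(role="museum_control"),
             "s1": dict(role="calculus"), "s2": dict(role="calculus")}
        )
        return FeatureTable(counts), meta

    def test_exceeding_taxon_removed(self):
        table, meta = self._table_meta(ctrl=(10, 0), samp=(1, 0))
        assert museum_exceedance_filter(table, meta) == {"taxon"}

    def test_absent_from_controls_retained(self):
        # s2 is pure filler so the filler taxon ties (not exceeds) the controls
        table, meta = self._table_meta(ctrl=(0, 0), samp=(5, 0))
        assert museum_exceedance_filter(table, meta) == set()

    def test_equality_retained_strict_rule(self):
        table, meta = self._table_meta(ctrl=(10, 0), samp=(10, 0))
        assert museum_exceedance_filter(table, meta) == set()

    def test_no_controls_warns_noop(self):
        counts = pd.DataFrame({"s1": [1], "s2": [2]}, index=["t"])
        meta = meta_frame({"s1": dict(role="calculus"), "s2": dict(role="calculus")})
        with pytest.warns(UserWarning, match="no museum controls"):
            assert museum_exceedance_filter(FeatureTable(counts), meta) == set()


class TestContaminantListFilter:
    def _table(self):
        counts = pd.DataFrame(
            {"s": [5, 5, 5, 5]},
            index=["Listed spA", "Dual spB", "Dual spC", "Clean spD"],
        )
        return FeatureTable(counts)

    def test_listed_genus_not_oral_removed(self):
        removed, _ = contaminant_list_filter(self._table(), {"Listed"}, set())
        assert removed == {"Listed spA"}

    def test_oral_listed_genus_rescued_by_damage(self):
        removed, rescued = contaminant_list_filter(
            self._table(), {"Listed", "Dual"}, {"Dual"},
            damage_calls={"Dual spB": "authentic", "Dual spC": "not_authentic"},
        )
        assert removed == {"Listed spA", "Dual spC"}
        assert rescued == {"Dual spB": "damage_authentic"}

    def test_untestable_species_retained(self):
        removed, rescued = contaminant_list_filter(
            self._table(), {"Dual"}, {"Dual"}, damage_calls={}
        )
        assert removed == set()
        assert rescued == {
            "Dual spB": "untestable_retained", "Dual spC": "untestable_retained"
        }


class TestPartitionReads:
    def test_count_arithmetic(self):
        labels = {f"r{i}": lab for i, lab in enumerate(
            ["contaminant"] * 3 + ["noncontaminant"] * 5 + ["unmapped"] * 2
        )}
        kept, counts = partition_reads_by_reference(labels)
        assert len(kept) == 7
        assert counts == {"contaminant": 3, "noncontaminant": 5, "unmapped": 2}

    def test_all_unmapped_kept_and_empty_input(self):
        kept, counts = partition_reads_by_reference({f"r{i}": "unmapped" for i in range(10)})
        assert len(kept) == 10
        kept, counts = partition_reads_by_reference({})
        assert kept == [] and sum(counts.values()) == 0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="host"):
            partition_reads_by_reference({"r1": "host"})


class TestDecontaminatePipeline:
    def test_each_removal_names_one_step(self, study):
        table, meta, gt = study
        filtered, report = decontaminate(
            table, meta, contaminant_genera=gt.contaminant_genera,
            oral_genera=gt.oral_genera,
        )
        steps = {"prevalence", "abundance_zeroed", "museum_exceedance",
                 "contaminant_list"}
        assert set(report.removals.unique()) <= steps
        assert set(report.removals.index).isdisjoint(set(filtered.taxa))
        # retained contaminant-list taxa carry a rescue reason
        listed_kept = [t for t in filtered.taxa
                       if filtered.taxonomy.loc[t, "genus"] in set(gt.contaminant_genera)]
        assert set(listed_kept) <= set(report.rescues)

    def test_idempotent_on_own_output(self, study):
        table, meta, gt = study
        filtered, _ = decontaminate(
            table, meta, contaminant_genera=gt.contaminant_genera,
            oral_genera=gt.oral_genera,
        )
        with pytest.warns(UserWarning):
            again, report2 = decontaminate(
                filtered, meta.select(filtered.samples),
                contaminant_genera=gt.contaminant_genera,
                oral_genera=gt.oral_genera,
            )
        pd.testing.assert_frame_equal(again.counts, filtered.counts)
        assert len(report2.removals) == 0

    def test_synthetic_recovery_over_ten_seeds(self):
        """>= 90% of true laboratory contaminants removed and >= 90% of true
        oral taxa retained, averaged over 10 seeds."""
        recalls, retentions = [], []
        for seed in range(10):
            table, meta, gt = simulate_profiles(SimConfig(seed=seed))
            filtered, _ = decontaminate(
                table, meta, contaminant_genera=gt.contaminant_genera,
                oral_genera=gt.oral_genera,
            )
            lab = set(gt.laboratory_taxa)
            oral = set(gt.oral_taxa)
            recalls.append(len(lab - set(filtered.taxa)) / len(lab))
            retentions.append(len(oral & set(filtered.taxa)) / len(oral))
        assert np.mean(recalls) >= 0.9
        assert np.mean(retentions) >= 0.9
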