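import numpy as np
import pandas as pd
import pytest

import methcall as mc
from methcall.diffmeth import (
    ContrastSpec,
    DiffMethConfig,
    DifferentialMethylation,
    aggregate_to_genes,
    call_probes,
    consensus_across_references,
    criterion_meandiff,
    criterion_threshold,
    rank_genes,
    run_subgroup_contrast,
)


def _bm(rows: dict, samples: list[str]) -> mc.BetaMatrix:
    return mc.BetaMatrix(pd.DataFrame(rows, index=samples).T)


def _gene_calls(entries):
    """entries: {gene: (direction, frac, delta)}"""
    df = pd.DataFrame.from_dict(
        {
            g: {
                "direction": d,
                "supporting_probes": "p",
                "n_supporting": 1,
                "best_fraction_cases": f,
                "max_abs_meandiff": m,
                "ambiguous": d == "ambiguous",
            }
            for g, (d, f, m) in entries.items()
        },
        orient="index",
    )
    df.index.name = "gene_symbol"
    return df


class TestCriterionThreshold:
    def test_hyper_when_refs_low_and_enough_cases_high(self):
        case = [0.8, 0.9, 0.78] + [0.1] * 18  # 3/21 = 0.143 >= 0.10
        assert criterion_threshold([0.10, 0.15], case) == "hyper"

    def test_hypo_boundary_fraction_is_inclusive(self):
        case = [0.1, 0.2] + [0.9] * 18  # 2/20 = 0.10 exactly
        assert criterion_threshold([0.90, 0.92], case) == "hypo"

    def test_flat_profile_not_called(self):
        assert criterion_threshold([0.5, 0.5], [0.5] * 10) == "none"

    def test_reference_condition_requires_all_samples(self):
        # one heterogeneous reference breaks the strict consensus
        case = [0.9] * 10
        assert criterion_threshold([0.1, 0.5], case) == "none"

    def test_missing_values_ignored(self):
        case = [0.9, 0.8, np.nan, np.nan]  # 2/2 non-missing above
        assert criterion_threshold([0.1, np.nan], case) == "hyper"


class TestCriterionMeandiff:
    def test_pass_with_signed_delta(self):
        passes, delta = criterion_meandiff([0.30], [0.60])
        assert passes and delta == pytest.approx(0.30)

    def test_boundary_is_strict(self):
        passes, delta = criterion_meandiff([0.25, 0.25], [0.50, 0.50])
        assert delta == pytest.approx(0.25) and not passes

    def test_identical_groups_fail(self):
        passes, delta = criterion_meandiff([0.4, 0.6], [0.4, 0.6])
        assert not passes and delta == 0.0


class TestCallProbes:
    def test_overlapping_groups_rejected(self, tiny_beta):
        with pytest.raises(ValueError, match="overlap"):
            call_probes(tiny_beta, ["s1", "s2"], ["s2", "s3"])

    def test_planted_full_penetrance_recovered(self, small_dataset):
        ds = small_dataset
        case = list(ds.sheet.index[ds.sheet["group"] == "NB"])
        refs = mc.reference_groups(ds.sheet)["GN_GNB"]
        calls = call_probes(ds.beta, case, refs, DiffMethConfig(seed=1))
        planted = {p for g in ds.truth.planted_genes
                   for p in ds.truth.planted_probes[g]}
        called = set(calls.index[calls["direction"] != "none"])
        # no false positives at probe level; reference-noise may drop single
        # probes, but every planted gene is recovered via the any-probe rule
        assert called <= planted
        genes = aggregate_to_genes(calls, ds.annotation)
        assert set(genes.index) == set(ds.truth.planted_genes)
        for g in ds.truth.hyper_genes:
            assert genes.loc[g, "direction"] == "hyper"

    def test_single_reference_skips_test(self, small_dataset):
        ds = small_dataset
        case = list(ds.sheet.index[ds.sheet["group"] == "NB"])
        calls = call_probes(ds.beta, case, mc.reference_groups(ds.sheet)["FB"],
                            DiffMethConfig(seed=1))
        assert calls["test_skipped"].all()
        assert calls["crit_test"].isna().all()
        assert calls["q_fdr"].isna().all()
        # consensus then rests on the threshold + mean-shift criteria
        planted = {p for g in ds.truth.planted_genes
                   for p in ds.truth.planted_probes[g]}
        assert planted <= set(calls.index[calls["direction"] != "none"])

    def test_partial_penetrance_called_via_threshold_and_meandiff(self):
        # shift to ~0.9 in half of 20 cases against 2 unmethylated refs
        rng = np.random.default_rng(0)
        samples = [f"c{i}" for i in range(20)] + ["r1", "r2"]
        case_vals = np.concatenate([rng.uniform(0.85, 0.95, 10),
                                    rng.uniform(0.05, 0.15, 10)])
        beta = _bm({"p1": np.concatenate([case_vals, [0.08, 0.12]])}, samples)
        calls = call_probes(beta, samples[:20], ["r1", "r2"])
        assert calls.loc["p1", "direction"] == "hyper"
        assert calls.loc["p1", "fraction_cases_shifted"] == pytest.approx(0.5)
        assert calls.loc["p1", "test_skipped"]

    def test_direction_must_agree_between_criteria(self):
        # threshold criterion says hyper, but the mean shift is too small
        samples = [f"c{i}" for i in range(10)] + ["r1", "r2"]
        vals = np.array([0.8] + [0.12] * 9 + [0.1, 0.1])
        beta = _bm({"p1": vals}, samples)
        calls = call_probes(beta, samples[:10], ["r1", "r2"])
        assert calls.loc["p1", "crit_threshold"]
        assert not calls.loc["p1", "crit_meandiff"]
        assert calls.loc["p1", "direction"] == "none"

    def test_calls_invariant_to_row_and_column_order(self, small_dataset):
        ds = small_dataset
        case = list(ds.sheet.index[ds.sheet["group"] == "NB"])
        refs = mc.reference_groups(ds.sheet)["GN_GNB"]
        cfg = DiffMethConfig(seed=3)
        base = call_probes(ds.beta, case, refs, cfg)
        rng = np.random.default_rng(0)
        b = ds.beta.beta
        shuffled = mc.BetaMatrix(
            b.iloc[rng.permutation(len(b)), rng.permutation(b.shape[1])]
        )
        redo = call_probes(shuffled, case, refs, cfg)
        pd.testing.assert_series_equal(
            base["direction"].sort_index(), redo["direction"].sort_index()
        )

    def test_monotone_in_mean_diff_threshold(self, small_dataset):
        ds = small_dataset
        case = list(ds.sheet.index[ds.sheet["group"] == "NB"])
        refs = mc.reference_groups(ds.sheet)["GN_GNB"]
        loose = call_probes(ds.beta, case, refs, DiffMethConfig(mean_diff=0.25, seed=1))
        strict = call_probes(ds.beta, case, refs, DiffMethConfig(mean_diff=0.40, seed=1))
        n_loose = (loose["direction"] != "none").sum()
        n_strict = (strict["direction"] != "none").sum()
        assert n_strict <= n_loose

    def test_model_results_summary(self, small_dataset):
        ds = small_dataset
        case = list(ds.sheet.index[ds.sheet["group"] == "NB"])
        refs = mc.reference_groups(ds.sheet)["GN_GNB"]
        model = DifferentialMethylation(ds.beta, case, refs, ds.annotation,
                                        DiffMethConfig(seed=1))
        res = model.fit()
        text = res.summary()
        assert "consensus hypoM" in text and str(len(case)) in text
        genes = res.gene_calls()
        assert set(ds.truth.planted_genes) == set(genes.index)


class TestGeneAggregation:
    def _ann(self, mapping):
        ann = pd.DataFrame(index=list(mapping))
        ann["gene_symbol"] = [mapping[p] for p in mapping]
        ann["chromosome"] = "1"
        ann["cytoband"] = "1p36"
        ann["position"] = pd.array(range(len(mapping)), dtype="Int64")
        ann["promoter_class"] = "UNKNOWN"
        ann["is_pcg_target"] = False
        ann["is_gonosomal"] = False
        return ann

    def _calls(self, directions, fracs=None, deltas=None):
        idx = list(directions)
        n = len(idx)
        return pd.DataFrame(
            {
                "direction": [directions[p] for p in idx],
                "fraction_cases_shifted": fracs or [0.5] * n,
                "delta": deltas or [0.3] * n,
            },
            index=idx,
        )

    def test_any_probe_rule(self):
        calls = self._calls({"p1": "hyper", "p2": "none"})
        genes = aggregate_to_genes(calls, self._ann({"p1": "G1", "p2": "G1"}))
        assert genes.loc["G1", "direction"] == "hyper"
        assert genes.loc["G1", "n_supporting"] == 1

    def test_conflicting_probes_flagged_ambiguous(self):
        calls = self._calls({"p1": "hyper", "p2": "hypo"})
        genes = aggregate_to_genes(calls, self._ann({"p1": "G1", "p2": "G1"}))
        assert genes.loc["G1", "direction"] == "ambiguous"
        assert genes.loc["G1", "ambiguous"]

    def test_unannotated_called_probe_warns(self):
        calls = self._calls({"p1": "hyper", "px": "hyper"})
        with pytest.warns(UserWarning, match="lack annotation"):
            genes = aggregate_to_genes(calls, self._ann({"p1": "G1"}))
        assert list(genes.index) == ["G1"]

    def test_statistics_take_best_probe(self):
        calls = self._calls({"p1": "hypo", "p2": "hypo"},
                            fracs=[0.4, 0.8], deltas=[-0.3, -0.6])
        genes = aggregate_to_genes(calls, self._ann({"p1": "G1", "p2": "G1"}))
        assert genes.loc["G1", "best_fraction_cases"] == pytest.approx(0.8)
        assert genes.loc["G1", "max_abs_meandiff"] == pytest.approx(0.6)


class TestConsensus:
    def test_identical_sets(self):
        gc = _gene_calls({"A": ("hyper", 0.5, 0.3), "B": ("hypo", 0.5, 0.3)})
        res = consensus_across_references([gc, gc.copy(), gc.copy()])
        assert res.hyper == ["A"] and res.hypo == ["B"]

    def test_set_arithmetic(self):
        g1 = _gene_calls({g: ("hypo", 0.5, 0.3) for g in "ABC"})
        g2 = _gene_calls({g: ("hypo", 0.5, 0.3) for g in "BC"})
        g3 = _gene_calls({g: ("hypo", 0.5, 0.3) for g in "BCD"})
        res = consensus_across_references([g1, g2, g3])
        assert res.hypo == ["B", "C"] and res.hyper == []

    def test_direction_conflict_excluded(self):
        g1 = _gene_calls({"A": ("hyper", 0.5, 0.3)})
        g2 = _gene_calls({"A": ("hyper", 0.5, 0.3)})
        g3 = _gene_calls({"A": ("hypo", 0.5, 0.3)})
        res = consensus_across_references([g1, g2, g3])
        assert res.hyper == [] and res.hypo == []

    def test_venn_regions_reported(self):
        g1 = _gene_calls({"A": ("hyper", 0.5, 0.3), "B": ("hyper", 0.5, 0.3)})
        g2 = _gene_calls({"B": ("hyper", 0.5, 0.3)})
        res = consensus_across_references([g1, g2], names=["FB", "AG"])
        excl = res.exclusive_to("FB")
        assert list(excl.index) == ["A"]
        assert res.regions.loc["B", ["FB", "AG"]].all()

    def test_consensus_never_larger_than_smallest_input(self):
        rng = np.random.default_rng(5)
        pools = []
        for _ in range(3):
            genes = rng.choice([f"G{i}" for i in range(30)], size=15, replace=False)
            pools.append(_gene_calls({g: ("hypo", 0.5, 0.3) for g in genes}))
        res = consensus_across_references(pools)
        assert len(res.hyper) + len(res.hypo) <= min(len(p) for p in pools)

    def test_single_input_rejected(self):
        with pytest.raises(ValueError, match="at least two"):
            consensus_across_references([_gene_calls({"A": ("hyper", 0.5, 0.3)})])


class TestRanking:
    def test_fraction_dominates(self):
        gc = _gene_calls({"AAA": ("hyper", 0.5, 0.9), "BBB": ("hyper", 0.8, 0.3)})
        ranked = rank_genes(gc)
        assert list(ranked.index) == ["BBB", "AAA"]
        assert list(ranked["rank"]) == [1, 2]

    def test_meandiff_breaks_fraction_ties(self):
        gc = _gene_calls({"AAA": ("hyper", 0.5, 0.4), "BBB": ("hyper", 0.5, 0.6)})
        assert list(rank_genes(gc).index) == ["BBB", "AAA"]

    def test_full_tie_alphabetical(self):
        gc = _gene_calls({"ZZZ": ("hyper", 0.5, 0.4), "AAA": ("hyper", 0.5, 0.4)})
        assert list(rank_genes(gc).index) == ["AAA", "ZZZ"]

    def test_ambiguous_excluded(self):
        gc = _gene_calls({"AAA": ("ambiguous", 0.9, 0.9), "BBB": ("hyper", 0.5, 0.4)})
        assert list(rank_genes(gc).index) == ["BBB"]


class TestSubgroupContrasts:
    def _sheet(self):
        # 21 tumors mirroring the study's age structure: 16 below 5 years
        ages = [3, 6, 9, 12, 15, 17, 20, 24, 28, 30, 36, 40, 44, 50, 55, 59,
                62, 70, 80, 100, 120]
        rows = {}
        for i, age in enumerate(ages):
            stage = "4" if i < 6 else ("4S" if i < 10 else str(1 + i % 3))
            mycn = "amplified" if i < 5 else "non_amplified"
            rows[f"NB{i + 1:02d}"] = {
                "group": "NB", "inss_stage": stage, "mycn": mycn,
                "age_months": float(age),
            }
        sheet = pd.DataFrame.from_dict(rows, orient="index")
        sheet["risk"] = [mc.derive_risk(s, m)
                         for s, m in zip(sheet["inss_stage"], sheet["mycn"])]
        return sheet

    def test_age_cutoff_partitions_16_vs_5(self):
        spec = ContrastSpec(group_by="age", age_cutoff_months=60)
        case, ref = spec.select(self._sheet())
        assert len(case) == 16 and len(ref) == 5

    def test_hr_lr_groups_disjoint(self):
        sheet = self._sheet()
        spec = ContrastSpec(group_by="risk", case_levels=("HR",), ref_levels=("LR",))
        case, ref = spec.select(sheet)
        assert set(case).isdisjoint(ref)
        assert all(sheet.loc[s, "risk"] == "HR" for s in case)
        assert all(sheet.loc[s, "risk"] == "LR" for s in ref)

    def test_empty_subgroup_errors(self):
        spec = ContrastSpec(group_by="mycn", case_levels=("amplified",),
                            ref_levels=("no_such_level",))
        with pytest.raises(ValueError, match="empty subgroup"):
            spec.select(self._sheet())

    def test_subgroup_signal_recovered_only_in_matching_contrast(self):
        cfg = mc.SyntheticConfig(
            n_genes=80, n_planted_hyper=0, n_planted_hypo=0,
            subgroup_specs=(("mycn", "amplified", 4, "hyper"),),
            seed=11,
        )
        ds = mc.generate(cfg)
        planted = set(ds.truth.subgroup_genes["mycn=amplified:hyper"])
        dm_cfg = DiffMethConfig(seed=11)
        match = run_subgroup_contrast(
            ds.beta, ds.sheet,
            ContrastSpec(group_by="mycn", case_levels=("amplified",),
                         ref_levels=("non_amplified",)),
            dm_cfg, annotation=ds.annotation,
        )
        found = set(match.gene_calls.index[match.gene_calls["direction"] == "hyper"])
        assert planted <= found
        mismatch = run_subgroup_contrast(
            ds.beta, ds.sheet,
            ContrastSpec(group_by="age", age_cutoff_months=18),
            dm_cfg, annotation=ds.annotation,
        )
        found_age = set(mismatch.gene_calls.index) if mismatch.gene_calls is not None else set()
        assert not (planted & found_age)

    def test_reference_consistency_flag(self):
        cfg = mc.SyntheticConfig(
            n_genes=60, n_planted_hyper=0, n_planted_hypo=0,
            subgroup_specs=(("mycn", "amplified", 3, "hyper"),),
            seed=13,
        )
        ds = mc.generate(cfg)
        refs = [s for s in ds.sheet.index if ds.sheet.loc[s, "group"] != "NB"]
        res = run_subgroup_contrast(
            ds.beta, ds.sheet,
            ContrastSpec(group_by="mycn", case_levels=("amplified",),
                         ref_levels=("non_amplified",)),
            DiffMethConfig(seed=13), annotation=ds.annotation,
            reference_ids=refs,
        )
        called = res.probe_calls[res.probe_calls["direction"] != "none"]
        # subgroup signal is absent from the normal references -> consistent
        assert called["ref_consistent"].all()
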