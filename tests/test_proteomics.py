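"""LFQ ratio analysis: parsing, ratio/status classification, the
Gaussian null fit, outlier calling, per-experiment consistency and
annotation."""

import io
import math

import numpy as np
import pandas as pd
import pytest

from mitocme import synthetic
from mitocme.proteomics import (
    CcsRatioModel,
    GaussianFitError,
    annotate,
    call_outliers,
    compute_ratios,
    fit_gaussian_null,
    per_experiment_consistency,
    read_protein_groups,
)
from mitocme.synthetic import ExclusiveSpec, LfqGenSpec, OutlierSpec


def _fixture_table(rows):
    cols = ["Protein IDs", "Gene names"] + [
        f"LFQ intensity {c}_{e}" for c in ("interphase", "mitotic") for e in (1, 2, 3, 4)
    ]
    return pd.DataFrame(rows, columns=cols)


@pytest.fixture
def six_protein_file(tmp_path):
    rows = []
    for i in range(6):
        rows.append([f"P{i}", f"G{i}"] + [1e7 * (i + 1)] * 8)
    path = tmp_path / "proteinGroups.txt"
    _fixture_table(rows).to_csv(path, sep="\t", index=False)
    return path


class TestReader:
    def test_fixture_round_trip(self, six_protein_file):
        table = read_protein_groups(six_protein_file)
        assert len(table.data) == 6
        assert table.experiments == ["1", "2", "3", "4"]
        assert set(table.condition_columns) == {"interphase", "mitotic"}

    def test_decoy_rows_dropped_with_count(self, tmp_path):
        rows = [["P1", "G1"] + [1e7] * 8, ["REV__P2", "G2"] + [1e7] * 8,
                ["CON__P3", "G3"] + [1e7] * 8]
        path = tmp_path / "pg.txt"
        _fixture_table(rows).to_csv(path, sep="\t", index=False)
        table = read_protein_groups(path)
        assert len(table.data) == 1
        assert table.n_dropped_contaminants == 2

    def test_negative_intensity_rejected(self):
        rows = [["P1", "G1"] + [1e7] * 7 + [-5.0]]
        with pytest.raises(ValueError, match="negative"):
            read_protein_groups(_fixture_table(rows))

    def test_missing_condition_columns_listed(self):
        df = pd.DataFrame({"Protein IDs": ["P1"], "LFQ intensity interphase_1": [1.0]})
        with pytest.raises(ValueError, match="mitotic"):
            read_protein_groups(df)


class TestRatios:
    def test_cortactin_like_ratio(self):
        rows = [["CTTN", "CTTN"] + [4.62e7] * 4 + [1.0e6] * 4]
        res = compute_ratios(read_protein_groups(_fixture_table(rows)))
        row = res.iloc[0]
        assert row["ratio"] == pytest.approx(46.2)
        assert row["log2_ratio"] == pytest.approx(5.530, abs=5e-4)
        assert row["status"] == "ratio_ok"

    def test_exclusive_above_threshold(self):
        rows = [["EPN1", "EPN1"] + [2e6] * 4 + [0.0] * 4]
        res = compute_ratios(read_protein_groups(_fixture_table(rows)))
        assert res.iloc[0]["status"] == "interphase_exclusive"

    def test_excluded_zero_below_threshold(self):
        rows = [["X", "X"] + [5e5] * 4 + [0.0] * 4]
        res = compute_ratios(read_protein_groups(_fixture_table(rows)))
        assert res.iloc[0]["status"] == "excluded_zero"

    def test_status_partition_exhaustive_and_exclusive(self):
        table, _ = synthetic.gen_lfq_table(LfqGenSpec(
            n_proteins=300, dropout_rate=0.3, seed=6,
            exclusive_specs=(ExclusiveSpec("A", "mitotic", 2e6),),
        ))
        res = compute_ratios(read_protein_groups(table))
        valid = {"ratio_ok", "excluded_zero", "interphase_exclusive", "mitotic_exclusive"}
        assert set(res["status"]) <= valid
        ok = res["status"] == "ratio_ok"
        assert res.loc[ok, "log2_ratio"].notna().all()
        assert res.loc[~ok, "log2_ratio"].isna().all()

    def test_permuting_experiment_labels_leaves_ratios_unchanged(self):
        table, _ = synthetic.gen_lfq_table(LfqGenSpec(n_proteins=100, dropout_rate=0.1, seed=2))
        pt = read_protein_groups(table)
        res1 = compute_ratios(pt)
        perm = {"1": "3", "2": "1", "3": "4", "4": "2"}
        renamed = table.rename(
            columns=lambda c: (
                f"LFQ intensity {c.split(' ')[-1].rsplit('_', 1)[0]}_"
                f"{perm[c.rsplit('_', 1)[1]]}"
                if c.startswith("LFQ intensity") else c
            )
        )
        res2 = compute_ratios(read_protein_groups(renamed))
        assert np.allclose(res1["ratio"], res2["ratio"], equal_nan=True)


class TestGaussianFit:
    def test_self_consistency_on_gaussian_quantile_sample(self):
        # a sample placed exactly at Gaussian quantiles has a histogram
        # following the density, so the fit must return the generating
        # (mu, sigma) to numerical tolerance
        from scipy.stats import norm

        mu, sigma, bw = 0.10, 0.80, 0.25
        q = (np.arange(20000) + 0.5) / 20000
        x = norm.ppf(q, loc=mu, scale=sigma)
        fit = fit_gaussian_null(x, bin_width=bw)
        assert fit.mu == pytest.approx(mu, abs=0.01)
        assert fit.sigma == pytest.approx(sigma, abs=0.01)

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(123)
        x = rng.normal(0.2, 0.8, 5000)
        fit = fit_gaussian_null(x, bin_width=0.25)
        assert fit.mu == pytest.approx(0.2, abs=0.05)
        assert fit.sigma == pytest.approx(0.8, abs=0.05)

    def test_degenerate_input_raises_with_initials(self):
        with pytest.raises((GaussianFitError, ValueError)):
            fit_gaussian_null(np.full(100, 1.5))

    def test_too_few_proteins_rejected(self):
        with pytest.raises(ValueError, match=">= 50"):
            fit_gaussian_null(np.random.default_rng(0).normal(size=20))

    def test_moments_method_matches_sample_moments(self):
        x = np.random.default_rng(7).normal(0.3, 0.6, 1000)
        fit = fit_gaussian_null(x, method="moments")
        assert fit.mu == pytest.approx(x.mean())
        assert fit.sigma == pytest.approx(x.std(ddof=1))


class TestOutlierCalls:
    @pytest.fixture
    def called(self):
        rows = [
            ["CTTN", "CTTN"] + [4.62e7] * 4 + [1.0e6] * 4,
            ["NSF", "NSF"] + [0.077e7] * 4 + [1.0e7] * 4,
            ["FLAT", "FLAT"] + [1e7] * 4 + [1e7] * 4,
        ]
        res = compute_ratios(read_protein_groups(_fixture_table(rows)))
        from mitocme.proteomics import GaussianFit
        fit = GaussianFit(mu=0.0, sigma=0.75, amplitude=1.0, bin_width=0.25, n_fitted=100)
        return call_outliers(res, fit).set_index("protein_id")

    def test_interphase_enrichment_called(self, called):
        assert called.loc["CTTN", "outlier_call"] == "interphase_enriched"

    def test_mitotic_enrichment_called(self, called):
        assert called.loc["NSF", "outlier_call"] == "mitotic_enriched"

    def test_ratio_at_mean_not_called(self, called):
        assert called.loc["FLAT", "outlier_call"] == "none"


class TestConsistency:
    def test_outlier_in_all_experiments_scores_4_of_4(self):
        table, _ = synthetic.gen_lfq_table(LfqGenSpec(
            n_proteins=500, dropout_rate=0.0, seed=21,
            outlier_specs=(OutlierSpec("HIT", 64.0),),
        ))
        cons = per_experiment_consistency(read_protein_groups(table))
        assert "HIT" in cons.intersection
        assert cons.consistency("HIT") == (4, 4)

    def test_outlier_in_one_experiment_scores_1_of_4(self):
        table, _ = synthetic.gen_lfq_table(LfqGenSpec(
            n_proteins=500, dropout_rate=0.0, seed=22,
            outlier_specs=(OutlierSpec("HIT", 64.0, experiments=(2,)),),
        ))
        cons = per_experiment_consistency(read_protein_groups(table))
        assert cons.consistency("HIT") == (1, 4)
        assert "HIT" not in cons.intersection

    def test_null_only_intersection_empty_with_per_experiment_fraction(self):
        # independent per-experiment scatter dominates, so each
        # experiment flags its own ~4.6% and the intersection is empty
        table, _ = synthetic.gen_lfq_table(LfqGenSpec(
            n_proteins=2000, null_sigma=0.05, experiment_scatter=0.8,
            dropout_rate=0.0, seed=23,
        ))
        cons = per_experiment_consistency(read_protein_groups(table))
        fractions = [len(s) / 2000 for s in cons.outlier_sets.values()]
        assert all(abs(f - 0.0455) < 0.02 for f in fractions)
        assert len(cons.intersection) <= 1

    def test_sparse_experiment_skipped_with_warning(self):
        table, _ = synthetic.gen_lfq_table(LfqGenSpec(n_proteins=200, dropout_rate=0.0, seed=3))
        # zero out experiment 4's interphase column: everything excluded there
        table["LFQ intensity interphase_4"] = 0.0
        with pytest.warns(UserWarning, match="skipped"):
            cons = per_experiment_consistency(read_protein_groups(table))
        assert cons.n_experiments == 3


class TestAnnotate:
    @pytest.fixture
    def ratios(self):
        rows = [
            ["CTTN", "CTTN"] + [4.62e7] * 4 + [1.0e6] * 4,
            ["CLTC", "CLTC"] + [1e7] * 4 + [1e7] * 4,
            ["OTHER", "OTHER"] + [1e7] * 4 + [2e7] * 4,
        ]
        return compute_ratios(read_protein_groups(_fixture_table(rows)))

    def test_membership_labelling(self, ratios):
        out = annotate(ratios, {"actin_related": {"CTTN"}, "ccs_core": {"CLTC"}})
        labels = out.set_index("protein_id")["labels"]
        assert labels["CTTN"] == "actin_related"
        assert "OTHER" not in labels.index

    def test_duplicate_across_lists_gets_both_labels(self, ratios):
        out = annotate(ratios, {"a": {"CTTN"}, "b": {"CTTN"}})
        assert set(out.iloc[0]["labels"].split(";")) == {"a", "b"}

    def test_empty_reference_list_rejected(self, ratios):
        with pytest.raises(ValueError, match="empty"):
            annotate(ratios, {"ccs_core": set()})

    def test_ordered_by_descending_log2_ratio(self, ratios):
        out = annotate(ratios, {"all": {"CTTN", "CLTC", "OTHER"}})
        vals = out["log2_ratio"].to_numpy()
        assert (np.diff(vals) <= 0).all()


class TestModelResults:
    def test_fit_summary_and_exclusives(self):
        table, _ = synthetic.gen_lfq_table(LfqGenSpec(
            n_proteins=500, seed=17, dropout_rate=0.0,
            outlier_specs=(OutlierSpec("CTTN", 46.2),),
            exclusive_specs=(ExclusiveSpec("EPN1", "interphase", 2e6),
                             ExclusiveSpec("CFL2", "mitotic", 2e6)),
        ))
        res = CcsRatioModel(read_protein_groups(table)).fit()
        assert res.exclusives == {"interphase": ["EPN1"], "mitotic": ["CFL2"]}
        assert "CTTN" in set(res.outliers["protein_id"])
        text = res.summary()
        assert "mu" in text and "sigma" in text and "CTTN" in text

    def test_injected_far_outliers_always_flagged(self):
        # |z| > 4 relative to the null must be called in the right
        # direction for every seed
        for seed in (1, 2, 3):
            table, truth = synthetic.gen_lfq_table(LfqGenSpec(
                n_proteins=1000, seed=seed,
                outlier_specs=(OutlierSpec("UP", 2.0**4.0), OutlierSpec("DOWN", 2.0**-4.0)),
            ))
            res = CcsRatioModel(read_protein_groups(table)).fit()
            calls = res.ratios.set_index("protein_id")["outlier_call"]
            assert calls["UP"] == "interphase_enriched"
            assert calls["DOWN"] == "mitotic_enriched"
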