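"""Binomial-GLM contrasts, taxonomy sweep and the responder decision rules."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from soilshift import (
    CommunitySpec,
    design,
    diminished_otus,
    enriched_taxa,
    fit_group_glm,
    generate_true_profiles,
    sample_reads,
    sweep_taxonomy,
    tukey_contrasts,
)
from soilshift.taxa import SkipTaxon
from conftest import make_groups, make_table


def labels(*pairs):
    out = []
    for name, k in pairs:
        out += [name] * k
    return pd.Series(out, index=[f"s{i}" for i in range(len(out))])


class TestGroupGlm:
    def test_null_gives_large_p(self):
        y = np.array([10, 10, 10, 10, 10, 10])
        n = np.full(6, 1000)
        fit = fit_group_glm(y, n, labels(("A", 3), ("B", 3)))
        con = tukey_contrasts(fit)
        assert (con["p"] > 0.5).all()

    def test_planted_difference_matches_two_proportion_oracle(self):
        y = np.array([10, 10, 10, 50, 50, 50])
        n = np.full(6, 1000)
        fit = fit_group_glm(y, n, labels(("A", 3), ("B", 3)))
        con = tukey_contrasts(fit).iloc[0]
        assert con["direction"] == "B"
        assert con["p"] < 0.05
        # pooled two-proportion z oracle agrees on the decision
        p1, p2 = 30 / 3000, 150 / 3000
        pp = (30 + 150) / 6000
        z = (p2 - p1) / math.sqrt(pp * (1 - pp) * (2 / 3000))
        assert 2 * stats.norm.sf(abs(z)) < 0.05
        # and Fisher on pooled counts agrees
        assert stats.fisher_exact([[30, 2970], [150, 2850]])[1] < 0.05

    def test_all_zero_taxon_is_skip_signal(self):
        with pytest.raises(SkipTaxon):
            fit_group_glm(np.zeros(4), np.full(4, 100), labels(("A", 2), ("B", 2)))

    def test_separation_falls_back_to_fisher(self):
        y = np.array([0, 0, 0, 20, 30, 25])
        n = np.full(6, 1000)
        fit = fit_group_glm(y, n, labels(("A", 3), ("B", 3)))
        assert fit.separated == ["A"]
        con = tukey_contrasts(fit).iloc[0]
        assert con["method"] == "fisher"
        expected = stats.fisher_exact([[0, 3000], [75, 2925]])[1]
        assert con["p"] == pytest.approx(expected)
        assert con["direction"] == "B"

    def test_two_group_z_squared_equals_wald_chi2(self):
        y = np.array([12, 9, 20, 35, 28, 40])
        n = np.array([800, 700, 1100, 900, 850, 1200])
        fit = fit_group_glm(y, n, labels(("A", 3), ("B", 3)))
        con = tukey_contrasts(fit).iloc[0]
        # oracle: intercept + dummy GLM; slope Wald chi-square
        x = sm.add_constant(np.array([0, 0, 0, 1, 1, 1.0]))
        res = sm.GLM(
            np.column_stack([y, n - y]), x, family=sm.families.Binomial()
        ).fit()
        chi2 = (res.params[1] / res.bse[1]) ** 2
        assert con["z"] ** 2 == pytest.approx(chi2, rel=1e-6)

    def test_four_groups_six_contrasts_adjusted_monotone(self):
        rng = np.random.default_rng(1)
        y = rng.integers(5, 50, size=8)
        n = np.full(8, 1000)
        fit = fit_group_glm(y, n, labels(("A", 2), ("B", 2), ("C", 2), ("D", 2)))
        con = tukey_contrasts(fit)
        assert len(con) == 6
        assert (con["p_adj"] >= con["p"] - 1e-12).all()
        assert con["p"].between(0, 1).all()


@pytest.fixture(scope="module")
def planted_dataset():
    spec = CommunitySpec.study_emulation(
        n_otus=400,
        dirichlet_concentration=None,
        depth_by_group=(),
        depth_default=(2500.0, 800.0),
    )
    profiles, truth = generate_true_profiles(spec, seed=21)
    table = sample_reads(profiles, spec, seed=21)
    return spec, table, design(spec), truth


class TestSweep:
    def test_planted_genus_flagged_at_genus_and_otu_rank(self, planted_dataset):
        _, table, groups, truth = planted_dataset
        sweep = sweep_taxonomy(table, groups, ranks=("genus", "otu"))
        enr = enriched_taxa(sweep, groups)
        dominant = truth.enriched[0]
        for soil in groups.soils:
            hits = enr.enriched[soil]
            assert dominant["genus"] in set(hits[hits["rank"] == "genus"]["taxon"])
            assert dominant["otu_id"] in set(hits[hits["rank"] == "otu"]["taxon"])
        assert dominant["genus"] in set(enr.common_enriched["taxon"])

    def test_row_bookkeeping(self, planted_dataset):
        _, table, groups, _ = planted_dataset
        sweep = sweep_taxonomy(table, groups, ranks=("phylum", "genus"))
        n_taxa = (
            table.aggregate_at_rank("phylum").n_otus
            + table.aggregate_at_rank("genus").n_otus
        )
        assert len(sweep) == n_taxa * 6  # C(4,2) contrasts each

    def test_label_permutation_destroys_signal(self, planted_dataset):
        _, table, groups, truth = planted_dataset
        rng = np.random.default_rng(3)
        frame = groups.frame.copy()
        perm = frame.copy()
        perm["treatment"] = rng.permutation(frame["treatment"].to_numpy())
        # keep a valid 2-per-group design: permute within soil blocks instead
        for soil in ("Cambisol", "Luvisol"):
            idx = frame.index[frame["soil"] == soil]
            perm.loc[idx, "treatment"] = rng.permutation(
                frame.loc[idx, "treatment"].to_numpy()
            )
        from soilshift import SampleGroups

        shuffled = SampleGroups(perm[["soil", "treatment", "replicate"]])
        sweep = sweep_taxonomy(table, shuffled, ranks=("genus",))
        within = sweep[
            [a.split(":")[0] == b.split(":")[0]
             for a, b in zip(sweep["group_a"], sweep["group_b"])]
        ]
        assert within["p"].median() > 0.1

    def test_alpha_zero_empty_report(self, planted_dataset):
        _, table, groups, _ = planted_dataset
        sweep = sweep_taxonomy(table, groups, ranks=("genus",))
        enr = enriched_taxa(sweep, groups, alpha=0.0)
        assert all(len(f) == 0 for f in enr.enriched.values())


def diminished_fixture():
    """One soil, 2+2 samples; 20 OTUs detected in control (average share
    5%), a 30%-share OTU absent from spiked (rule 1), a 10%-share OTU absent
    from spiked (below 4x/5x threshold: not diminished)."""
    n_otus = 20
    control_col = np.zeros(n_otus, dtype=int)
    control_col[0] = 30  # 30% of 100 reads
    control_col[1] = 10  # 10%
    control_col[2:14] = 4  # 12 OTUs x 4
    control_col[14:20] = 2  # 6 OTUs x 2
    assert control_col.sum() == 100
    spiked_col = np.full(n_otus, 5, dtype=int)
    spiked_col[0] = 0
    spiked_col[1] = 0
    counts = np.column_stack([control_col, control_col, spiked_col, spiked_col])
    table = make_table(counts, sample_ids=["c1", "c2", "p1", "p2"])
    groups = make_groups(
        ["c1", "c2", "p1", "p2"],
        soils=["Cambisol"] * 4,
        treatments=["control", "control", "spiked", "spiked"],
    )
    return table, groups


class TestDiminished:
    def test_rule1_fires_on_hand_fixture(self):
        table, groups = diminished_fixture()
        report = diminished_otus(table, groups)
        frame = report.diminished["Cambisol"]
        rule1 = frame[frame["rule"] == "rule1_absent"]
        assert "otu0" in set(rule1["otu_id"])  # 30% >= 5 x 5%, absent
        assert "otu1" not in set(frame["otu_id"])  # 10% < 4 x 5%
        assert frame["average"].tolist() == pytest.approx([1 / 20] * len(frame))

    def test_no_taxon_both_enriched_and_diminished(self, planted_dataset):
        _, table, groups, _ = planted_dataset
        sweep = sweep_taxonomy(table, groups, ranks=("otu",))
        enr = enriched_taxa(sweep, groups)
        dim = diminished_otus(table, groups)
        for soil in groups.soils:
            up = set(enr.enriched[soil]["taxon"])
            down = set(dim.diminished[soil]["otu_id"])
            assert not up & down

    def test_soil_without_both_treatments_is_usage_error(self):
        table, _ = diminished_fixture()
        groups = make_groups(
            ["c1", "c2", "p1", "p2"],
            soils=["Cambisol"] * 4,
            treatments=["control"] * 4,
        )
        with pytest.raises(ValueError, match="control and"):
            diminished_otus(table, groups)


def test_null_wald_calibration_for_adequately_sampled_taxa():
    """Within-soil treatment contrasts on null data: the fraction of
    unadjusted p < 0.05 among Wald-tested genera with >= 50 pooled reads
    stays inside the 95% binomial envelope of 0.05."""
    spec = CommunitySpec(n_otus=1000, dirichlet_concentration=None)
    groups = design(spec)
    pvals = []
    for seed in (11, 12, 13):
        profiles, _ = generate_true_profiles(spec, seed)
        table = sample_reads(profiles, spec, seed)
        totals = table.aggregate_at_rank("genus").counts.sum(axis=1)
        sweep = sweep_taxonomy(table, groups, ranks=("genus",))
        within = sweep[
            [a.split(":")[0] == b.split(":")[0]
             for a, b in zip(sweep["group_a"], sweep["group_b"])]
        ]
        wald = within[within["method"] == "wald"]
        wald = wald[totals.reindex(wald["taxon"]).to_numpy() >= 50]
        pvals += list(wald["p"])
    rate = float(np.mean(np.array(pvals) < 0.05))
    half = 1.96 * math.sqrt(0.05 * 0.95 / len(pvals))
    assert 0.05 - half <= rate <= 0.05 + half
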