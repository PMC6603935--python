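"""Relative-risk statistic and ethnicity-by-SNP matrix assembly.

The independent oracle recomputes every RR cell directly from the raw
genotype-frequency triples with plain dict/float arithmetic, bypassing the
matrix-assembly code entirely.
"""

import numpy as np
import pandas as pd
import pytest

from ethnorisk import (
    ConfigError,
    EmptyMatrixError,
    FrequencyTable,
    GenePanel,
    GenotypeFrequencySet,
    RelativeRiskModel,
    SnpDescriptor,
    UndefinedRelativeRiskError,
    build_rr_matrix,
    heterozygous_relative_risk,
    hwe_expand,
    relative_risk_variant,
    relative_risk_wildtype,
)
from ethnorisk.panel import VARIANT_RISK, WILDTYPE_RISK
from conftest import random_frequency_table


def brute_force_rr(table, panel, ethnicities):
    """Oracle: RR per (ethnicity, SNP) straight from the frequency triples."""
    out = {}
    for snp in panel:
        all_entry = table.get(snp.rsid, "ALL")
        if snp.risk_direction == "variant_risk":
            denom = all_entry.f_hom_alt
            pick = lambda e: e.f_hom_alt
        else:
            denom = all_entry.f_hom_ref
            pick = lambda e: e.f_hom_ref
        if denom == 0:
            continue
        for eth in ethnicities:
            e = table.get(snp.rsid, eth)
            out[(eth, snp.label)] = pick(e) / denom
    return out


class TestRatioFunctions:
    @pytest.mark.parametrize(
        "fn, eg, all_, expected",
        [
            (relative_risk_variant, 0.2, 0.1, 2.0),
            (relative_risk_variant, 0.1, 0.1, 1.0),
            (relative_risk_variant, 0.5, 0.2, 2.5),  # 50/100 vs 200/1000 hom-variant counts
            (relative_risk_wildtype, 0.9, 0.45, 2.0),
            (relative_risk_wildtype, 0.45, 0.45, 1.0),
            (heterozygous_relative_risk, 0.5, 0.25, 2.0),
            (heterozygous_relative_risk, 0.32, 0.32, 1.0),
        ],
    )
    def test_direct_ratios(self, fn, eg, all_, expected):
        assert fn(eg, all_) == pytest.approx(expected, abs=1e-15)

    def test_wildtype_from_hwe_frequencies(self):
        wt_eg = hwe_expand(0.1)[0]
        wt_all = hwe_expand(0.5)[0]
        assert relative_risk_wildtype(wt_eg, wt_all) == pytest.approx(3.24, abs=1e-12)

    def test_het_from_hwe_frequencies(self):
        het_eg = hwe_expand(0.2)[1]
        het_all = hwe_expand(0.4)[1]
        assert heterozygous_relative_risk(het_eg, het_all) == pytest.approx(2 / 3, abs=1e-12)

    def test_zero_worldwide_denominator_signals(self):
        with pytest.raises(UndefinedRelativeRiskError):
            relative_risk_variant(0.2, 0.0)

    def test_out_of_range_frequency_rejected(self):
        with pytest.raises(ValueError):
            relative_risk_variant(1.2, 0.5)


def _two_snp_panel():
    return GenePanel(
        snps=(
            SnpDescriptor("rs100", "VAR", "oxidative_stress", VARIANT_RISK),
            SnpDescriptor("rs200", "WT", "oxidative_stress", WILDTYPE_RISK),
        ),
        name="mini",
    )


def _mini_table(entries):
    return FrequencyTable.from_entries(
        [GenotypeFrequencySet(*e) for e in entries], source="mini"
    )


class TestBuildMatrix:
    def test_variant_and_wildtype_bases(self):
        table = _mini_table(
            [
                ("rs100", "EAS", 0.40, 0.30, 0.30),
                ("rs100", "EUR", 0.50, 0.40, 0.10),
                ("rs100", "ALL", 0.50, 0.40, 0.10),
                ("rs200", "EAS", 0.50, 0.40, 0.10),
                ("rs200", "EUR", 0.60, 0.30, 0.10),
                ("rs200", "ALL", 0.50, 0.40, 0.10),
            ]
        )
        m = build_rr_matrix(table, _two_snp_panel(), ethnicities=("EAS", "EUR"))
        assert m.rr.loc["EAS", "VAR rs100"] == pytest.approx(3.0)
        assert m.rr.loc["EUR", "WT rs200"] == pytest.approx(1.2)
        assert {s.rsid: s.risk_direction for s in m.snps}["rs200"] == WILDTYPE_RISK
        # heterozygous RRs computed alongside
        assert m.rr_het.loc["EUR", "WT rs200"] == pytest.approx(0.75)

    def test_zero_worldwide_unfavorable_drops_snp_everywhere(self):
        table = _mini_table(
            [
                ("rs100", "EAS", 0.70, 0.30, 0.00),
                ("rs100", "EUR", 0.50, 0.40, 0.10),
                ("rs100", "ALL", 0.60, 0.40, 0.00),
                ("rs200", "EAS", 0.50, 0.40, 0.10),
                ("rs200", "EUR", 0.60, 0.30, 0.10),
                ("rs200", "ALL", 0.50, 0.40, 0.10),
            ]
        )
        m = build_rr_matrix(table, _two_snp_panel(), ethnicities=("EAS", "EUR"))
        assert [s.rsid for s in m.snps] == ["rs200"]
        assert m.dropped_snps == [("rs100", "worldwide unfavorable (variant-homozygote) frequency is zero")]
        assert "VAR rs100" not in m.rr.columns

    def test_pseudo_freq_retains_zero_denominator_snp(self):
        table = _mini_table(
            [
                ("rs100", "EAS", 0.70, 0.30, 0.00),
                ("rs100", "ALL", 0.60, 0.40, 0.00),
                ("rs200", "EAS", 0.50, 0.40, 0.10),
                ("rs200", "ALL", 0.50, 0.40, 0.10),
            ]
        )
        m = build_rr_matrix(table, _two_snp_panel(), ethnicities=("EAS",), pseudo_freq=1e-3)
        assert "VAR rs100" in m.rr.columns
        assert m.rr.loc["EAS", "VAR rs100"] == pytest.approx(1.0)

    def test_missing_population_drops_snp(self):
        table = _mini_table(
            [
                ("rs100", "EAS", 0.40, 0.30, 0.30),
                ("rs100", "ALL", 0.50, 0.40, 0.10),
                ("rs200", "EAS", 0.50, 0.40, 0.10),
                ("rs200", "EUR", 0.60, 0.30, 0.10),
                ("rs200", "ALL", 0.50, 0.40, 0.10),
            ]
        )
        m = build_rr_matrix(table, _two_snp_panel(), ethnicities=("EAS", "EUR"))
        assert [s.rsid for s in m.snps] == ["rs200"]
        assert "EUR" in m.dropped_snps[0][1]

    def test_all_dropped_is_an_error(self):
        table = _mini_table(
            [("rs100", "EAS", 0.60, 0.40, 0.00), ("rs100", "ALL", 0.60, 0.40, 0.00)]
        )
        panel = GenePanel(snps=(_two_snp_panel().snps[0],), name="one")
        with pytest.raises(EmptyMatrixError):
            build_rr_matrix(table, panel, ethnicities=("EAS",))

    def test_unknown_ethnicity_is_config_error(self, null_table, panel):
        with pytest.raises(ConfigError, match="XXX"):
            build_rr_matrix(null_table, panel, ethnicities=("AFR", "XXX"))


class TestMatrixProperties:
    def test_null_data_gives_exact_ones(self, null_table, panel):
        m = build_rr_matrix(null_table, panel)
        assert (m.rr.to_numpy() == 1.0).all()
        assert (m.rr_het.to_numpy() == 1.0).all()
        assert m.dropped_snps == []

    def test_worldwide_as_ethnicity_is_identically_one(self, sim_table, panel):
        m = build_rr_matrix(sim_table, panel, ethnicities=("ALL", "EUR"))
        assert (m.rr.loc["ALL"].to_numpy() == 1.0).all()

    def test_oracle_equivalence_on_random_tables(self, panel):
        rng = np.random.default_rng(424242)
        for _ in range(100):
            table = random_frequency_table(rng, panel.rsids)
            m = build_rr_matrix(table, panel)
            oracle = brute_force_rr(table, panel, m.ethnicities)
            for (eth, label), expected in oracle.items():
                assert m.rr.loc[eth, label] == pytest.approx(expected, abs=1e-12)

    def test_direction_flip_changes_only_that_column(self, sim_table, panel):
        from ethnorisk.panel import override_risk_direction

        m0 = build_rr_matrix(sim_table, panel)
        flipped = override_risk_direction(panel, {"rs4880": "wildtype_risk"})
        m1 = build_rr_matrix(sim_table, flipped)
        for label in m0.rr.columns:
            if label == "SOD2 rs4880":
                continue
            pd.testing.assert_series_equal(m0.rr[label], m1.rr[label])
        # flipped column equals the wild-type ratio computed independently
        all_entry = sim_table.get("rs4880", "ALL")
        for eth in m1.ethnicities:
            expected = sim_table.get("rs4880", eth).f_hom_ref / all_entry.f_hom_ref
            assert m1.rr.loc[eth, "SOD2 rs4880"] == pytest.approx(expected, abs=1e-12)

    def test_scale_free_in_sample_sizes(self, panel):
        """Multiplying all n by a constant leaves the matrix unchanged."""
        rng = np.random.default_rng(7)
        t1 = random_frequency_table(rng, panel.rsids, n=100)
        df2 = t1.df.copy()
        df2["n"] = df2["n"] * 10
        t2 = FrequencyTable(df2, source="scaled")
        m1 = build_rr_matrix(t1, panel)
        m2 = build_rr_matrix(t2, panel)
        pd.testing.assert_frame_equal(m1.rr, m2.rr)


class TestEstimatorWrapper:
    def test_fit_exposes_grid_and_sklearn_params(self, null_table):
        model = RelativeRiskModel(panel="builtin")
        assert model.get_params()["panel"] == "builtin"
        model.fit(null_table)
        assert model.rr_.shape == (4, 24)
        assert model.dropped_snps_ == []
        clone_params = model.set_params(pseudo_freq=0.0).get_params()
        assert clone_params["pseudo_freq"] == 0.0

    def test_export_round_trip(self, sim_table, panel, tmp_path):
        from ethnorisk import export_rr_matrix

        model = RelativeRiskModel(panel=panel).fit(sim_table)
        paths = export_rr_matrix(model.matrix_, tmp_path)
        back = pd.read_csv(paths["rr"])
        assert list(back.columns[:4]) == ["rsid", "gene", "group", "basis"]
        assert len(back) == 24
        np.testing.assert_allclose(
            back[list(model.matrix_.ethnicities)].to_numpy(),
            model.rr_.T.to_numpy(),
            rtol=1e-10,
        )
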