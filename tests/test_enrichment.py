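"""CAST exact test, carrier counting, stratification, damaging-missense filter."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idpanel.enrichment import (
    EnrichmentResult,
    StratumSpec,
    carrier_counts,
    cast_test,
    damaging_missense_cast,
    damaging_missense_mask,
    enrichment_to_frame,
    stratified_table,
    threshold_sweep,
)
from idpanel.filtering import add_consequence_class, filter_pipeline
from idpanel.records import ValidationError, VariantRecord


def hypergeom_tail_enumeration(a, n1, b, n2):
    """Independent oracle: exhaustive hypergeometric sum over all 2x2
    tables with the observed margins, at least as extreme (greater)."""
    K, N = a + b, n1 + n2
    denom = math.comb(N, K)
    total = 0
    for x in range(max(0, K - n2), min(n1, K) + 1):
        if x >= a:
            total += math.comb(n1, x) * math.comb(n2, K - x)
    return total / denom


class TestCastTest:
    @given(
        n1=st.integers(1, 30), n2=st.integers(1, 30),
        a_frac=st.floats(0, 1), b_frac=st.floats(0, 1),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_enumeration_oracle(self, n1, n2, a_frac, b_frac):
        a, b = int(round(a_frac * n1)), int(round(b_frac * n2))
        assert cast_test(a, n1, b, n2, "greater") == pytest.approx(
            hypergeom_tail_enumeration(a, n1, b, n2), abs=1e-12
        )

    def test_zero_cell_example_equals_enumeration(self):
        assert cast_test(3, 10, 0, 10, "greater") == pytest.approx(
            hypergeom_tail_enumeration(3, 10, 0, 10), abs=1e-12
        )

    def test_identical_proportions_not_significant(self):
        assert cast_test(10, 100, 10, 100, "greater") >= 0.5

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            cast_test(11, 10, 0, 10)
        with pytest.raises(ValidationError):
            cast_test(-1, 10, 0, 10)
        with pytest.raises(ValidationError):
            cast_test(1, 10, 1, 10, alternative="bogus")

    @given(
        n1=st.integers(1, 40), n2=st.integers(1, 40),
        a_frac=st.floats(0, 1), b_frac=st.floats(0, 1),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_tail_identities(self, n1, n2, a_frac, b_frac):
        a, b = int(round(a_frac * n1)), int(round(b_frac * n2))
        p_g = cast_test(a, n1, b, n2, "greater")
        p_l = cast_test(a, n1, b, n2, "less")
        # label-swap antisymmetry and the shared boundary table
        assert p_g == pytest.approx(cast_test(b, n2, a, n1, "less"), abs=1e-12)
        assert p_g + p_l >= 1.0 - 1e-12
        # two-sided cannot beat the enriched one-sided direction
        assert cast_test(a, n1, b, n2, "two_sided") >= min(p_g, p_l) - 1e-12


class TestDamagingMissenseMask:
    def _rec(self, scores, freqs=None, term="missense_variant"):
        return VariantRecord(
            sample_id="S", gene="G", chrom_class="autosome", position=1,
            ref="G", alt="C", consequence_term=term, variant_class="SNV",
            zygosity="het", scores=scores, ref_freqs=freqs or {},
        )

    def test_all_four_scores_and_absence_required(self):
        good = {"polyphen2": 0.95, "sift": 0.03, "condel": 0.60, "cadd": 25}
        assert damaging_missense_mask(self._rec(good)) is True
        # boundary is strict on every score
        assert not damaging_missense_mask(self._rec({**good, "polyphen2": 0.9}))
        assert not damaging_missense_mask(self._rec({**good, "sift": 0.06}))
        assert not damaging_missense_mask(self._rec({**good, "condel": 0.47}))
        assert not damaging_missense_mask(self._rec({**good, "cadd": 20}))
        # a missing score never counts as damaging
        assert not damaging_missense_mask(
            self._rec({k: v for k, v in good.items() if k != "cadd"})
        )
        # presence in any reference set disqualifies
        assert not damaging_missense_mask(self._rec(good, {"evs": 1e-5}))
        assert not damaging_missense_mask(self._rec(good, term="stop_gained"))

    def test_vectorised_matches_scalar(self):
        df = pd.DataFrame(
            {
                "consequence": ["missense_variant"] * 3 + ["stop_gained"],
                "polyphen2": [0.95, 0.90, 0.95, 0.95],
                "sift": [0.03, 0.03, 0.03, 0.03],
                "condel": [0.6, 0.6, 0.6, 0.6],
                "cadd": [25, 25, np.nan, 25],
                "freq_evs": [np.nan, np.nan, np.nan, np.nan],
            }
        )
        assert damaging_missense_mask(df).tolist() == [True, False, False, False]


def test_stratum_spec_validity():
    StratumSpec("X_males_only", "known_x", "lof_snv")
    with pytest.raises(ValidationError):
        StratumSpec("autosome_or_PAR", "known_x", "lof_snv")
    with pytest.raises(ValidationError):
        StratumSpec("X_males_only", "known_monoallelic", "lof_snv")
    with pytest.raises(ValidationError):
        StratumSpec("autosome_or_PAR", "known_monoallelic", "nonsense_type")


class TestCarrierCounts:
    def test_multiple_qualifying_variants_count_once(self, default_panel):
        samples = pd.DataFrame(
            {"sample_id": ["A", "B"], "sex": "male",
             "cohort": ["case", "comparison"], "qc_pass": True}
        )
        rows = []
        for pos in (1, 2, 3):
            rows.append(
                dict(sample_id="A", gene="KMA0000", chrom_class="autosome",
                     pos=pos, ref="C", alt="T", consequence="stop_gained",
                     variant_class="SNV", zygosity="het", carriers_internal=1)
            )
        v = add_consequence_class(pd.DataFrame(rows))
        spec = StratumSpec("autosome_or_PAR", "known_monoallelic", "lof_snv")
        assert carrier_counts(v, samples, default_panel, spec) == (1, 1, 0, 1)

    def test_male_only_stratum_drops_females(self, default_panel):
        samples = pd.DataFrame(
            {"sample_id": ["F1", "M1"], "sex": ["female", "male"],
             "cohort": ["case", "case"], "qc_pass": True}
        )
        v = add_consequence_class(pd.DataFrame([
            dict(sample_id="F1", gene="KXL0000", chrom_class="X", pos=1,
                 ref="C", alt="T", consequence="stop_gained",
                 variant_class="SNV", zygosity="het", carriers_internal=1)
        ]))
        spec = StratumSpec("X_males_only", "known_x", "lof_snv")
        a, n1, b, n2 = carrier_counts(v, samples, default_panel, spec)
        assert (a, n1) == (0, 1)  # female carrier and denominator both dropped

    def test_empty_stratum_warns_and_zeroes(self, default_panel, caplog):
        empty_panel = default_panel[default_panel["status"] == "nothing"]
        samples = pd.DataFrame(
            {"sample_id": ["A"], "sex": ["male"], "cohort": ["case"],
             "qc_pass": True}
        )
        v = add_consequence_class(pd.DataFrame(
            columns=["sample_id", "gene", "chrom_class", "pos", "ref", "alt",
                     "consequence", "variant_class", "zygosity",
                     "carriers_internal"]
        ).astype({"carriers_internal": int}))
        spec = StratumSpec("autosome_or_PAR", "known_monoallelic", "lof_snv")
        with caplog.at_level("WARNING", logger="idpanel"):
            a, n1, b, n2 = carrier_counts(v, samples, empty_panel, spec)
        assert (a, b) == (0, 0)
        assert "empty stratum" in caplog.text


class TestStratifiedTable:
    def test_reproduces_published_row_structure(self, fixtures):
        fx = fixtures["table2"]
        res = stratified_table(fx["variants"], fx["samples"], fx["panel"])
        assert len(res) == 15  # 3 autosomal + 2 X strata, 3 variant types each
        for r in res:
            key = (r.stratum.chrom_stratum, r.stratum.gene_category,
                   r.stratum.variant_type)
            assert (r.carriers_case, r.n_case, r.carriers_comparison,
                    r.n_comparison) == fx["expected"][key]

    def test_known_mono_snv_row(self, fixtures):
        fx = fixtures["table2_known_mono_snv"]
        res = stratified_table(fx["variants"], fx["samples"], fx["panel"])
        row = next(r for r in res if r.stratum.variant_type == "lof_snv"
                   and r.stratum.gene_category == "known_monoallelic")
        assert (row.carriers_case, row.n_case, row.carriers_comparison,
                row.n_comparison) == (42, 986, 6, 899)
        assert row.significant

    def test_synonymous_rows_never_significant_by_design(self, default_panel):
        # huge synonymous imbalance: still a negative control, never flagged
        samples = pd.DataFrame(
            {"sample_id": [f"S{i}" for i in range(200)], "sex": "male",
             "cohort": ["case"] * 100 + ["comparison"] * 100, "qc_pass": True}
        )
        rows = [
            dict(sample_id=f"S{i}", gene="KMA0000", chrom_class="autosome",
                 pos=i + 1, ref="G", alt="A", consequence="synonymous_variant",
                 variant_class="SNV", zygosity="het", carriers_internal=1)
            for i in range(60)
        ]
        res = stratified_table(
            add_consequence_class(pd.DataFrame(rows)), samples, default_panel
        )
        syn = [r for r in res if r.stratum.variant_type == "synonymous"]
        enriched = next(r for r in syn
                        if r.stratum.gene_category == "known_monoallelic")
        assert enriched.p_value < 0.005 and not enriched.significant

    def test_empty_panel_empty_strata(self):
        panel = pd.DataFrame(
            columns=["gene", "status", "chrom_class", "inheritance", "transcript"]
        )
        samples = pd.DataFrame(
            {"sample_id": ["A"], "sex": ["male"], "cohort": ["case"],
             "qc_pass": True}
        )
        v = add_consequence_class(pd.DataFrame(
            columns=["sample_id", "gene", "chrom_class", "pos", "ref", "alt",
                     "consequence", "variant_class", "zygosity",
                     "carriers_internal"]
        ).astype({"carriers_internal": int}))
        res = stratified_table(v, samples, panel)
        assert len(res) == 15
        assert all(r.carriers_case == 0 and r.carriers_comparison == 0
                   for r in res)


class TestThresholdSweep:
    def test_headline_counts_at_one_percent(self, fixtures):
        fx = fixtures["fig1_maf1pct"]
        from idpanel.filtering import frequency_filter_table
        flt = frequency_filter_table(fx["variants"])
        kept = add_consequence_class(flt[flt["keep_flag"]])
        sweep = threshold_sweep(kept, fx["samples"], thresholds=[0.01])
        row = sweep.iloc[0]
        assert (row["carriers_case"], row["carriers_comparison"]) == (341, 222)

    def test_threshold_one_keeps_everything(self, small_cohort):
        _, variants, samples, _ = small_cohort
        kept, retained, _ = filter_pipeline(variants, samples)
        sweep = threshold_sweep(kept, retained, thresholds=[1.0, 0.01])
        lof = kept[kept["consequence_class"] == "lof"]
        assert sweep.iloc[0]["carriers_case"] + sweep.iloc[0][
            "carriers_comparison"
        ] == lof["sample_id"].nunique()

    def test_carriers_monotone_as_threshold_tightens(self, small_cohort):
        _, variants, samples, _ = small_cohort
        kept, retained, _ = filter_pipeline(variants, samples)
        sweep = threshold_sweep(kept, retained)
        assert (sweep["carriers_case"].diff().dropna() <= 0).all()
        assert (sweep["carriers_comparison"].diff().dropna() <= 0).all()


class TestDamagingMissenseCast:
    def test_published_counts_and_p(self, fixtures):
        fx = fixtures["damaging_missense"]
        res = damaging_missense_cast(
            fx["variants"], fx["samples"], fx["panel"], fx["lof_excluded"]
        )
        assert (res.carriers_case, res.n_case) == (284, 900)
        assert (res.carriers_comparison, res.n_comparison) == (245, 899)
        assert f"{res.p_value:.2g}" == "0.025"

    def test_no_damaging_missense_p_one(self, fixtures, default_panel):
        fx = fixtures["fig1_maf1pct"]  # LoF-only fixture: no missense at all
        res = damaging_missense_cast(
            fx["variants"], fx["samples"], default_panel, []
        )
        assert res.p_value == 1.0
        assert res.carriers_case == 0


def test_enrichment_result_invariants():
    with pytest.raises(ValidationError):
        EnrichmentResult(None, 11, 10, 0, 10, 0.5, 0.05)
    with pytest.raises(ValidationError):
        EnrichmentResult(None, 1, 10, 0, 10, 0.0, 0.05)
    r = EnrichmentResult(None, 5, 10, 0, 10, 0.01, 0.05)
    assert r.significant == (r.p_value < r.alpha_adjusted)
    assert len(enrichment_to_frame([r])) == 1


def test_null_pvalues_roughly_uniform(default_panel):
    """Under equal background rates the CAST p-value is approximately
    uniform (slightly conservative from discreteness)."""
    from idpanel.simulate import SimulationConfig, simulate_cohorts

    ps = []
    for i in range(100):
        cfg = SimulationConfig(
            n_case=300, n_comparison=300,
            planted_lof_diagnostic_fraction=0.0,
            planted_missense_diagnostic_fraction=0.0, dual_pathway_overlap=0,
            mean_lof_per_person_comparison=0.46, seed=40_000 + i,
        )
        variants, samples, _ = simulate_cohorts(cfg, default_panel)
        kept, retained, _ = filter_pipeline(variants, samples)
        ps.append(threshold_sweep(kept, retained, thresholds=[0.01])
                  ["p_value"].iloc[0])
    ps = np.asarray(ps)
    assert 0.35 < ps.mean() < 0.65
    assert 0.02 <= (ps < 0.1).mean() <= 0.20
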