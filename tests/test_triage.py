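"""Inheritance-aware triage rules, missense checklist order, diagnostic yield."""

import numpy as np
import pandas as pd
import pytest

from idpanel.records import GeneDefinition, Pathway, ReasonCode, Verdict
from idpanel.filtering import filter_pipeline
from idpanel.simulate import SimulationConfig, simulate_cohorts, simulate_panel
from idpanel.triage import (
    GeneNotInPanelError,
    annotate_external_presence,
    diagnostic_yield,
    mode_consistent,
    triage_cohort,
    triage_lof,
    triage_missense,
)

MONO = GeneDefinition("GM", "known", "autosome", "monoallelic", "T1")
BI = GeneDefinition("GB", "known", "autosome", "biallelic", "T2")
XL = GeneDefinition("GX", "known", "X", "x_linked", "T3")
CAND = GeneDefinition("GC", "candidate", "autosome", "monoallelic", "T4")


def _row(**kw):
    base = dict(
        sample_id="S1", gene="GM", chrom_class="autosome", pos=100, ref="C",
        alt="T", consequence="stop_gained", variant_class="SNV",
        zygosity="het", carriers_internal=1, known_pathogenic=False,
        literature_excluded=False, mode_mismatch=False, transcript=None,
        freq_evs=np.nan,
    )
    base.update(kw)
    return pd.Series(base)


@pytest.mark.parametrize(
    "gene,zygosity,sex,comp_het,override,expected",
    [
        (MONO, "het", "male", False, (), True),
        (MONO, "hom", "female", False, (), True),
        (BI, "het", "male", False, (), False),   # single allele in recessive gene
        (BI, "het", "male", True, (), True),     # compound het completes it
        (BI, "hom", "female", False, (), True),
        (XL, "hemi", "male", False, (), True),
        (XL, "het", "female", False, (), False), # female carrier, default
        (XL, "het", "female", False, ("GX",), True),  # female-manifesting gene
        (XL, "hom", "female", False, (), True),
    ],
)
def test_mode_consistency(gene, zygosity, sex, comp_het, override, expected):
    row = _row(zygosity=zygosity, chrom_class=gene.chrom_class.value)
    assert mode_consistent(row, gene, sex, comp_het, override) is expected


class TestLofTriage:
    def test_unique_nonsense_known_monoallelic_is_diagnostic(self):
        res = triage_lof(_row(), MONO, "male", False, ["freq_evs"])
        assert res.verdict is Verdict.likely_pathogenic
        assert res.pathway is Pathway.lof_known_gene

    def test_male_hemizygous_x_linked_is_diagnostic(self):
        row = _row(gene="GX", chrom_class="X", zygosity="hemi")
        res = triage_lof(row, XL, "male", False, ["freq_evs"])
        assert res.verdict is Verdict.likely_pathogenic

    def test_candidate_gene_is_uncertain(self):
        res = triage_lof(_row(gene="GC"), CAND, "male", False, ["freq_evs"])
        assert res.verdict is Verdict.uncertain
        assert ReasonCode.R_CANDIDATE_GENE in res.reason_codes

    def test_single_het_in_recessive_gene_is_uncertain(self):
        res = triage_lof(_row(gene="GB"), BI, "male", False, ["freq_evs"])
        assert res.verdict is Verdict.uncertain
        assert res.reason_codes == {ReasonCode.R_RECESSIVE_SINGLE_ALLELE}

    def test_homozygous_recessive_is_diagnostic_despite_carriers(self):
        # healthy het carriers of recessive alleles are expected in controls
        row = _row(gene="GB", zygosity="hom", freq_evs=1e-5, carriers_internal=2)
        res = triage_lof(row, BI, "female", False, ["freq_evs"])
        assert res.verdict is Verdict.likely_pathogenic

    def test_control_presence_blocks_dominant_gene(self):
        res = triage_lof(_row(freq_evs=1e-4), MONO, "male", False, ["freq_evs"])
        assert ReasonCode.R_IN_CONTROLS in res.reason_codes
        res2 = triage_lof(_row(carriers_internal=2), MONO, "male", False,
                          ["freq_evs"])
        assert ReasonCode.R_IN_CONTROLS in res2.reason_codes

    def test_off_canonical_transcript_flagged(self):
        res = triage_lof(_row(transcript="T_other"), MONO, "male", False,
                         ["freq_evs"])
        assert ReasonCode.R_NOT_CANONICAL_TRANSCRIPT in res.reason_codes


class TestMissenseChecklist:
    def _kp_row(self, **kw):
        kw.setdefault("consequence", "missense_variant")
        kw.setdefault("known_pathogenic", True)
        return _row(**kw)

    def test_unreported_missense_never_assessed(self):
        res = triage_missense(_row(consequence="missense_variant"), MONO,
                              "male", False, False, ["freq_evs"])
        assert res.verdict is Verdict.excluded
        assert res.reason_codes == {ReasonCode.R_NOT_KNOWN_PATHOGENIC}

    def test_survivor_is_diagnostic(self):
        res = triage_missense(self._kp_row(), MONO, "male", False, False,
                              ["freq_evs"])
        assert res.verdict is Verdict.likely_pathogenic
        assert res.pathway is Pathway.missense_known_pathogenic

    def test_rule_i_candidate_gene(self):
        res = triage_missense(self._kp_row(gene="GC"), CAND, "male", False,
                              False, ["freq_evs"])
        assert res.reason_codes == {ReasonCode.R_CANDIDATE_GENE}

    def test_rule_order_stops_at_first_failure(self):
        # candidate gene AND present in controls: only rule (i) is reported
        res = triage_missense(self._kp_row(gene="GC", freq_evs=1e-4), CAND,
                              "male", False, True, ["freq_evs"])
        assert res.reason_codes == {ReasonCode.R_CANDIDATE_GENE}

    def test_rule_ii_control_presence(self):
        res = triage_missense(self._kp_row(freq_evs=1e-4), MONO, "male",
                              False, False, ["freq_evs"])
        assert res.reason_codes == {ReasonCode.R_IN_CONTROLS}

    def test_rule_ii_tolerated_for_recessive_comp_het(self):
        res = triage_missense(self._kp_row(gene="GB", freq_evs=1e-4), BI,
                              "male", True, False, ["freq_evs"])
        assert res.verdict is Verdict.likely_pathogenic

    def test_rule_iii_recessive_single_allele(self):
        res = triage_missense(self._kp_row(gene="GB"), BI, "male", False,
                              False, ["freq_evs"])
        assert res.reason_codes == {ReasonCode.R_RECESSIVE_SINGLE_ALLELE}

    def test_rule_iv_literature_exclusion_flag(self):
        res = triage_missense(self._kp_row(literature_excluded=True), MONO,
                              "male", False, False, ["freq_evs"])
        assert res.reason_codes == {ReasonCode.R_LITERATURE_EXCLUDED}

    def test_rule_v_lof_better_explains(self):
        res = triage_missense(self._kp_row(), MONO, "male", False, True,
                              ["freq_evs"])
        assert res.reason_codes == {ReasonCode.R_BETTER_LOF_EXPLANATION}

    def test_rule_vi_vii_mode_mismatch(self):
        res = triage_missense(self._kp_row(mode_mismatch=True), MONO, "male",
                              False, False, ["freq_evs"])
        assert res.reason_codes == {ReasonCode.R_MODE_MISMATCH}
        row = self._kp_row(gene="GX", chrom_class="X", zygosity="het")
        res = triage_missense(row, XL, "female", False, False, ["freq_evs"])
        assert res.reason_codes == {ReasonCode.R_MODE_MISMATCH}

    def test_male_hemi_x_known_pathogenic_is_diagnostic(self):
        row = self._kp_row(gene="GX", chrom_class="X", zygosity="hemi")
        res = triage_missense(row, XL, "male", False, False, ["freq_evs"])
        assert res.verdict is Verdict.likely_pathogenic


def test_gene_absent_from_panel_raises(default_panel):
    variants = pd.DataFrame([_row(gene="NOT_A_GENE")])
    variants["consequence_class"] = "lof"
    variants["comp_het_flag"] = False
    samples = pd.DataFrame(
        {"sample_id": ["S1"], "sex": ["male"], "cohort": ["case"],
         "qc_pass": [True]}
    )
    with pytest.raises(GeneNotInPanelError, match="NOT_A_GENE"):
        triage_cohort(variants, samples, default_panel)


def test_triage_verdicts_independent_of_record_order(small_cohort, default_panel):
    _, variants, samples, _ = small_cohort
    kept, retained, _ = filter_pipeline(variants, samples)
    a = triage_cohort(kept, retained, default_panel)
    b = triage_cohort(kept.sample(frac=1.0, random_state=3), retained,
                      default_panel)
    key = lambda cs: sorted((c.sample_id, c.variant_key, c.verdict.value) for c in cs)
    assert key(a) == key(b)


def test_external_presence_annotation_reporting_only(fixtures):
    fx = fixtures["yield_107"]
    cls = fx["classifications"][:5]
    secondary = {cls[0].variant_key: 4}  # e.g. 4 alleles in ~122k sequenced
    out = annotate_external_presence(cls, secondary)
    assert out[0].external_presence == 4
    assert all(c.external_presence == 0 for c in out[1:])
    assert [c.verdict for c in out] == [c.verdict for c in cls]
    assert annotate_external_presence([], secondary) == []


class TestDiagnosticYield:
    def test_union_inclusion_exclusion_on_fixture(self, fixtures):
        fx = fixtures["yield_107"]
        case = fx["samples"][fx["samples"]["cohort"] == "case"]
        ys = diagnostic_yield(fx["classifications"], case)
        assert (ys.n_lof_diagnosed, ys.n_missense_diagnosed, ys.n_both) == (77, 33, 3)
        assert ys.n_diagnosed_union == 107
        assert ys.yield_fraction == pytest.approx(107 / 986)

    def test_identity_holds_exactly(self, fixtures):
        fx = fixtures["yield_107"]
        case = fx["samples"][fx["samples"]["cohort"] == "case"]
        for k in (0, 10, 50, 110):
            ys = diagnostic_yield(fx["classifications"][:k], case)
            assert ys.n_diagnosed_union == (
                ys.n_lof_diagnosed + ys.n_missense_diagnosed - ys.n_both
            )

    def test_no_diagnoses_zero_yield(self):
        samples = pd.DataFrame(
            {"sample_id": ["A"], "sex": ["male"], "cohort": ["case"],
             "qc_pass": [True]}
        )
        ys = diagnostic_yield([], samples)
        assert ys.n_diagnosed_union == 0 and ys.yield_fraction == 0.0


def test_null_cohort_missense_yield_exactly_zero(default_panel):
    """Without planted variants or reported-pathogenic hits, the missense
    pathway yields nothing and LoF diagnoses match the generator's
    background rate of diagnostic-looking unique LoF."""
    from idpanel.simulate import expected_background_diagnostic_rate

    cfg = SimulationConfig(
        planted_lof_diagnostic_fraction=0.0,
        planted_missense_diagnostic_fraction=0.0,
        dual_pathway_overlap=0, seed=21,
    )
    variants, samples, truth = simulate_cohorts(cfg, default_panel)
    assert len(truth.planted) == 0
    kept, retained, _ = filter_pipeline(variants, samples)
    case = retained[retained["cohort"] == "case"]
    kept_case = kept[kept["sample_id"].isin(set(case["sample_id"]))]
    cls = triage_cohort(kept_case, case, default_panel)
    ys = diagnostic_yield(cls, case)
    assert ys.n_missense_diagnosed == 0
    expected = expected_background_diagnostic_rate(cfg, default_panel) * len(case)
    assert 0.4 * expected <= ys.n_lof_diagnosed <= 2.0 * expected + 5
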