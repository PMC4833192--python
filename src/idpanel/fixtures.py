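"""Deterministic regression fixtures with the published contingency structure.

These small tables are generated programmatically (no packaged data files)
and reproduce, bit-exactly, the carrier counts of the published burden
analysis: the headline any-LoF comparison (341/986 vs 222/899 at MAF<1%),
every row of the stratified unique-LoF table, the damaging-missense
comparison (284/900 vs 245/899), the outlier-exclusion accounting
(996 -> 986 samples), and the diagnostic-yield union (77 + 33 - 3 = 107).
Each fixture carries a manifest of its expected counts.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np
import pandas as pd

from .records import ClassificationResult, Pathway, Verdict
from .simulate import (
    SimulationConfig,
    VARIANT_COLUMNS,
    _make_samples,
    simulate_panel,
)

#: (chrom_stratum, gene_category, variant_type) -> (carriers_case, carriers_comparison)
TABLE2_ROWS = [
    ("autosome_or_PAR", "known_monoallelic", "lof_snv", 42, 6),
    ("autosome_or_PAR", "known_monoallelic", "lof_indel", 13, 7),
    ("autosome_or_PAR", "known_monoallelic", "synonymous", 394, 357),
    ("autosome_or_PAR", "known_biallelic", "lof_snv", 43, 26),
    ("autosome_or_PAR", "known_biallelic", "lof_indel", 23, 13),
    ("autosome_or_PAR", "known_biallelic", "synonymous", 294, 258),
    ("autosome_or_PAR", "candidate", "lof_snv", 52, 22),
    ("autosome_or_PAR", "candidate", "lof_indel", 26, 23),
    ("autosome_or_PAR", "candidate", "synonymous", 450, 400),
    ("X_males_only", "known_x", "lof_snv", 17, 0),
    ("X_males_only", "known_x", "lof_indel", 14, 0),
    ("X_males_only", "known_x", "synonymous", 121, 41),
    ("X_males_only", "candidate", "lof_snv", 11, 2),
    ("X_males_only", "candidate", "lof_indel", 4, 1),
    ("X_males_only", "candidate", "synonymous", 179, 92),
]

_CATEGORY_GENE = {
    "known_monoallelic": "KMA0000",
    "known_biallelic": "KBA0000",
    "known_x": "KXL0000",
    ("candidate", "autosome_or_PAR"): "CAU0000",
    ("candidate", "X_males_only"): "CXL0000",
}

_VTYPE_FIELDS = {
    "lof_snv": ("stop_gained", "C", "T", "SNV"),
    "lof_indel": ("frameshift_variant", "AT", "A", "indel"),
    "synonymous": ("synonymous_variant", "G", "A", "SNV"),
}


def _blank_row() -> dict:
    return {
        "carriers_internal": 1, "polyphen2": np.nan, "sift": np.nan,
        "condel": np.nan, "cadd": np.nan, "known_pathogenic": False,
        "literature_excluded": False, "mode_mismatch": False,
        "freq_1000g": np.nan, "freq_uk10k_twins": np.nan,
        "freq_evs": np.nan, "freq_inhouse": np.nan,
    }


def _variants_frame(rows: List[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def fixture_tables() -> Dict[str, dict]:
    """Build all packaged fixtures; see module docstring for contents."""
    panel = simulate_panel(SimulationConfig())
    tx = dict(zip(panel["gene"], panel["transcript"]))
    chrom_of = dict(zip(panel["gene"], panel["chrom_class"]))
    samples = _make_samples(SimulationConfig())
    case = samples[samples["cohort"] == "case"]
    comp = samples[samples["cohort"] == "comparison"]
    case_male = case[case["sex"] == "male"]["sample_id"].tolist()
    comp_male = comp[comp["sex"] == "male"]["sample_id"].tolist()
    case_all = case["sample_id"].tolist()
    comp_all = comp["sample_id"].tolist()

    fixtures: Dict[str, dict] = {}
    pos = [1000]

    def _next_pos() -> int:
        pos[0] += 1
        return pos[0]

    def _plant(sid: str, gene: str, vtype: str, zygosity: str) -> dict:
        cons, ref, alt, vclass = _VTYPE_FIELDS[vtype]
        row = _blank_row()
        row.update(
            sample_id=sid, gene=gene, chrom_class=chrom_of[gene],
            pos=_next_pos(), ref=ref, alt=alt, consequence=cons,
            variant_class=vclass, zygosity=zygosity, transcript=tx[gene],
        )
        return row

    # --- stratified unique-LoF table -------------------------------------
    t2_rows: List[dict] = []
    expected_rows = {}
    for chrom_stratum, category, vtype, k_case, k_comp in TABLE2_ROWS:
        gene = _CATEGORY_GENE.get(category) or _CATEGORY_GENE[(category, chrom_stratum)]
        if chrom_stratum == "X_males_only":
            case_pool, comp_pool, zyg = case_male, comp_male, "hemi"
            n_case, n_comp = len(case_male), len(comp_male)
        else:
            case_pool, comp_pool, zyg = case_all, comp_all, "het"
            n_case, n_comp = len(case_all), len(comp_all)
        for sid in case_pool[:k_case]:
            t2_rows.append(_plant(sid, gene, vtype, zyg))
        for sid in comp_pool[:k_comp]:
            t2_rows.append(_plant(sid, gene, vtype, zyg))
        expected_rows[(chrom_stratum, category, vtype)] = (
            k_case, n_case, k_comp, n_comp
        )
    t2_variants = _variants_frame(t2_rows)
    fixtures["table2"] = {
        "variants": t2_variants, "samples": samples, "panel": panel,
        "expected": expected_rows,
    }
    mono_snv = t2_variants[
        (t2_variants["gene"] == "KMA0000")
        & (t2_variants["consequence"] == "stop_gained")
    ].reset_index(drop=True)
    fixtures["table2_known_mono_snv"] = {
        "variants": mono_snv, "samples": samples, "panel": panel,
        "expected": {("autosome_or_PAR", "known_monoallelic", "lof_snv"):
                     (42, 986, 6, 899)},
    }

    # --- headline any-LoF comparison at MAF<1% ---------------------------
    f1_rows: List[dict] = []
    for sid in case_all[:341]:
        f1_rows.append(_plant(sid, "KMA0001", "lof_snv", "het"))
    for sid in comp_all[:222]:
        f1_rows.append(_plant(sid, "KMA0001", "lof_snv", "het"))
    # common LoF alleles in non-carrier samples: removed by the MAF filter
    for sid in case_all[341:371]:
        row = _plant(sid, "KBA0001", "lof_snv", "het")
        row["freq_evs"] = 0.02
        f1_rows.append(row)
    fixtures["fig1_maf1pct"] = {
        "variants": _variants_frame(f1_rows), "samples": samples,
        "panel": panel,
        "expected": {"carriers_case": 341, "n_case": 986,
                     "carriers_comparison": 222, "n_comparison": 899},
    }

    # --- outlier exclusion: 996 samples, 10 above the 30-variant cutoff --
    o_samples = pd.DataFrame(
        {"sample_id": [f"OL{i:05d}" for i in range(996)],
         "sex": "male", "cohort": "case", "qc_pass": True}
    )
    o_rows: List[dict] = []
    for i, sid in enumerate(o_samples["sample_id"]):
        n_var = 31 + (i - 986) if i >= 986 else 2
        for _ in range(n_var):
            o_rows.append(_plant(sid, "KMA0002", "lof_snv", "het"))
    fixtures["outliers_996"] = {
        "variants": _variants_frame(o_rows), "samples": o_samples,
        "panel": panel,
        "expected": {"n_samples": 996, "n_retained": 986, "n_excluded": 10},
    }

    # --- diagnostic-yield union: 77 LoF + 33 missense, 3 dual ------------
    lof_ids = case_all[:77]
    mis_ids = case_all[:3] + case_all[77:107]
    classifications = []
    for i, sid in enumerate(lof_ids):
        classifications.append(
            ClassificationResult(
                variant_key=("autosome", 50000 + i, "C", "T", None),
                sample_id=sid, gene="KMA0000",
                verdict=Verdict.likely_pathogenic, pathway=Pathway.lof_known_gene,
            )
        )
    for i, sid in enumerate(mis_ids):
        classifications.append(
            ClassificationResult(
                variant_key=("autosome", 60000 + i, "G", "C", None),
                sample_id=sid, gene="KMA0001",
                verdict=Verdict.likely_pathogenic,
                pathway=Pathway.missense_known_pathogenic,
            )
        )
    fixtures["yield_107"] = {
        "classifications": classifications, "samples": samples,
        "expected": {"n_lof": 77, "n_missense": 33, "n_both": 3,
                     "n_union": 107, "n_samples": 986},
    }

    # --- damaging-missense comparison ------------------------------------
    lof_excluded = case_all[:86]  # exclusion list as given; denominator 900
    dm_rows: List[dict] = []
    for sid in case_all[86:86 + 284]:
        row = _plant(sid, "KMA0003", "lof_snv", "het")
        row.update(consequence="missense_variant", ref="G", alt="C",
                   variant_class="SNV", polyphen2=0.95, sift=0.03,
                   condel=0.6, cadd=25.0)
        dm_rows.append(row)
    for sid in comp_all[:245]:
        row = _plant(sid, "KMA0003", "lof_snv", "het")
        row.update(consequence="missense_variant", ref="G", alt="C",
                   variant_class="SNV", polyphen2=0.95, sift=0.03,
                   condel=0.6, cadd=25.0)
        dm_rows.append(row)
    fixtures["damaging_missense"] = {
        "variants": _variants_frame(dm_rows), "samples": samples,
        "panel": panel, "lof_excluded": lof_excluded,
        "expected": {"carriers_case": 284, "n_case": 900,
                     "carriers_comparison": 245, "n_comparison": 899},
    }
    return fixtures
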