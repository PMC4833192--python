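"""Inheritance-aware diagnostic triage of LoF and known-pathogenic missense variants.

The engine is a faithful executable form of the proband-only curation
checklist.  LoF variants in known genes are called likely pathogenic when
they fit the gene's inheritance mode, are absent from control sets (unless
the gene is recessive) and sit on the canonical transcript.  Missense
variants are only considered if previously reported pathogenic, then pass
an ordered exclusion checklist; the inherently manual steps (literature
review, pedigree/phenotype assessment) are consumed as input flag columns.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .filtering import add_consequence_class, flag_compound_het
from .records import (
    ClassificationResult,
    GeneDefinition,
    Inheritance,
    Pathway,
    ReasonCode,
    Sex,
    Verdict,
)


class GeneNotInPanelError(KeyError):
    """A variant's gene has no panel definition."""


def panel_index(panel: pd.DataFrame) -> Dict[str, GeneDefinition]:
    """Build a gene-symbol lookup of :class:`GeneDefinition` from a panel table."""
    out: Dict[str, GeneDefinition] = {}
    for row in panel.itertuples(index=False):
        out[row.gene] = GeneDefinition(
            gene=row.gene,
            status=row.status,
            chrom_class=row.chrom_class,
            inheritance=row.inheritance,
            transcript=getattr(row, "transcript", None),
        )
    return out


def _variant_key(row) -> tuple:
    return (row["chrom_class"], int(row["pos"]), row["ref"], row["alt"],
            row.get("transcript"))


def in_controls(row, freq_cols: Sequence[str]) -> bool:
    """True when the allele is seen in any external reference set or in
    another individual of the internal multi-phenotype dataset."""
    for col in freq_cols:
        v = row.get(col)
        if v is not None and pd.notna(v) and v > 0:
            return True
    return int(row["carriers_internal"]) > 1


def mode_consistent(
    row,
    gene: GeneDefinition,
    sample_sex: str,
    comp_het_flag: bool,
    female_manifesting_override: Iterable[str] = (),
) -> bool:
    """Does this genotype fit the gene's expected mode of inheritance?

    Monoallelic genes accept het or hom; biallelic genes require both
    alleles hit (homozygous, or flagged compound het); X-linked genes
    accept male hemizygous (and female homozygous) calls, while female het
    carriers only qualify for genes on the female-manifesting override
    list (severity in female carriers is gene-dependent).
    """
    zyg = row["zygosity"]
    sex = Sex(sample_sex)
    if gene.inheritance is Inheritance.monoallelic:
        return zyg in ("het", "hom")
    if gene.inheritance is Inheritance.biallelic:
        return zyg == "hom" or bool(comp_het_flag)
    # x_linked
    if sex is Sex.male:
        return zyg in ("hemi", "hom")
    if zyg == "hom":
        return True
    return gene.gene in set(female_manifesting_override)


def _mode_reason(row, gene: GeneDefinition, comp_het_flag: bool) -> ReasonCode:
    if (
        gene.inheritance is Inheritance.biallelic
        and row["zygosity"] == "het"
        and not comp_het_flag
    ):
        return ReasonCode.R_RECESSIVE_SINGLE_ALLELE
    return ReasonCode.R_MODE_MISMATCH


def _off_canonical(row, gene: GeneDefinition) -> bool:
    tx = row.get("transcript")
    return (
        tx is not None and pd.notna(tx) and gene.transcript is not None
        and tx != gene.transcript
    )


def triage_lof(
    row,
    gene: GeneDefinition,
    sample_sex: str,
    comp_het_flag: bool,
    freq_cols: Sequence[str],
    female_manifesting_override: Iterable[str] = (),
) -> ClassificationResult:
    """Triage one LoF observation.

    Likely pathogenic requires: known gene, mode-consistent genotype,
    absence from control sets (presence tolerated for recessive genes,
    where healthy carriers are expected), canonical transcript.  Failures
    yield an *uncertain* verdict carrying every independently failing
    reason code.
    """
    reasons = set()
    if gene.status.value == "candidate":
        reasons.add(ReasonCode.R_CANDIDATE_GENE)
    if not mode_consistent(row, gene, sample_sex, comp_het_flag,
                           female_manifesting_override):
        reasons.add(_mode_reason(row, gene, comp_het_flag))
    if gene.inheritance is not Inheritance.biallelic and in_controls(row, freq_cols):
        reasons.add(ReasonCode.R_IN_CONTROLS)
    if _off_canonical(row, gene):
        reasons.add(ReasonCode.R_NOT_CANONICAL_TRANSCRIPT)
    if reasons:
        return ClassificationResult(
            variant_key=_variant_key(row), sample_id=row["sample_id"],
            gene=gene.gene, verdict=Verdict.uncertain, pathway=Pathway.none,
            reason_codes=frozenset(reasons),
        )
    return ClassificationResult(
        variant_key=_variant_key(row), sample_id=row["sample_id"],
        gene=gene.gene, verdict=Verdict.likely_pathogenic,
        pathway=Pathway.lof_known_gene,
    )


def triage_missense(
    row,
    gene: GeneDefinition,
    sample_sex: str,
    comp_het_flag: bool,
    sample_has_lof_diagnosis: bool,
    freq_cols: Sequence[str],
    female_manifesting_override: Iterable[str] = (),
) -> ClassificationResult:
    """Triage one functional (missense-class) observation.

    Only variants previously reported as disease causing are assessed; the
    exclusion checklist then runs in order and stops at the first failing
    rule, so the reason codes identify exactly the rule that removed the
    variant: (i) candidate gene; (ii) present in control sets, tolerated
    for recessive genes; (iii) recessive gene with a single hit allele;
    (iv) literature-excluded flag; (v) a likely pathogenic LoF in the same
    individual better explains the phenotype; (vi/vii) pedigree/phenotype
    mode mismatch, including the genotype not fitting the inheritance
    model.  Survivors are likely pathogenic.
    """
    def _excl(code: ReasonCode) -> ClassificationResult:
        return ClassificationResult(
            variant_key=_variant_key(row), sample_id=row["sample_id"],
            gene=gene.gene, verdict=Verdict.excluded, pathway=Pathway.none,
            reason_codes=frozenset({code}),
        )

    if not bool(row["known_pathogenic"]):
        return _excl(ReasonCode.R_NOT_KNOWN_PATHOGENIC)
    if gene.status.value == "candidate":                               # (i)
        return _excl(ReasonCode.R_CANDIDATE_GENE)
    if gene.inheritance is not Inheritance.biallelic and in_controls(row, freq_cols):
        return _excl(ReasonCode.R_IN_CONTROLS)                         # (ii)
    if gene.inheritance is Inheritance.biallelic and not (
        row["zygosity"] == "hom" or comp_het_flag
    ):
        return _excl(ReasonCode.R_RECESSIVE_SINGLE_ALLELE)             # (iii)
    if bool(row.get("literature_excluded", False)):                    # (iv)
        return _excl(ReasonCode.R_LITERATURE_EXCLUDED)
    if sample_has_lof_diagnosis:                                       # (v)
        return _excl(ReasonCode.R_BETTER_LOF_EXPLANATION)
    if bool(row.get("mode_mismatch", False)) or not mode_consistent(   # (vi/vii)
        row, gene, sample_sex, comp_het_flag, female_manifesting_override
    ):
        return _excl(ReasonCode.R_MODE_MISMATCH)
    return ClassificationResult(
        variant_key=_variant_key(row), sample_id=row["sample_id"],
        gene=gene.gene, verdict=Verdict.likely_pathogenic,
        pathway=Pathway.missense_known_pathogenic,
    )


def triage_cohort(
    variants: pd.DataFrame,
    samples: pd.DataFrame,
    panel: pd.DataFrame,
    female_manifesting_override: Iterable[str] = (),
) -> List[ClassificationResult]:
    """Run the full triage over a filtered variant table.

    LoF observations are triaged first; the resulting set of LoF-diagnosed
    individuals feeds the missense checklist's rule (v).  Records are
    processed in a canonical sort order so verdicts are independent of
    input ordering.
    """
    v = variants
    if "consequence_class" not in v.columns:
        v = add_consequence_class(v)
    if "comp_het_flag" not in v.columns:
        v = flag_compound_het(v)
    v = v.sort_values(["sample_id", "gene", "pos", "ref", "alt"], kind="mergesort")
    genes = panel_index(panel)
    sex_of = dict(zip(samples["sample_id"], samples["sex"]))
    fcols = [c for c in v.columns if c.startswith("freq_")]
    override = set(female_manifesting_override)

    def _gene(symbol: str) -> GeneDefinition:
        try:
            return genes[symbol]
        except KeyError:
            raise GeneNotInPanelError(f"gene {symbol!r} absent from panel") from None

    results: List[ClassificationResult] = []
    lof_rows = v[v["consequence_class"] == "lof"]
    lof_dx: set = set()
    for _, row in lof_rows.iterrows():
        res = triage_lof(row, _gene(row["gene"]), sex_of[row["sample_id"]],
                         bool(row["comp_het_flag"]), fcols, override)
        results.append(res)
        if res.verdict is Verdict.likely_pathogenic:
            lof_dx.add(res.sample_id)

    func_rows = v[v["consequence_class"] == "functional"]
    for _, row in func_rows.iterrows():
        results.append(
            triage_missense(row, _gene(row["gene"]), sex_of[row["sample_id"]],
                            bool(row["comp_het_flag"]), row["sample_id"] in lof_dx,
                            fcols, override)
        )
    return results


def annotate_external_presence(
    classifications: Sequence[ClassificationResult],
    secondary_panel: Mapping[tuple, int],
) -> List[ClassificationResult]:
    """Attach allele counts from a secondary reference panel (reporting only).

    Verdicts are never changed: presence at trace frequency in a large
    anonymised panel does not overturn a likely pathogenic call, it is
    simply reported alongside it.
    """
    out = []
    for c in classifications:
        out.append(
            ClassificationResult(
                variant_key=c.variant_key, sample_id=c.sample_id, gene=c.gene,
                verdict=c.verdict, pathway=c.pathway, reason_codes=c.reason_codes,
                external_presence=int(secondary_panel.get(c.variant_key, 0)),
            )
        )
    return out


def diagnostic_yield(
    classifications: Sequence[ClassificationResult], samples: pd.DataFrame
):
    """Per-sample union of diagnostic pathways over QC-passing samples."""
    from .records import YieldSummary

    if "qc_pass" in samples.columns:
        eligible = set(samples.loc[samples["qc_pass"].astype(bool), "sample_id"])
    else:
        eligible = set(samples["sample_id"])
    lof = {
        c.sample_id for c in classifications
        if c.verdict is Verdict.likely_pathogenic
        and c.pathway is Pathway.lof_known_gene and c.sample_id in eligible
    }
    mis = {
        c.sample_id for c in classifications
        if c.verdict is Verdict.likely_pathogenic
        and c.pathway is Pathway.missense_known_pathogenic and c.sample_id in eligible
    }
    return YieldSummary(
        n_samples=len(eligible),
        n_lof_diagnosed=len(lof),
        n_missense_diagnosed=len(mis),
        n_both=len(lof & mis),
    )


def classifications_to_frame(
    classifications: Sequence[ClassificationResult],
) -> pd.DataFrame:
    """Flatten triage results to a report table (one row per observation)."""
    rows = []
    for c in classifications:
        chrom_class, pos, ref, alt, tx = c.variant_key
        rows.append(
            {
                "sample_id": c.sample_id, "gene": c.gene,
                "chrom_class": chrom_class, "pos": pos, "ref": ref, "alt": alt,
                "transcript": tx, "verdict": c.verdict.value,
                "pathway": c.pathway.value,
                "reason_codes": ";".join(sorted(r.value for r in c.reason_codes)),
                "external_presence": c.external_presence,
            }
        )
    cols = ["sample_id", "gene", "chrom_class", "pos", "ref", "alt", "transcript",
            "verdict", "pathway", "reason_codes", "external_presence"]
    return pd.DataFrame(rows, columns=cols)
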