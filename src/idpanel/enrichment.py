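"""Carrier-level burden testing (CAST) between case and comparison cohorts.

The cohort allelic sums test collapses a category of qualifying variants to
a per-sample carrier indicator and compares carrier counts between two
cohorts with a one-tailed exact test on the 2x2 table (enrichment in the
case cohort).  Strata follow the published analysis: autosome-or-PAR genes
split into known monoallelic / known biallelic / candidate, X-linked genes
(tested in males only) split into known / candidate, each crossed with LoF
SNVs, LoF indels, and synonymous variants as a negative control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .filtering import FilterConfig, add_consequence_class, uniqueness_filter
from .records import ValidationError, VariantRecord

logger = logging.getLogger("idpanel")

CHROM_STRATA = ("autosome_or_PAR", "X_males_only")
GENE_CATEGORIES = ("known_monoallelic", "known_biallelic", "known_x", "candidate")
VARIANT_TYPES = ("lof_snv", "lof_indel", "synonymous", "damaging_missense")

#: (chrom_stratum, gene_category) combinations that exist, in report order.
VALID_STRATA = (
    ("autosome_or_PAR", "known_monoallelic"),
    ("autosome_or_PAR", "known_biallelic"),
    ("autosome_or_PAR", "candidate"),
    ("X_males_only", "known_x"),
    ("X_males_only", "candidate"),
)


@dataclass(frozen=True)
class StratumSpec:
    """One cell of the stratified burden analysis."""

    chrom_stratum: str
    gene_category: str
    variant_type: str

    def __post_init__(self) -> None:
        if self.chrom_stratum not in CHROM_STRATA:
            raise ValidationError(f"bad chrom_stratum {self.chrom_stratum!r}")
        if self.gene_category not in GENE_CATEGORIES:
            raise ValidationError(f"bad gene_category {self.gene_category!r}")
        if self.variant_type not in VARIANT_TYPES:
            raise ValidationError(f"bad variant_type {self.variant_type!r}")
        if (self.chrom_stratum, self.gene_category) not in VALID_STRATA:
            raise ValidationError(
                f"gene category {self.gene_category!r} not valid on "
                f"{self.chrom_stratum!r}"
            )


@dataclass
class EnrichmentResult:
    """One stratified CAST cell: carrier counts, denominators, p-value."""

    stratum: Optional[StratumSpec]
    carriers_case: int
    n_case: int
    carriers_comparison: int
    n_comparison: int
    p_value: float
    alpha_adjusted: float
    n_genes: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 <= self.carriers_case <= self.n_case):
            raise ValidationError("case carrier count outside [0, n_case]")
        if not (0 <= self.carriers_comparison <= self.n_comparison):
            raise ValidationError("comparison carrier count outside [0, n]")
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside (0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha_adjusted


def cast_test(
    carriers_case: int,
    n_case: int,
    carriers_comparison: int,
    n_comparison: int,
    alternative: str = "greater",
) -> float:
    """Exact conditional tail probability for a 2x2 carrier table.

    With both margins fixed, the case carrier count is hypergeometric under
    the null of equal carrier probability; the returned p is the
    probability of a table at least as extreme in the stated direction
    (default: enrichment in the case cohort).
    """
    if alternative not in ("greater", "less", "two-sided", "two_sided"):
        raise ValidationError(f"bad alternative {alternative!r}")
    for k, n in ((carriers_case, n_case), (carriers_comparison, n_comparison)):
        if n < 0 or not (0 <= k <= n):
            raise ValidationError(
                f"inconsistent counts: {carriers_case}/{n_case}, "
                f"{carriers_comparison}/{n_comparison}"
            )
    table = [
        [carriers_case, n_case - carriers_case],
        [carriers_comparison, n_comparison - carriers_comparison],
    ]
    alt = "two-sided" if alternative == "two_sided" else alternative
    return float(fisher_exact(table, alternative=alt)[1])


def damaging_missense_mask(variants):
    """Consensus in-silico damaging filter for missense variants.

    True only when all four scores call damage (PolyPhen2 > 0.9,
    SIFT < 0.06, Condel > 0.47, CADD Phred > 20, strict inequalities) and
    the allele is absent from every reference set.  A missing score never
    counts as damaging.  Accepts a variant table (returns a boolean
    Series) or a single :class:`VariantRecord` (returns bool).
    """
    if isinstance(variants, VariantRecord):
        s = variants.scores
        vals = [s.get(k) for k in ("polyphen2", "sift", "condel", "cadd")]
        if any(v is None or pd.isna(v) for v in vals):
            return False
        pp2, sift, condel, cadd = vals
        if any(f > 0 for f in variants.ref_freqs.values()):
            return False
        return (
            variants.consequence_term == "missense_variant"
            and pp2 > 0.9 and sift < 0.06 and condel > 0.47 and cadd > 20
        )
    df = variants
    mask = df["consequence"] == "missense_variant"
    pp2 = pd.to_numeric(df["polyphen2"], errors="coerce")
    sift = pd.to_numeric(df["sift"], errors="coerce")
    condel = pd.to_numeric(df["condel"], errors="coerce")
    cadd = pd.to_numeric(df["cadd"], errors="coerce")
    mask &= (pp2 > 0.9) & (sift < 0.06) & (condel > 0.47) & (cadd > 20)
    for col in (c for c in df.columns if c.startswith("freq_")):
        vals = pd.to_numeric(df[col], errors="coerce")
        mask &= ~(vals > 0).fillna(False)
    return mask.fillna(False)


def _category_genes(panel: pd.DataFrame, stratum: StratumSpec) -> Set[str]:
    status = panel["status"]
    inher = panel["inheritance"]
    chrom = panel["chrom_class"]
    cat = stratum.gene_category
    if cat == "known_monoallelic":
        m = (status == "known") & (inher == "monoallelic")
    elif cat == "known_biallelic":
        m = (status == "known") & (inher == "biallelic")
    elif cat == "known_x":
        m = (status == "known") & (inher == "x_linked")
    else:  # candidate, restricted to the chromosome stratum
        m = status == "candidate"
        if stratum.chrom_stratum == "X_males_only":
            m &= chrom == "X"
        else:
            m &= chrom != "X"
    return set(panel.loc[m, "gene"])


def _type_mask(variants: pd.DataFrame, variant_type: str) -> pd.Series:
    if variant_type == "lof_snv":
        return (variants["consequence_class"] == "lof") & (
            variants["variant_class"] == "SNV"
        )
    if variant_type == "lof_indel":
        return (variants["consequence_class"] == "lof") & (
            variants["variant_class"] == "indel"
        )
    if variant_type == "synonymous":
        return variants["consequence_class"] == "synonymous"
    return damaging_missense_mask(variants)


def carrier_counts(
    variants: pd.DataFrame,
    samples: pd.DataFrame,
    panel: pd.DataFrame,
    stratum: StratumSpec,
    uniqueness: float = 0.0005,
    cfg: Optional[FilterConfig] = None,
    case_label: str = "case",
    comparison_label: str = "comparison",
) -> Tuple[int, int, int, int]:
    """Count samples carrying >=1 qualifying variant in each cohort.

    A sample counts at most once however many qualifying variants it has.
    The X stratum restricts both numerators and denominators to males.
    """
    cfg = cfg or FilterConfig()
    if "consequence_class" not in variants.columns:
        variants = add_consequence_class(variants, cfg)

    genes = _category_genes(panel, stratum)
    if not genes:
        logger.warning("empty stratum %s: no matching panel genes", stratum)

    v = variants[variants["gene"].isin(genes)]
    if stratum.chrom_stratum == "X_males_only":
        v = v[v["chrom_class"] == "X"]
        males = set(samples.loc[samples["sex"] == "male", "sample_id"])
        pool = samples[samples["sample_id"].isin(males)]
    else:
        v = v[v["chrom_class"].isin(("autosome", "PAR"))]
        pool = samples
    v = v[_type_mask(v, stratum.variant_type)]
    v = uniqueness_filter(v, uniqueness, cfg)

    carriers = set(v["sample_id"])
    case_ids = set(pool.loc[pool["cohort"] == case_label, "sample_id"])
    comp_ids = set(pool.loc[pool["cohort"] == comparison_label, "sample_id"])
    return (
        len(carriers & case_ids), len(case_ids),
        len(carriers & comp_ids), len(comp_ids),
    )


def stratified_table(
    variants: pd.DataFrame,
    samples: pd.DataFrame,
    panel: pd.DataFrame,
    uniqueness: float = 0.0005,
    alpha: float = 0.05,
    bonferroni_m: int = 10,
    cfg: Optional[FilterConfig] = None,
    case_label: str = "case",
    comparison_label: str = "comparison",
) -> List[EnrichmentResult]:
    """Full stratified CAST table of unique-variant carrier burden.

    One row per valid (chromosome stratum x gene category) combination and
    variant type (LoF SNV, LoF indel, synonymous control): 15 rows.  The
    Bonferroni family comprises the 10 LoF tests (5 strata x 2 LoF types);
    synonymous rows are negative controls outside the family and are never
    flagged significant.
    """
    cfg = cfg or FilterConfig()
    if "consequence_class" not in variants.columns:
        variants = add_consequence_class(variants, cfg)
    alpha_lof = alpha / bonferroni_m
    out: List[EnrichmentResult] = []
    for chrom_stratum, gene_category in VALID_STRATA:
        for vtype in ("lof_snv", "lof_indel", "synonymous"):
            spec = StratumSpec(chrom_stratum, gene_category, vtype)
            a, n1, b, n2 = carrier_counts(
                variants, samples, panel, spec, uniqueness, cfg,
                case_label, comparison_label,
            )
            p = cast_test(a, n1, b, n2, "greater")
            out.append(
                EnrichmentResult(
                    stratum=spec, carriers_case=a, n_case=n1,
                    carriers_comparison=b, n_comparison=n2, p_value=p,
                    alpha_adjusted=alpha_lof if vtype != "synonymous" else 0.0,
                    n_genes=len(_category_genes(panel, spec)),
                )
            )
    logger.info("stage=stratified_table rows=%d uniqueness=%g", len(out), uniqueness)
    return out


def threshold_sweep(
    variants: pd.DataFrame,
    samples: pd.DataFrame,
    thresholds: Optional[Sequence[float]] = None,
    cfg: Optional[FilterConfig] = None,
    case_label: str = "case",
    comparison_label: str = "comparison",
) -> pd.DataFrame:
    """Carrier fractions with >=1 LoF in any panel gene per frequency rung.

    Sweeps the internal-frequency ladder; the loosest rung (equal to the
    MAF threshold) reproduces the headline any-LoF carrier comparison, the
    tightest retains unique variants only.
    """
    cfg = cfg or FilterConfig()
    thresholds = list(thresholds if thresholds is not None
                      else cfg.internal_freq_thresholds)
    if "consequence_class" not in variants.columns:
        variants = add_consequence_class(variants, cfg)
    lof = variants[variants["consequence_class"] == "lof"]
    case_ids = set(samples.loc[samples["cohort"] == case_label, "sample_id"])
    comp_ids = set(samples.loc[samples["cohort"] == comparison_label, "sample_id"])
    rows = []
    for t in thresholds:
        carriers = set(uniqueness_filter(lof, t, cfg)["sample_id"])
        a, b = len(carriers & case_ids), len(carriers & comp_ids)
        rows.append(
            {
                "threshold": t,
                "carriers_case": a, "n_case": len(case_ids),
                "frac_case": a / len(case_ids) if case_ids else 0.0,
                "carriers_comparison": b, "n_comparison": len(comp_ids),
                "frac_comparison": b / len(comp_ids) if comp_ids else 0.0,
                "p_value": cast_test(a, len(case_ids), b, len(comp_ids), "greater"),
            }
        )
    return pd.DataFrame(rows)


def damaging_missense_cast(
    variants: pd.DataFrame,
    samples: pd.DataFrame,
    panel: pd.DataFrame,
    lof_diagnosed_sample_ids: Iterable[str],
    uniqueness: float = 0.0005,
    cfg: Optional[FilterConfig] = None,
    alpha: float = 0.05,
    case_label: str = "case",
    comparison_label: str = "comparison",
) -> EnrichmentResult:
    """CAST on unique consensus-damaging missense carriers.

    Individuals already explained by a clearly causal LoF are removed from
    the case cohort (the exclusion list is taken as given and the
    resulting denominator reported).  Carriers of >=1 unique damaging
    missense variant in any panel gene are compared one-tailed.
    """
    cfg = cfg or FilterConfig()
    excluded = set(lof_diagnosed_sample_ids)
    s = samples[~((samples["cohort"] == case_label)
                  & samples["sample_id"].isin(excluded))]
    panel_genes = set(panel["gene"])
    v = variants[variants["gene"].isin(panel_genes)]
    v = v[damaging_missense_mask(v)]
    v = uniqueness_filter(v, uniqueness, cfg)
    carriers = set(v["sample_id"])
    case_ids = set(s.loc[s["cohort"] == case_label, "sample_id"])
    comp_ids = set(s.loc[s["cohort"] == comparison_label, "sample_id"])
    a, n1 = len(carriers & case_ids), len(case_ids)
    b, n2 = len(carriers & comp_ids), len(comp_ids)
    return EnrichmentResult(
        stratum=None, carriers_case=a, n_case=n1,
        carriers_comparison=b, n_comparison=n2,
        p_value=cast_test(a, n1, b, n2, "greater"), alpha_adjusted=alpha,
    )


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Report table mirroring the published layout (freq cells "k/n (pct)")."""
    rows = []
    for r in results:
        spec = r.stratum
        rows.append(
            {
                "chrom_stratum": spec.chrom_stratum if spec else "all",
                "gene_category": spec.gene_category if spec else "panel",
                "n_genes": r.n_genes,
                "variant_type": spec.variant_type if spec else "damaging_missense",
                "carriers_case": r.carriers_case,
                "n_case": r.n_case,
                "freq_case": f"{r.carriers_case}/{r.n_case} "
                             f"({100 * r.carriers_case / max(r.n_case, 1):.2f}%)",
                "carriers_comparison": r.carriers_comparison,
                "n_comparison": r.n_comparison,
                "freq_comparison": f"{r.carriers_comparison}/{r.n_comparison} "
                f"({100 * r.carriers_comparison / max(r.n_comparison, 1):.2f}%)",
                "p_value": r.p_value,
                "alpha_adjusted": r.alpha_adjusted,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)
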