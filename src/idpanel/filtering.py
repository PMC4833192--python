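"""Rare-variant filtering: frequency, consequence class, outliers, uniqueness.

Stage order follows the cohort analysis: the frequency filter (MAF < 1% in
every external reference set and in the internal multi-phenotype dataset)
runs first, per-sample outlier exclusion runs on the frequency-filtered
counts, and the uniqueness ladder (internal frequency 1%, 0.5%, 0.1%,
0.05%) is applied inside the burden tests.  All boundary comparisons are
strict: a frequency exactly equal to a threshold is dropped, and a sample
with exactly the cutoff number of variants is retained ("more than" the
cutoff excludes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import (
    ConsequenceClass,
    FUNCTIONAL_TERMS,
    KNOWN_TERMS,
    LOF_TERMS,
    SYNONYMOUS_TERMS,
    ValidationError,
    VariantRecord,
)

logger = logging.getLogger("idpanel")


class UnknownConsequenceError(ValueError):
    """A consequence term outside the controlled vocabulary was seen."""


@dataclass
class FilterConfig:
    """Thresholds for the rare-variant filtering stages.

    maf_threshold
        External/internal minor-allele-frequency cutoff; variants at or
        above it in any reference set are dropped (default 1%).
    internal_freq_thresholds
        Strictly decreasing ladder of internal carrier-frequency cutoffs
        swept in the enrichment analysis; the smallest (0.05% of 2,812
        individuals) retains only variants seen in a single individual.
    outlier_variant_cutoff
        Samples with more than this many variants after frequency
        filtering are excluded as technical outliers (default 30).
    internal_cohort_size
        Number of individuals in the multi-phenotype dataset used as the
        internal-frequency denominator (default 2,812).
    """

    maf_threshold: float = 0.01
    internal_freq_thresholds: Sequence[float] = (0.01, 0.005, 0.001, 0.0005)
    outlier_variant_cutoff: int = 30
    internal_cohort_size: int = 2812
    extra_other_terms: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        ladder = tuple(self.internal_freq_thresholds)
        if any(a <= b for a, b in zip(ladder, ladder[1:])):
            raise ValidationError(
                f"internal_freq_thresholds must be strictly decreasing: {ladder}"
            )
        if self.outlier_variant_cutoff <= 0:
            raise ValidationError("outlier_variant_cutoff must be positive")
        self.internal_freq_thresholds = ladder
        self.extra_other_terms = frozenset(self.extra_other_terms)


def classify_consequence(
    term: str, extra_other_terms: Iterable[str] = ()
) -> ConsequenceClass:
    """Map a consequence term to its coarse class.

    Unknown terms raise: triage correctness depends on the vocabulary, so
    nothing is silently mapped to ``other``.  ``other`` is only returned
    for terms the caller explicitly configured as ignorable.
    """
    if term in LOF_TERMS:
        return ConsequenceClass.lof
    if term in FUNCTIONAL_TERMS:
        return ConsequenceClass.functional
    if term in SYNONYMOUS_TERMS:
        return ConsequenceClass.synonymous
    if term in set(extra_other_terms):
        return ConsequenceClass.other
    raise UnknownConsequenceError(f"unknown consequence term: {term!r}")


def add_consequence_class(
    variants: pd.DataFrame, cfg: Optional[FilterConfig] = None
) -> pd.DataFrame:
    """Vectorised consequence classification; adds ``consequence_class``."""
    cfg = cfg or FilterConfig()
    terms = set(variants["consequence"].unique())
    unknown = terms - KNOWN_TERMS - cfg.extra_other_terms
    if unknown:
        raise UnknownConsequenceError(
            f"unknown consequence terms: {sorted(unknown)}"
        )
    out = variants.copy()
    cls = pd.Series(ConsequenceClass.other.value, index=out.index)
    cons = out["consequence"]
    cls[cons.isin(LOF_TERMS)] = ConsequenceClass.lof.value
    cls[cons.isin(FUNCTIONAL_TERMS)] = ConsequenceClass.functional.value
    cls[cons.isin(SYNONYMOUS_TERMS)] = ConsequenceClass.synonymous.value
    out["consequence_class"] = cls
    return out


def freq_columns(variants: pd.DataFrame) -> list:
    return [c for c in variants.columns if c.startswith("freq_")]


def frequency_filter(
    record: VariantRecord, cfg: FilterConfig
) -> Tuple[bool, Optional[str]]:
    """Keep/drop decision for one record under the MAF threshold.

    Drops when any reference-set frequency, or the internal carrier
    frequency, reaches the threshold (strict "<" keeps).  Absent
    frequencies mean the allele was never observed in that set.
    """
    for name, f in record.ref_freqs.items():
        if not (0.0 <= f <= 1.0):
            raise ValidationError(f"frequency {name}={f} outside [0, 1]")
        if f >= cfg.maf_threshold:
            return False, f"ref_freq_{name}"
    internal = record.internal_carrier_count / cfg.internal_cohort_size
    if internal >= cfg.maf_threshold:
        return False, "internal_freq"
    return True, None


def frequency_filter_table(
    variants: pd.DataFrame, cfg: Optional[FilterConfig] = None
) -> pd.DataFrame:
    """Apply the MAF filter to a variant table.

    Adds ``keep_flag`` and ``drop_reason`` columns; the caller decides
    whether to subset.  NaN frequencies are treated as unobserved.
    """
    cfg = cfg or FilterConfig()
    out = variants.copy()
    keep = np.ones(len(out), dtype=bool)
    reason = np.array([""] * len(out), dtype=object)
    for col in freq_columns(out):
        vals = out[col].to_numpy(dtype=float)
        bad = np.isfinite(vals) & ((vals < 0) | (vals > 1))
        if bad.any():
            raise ValidationError(f"column {col}: frequencies outside [0, 1]")
        hit = np.isfinite(vals) & (vals >= cfg.maf_threshold)
        reason[hit & keep] = f"ref_{col}"
        keep &= ~hit
    internal = out["carriers_internal"].to_numpy(dtype=float) / cfg.internal_cohort_size
    hit = internal >= cfg.maf_threshold
    reason[hit & keep] = "internal_freq"
    keep &= ~hit
    out["keep_flag"] = keep
    out["drop_reason"] = reason
    logger.info(
        "stage=frequency_filter in=%d kept=%d dropped=%d",
        len(out), int(keep.sum()), int((~keep).sum()),
    )
    return out


def exclude_outlier_samples(
    samples: pd.DataFrame, variants: pd.DataFrame, cfg: Optional[FilterConfig] = None
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude samples carrying more than the cutoff number of variants.

    ``variants`` must already be frequency-filtered (use the kept subset).
    Returns (retained, excluded) sample tables with a recomputed
    ``variant_count`` column.  Idempotent: re-running on the retained set
    excludes nothing further.
    """
    cfg = cfg or FilterConfig()
    counts = variants.groupby("sample_id").size()
    out = samples.copy()
    out["variant_count"] = out["sample_id"].map(counts).fillna(0).astype(int)
    mask = out["variant_count"] > cfg.outlier_variant_cutoff
    excluded = out[mask].copy()
    retained = out[~mask].copy()
    logger.info(
        "stage=outlier_exclusion in=%d retained=%d excluded=%d cutoff=%d",
        len(out), len(retained), len(excluded), cfg.outlier_variant_cutoff,
    )
    return retained, excluded


def uniqueness_filter(
    variants: pd.DataFrame,
    threshold: float,
    cfg: Optional[FilterConfig] = None,
) -> pd.DataFrame:
    """Retain variants whose internal carrier frequency is below ``threshold``.

    At the 0.05% rung with the default 2,812-individual denominator this
    keeps exactly the variants carried by a single individual ("unique"
    variants).
    """
    cfg = cfg or FilterConfig()
    if threshold not in cfg.internal_freq_thresholds:
        logger.warning(
            "uniqueness threshold %g not in configured ladder %s; honoring anyway",
            threshold, cfg.internal_freq_thresholds,
        )
    internal = variants["carriers_internal"].to_numpy(dtype=float) / cfg.internal_cohort_size
    return variants[internal < threshold]


def flag_compound_het(variants: pd.DataFrame) -> pd.DataFrame:
    """Flag potential compound heterozygotes per (sample, gene).

    A sample is flagged for a gene when it carries two or more distinct
    heterozygous variants there; homozygous and hemizygous calls do not
    contribute (they are handled by their own inheritance pathway).  Adds a
    boolean ``comp_het_flag`` column set on every record of a flagged
    (sample, gene) pair.
    """
    out = variants.copy()
    het = out[out["zygosity"] == "het"]
    if len(het):
        distinct = het.drop_duplicates(subset=["sample_id", "gene", "pos", "ref", "alt"])
        counts = distinct.groupby(["sample_id", "gene"]).size()
        flagged = set(counts[counts >= 2].index)
    else:
        flagged = set()
    pairs = list(zip(out["sample_id"], out["gene"]))
    out["comp_het_flag"] = [p in flagged for p in pairs]
    return out


def filter_pipeline(
    variants: pd.DataFrame,
    samples: pd.DataFrame,
    cfg: Optional[FilterConfig] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Frequency filter, outlier exclusion, consequence classes, comp-het flags.

    Returns (filtered variants restricted to retained samples, retained
    samples, excluded samples).
    """
    cfg = cfg or FilterConfig()
    flagged = frequency_filter_table(variants, cfg)
    kept = flagged[flagged["keep_flag"]].copy()
    retained, excluded = exclude_outlier_samples(samples, kept, cfg)
    kept = kept[kept["sample_id"].isin(set(retained["sample_id"]))]
    kept = add_consequence_class(kept, cfg)
    kept = flag_compound_het(kept)
    logger.info(
        "stage=filter_pipeline variants_out=%d samples_out=%d", len(kept), len(retained)
    )
    return kept, retained, excluded
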