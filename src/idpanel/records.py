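"""Domain records for the proband-only gene-panel pipeline.

The pipeline moves variant observations, panel genes and proband metadata
between stages.  Bulk operations work on pandas DataFrames whose columns
mirror these records (see :mod:`idpanel.io` for the on-disk dialects); the
dataclasses here are the validated per-row views used at I/O boundaries and
in the rule engine, where per-record reasoning is clearer than vectorised
code.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional


class ChromClass(str, enum.Enum):
    """Chromosome class for burden stratification.

    Pseudo-autosomal (PAR) variants behave like autosomal ones in both
    cohorts' sexes and are tested together with autosomes.
    """

    autosome = "autosome"
    PAR = "PAR"
    X = "X"


class VariantClass(str, enum.Enum):
    SNV = "SNV"
    indel = "indel"


class Zygosity(str, enum.Enum):
    het = "het"
    hom = "hom"
    hemi = "hemi"


class GeneStatus(str, enum.Enum):
    known = "known"
    candidate = "candidate"


class Inheritance(str, enum.Enum):
    monoallelic = "monoallelic"
    biallelic = "biallelic"
    x_linked = "x_linked"


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class ConsequenceClass(str, enum.Enum):
    """Coarse functional impact classes used throughout the analysis.

    ``lof`` covers nonsense, frameshift and the two essential (canonical
    dinucleotide) splice-site classes; ``functional`` covers missense,
    inframe indels and stop-codon loss; ``other`` is reserved for terms a
    user explicitly configures as ignorable — unknown terms are rejected.
    """

    lof = "lof"
    functional = "functional"
    synonymous = "synonymous"
    other = "other"


class Verdict(str, enum.Enum):
    likely_pathogenic = "likely_pathogenic"
    uncertain = "uncertain"
    excluded = "excluded"


class Pathway(str, enum.Enum):
    lof_known_gene = "lof_known_gene"
    missense_known_pathogenic = "missense_known_pathogenic"
    none = "none"


class ReasonCode(str, enum.Enum):
    """Machine-readable grounds for a non-diagnostic verdict."""

    R_CANDIDATE_GENE = "R_CANDIDATE_GENE"
    R_IN_CONTROLS = "R_IN_CONTROLS"
    R_RECESSIVE_SINGLE_ALLELE = "R_RECESSIVE_SINGLE_ALLELE"
    R_LITERATURE_EXCLUDED = "R_LITERATURE_EXCLUDED"
    R_BETTER_LOF_EXPLANATION = "R_BETTER_LOF_EXPLANATION"
    R_MODE_MISMATCH = "R_MODE_MISMATCH"
    R_NOT_CANONICAL_TRANSCRIPT = "R_NOT_CANONICAL_TRANSCRIPT"
    R_NOT_KNOWN_PATHOGENIC = "R_NOT_KNOWN_PATHOGENIC"


#: Controlled consequence vocabulary -> coarse class.
LOF_TERMS = frozenset(
    {
        "stop_gained",
        "frameshift_variant",
        "splice_donor_variant",
        "splice_acceptor_variant",
    }
)
FUNCTIONAL_TERMS = frozenset(
    {"missense_variant", "inframe_insertion", "inframe_deletion", "stop_lost"}
)
SYNONYMOUS_TERMS = frozenset({"synonymous_variant"})
KNOWN_TERMS = LOF_TERMS | FUNCTIONAL_TERMS | SYNONYMOUS_TERMS

SCORE_NAMES = ("polyphen2", "sift", "condel", "cadd")


class ValidationError(ValueError):
    """An input record violates a structural invariant."""


@dataclass
class VariantRecord:
    """One observed variant call in one proband.

    ``ref_freqs`` maps reference-set name to the allele frequency observed
    there; an absent key means the allele was never seen in that set.
    ``internal_carrier_count`` counts carriers across the full
    multi-phenotype internal dataset (all sequenced disease cohorts), and is
    at least 1 because the observation itself is a carrier.
    """

    sample_id: str
    gene: str
    chrom_class: ChromClass
    position: int
    ref: str
    alt: str
    consequence_term: str
    variant_class: VariantClass
    zygosity: Zygosity
    ref_freqs: Mapping[str, float] = field(default_factory=dict)
    internal_carrier_count: int = 1
    scores: Mapping[str, float] = field(default_factory=dict)
    known_pathogenic: bool = False
    transcript: Optional[str] = None
    literature_excluded: bool = False
    mode_mismatch: bool = False

    def __post_init__(self) -> None:
        self.chrom_class = ChromClass(self.chrom_class)
        self.variant_class = VariantClass(self.variant_class)
        self.zygosity = Zygosity(self.zygosity)
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")
        if self.internal_carrier_count < 1:
            raise ValidationError(
                "internal_carrier_count must be >= 1 for an observed variant, "
                f"got {self.internal_carrier_count}"
            )
        for name, freq in self.ref_freqs.items():
            if not (0.0 <= freq <= 1.0):
                raise ValidationError(
                    f"reference frequency {name}={freq} outside [0, 1]"
                )
        if self.zygosity is Zygosity.hemi and self.chrom_class is not ChromClass.X:
            raise ValidationError(
                f"hemizygous call on {self.chrom_class.value}: only valid on X"
            )

    @property
    def key(self) -> tuple:
        """Identity key for allele-sharing: same allele, same transcript."""
        return (self.chrom_class.value, self.position, self.ref, self.alt, self.transcript)


@dataclass
class GeneDefinition:
    """One panel entry: disease-association status and inheritance model."""

    gene: str
    status: GeneStatus
    chrom_class: ChromClass
    inheritance: Inheritance
    transcript: Optional[str] = None

    def __post_init__(self) -> None:
        self.status = GeneStatus(self.status)
        self.chrom_class = ChromClass(self.chrom_class)
        self.inheritance = Inheritance(self.inheritance)
        x_gene = self.chrom_class is ChromClass.X
        x_mode = self.inheritance is Inheritance.x_linked
        if x_gene != x_mode:
            raise ValidationError(
                f"gene {self.gene}: inheritance {self.inheritance.value} "
                f"inconsistent with chromosome class {self.chrom_class.value}"
            )


@dataclass
class SampleRecord:
    sample_id: str
    sex: Sex
    cohort: str
    qc_pass: bool = True
    variant_count: int = 0

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        if self.variant_count < 0:
            raise ValidationError("variant_count must be non-negative")


@dataclass
class ClassificationResult:
    """Triage verdict for one (variant, sample) observation."""

    variant_key: tuple
    sample_id: str
    gene: str
    verdict: Verdict
    pathway: Pathway = Pathway.none
    reason_codes: frozenset = frozenset()
    external_presence: Optional[int] = None

    def __post_init__(self) -> None:
        self.verdict = Verdict(self.verdict)
        self.pathway = Pathway(self.pathway)
        self.reason_codes = frozenset(ReasonCode(r) for r in self.reason_codes)
        if self.verdict is Verdict.excluded and not self.reason_codes:
            raise ValidationError("excluded verdict requires at least one reason code")
        if self.verdict is Verdict.likely_pathogenic and self.pathway is Pathway.none:
            raise ValidationError("likely_pathogenic verdict requires a pathway")


@dataclass
class YieldSummary:
    """Cohort diagnostic yield with inclusion–exclusion accounting.

    Individuals diagnosed through both the LoF and the missense pathway are
    counted once in the union.
    """

    n_samples: int
    n_lof_diagnosed: int
    n_missense_diagnosed: int
    n_both: int

    @property
    def n_diagnosed_union(self) -> int:
        return self.n_lof_diagnosed + self.n_missense_diagnosed - self.n_both

    @property
    def yield_fraction(self) -> float:
        return self.n_diagnosed_union / self.n_samples if self.n_samples else 0.0
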