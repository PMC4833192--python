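"""Synthetic case/comparison cohort generator with known ground truth.

The generator emulates the statistical structure the pipeline assumes: a
gene panel of known and candidate disease genes, probands carrying
Poisson-distributed background rare variants (LoF, missense-class,
synonymous, plus common alleles the frequency filter must remove), and a
configurable fraction of cases with a planted diagnostic variant that is
unique, absent from reference sets, and consistent with the gene's
inheritance mode.  The comparison cohort receives background only.  Every
planted event is recorded so recovery by the triage engine and carrier
counts in the burden tests can be checked against ground truth.

Background sharing and control-set presence are calibrated so that most
background LoF carriers look non-diagnostic (the variant recurs internally
or appears in an external control, or sits in a candidate gene or as a
single het allele in a recessive gene), leaving a small residual of
diagnostic-looking background — the structure observed in the comparison
cohort of the study this pipeline models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import ValidationError

REFERENCE_SETS = ("1000g", "uk10k_twins", "evs", "inhouse")

VARIANT_COLUMNS = [
    "sample_id", "gene", "chrom_class", "pos", "ref", "alt", "consequence",
    "variant_class", "zygosity", "carriers_internal",
    "polyphen2", "sift", "condel", "cadd",
    "known_pathogenic", "literature_excluded", "mode_mismatch", "transcript",
] + [f"freq_{s}" for s in REFERENCE_SETS]

_LOF_CONSEQ = np.array(
    ["stop_gained", "frameshift_variant", "splice_donor_variant",
     "splice_acceptor_variant"]
)
# mix matching the observed LoF composition (~40% nonsense, 35% frameshift,
# 15% donor, 10% acceptor)
_LOF_P = np.array([0.40, 0.35, 0.15, 0.10])
_FUNC_CONSEQ = np.array(
    ["missense_variant", "inframe_insertion", "inframe_deletion", "stop_lost"]
)
_FUNC_P = np.array([0.96, 0.015, 0.015, 0.01])

_ALLELES = {
    "stop_gained": ("C", "T"),
    "frameshift_variant": ("AT", "A"),
    "splice_donor_variant": ("G", "A"),
    "splice_acceptor_variant": ("A", "G"),
    "missense_variant": ("G", "C"),
    "inframe_insertion": ("A", "ACCC"),
    "inframe_deletion": ("TGGG", "T"),
    "stop_lost": ("T", "C"),
    "synonymous_variant": ("G", "A"),
}


def _allocate(total: int, weights: Sequence[float]) -> List[int]:
    """Largest-remainder allocation of ``total`` over ``weights``."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValidationError("weights must be positive")
    exact = total * w / w.sum()
    counts = np.floor(exact).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(exact - counts))
    counts[order[:rem]] += 1
    return counts.tolist()


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohorts.

    Sample sizes, sex ratios, panel composition and per-person variant
    rates default to the modelled study: 986 cases (93.8% male) vs 899
    comparison probands (466 males), a 565-gene panel (253 known / 312
    candidate), 0.46 LoF and 8 missense-class rare variants per case.
    ``planted_*`` fractions control the simulated true diagnostic content
    of the case cohort; ``dual_pathway_overlap`` cases receive both a LoF
    and a missense diagnosis.
    """

    n_case: int = 986
    n_comparison: int = 899
    male_fraction_case: float = 0.938
    male_fraction_comparison: float = 466 / 899

    panel_size: int = 565
    n_known: int = 253
    n_candidate: int = 312
    known_category_weights: Tuple[float, float, float] = (78, 86, 89)
    candidate_category_weights: Tuple[float, float] = (162, 150)

    mean_lof_per_person: float = 0.46
    mean_lof_per_person_comparison: float = 0.28
    mean_missense_per_person: float = 8.0
    mean_synonymous_per_person: float = 4.0
    mean_common_per_person: float = 1.0

    planted_lof_diagnostic_fraction: float = 0.08
    planted_missense_diagnostic_fraction: float = 0.03
    dual_pathway_overlap: int = 3

    background_reference_presence_prob: float = 0.6
    background_shared_prob: float = 0.55
    damaging_score_prob: float = 0.22
    background_known_pathogenic_prob: float = 0.0
    background_hom_prob: float = 0.01

    gene_weights: Optional[Sequence[float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("male_fraction_case", "male_fraction_comparison",
                     "planted_lof_diagnostic_fraction",
                     "planted_missense_diagnostic_fraction",
                     "background_reference_presence_prob",
                     "background_shared_prob", "damaging_score_prob",
                     "background_known_pathogenic_prob", "background_hom_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if (self.planted_lof_diagnostic_fraction
                + self.planted_missense_diagnostic_fraction) > 1.0:
            raise ValidationError("planted fractions sum above 1")
        for name in ("mean_lof_per_person", "mean_missense_per_person",
                     "mean_synonymous_per_person", "mean_common_per_person",
                     "mean_lof_per_person_comparison"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.n_known + self.n_candidate != self.panel_size:
            raise ValidationError(
                f"known ({self.n_known}) + candidate ({self.n_candidate}) "
                f"must equal panel_size ({self.panel_size})"
            )

    @property
    def background_lof_mean_case(self) -> float:
        """Case background LoF rate: observed mean minus the planted share."""
        return max(self.mean_lof_per_person
                   - self.planted_lof_diagnostic_fraction, 0.0)


@dataclass
class GroundTruth:
    """Planted diagnostic events and derived per-sample truth."""

    planted: pd.DataFrame  # sample_id, pathway, gene, chrom_class, pos, ref, alt
    n_case: int

    @property
    def lof_samples(self) -> set:
        return set(self.planted.loc[self.planted["pathway"] == "lof", "sample_id"])

    @property
    def missense_samples(self) -> set:
        return set(
            self.planted.loc[self.planted["pathway"] == "missense", "sample_id"]
        )

    @property
    def diagnosed_samples(self) -> set:
        return self.lof_samples | self.missense_samples

    @property
    def union_fraction(self) -> float:
        return len(self.diagnosed_samples) / self.n_case if self.n_case else 0.0

    @property
    def planted_keys(self) -> set:
        return set(
            zip(self.planted["chrom_class"], self.planted["pos"],
                self.planted["ref"], self.planted["alt"])
        )


def simulate_panel(cfg: Optional[SimulationConfig] = None) -> pd.DataFrame:
    """Deterministic synthetic gene panel.

    Known genes split into monoallelic-autosomal, biallelic-autosomal and
    X-linked categories; candidates into autosomal and X.  The default
    weights reproduce the modelled panel's category sizes (78/86/89 known,
    162/150 candidate).  One known-monoallelic and one candidate autosomal
    gene are placed in the pseudo-autosomal region so PAR handling is
    exercised.
    """
    cfg = cfg or SimulationConfig()
    n_mono, n_bi, n_x = _allocate(cfg.n_known, cfg.known_category_weights)
    n_cand_a, n_cand_x = _allocate(cfg.n_candidate, cfg.candidate_category_weights)
    rows = []
    specs = [
        ("KMA", n_mono, "known", "autosome", "monoallelic"),
        ("KBA", n_bi, "known", "autosome", "biallelic"),
        ("KXL", n_x, "known", "X", "x_linked"),
        ("CAU", n_cand_a, "candidate", "autosome", "monoallelic"),
        ("CXL", n_cand_x, "candidate", "X", "x_linked"),
    ]
    for prefix, n, status, chrom, inher in specs:
        for i in range(n):
            chrom_class = chrom
            if i == n - 1 and n >= 2 and prefix in ("KMA", "CAU"):
                chrom_class = "PAR"
            gene = f"{prefix}{i:04d}"
            rows.append(
                {"gene": gene, "status": status, "chrom_class": chrom_class,
                 "inheritance": inher, "transcript": f"ENST_{gene}"}
            )
    return pd.DataFrame(rows, columns=["gene", "status", "chrom_class",
                                       "inheritance", "transcript"])


def _make_samples(cfg: SimulationConfig) -> pd.DataFrame:
    def cohort(prefix: str, n: int, male_frac: float, label: str) -> pd.DataFrame:
        n_male = int(round(n * male_frac))
        sex = ["male"] * n_male + ["female"] * (n - n_male)
        return pd.DataFrame(
            {"sample_id": [f"{prefix}{i:05d}" for i in range(n)],
             "sex": sex, "cohort": label, "qc_pass": True}
        )

    return pd.concat(
        [cohort("ID", cfg.n_case, cfg.male_fraction_case, "case"),
         cohort("CMP", cfg.n_comparison, cfg.male_fraction_comparison,
                "comparison")],
        ignore_index=True,
    )


class _PosCounter:
    """Hands out distinct genomic positions so unique alleles never collide."""

    def __init__(self, start: int = 1000):
        self.next = start

    def take(self, n: int) -> np.ndarray:
        out = np.arange(self.next, self.next + n)
        self.next += n
        return out


def _background_block(
    sample_ids: np.ndarray,
    sexes: np.ndarray,
    var_class: str,
    cfg: SimulationConfig,
    panel: pd.DataFrame,
    rng: np.random.Generator,
    counter: _PosCounter,
) -> pd.DataFrame:
    """One background variant block ('lof'|'functional'|'synonymous'|'common')."""
    n = len(sample_ids)
    if n == 0:
        return pd.DataFrame(columns=VARIANT_COLUMNS)
    genes = panel["gene"].to_numpy()
    chroms = panel["chrom_class"].to_numpy()
    txs = panel["transcript"].to_numpy()
    if cfg.gene_weights is not None:
        w = np.asarray(cfg.gene_weights, dtype=float)
        gidx = rng.choice(len(genes), size=n, p=w / w.sum())
    else:
        gidx = rng.integers(0, len(genes), size=n)

    if var_class == "lof":
        cons = _LOF_CONSEQ[rng.choice(4, size=n, p=_LOF_P)]
    elif var_class in ("functional", "common"):
        cons = _FUNC_CONSEQ[rng.choice(4, size=n, p=_FUNC_P)]
    else:
        cons = np.full(n, "synonymous_variant")

    refs = np.array([_ALLELES[c][0] for c in cons])
    alts = np.array([_ALLELES[c][1] for c in cons])
    pos = counter.take(n)
    carriers = np.ones(n, dtype=int)
    freq_evs = np.full(n, np.nan)

    # in-silico scores are a property of the allele; drawn per row here and
    # overwritten from the pool for recurring alleles below
    pp2 = np.full(n, np.nan)
    sift = np.full(n, np.nan)
    condel = np.full(n, np.nan)
    cadd = np.full(n, np.nan)

    def _draw_scores(rng, size):
        dmg = rng.random(size) < cfg.damaging_score_prob
        nd = ~dmg
        s_pp2 = np.where(dmg, rng.uniform(0.91, 1.0, size),
                         rng.uniform(0.0, 0.89, size))
        s_sift = np.where(dmg, rng.uniform(0.0, 0.059, size),
                          rng.uniform(0.061, 1.0, size))
        s_condel = np.where(dmg, rng.uniform(0.48, 1.0, size),
                            rng.uniform(0.0, 0.46, size))
        s_cadd = np.where(dmg, rng.uniform(20.5, 40.0, size),
                          rng.uniform(1.0, 19.9, size))
        s_cadd[nd & (rng.random(size) < 0.05)] = np.nan
        return s_pp2, s_sift, s_condel, s_cadd

    if var_class in ("functional", "common"):
        pp2, sift, condel, cadd = _draw_scores(rng, n)

    if var_class == "common":
        # common alleles: high reference frequency, proportionate internal count
        f = rng.uniform(0.01, 0.5, size=n)
        freq_evs = f
        carriers = np.maximum((f * 2812).astype(int), 29)
    else:
        shared = rng.random(n) < cfg.background_shared_prob
        n_shared = int(shared.sum())
        if n_shared:
            # recurring-allele pool shared across cohorts; identical keys
            # carry identical internal counts and reference presence
            n_pool = max(1, n_shared // 3)
            pool_pos = counter.take(n_pool)
            pool_gidx = rng.integers(0, len(genes), size=n_pool)
            pool_carriers = np.minimum(2 + rng.geometric(0.5, size=n_pool), 27)
            pool_present = rng.random(n_pool) < cfg.background_reference_presence_prob
            pool_freq = np.where(
                pool_present, 10 ** rng.uniform(-5, np.log10(0.009), size=n_pool),
                np.nan,
            )
            pool_cons_i = rng.choice(4, size=n_pool,
                                     p=_LOF_P if var_class == "lof" else _FUNC_P)
            if var_class == "lof":
                pool_cons = _LOF_CONSEQ[pool_cons_i]
            elif var_class == "functional":
                pool_cons = _FUNC_CONSEQ[pool_cons_i]
            else:
                pool_cons = np.full(n_pool, "synonymous_variant")
            pick = rng.integers(0, n_pool, size=n_shared)
            pos[shared] = pool_pos[pick]
            gidx[shared] = pool_gidx[pick]
            carriers[shared] = pool_carriers[pick]
            freq_evs[shared] = pool_freq[pick]
            cons[shared] = pool_cons[pick]
            refs[shared] = [_ALLELES[c][0] for c in pool_cons[pick]]
            alts[shared] = [_ALLELES[c][1] for c in pool_cons[pick]]
            if var_class == "functional":
                p_pp2, p_sift, p_condel, p_cadd = _draw_scores(rng, n_pool)
                pp2[shared] = p_pp2[pick]
                sift[shared] = p_sift[pick]
                condel[shared] = p_condel[pick]
                cadd[shared] = p_cadd[pick]
        unique = ~shared
        n_unique = int(unique.sum())
        present = np.zeros(n, dtype=bool)
        present[unique] = (
            rng.random(n_unique) < cfg.background_reference_presence_prob
        )
        freq_evs[present] = 10 ** rng.uniform(-5, np.log10(0.009),
                                              size=int(present.sum()))

    chrom_class = chroms[gidx]
    zyg = np.full(n, "het", dtype=object)
    hom = (rng.random(n) < cfg.background_hom_prob) & (chrom_class != "X")
    zyg[hom] = "hom"
    zyg[(chrom_class == "X") & (sexes == "male")] = "hemi"

    vclass = np.where(
        np.isin(cons, ["frameshift_variant", "inframe_insertion",
                       "inframe_deletion"]),
        "indel", "SNV",
    )

    kp = rng.random(n) < cfg.background_known_pathogenic_prob

    df = pd.DataFrame(
        {
            "sample_id": sample_ids, "gene": genes[gidx],
            "chrom_class": chrom_class, "pos": pos, "ref": refs, "alt": alts,
            "consequence": cons, "variant_class": vclass, "zygosity": zyg,
            "carriers_internal": carriers,
            "polyphen2": pp2, "sift": sift, "condel": condel, "cadd": cadd,
            "known_pathogenic": kp,
            "literature_excluded": False, "mode_mismatch": False,
            "transcript": txs[gidx],
            "freq_1000g": np.nan, "freq_uk10k_twins": np.nan,
            "freq_evs": freq_evs, "freq_inhouse": np.nan,
        }
    )
    return df[VARIANT_COLUMNS]


def _planted_rows(
    cfg: SimulationConfig,
    samples: pd.DataFrame,
    panel: pd.DataFrame,
    rng: np.random.Generator,
    counter: _PosCounter,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Plant diagnostic variants in case samples; returns (rows, truth)."""
    case = samples[samples["cohort"] == "case"]
    sex_of = dict(zip(case["sample_id"], case["sex"]))
    case_ids = case["sample_id"].to_numpy()
    n_lof = int(round(cfg.planted_lof_diagnostic_fraction * cfg.n_case))
    n_mis = int(round(cfg.planted_missense_diagnostic_fraction * cfg.n_case))
    overlap = min(cfg.dual_pathway_overlap, n_lof, n_mis)

    chosen = rng.choice(case_ids, size=n_lof + (n_mis - overlap), replace=False)
    lof_ids = list(chosen[:n_lof])
    mis_ids = list(chosen[:overlap]) + list(chosen[n_lof:])

    mono = panel[(panel["status"] == "known") & (panel["inheritance"] == "monoallelic")]
    bi = panel[(panel["status"] == "known") & (panel["inheritance"] == "biallelic")]
    xl = panel[(panel["status"] == "known") & (panel["inheritance"] == "x_linked")]

    rows, truth = [], []

    def _emit(sid, gene_row, consequence, zygosity, pathway, kp):
        ref, alt = _ALLELES[consequence]
        pos = int(counter.take(1)[0])
        vclass = "indel" if consequence in (
            "frameshift_variant", "inframe_insertion", "inframe_deletion"
        ) else "SNV"
        dmg = consequence == "missense_variant"
        rows.append(
            {
                "sample_id": sid, "gene": gene_row.gene,
                "chrom_class": gene_row.chrom_class, "pos": pos,
                "ref": ref, "alt": alt, "consequence": consequence,
                "variant_class": vclass, "zygosity": zygosity,
                "carriers_internal": 1,
                "polyphen2": rng.uniform(0.95, 1.0) if dmg else np.nan,
                "sift": rng.uniform(0.0, 0.03) if dmg else np.nan,
                "condel": rng.uniform(0.6, 1.0) if dmg else np.nan,
                "cadd": rng.uniform(25, 40) if dmg else np.nan,
                "known_pathogenic": kp,
                "literature_excluded": False, "mode_mismatch": False,
                "transcript": gene_row.transcript,
                "freq_1000g": np.nan, "freq_uk10k_twins": np.nan,
                "freq_evs": np.nan, "freq_inhouse": np.nan,
            }
        )
        truth.append(
            {"sample_id": sid, "pathway": pathway, "gene": gene_row.gene,
             "chrom_class": gene_row.chrom_class, "pos": pos,
             "ref": ref, "alt": alt, "zygosity": zygosity}
        )

    def _pick(df):
        return df.iloc[int(rng.integers(0, len(df)))]

    # mode mix loosely matching the published diagnoses (roughly half
    # dominant-autosomal, half X-linked males, a few recessive)
    for sid in lof_ids:
        male = sex_of[sid] == "male"
        p = np.array([0.48, 0.47, 0.05]) if male else np.array([0.90, 0.0, 0.10])
        mode = ("mono", "x", "bi")[int(rng.choice(3, p=p / p.sum()))]
        cons = str(_LOF_CONSEQ[int(rng.choice(4, p=_LOF_P))])
        if mode == "mono":
            _emit(sid, _pick(mono), cons, "het", "lof", False)
        elif mode == "x":
            _emit(sid, _pick(xl), cons, "hemi", "lof", False)
        else:
            g = _pick(bi)
            if rng.random() < 0.5:
                _emit(sid, g, cons, "hom", "lof", False)
            else:  # compound het: two distinct het LoF alleles in one gene
                cons2 = str(_LOF_CONSEQ[int(rng.choice(4, p=_LOF_P))])
                _emit(sid, g, cons, "het", "lof", False)
                _emit(sid, g, cons2, "het", "lof", False)

    for sid in mis_ids:
        male = sex_of[sid] == "male"
        p = np.array([0.50, 0.47, 0.03]) if male else np.array([0.95, 0.0, 0.05])
        mode = ("mono", "x", "bi")[int(rng.choice(3, p=p / p.sum()))]
        if mode == "mono":
            _emit(sid, _pick(mono), "missense_variant", "het", "missense", True)
        elif mode == "x":
            _emit(sid, _pick(xl), "missense_variant", "hemi", "missense", True)
        else:  # recessive: compound het pair of reported pathogenic alleles
            g = _pick(bi)
            _emit(sid, g, "missense_variant", "het", "missense", True)
            _emit(sid, g, "missense_variant", "het", "missense", True)

    rows_df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    truth_df = pd.DataFrame(
        truth, columns=["sample_id", "pathway", "gene", "chrom_class", "pos",
                        "ref", "alt", "zygosity"],
    )
    return rows_df, truth_df


def simulate_cohorts(
    cfg: Optional[SimulationConfig] = None,
    panel: Optional[pd.DataFrame] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (variant table, sample table, ground truth) for both cohorts.

    Output is byte-identical for a fixed ``cfg.seed``.  Background variant
    counts per person are Poisson with the configured means (the minimal
    assumption given that only means are modelled); the case LoF mean is
    reduced by the planted fraction so the observed case mean matches the
    configured value.
    """
    cfg = cfg or SimulationConfig()
    panel = panel if panel is not None else simulate_panel(cfg)
    rng = np.random.default_rng(cfg.seed)
    counter = _PosCounter()
    samples = _make_samples(cfg)

    blocks = []
    rates = {
        "lof": {"case": cfg.background_lof_mean_case,
                "comparison": cfg.mean_lof_per_person_comparison},
        "functional": {"case": cfg.mean_missense_per_person,
                       "comparison": cfg.mean_missense_per_person},
        "synonymous": {"case": cfg.mean_synonymous_per_person,
                       "comparison": cfg.mean_synonymous_per_person},
        "common": {"case": cfg.mean_common_per_person,
                   "comparison": cfg.mean_common_per_person},
    }
    ids = samples["sample_id"].to_numpy()
    sex = samples["sex"].to_numpy()
    cohort = samples["cohort"].to_numpy()
    for var_class, per_cohort in rates.items():
        mean = np.where(cohort == "case", per_cohort["case"],
                        per_cohort["comparison"])
        counts = rng.poisson(mean)
        rep_ids = np.repeat(ids, counts)
        rep_sex = np.repeat(sex, counts)
        blocks.append(
            _background_block(rep_ids, rep_sex, var_class, cfg, panel, rng,
                              counter)
        )

    planted_rows, truth = _planted_rows(cfg, samples, panel, rng, counter)
    blocks.append(planted_rows)
    blocks = [b for b in blocks if len(b)]
    variants = pd.concat(blocks, ignore_index=True)
    # a sample carries a given allele at most once; repeated draws of the
    # same recurring pool allele collapse to one observation
    variants = variants.drop_duplicates(
        subset=["sample_id", "chrom_class", "pos", "ref", "alt"]
    )
    variants = variants.sort_values(
        ["sample_id", "gene", "pos"], kind="mergesort"
    ).reset_index(drop=True)
    return variants, samples, GroundTruth(planted=truth, n_case=cfg.n_case)


def expected_background_diagnostic_rate(
    cfg: SimulationConfig, panel: pd.DataFrame
) -> float:
    """Approximate per-case rate of diagnostic-looking background LoF.

    A background LoF looks diagnostic when it is unique, absent from
    reference sets, and falls het in a known monoallelic gene or
    hemizygous in a known X-linked gene of a male.  Recessive-gene
    homozygotes contribute negligibly and are ignored.
    """
    p_pass = (1 - cfg.background_shared_prob) * (
        1 - cfg.background_reference_presence_prob
    )
    n = len(panel)
    n_mono = int(((panel["status"] == "known")
                  & (panel["inheritance"] == "monoallelic")).sum())
    n_x = int(((panel["status"] == "known")
               & (panel["inheritance"] == "x_linked")).sum())
    p_gene = n_mono / n + (n_x / n) * cfg.male_fraction_case
    return cfg.background_lof_mean_case * p_pass * p_gene
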