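"""Readers, writers and report emission for the pipeline's table dialects.

Two variant dialects are supported: a tab-separated table (the native
exchange format, one row per observed variant per sample) and a minimal
VCF 4.2 with per-sample genotypes and the annotations carried in INFO
keys.  Coordinates are 1-based inclusive in both dialects.  All readers
validate records on the way in and report offending line numbers; unknown
consequence terms are rejected rather than silently remapped.
"""

from __future__ import annotations

import logging
import os
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .enrichment import EnrichmentResult, enrichment_to_frame
from .records import KNOWN_TERMS, ValidationError
from .triage import ClassificationResult, classifications_to_frame

logger = logging.getLogger("idpanel")

REQUIRED_VARIANT_COLUMNS = [
    "sample_id", "gene", "chrom_class", "pos", "ref", "alt", "consequence",
    "variant_class", "zygosity", "carriers_internal",
]
OPTIONAL_BOOL_COLUMNS = ["known_pathogenic", "literature_excluded", "mode_mismatch"]
SCORE_COLUMNS = ["polyphen2", "sift", "condel", "cadd"]

_CHROM_TO_CONTIG = {"autosome": "1", "PAR": "X_PAR", "X": "X"}


class FormatError(ValueError):
    """The file does not declare the structure the dialect requires."""


def _to_bool(series: pd.Series) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False,
               True: True, False: False}
    return series.map(
        lambda v: mapping.get(v.lower() if isinstance(v, str) else v, False)
    )


def _validate_variants(
    df: pd.DataFrame, samples: Optional[pd.DataFrame], source: str
) -> None:
    errors: List[str] = []

    def _line(i) -> int:
        return int(i) + 2  # header is line 1

    unknown = set(df["consequence"].unique()) - KNOWN_TERMS
    if unknown:
        errors.append(f"unknown consequence terms: {sorted(unknown)}")
    bad = df.index[df["pos"] < 1]
    errors.extend(f"line {_line(i)}: position < 1" for i in bad)
    bad = df.index[df["carriers_internal"] < 1]
    errors.extend(f"line {_line(i)}: internal carrier count < 1" for i in bad)
    for col in (c for c in df.columns if c.startswith("freq_")):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.notna() & ((vals < 0) | (vals > 1))]
        errors.extend(f"line {_line(i)}: {col} outside [0, 1]" for i in bad)
    bad = df.index[~df["zygosity"].isin(["het", "hom", "hemi"])]
    errors.extend(f"line {_line(i)}: bad zygosity" for i in bad)
    bad = df.index[(df["zygosity"] == "hemi") & (df["chrom_class"] != "X")]
    errors.extend(f"line {_line(i)}: hemizygous call off the X" for i in bad)
    if samples is not None:
        sex_of = dict(zip(samples["sample_id"], samples["sex"]))
        hemi = df[df["zygosity"] == "hemi"]
        bad = hemi.index[
            hemi["sample_id"].map(lambda s: sex_of.get(s)) == "female"
        ]
        errors.extend(
            f"line {_line(i)}: hemizygous call in a female sample" for i in bad
        )
        missing = set(df["sample_id"]) - set(samples["sample_id"])
        if missing:
            errors.append(f"sample ids absent from metadata: {sorted(missing)[:5]}")
    if errors:
        raise ValidationError(f"{source}: " + "; ".join(errors[:20]))


def read_variant_table(
    path: str,
    dialect: str = "tsv",
    samples: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Read and validate a per-sample variant table.

    ``dialect`` is ``"tsv"`` or ``"vcf"``.  Passing the sample metadata
    table enables cross-checks (hemizygous calls only in males, every
    sample id known).
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene": str})
        missing = [c for c in REQUIRED_VARIANT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing required columns {missing}")
        for col in OPTIONAL_BOOL_COLUMNS:
            if col in df.columns:
                df[col] = _to_bool(df[col])
            else:
                df[col] = False
        for col in SCORE_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        if "transcript" not in df.columns:
            df["transcript"] = None
    elif dialect == "vcf":
        df = _read_vcf(path)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    _validate_variants(df, samples, path)
    logger.info("stage=read_variants dialect=%s in=%s records=%d",
                dialect, path, len(df))
    return df


def write_variant_table(df: pd.DataFrame, path: str, dialect: str = "tsv") -> None:
    if dialect == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif dialect == "vcf":
        _write_vcf(df, path)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    logger.info("stage=write_variants dialect=%s out=%s records=%d",
                dialect, path, len(df))


def _contig_to_chrom_class(contig: str) -> str:
    if contig in ("X_PAR", "PAR"):
        return "PAR"
    if contig == "X":
        return "X"
    return "autosome"


def _read_vcf(path: str) -> pd.DataFrame:
    """Minimal VCF 4.2 reader: GT per sample, annotations in INFO.

    Recognised INFO keys: GENE, CSQCLASS (consequence term), PP2, SIFT,
    CONDEL, CADD, KP (flag), CARRIERS, TX, and FREQ_<SET> frequency keys.
    """
    def _info(info, key, default=None):
        try:
            return info[key] if key in info else default
        except (KeyError, ValueError):
            return default

    rows = []
    with pysam.VariantFile(path) as vcf:
        sample_names = list(vcf.header.samples)
        freq_keys = [k for k in vcf.header.info if k.startswith("FREQ_")]
        for rec in vcf:
            info = rec.info
            if "GENE" not in info or "CSQCLASS" not in info:
                raise FormatError(
                    f"{path}: record at {rec.chrom}:{rec.pos} lacks "
                    "GENE/CSQCLASS INFO fields"
                )
            ref, alt = rec.ref, rec.alts[0]
            base = {
                "gene": info["GENE"],
                "chrom_class": _contig_to_chrom_class(rec.chrom),
                "pos": rec.pos, "ref": ref, "alt": alt,
                "consequence": info["CSQCLASS"],
                "variant_class": "SNV" if len(ref) == len(alt) == 1 else "indel",
                "carriers_internal": int(_info(info, "CARRIERS", 1)),
                "polyphen2": float(_info(info, "PP2", np.nan)),
                "sift": float(_info(info, "SIFT", np.nan)),
                "condel": float(_info(info, "CONDEL", np.nan)),
                "cadd": float(_info(info, "CADD", np.nan)),
                "known_pathogenic": bool(_info(info, "KP", False)),
                "literature_excluded": False, "mode_mismatch": False,
                "transcript": _info(info, "TX"),
            }
            for k in freq_keys:
                base["freq_" + k[len("FREQ_"):].lower()] = float(
                    _info(info, k, np.nan)
                )
            for sid in sample_names:
                gt = rec.samples[sid]["GT"]
                alleles = [a for a in gt if a is not None]
                if not alleles or not any(a == 1 for a in alleles):
                    continue
                if len(alleles) == 1:
                    zyg = "hemi"
                elif all(a == 1 for a in alleles):
                    zyg = "hom"
                else:
                    zyg = "het"
                row = dict(base)
                row["sample_id"] = sid
                row["zygosity"] = zyg
                rows.append(row)
    cols = REQUIRED_VARIANT_COLUMNS + SCORE_COLUMNS + OPTIONAL_BOOL_COLUMNS + [
        "transcript"
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=cols)
    extra = [c for c in df.columns if c.startswith("freq_")]
    return df[[c for c in cols if c in df.columns] + extra]


def _write_vcf(df: pd.DataFrame, path: str) -> None:
    header = pysam.VariantHeader()
    for contig in ("1", "X", "X_PAR"):
        header.contigs.add(contig)
    for key, num, typ, desc in [
        ("GENE", "1", "String", "Gene symbol"),
        ("CSQCLASS", "1", "String", "Consequence term"),
        ("PP2", "1", "Float", "PolyPhen2 score"),
        ("SIFT", "1", "Float", "SIFT score"),
        ("CONDEL", "1", "Float", "Condel score"),
        ("CADD", "1", "Float", "CADD Phred score"),
        ("KP", "0", "Flag", "Previously reported pathogenic"),
        ("CARRIERS", "1", "Integer", "Internal carrier count"),
        ("TX", "1", "String", "Transcript"),
    ]:
        header.info.add(key, num, typ, desc)
    freq_cols = [c for c in df.columns if c.startswith("freq_")]
    for c in freq_cols:
        header.info.add("FREQ_" + c[len("freq_"):].upper(), "1", "Float",
                        f"Allele frequency in {c[len('freq_'):]}")
    header.formats.add("GT", "1", "String", "Genotype")
    sample_names = sorted(df["sample_id"].unique())
    for sid in sample_names:
        header.add_sample(sid)

    with pysam.VariantFile(path, "w", header=header) as out:
        keys = ["chrom_class", "pos", "ref", "alt", "gene", "transcript"]
        for key_vals, grp in df.groupby(keys, dropna=False, sort=True):
            chrom_class, pos, ref, alt, gene, tx = key_vals
            first = grp.iloc[0]
            rec = out.new_record(
                contig=_CHROM_TO_CONTIG[chrom_class], start=int(pos) - 1,
                alleles=(ref, alt),
            )
            rec.info["GENE"] = gene
            rec.info["CSQCLASS"] = first["consequence"]
            rec.info["CARRIERS"] = int(first["carriers_internal"])
            if pd.notna(tx) and tx is not None:
                rec.info["TX"] = tx
            for col, key in zip(SCORE_COLUMNS, ("PP2", "SIFT", "CONDEL", "CADD")):
                if pd.notna(first[col]):
                    rec.info[key] = float(first[col])
            if bool(first["known_pathogenic"]):
                rec.info["KP"] = True
            for c in freq_cols:
                if pd.notna(first[c]):
                    rec.info["FREQ_" + c[len("freq_"):].upper()] = float(first[c])
            for sid in sample_names:
                rec.samples[sid]["GT"] = (None,)
            for _, row in grp.iterrows():
                gt = {"het": (0, 1), "hom": (1, 1), "hemi": (1,)}[row["zygosity"]]
                rec.samples[row["sample_id"]]["GT"] = gt
            out.write(rec)


def read_panel(path: str) -> pd.DataFrame:
    """Read a gene-panel definition table (tsv)."""
    df = pd.read_csv(path, sep="\t")
    required = ["gene", "status", "chrom_class", "inheritance"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if df.empty:
        logger.warning("panel %s is empty", path)
        return df
    dup = df["gene"][df["gene"].duplicated()]
    if len(dup):
        raise ValidationError(
            f"{path}: duplicate gene symbols: {sorted(set(dup))}"
        )
    bad_x = df[(df["inheritance"] == "x_linked") != (df["chrom_class"] == "X")]
    if len(bad_x):
        raise ValidationError(
            f"{path}: x_linked inheritance must pair with chromosome class X: "
            f"{sorted(bad_x['gene'])[:5]}"
        )
    counts = df["status"].value_counts().to_dict()
    logger.info("stage=read_panel genes=%d known=%d candidate=%d",
                len(df), counts.get("known", 0), counts.get("candidate", 0))
    return df


def read_samples(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = ["sample_id", "sex", "cohort"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample ids")
    if "qc_pass" not in df.columns:
        df["qc_pass"] = True
    else:
        df["qc_pass"] = _to_bool(df["qc_pass"])
    return df


def read_known_pathogenic(path: str) -> pd.DataFrame:
    """4-column lookup (gene, pos, ref, alt) of previously reported variants."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("gene", "pos", "ref", "alt") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def apply_known_pathogenic(
    variants: pd.DataFrame, lookup: pd.DataFrame
) -> pd.DataFrame:
    """Set ``known_pathogenic`` from membership in the lookup table."""
    keys = set(zip(lookup["gene"], lookup["pos"], lookup["ref"], lookup["alt"]))
    out = variants.copy()
    out["known_pathogenic"] = [
        (g, p, r, a) in keys
        for g, p, r, a in zip(out["gene"], out["pos"], out["ref"], out["alt"])
    ]
    return out


def write_reports(
    classifications: Sequence[ClassificationResult],
    enrichments: Sequence[EnrichmentResult],
    out_dir: str,
    samples: Optional[pd.DataFrame] = None,
) -> Dict[str, str]:
    """Write the classification, per-sample summary and enrichment reports.

    Returns a name -> path map of the files written.  Empty inputs produce
    headers-only files.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "classifications": os.path.join(out_dir, "classifications.tsv"),
        "sample_summary": os.path.join(out_dir, "sample_summary.tsv"),
        "enrichment": os.path.join(out_dir, "enrichment.tsv"),
    }
    cls_df = classifications_to_frame(classifications)
    cls_df.to_csv(paths["classifications"], sep="\t", index=False)

    if len(cls_df):
        lp = cls_df[cls_df["verdict"] == "likely_pathogenic"]
        summary = (
            cls_df.groupby("sample_id")
            .agg(n_classified=("verdict", "size"))
            .reset_index()
        )
        lof = set(lp.loc[lp["pathway"] == "lof_known_gene", "sample_id"])
        mis = set(lp.loc[lp["pathway"] == "missense_known_pathogenic", "sample_id"])
        summary["lof_diagnosed"] = summary["sample_id"].isin(lof)
        summary["missense_diagnosed"] = summary["sample_id"].isin(mis)
        summary["diagnosed"] = summary["lof_diagnosed"] | summary["missense_diagnosed"]
    else:
        summary = pd.DataFrame(
            columns=["sample_id", "n_classified", "lof_diagnosed",
                     "missense_diagnosed", "diagnosed"]
        )
    if samples is not None and len(summary):
        known = set(samples["sample_id"])
        stray = set(summary["sample_id"]) - known
        if stray:
            raise ValidationError(
                f"report references unknown sample ids: {sorted(stray)[:5]}"
            )
    summary.to_csv(paths["sample_summary"], sep="\t", index=False)

    enr_df = enrichment_to_frame(enrichments) if len(enrichments) else pd.DataFrame(
        columns=["chrom_stratum", "gene_category", "n_genes", "variant_type",
                 "carriers_case", "n_case", "freq_case", "carriers_comparison",
                 "n_comparison", "freq_comparison", "p_value", "alpha_adjusted",
                 "significant"]
    )
    enr_df.to_csv(paths["enrichment"], sep="\t", index=False)
    logger.info(
        "stage=write_reports out=%s classifications=%d enrichment_rows=%d",
        out_dir, len(cls_df), len(enr_df),
    )
    return paths


def read_classification_report(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_enrichment_report(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
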