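"""Cohort serialization: VCF v4.2 genotypes + phenotype/covariate TSV.

The genotype file carries the two focal variants at their GRCh37 positions
(chr6:32440321 two-base indel, chr6:32591291 T/A SNP) with phased GT fields so
diplotypes round-trip exactly. The phenotype table is a TSV with columns
subject_id, status, onset_age, stratum, ev1..evK, comorbid, classical_count.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .simulate import Cohort, HAPLOTYPES

# Fixed variant records: (chrom, pos, id, ref, alt); ALT is the risk allele.
VARIANTS = (
    ("6", 32440321, "rs145954018", "GTG", "G"),
    ("6", 32591291, "rs9271597", "T", "A"),
)

PHENO_COLUMNS = ("subject_id", "status", "onset_age", "stratum", "comorbid",
                 "classical_count")


class CohortParseError(ValueError):
    """A genotype or phenotype record failed validation; names the record."""


def _hap_alleles(hap: str) -> tuple:
    # allele index at (indel, snp); ALT=1 is the risk allele at both sites
    indel = 1 if hap.startswith("del") else 0
    snp = 1 if hap.endswith("-A") else 0
    return indel, snp


_ALLELES_TO_HAP = {_hap_alleles(h): h for h in HAPLOTYPES}


def write_cohort(cohort: Cohort, vcf_path, pheno_path) -> None:
    """Write genotypes as phased VCF v4.2 and phenotypes as TSV."""
    df = cohort.data
    samples = list(df["subject_id"])
    if len(set(samples)) != len(samples):
        raise CohortParseError("duplicated subject ids in cohort")

    a_indel = np.array([_hap_alleles(h) for h in df["hap1"]])
    b_indel = np.array([_hap_alleles(h) for h in df["hap2"]])
    lines = [
        "##fileformat=VCFv4.2",
        "##reference=GRCh37",
        "##contig=<ID=6>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for j, (chrom, pos, vid, ref, alt) in enumerate(VARIANTS):
        gts = "\t".join(f"{a}|{b}" for a, b in zip(a_indel[:, j], b_indel[:, j]))
        lines.append(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}")
    Path(vcf_path).write_text("\n".join(lines) + "\n")

    cols = ["subject_id", "status", "onset_age", "stratum"]
    cols += cohort.covariate_columns + ["comorbid", "classical_count"]
    df[cols].to_csv(pheno_path, sep="\t", index=False, na_rep="NA")


def _read_genotypes(vcf_path) -> pd.DataFrame:
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise CohortParseError(f"duplicated subject ids in {vcf_path}")
    by_id = {}
    for var in vcf:
        geno = np.array([g[:2] for g in var.genotypes], dtype=int)
        phased = all(g[2] for g in var.genotypes)
        by_id[var.ID] = (geno, phased)
    vcf.close()
    missing = [vid for _, _, vid, _, _ in VARIANTS if vid not in by_id]
    if missing:
        raise CohortParseError(f"variant record(s) {missing} missing from {vcf_path}")
    g_ind, ph1 = by_id[VARIANTS[0][2]]
    g_snp, ph2 = by_id[VARIANTS[1][2]]
    out = pd.DataFrame({"subject_id": samples})
    out["g_indel"] = g_ind.sum(axis=1)
    out["g_snp"] = g_snp.sum(axis=1)
    if ph1 and ph2:
        out["hap1"] = [_ALLELES_TO_HAP[(i, s)] for i, s in zip(g_ind[:, 0], g_snp[:, 0])]
        out["hap2"] = [_ALLELES_TO_HAP[(i, s)] for i, s in zip(g_ind[:, 1], g_snp[:, 1])]
    return out


def read_cohort(vcf_path, pheno_path) -> Cohort:
    """Read a cohort written by :func:`write_cohort` (or compatible files).

    Raises :class:`CohortParseError` naming the offending record on duplicated
    subject ids, phenotype rows without a genotype column, or a case with a
    non-numeric onset age.
    """
    geno = _read_genotypes(vcf_path)
    pheno = pd.read_csv(pheno_path, sep="\t", dtype={"subject_id": str},
                        float_precision="round_trip")
    for col in ("subject_id", "status"):
        if col not in pheno.columns:
            raise CohortParseError(f"phenotype table {pheno_path} lacks column {col!r}")
    dup = pheno["subject_id"][pheno["subject_id"].duplicated()]
    if len(dup):
        raise CohortParseError(f"duplicated subject id(s) in phenotype table: "
                               f"{sorted(set(dup))}")
    known = set(geno["subject_id"])
    orphan = [s for s in pheno["subject_id"] if s not in known]
    if orphan:
        raise CohortParseError(
            f"phenotype row(s) without genotype column: {orphan[:5]}"
        )
    if "onset_age" in pheno.columns:
        onset = pd.to_numeric(pheno["onset_age"], errors="coerce")
        bad = pheno.index[(pheno["status"] == 1)
                          & onset.isna() & pheno["onset_age"].notna()]
        if len(bad):
            i = bad[0]
            raise CohortParseError(
                f"non-numeric onset_age {pheno.loc[i, 'onset_age']!r} for case "
                f"{pheno.loc[i, 'subject_id']!r} (line {i + 2} of {pheno_path})"
            )
        pheno["onset_age"] = onset
    merged = pheno.merge(geno, on="subject_id", how="left", validate="1:1")
    hap_cols = [c for c in ("hap1", "hap2") if c in merged.columns]
    if hap_cols:
        merged["hap_copies"] = sum(
            (merged[c] == "del-A").astype(int) for c in hap_cols
        )
    front = [c for c in ("subject_id", "hap1", "hap2", "g_indel", "g_snp",
                         "hap_copies", "classical_count", "status", "onset_age",
                         "stratum") if c in merged.columns]
    rest = [c for c in merged.columns if c not in front]
    return Cohort(data=merged[front + rest], config=None)
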