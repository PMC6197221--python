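"""Genotype/HLA file handling and cohort quality control.

Reads PLINK-style text ``.ped``/``.map`` files into a dosage matrix, reads
two-field classical HLA allele calls from TSV, and applies the standard
case-control QC cascade: sample call rate, variant call rate, minor allele
frequency and Hardy-Weinberg equilibrium (exact test, stratified by
phenotype).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from math import lgamma, exp, log
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "QCReport",
    "HLACallTable",
    "read_genotypes",
    "write_genotypes",
    "read_hla_table",
    "write_hla_table",
    "qc_filter",
    "hwe_exact_test",
]

CASE = "case"
CONTROL = "control"

_HLA_ALLELE_RE = re.compile(r"^[A-Za-z0-9]+\*\d{2,3}:\d{2,3}$")


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


@dataclass
class GenotypeMatrix:
    """Unphased biallelic genotypes as alt-allele dosages.

    ``dosage`` is an (n_samples, n_variants) float array with values in
    {0, 1, 2} and NaN for missing genotypes.  ``alleles[j]`` is the
    (ref, alt) symbol pair of variant j; dosage counts the alt allele
    (by convention the minor allele as observed in the source file).
    """

    sample_ids: list[str]
    variant_ids: list[str]
    alleles: list[tuple[str, str]]
    dosage: np.ndarray
    phenotype: np.ndarray  # per-sample, "case"/"control"

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.phenotype = np.asarray(self.phenotype, dtype=object)
        n, m = self.dosage.shape
        if n != len(self.sample_ids):
            raise ValueError("dosage rows do not match sample_ids")
        if m != len(self.variant_ids) or m != len(self.alleles):
            raise ValueError("dosage columns do not match variant metadata")
        if len(self.phenotype) != n:
            raise ValueError("phenotype length does not match samples")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosage values must be 0/1/2 or missing")
        for vid, (ref, alt) in zip(self.variant_ids, self.alleles):
            if ref == alt:
                raise ValueError(f"variant {vid}: ref and alt alleles identical")
        bad = set(self.phenotype) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"unknown phenotype labels: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def variant_index(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"variant {variant_id!r} not present") from None

    def is_case(self) -> np.ndarray:
        return np.asarray([p == CASE for p in self.phenotype], dtype=bool)

    def subset(self, sample_mask=None, variant_mask=None) -> "GenotypeMatrix":
        smask = np.ones(self.n_samples, bool) if sample_mask is None else np.asarray(sample_mask, bool)
        vmask = np.ones(self.n_variants, bool) if variant_mask is None else np.asarray(variant_mask, bool)
        return GenotypeMatrix(
            sample_ids=[s for s, k in zip(self.sample_ids, smask) if k],
            variant_ids=[v for v, k in zip(self.variant_ids, vmask) if k],
            alleles=[a for a, k in zip(self.alleles, vmask) if k],
            dosage=self.dosage[np.ix_(smask, vmask)],
            phenotype=self.phenotype[smask],
        )


@dataclass
class QCReport:
    """Record of every removal made by :func:`qc_filter`."""

    removed_samples: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)
    removed_variants: list[tuple[str, str]] = field(default_factory=list)
    thresholds: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("sample", i, r) for i, r in self.removed_samples]
        rows += [("variant", i, r) for i, r in self.removed_variants]
        return pd.DataFrame(rows, columns=["kind", "id", "reason"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class HLACallTable:
    """Two-field classical HLA calls at one locus, one row per sample."""

    locus: str
    sample_ids: list[str]
    allele_1: list[str | None]
    allele_2: list[str | None]
    phenotype: np.ndarray

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=object)
        n = len(self.sample_ids)
        if not (len(self.allele_1) == len(self.allele_2) == len(self.phenotype) == n):
            raise ValueError("HLACallTable columns have unequal lengths")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def is_case(self) -> np.ndarray:
        return np.asarray([p == CASE for p in self.phenotype], dtype=bool)

    def chromosome_total(self, group: str) -> int:
        """Number of typed chromosomes in a phenotype group.

        Each non-missing allele call contributes one chromosome, so a
        sample with a single missing field contributes 1.
        """
        total = 0
        for a1, a2, p in zip(self.allele_1, self.allele_2, self.phenotype):
            if p != group:
                continue
            total += (a1 is not None) + (a2 is not None)
        return total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_ids,
                "locus": self.locus,
                "allele_1": [a if a is not None else "NA" for a in self.allele_1],
                "allele_2": [a if a is not None else "NA" for a in self.allele_2],
                "phenotype": self.phenotype,
            }
        )


# ---------------------------------------------------------------------------
# PLINK text .ped/.map
# ---------------------------------------------------------------------------

_PED_PHENO = {"1": CONTROL, "2": CASE}


def read_genotypes(ped_path, map_path, allele_map: dict[str, tuple[str, str]] | None = None) -> GenotypeMatrix:
    """Read a whitespace-delimited .ped/.map pair into a GenotypeMatrix.

    Dosages count the minor allele observed in the file unless
    ``allele_map`` supplies an explicit (ref, alt) pair per variant.
    Missing genotypes use the "0" allele code.  Phenotype column follows
    the 1=control / 2=case convention.
    """
    variant_ids: list[str] = []
    for ln, line in enumerate(Path(map_path).read_text().splitlines(), 1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) < 2:
            raise FormatError(f"{map_path}: line {ln}: expected >= 2 columns")
        variant_ids.append(parts[1])
    m = len(variant_ids)

    sample_ids: list[str] = []
    phenos: list[str] = []
    raw: list[list[tuple[str, str]]] = []
    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), 1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 6 + 2 * m:
            raise FormatError(
                f"{ped_path}: row {ln}: expected {6 + 2 * m} columns for {m} variants, got {len(parts)}"
            )
        sample_ids.append(parts[1])
        pheno = _PED_PHENO.get(parts[5])
        if pheno is None:
            raise FormatError(f"{ped_path}: row {ln}: phenotype code {parts[5]!r} (expect 1 or 2)")
        phenos.append(pheno)
        raw.append([(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(m)])

    n = len(sample_ids)
    dosage = np.full((n, m), np.nan)
    alleles: list[tuple[str, str]] = []
    for j, vid in enumerate(variant_ids):
        counts: dict[str, int] = {}
        for i in range(n):
            for a in raw[i][j]:
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        if allele_map is not None and vid in allele_map:
            ref, alt = allele_map[vid]
        else:
            if len(counts) > 2:
                raise FormatError(f"variant {vid}: more than two alleles observed: {sorted(counts)}")
            if not counts:
                ref, alt = "N", "n"  # fully missing variant, placeholder symbols
            elif len(counts) == 1:
                (ref,) = counts
                alt = ref.lower() if ref.lower() != ref else ref + "'"
            else:
                # alt = minor allele; ties broken lexicographically for determinism
                (a1, c1), (a2, c2) = sorted(counts.items())
                alt, ref = (a1, a2) if (c1 < c2 or c1 == c2) else (a2, a1)
                if c1 > c2:
                    alt, ref = a2, a1
        known = {ref, alt, "0"}
        for i in range(n):
            a, b = raw[i][j]
            if a not in known or b not in known:
                bad = a if a not in known else b
                raise FormatError(f"variant {vid}: unknown allele symbol {bad!r}")
            if a == "0" or b == "0":
                continue
            dosage[i, j] = (a == alt) + (b == alt)
        alleles.append((ref, alt))

    return GenotypeMatrix(sample_ids, variant_ids, alleles, dosage, np.array(phenos, object))


def write_genotypes(gm: GenotypeMatrix, ped_path, map_path, chrom: str = "0", pos_start: int = 1) -> None:
    """Write a GenotypeMatrix back to .ped/.map text files."""
    with open(map_path, "w") as fh:
        for j, vid in enumerate(gm.variant_ids):
            fh.write(f"{chrom}\t{vid}\t0\t{pos_start + j}\n")
    pheno_code = {CONTROL: "1", CASE: "2"}
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(gm.sample_ids):
            fields = [sid, sid, "0", "0", "0", pheno_code[gm.phenotype[i]]]
            for j, (ref, alt) in enumerate(gm.alleles):
                d = gm.dosage[i, j]
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [ref, ref]
                elif d == 1:
                    fields += [ref, alt]
                else:
                    fields += [alt, alt]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# HLA call TSV
# ---------------------------------------------------------------------------

def read_hla_table(tsv_path) -> dict[str, HLACallTable]:
    """Read per-sample two-allele HLA calls from a TSV.

    Expected header: sample, locus, allele_1, allele_2, phenotype.  Returns
    one :class:`HLACallTable` per locus.  Allele names must look like
    ``LOCUS*NN:NN``; empty or "NA" fields are treated as missing.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    required = {"sample", "locus", "allele_1", "allele_2", "phenotype"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise FormatError(f"{tsv_path}: missing columns {sorted(missing_cols)}")

    def parse(val, row):
        if pd.isna(val) or val in ("", "NA", "0"):
            return None
        if not _HLA_ALLELE_RE.match(val):
            raise FormatError(f"{tsv_path}: row {row + 2}: malformed allele name {val!r}")
        return val

    out: dict[str, HLACallTable] = {}
    for locus, sub in df.groupby("locus", sort=False):
        out[str(locus)] = HLACallTable(
            locus=str(locus),
            sample_ids=sub["sample"].tolist(),
            allele_1=[parse(v, i) for i, v in zip(sub.index, sub["allele_1"])],
            allele_2=[parse(v, i) for i, v in zip(sub.index, sub["allele_2"])],
            phenotype=sub["phenotype"].to_numpy(object),
        )
    return out


def write_hla_table(tables: Iterable[HLACallTable], tsv_path) -> None:
    frames = [t.to_frame() for t in tables]
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(tsv_path, sep="\t", index=False)
    else:
        pd.DataFrame(columns=["sample", "locus", "allele_1", "allele_2", "phenotype"]).to_csv(
            tsv_path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test.

    Enumerates every heterozygote count compatible with the observed allele
    totals and sums the probabilities of all configurations no more likely
    than the observed one (conditional on allele counts).  Monomorphic
    input returns 1.0 by convention.
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0 or int(c) != c:
            raise ValueError("genotype counts must be nonnegative integers")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotyped sample required")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    if n_A == 0 or n_a == 0:
        return 1.0

    # log P(het = h | allele counts) up to the shared normalising constant
    def logw(h: int) -> float:
        hom_A = (n_A - h) // 2
        hom_a = (n_a - h) // 2
        return h * log(2.0) + lgamma(n + 1) - lgamma(hom_A + 1) - lgamma(h + 1) - lgamma(hom_a + 1)

    hets = range(n_A % 2, min(n_A, n_a) + 1, 2)
    logs = {h: logw(h) for h in hets}
    mx = max(logs.values())
    weights = {h: exp(v - mx) for h, v in logs.items()}
    total = sum(weights.values())
    w_obs = weights[n_Aa]
    p = sum(w for w in weights.values() if w <= w_obs * (1 + 1e-12)) / total
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# QC cascade
# ---------------------------------------------------------------------------

def qc_filter(
    gm: GenotypeMatrix,
    sample_cr: float = 0.97,
    variant_cr: float = 0.99,
    maf_min: float = 0.05,
    hwe_alpha: float = 1e-3,
    hwe_rule: str = "both",
    exclude_samples: Sequence[str] = (),
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the QC cascade and return the filtered matrix plus a report.

    Order of application: sample exclusion list, sample call rate, variant
    call rate, MAF, HWE.  The HWE filter is computed separately in cases
    and in controls; with ``hwe_rule="both"`` a variant is removed only
    when its exact-test P falls below ``hwe_alpha`` in *both* strata,
    with ``"either"`` when it fails in at least one.
    """
    for name, t in (("sample_cr", sample_cr), ("variant_cr", variant_cr), ("maf_min", maf_min), ("hwe_alpha", hwe_alpha)):
        if not (0 < t <= 1):
            raise ValueError(f"{name} must be in (0, 1]")
    if hwe_rule not in ("both", "either"):
        raise ValueError("hwe_rule must be 'both' or 'either'")

    report = QCReport(thresholds={
        "sample_cr": sample_cr, "variant_cr": variant_cr, "maf_min": maf_min, "hwe_alpha": hwe_alpha,
    })

    # 1. precomputed exclusion list (PCA / IBD outliers supplied upstream)
    excl = set(exclude_samples)
    keep = np.array([s not in excl for s in gm.sample_ids], bool)
    report.removed_samples += [(s, "exclusion-list") for s in gm.sample_ids if s in excl]
    gm = gm.subset(sample_mask=keep)

    # 2. sample call rate
    if gm.n_variants > 0:
        cr = 1.0 - np.isnan(gm.dosage).mean(axis=1)
        keep = cr >= sample_cr
        report.removed_samples += [(s, "call-rate") for s, k in zip(gm.sample_ids, keep) if not k]
        gm = gm.subset(sample_mask=keep)
    if gm.n_samples == 0:
        raise ValueError("empty cohort: all samples removed by QC")

    # 3. variant call rate
    cr = 1.0 - np.isnan(gm.dosage).mean(axis=0)
    keep = cr >= variant_cr
    report.removed_variants += [(v, "call-rate") for v, k in zip(gm.variant_ids, keep) if not k]
    gm = gm.subset(variant_mask=keep)

    # 4. minor allele frequency
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        af = np.nanmean(gm.dosage, axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    keep = ~(maf < maf_min)
    report.removed_variants += [(v, "maf") for v, k in zip(gm.variant_ids, keep) if not k]
    gm = gm.subset(variant_mask=keep)

    # 5. Hardy-Weinberg, stratified by phenotype
    case_mask = gm.is_case()
    keep = np.ones(gm.n_variants, bool)
    for j in range(gm.n_variants):
        ps = []
        for mask in (case_mask, ~case_mask):
            col = gm.dosage[mask, j]
            col = col[~np.isnan(col)]
            if col.size == 0:
                ps.append(1.0)
                continue
            n_aa_ = int((col == 0).sum())
            n_het = int((col == 1).sum())
            n_AA_ = int((col == 2).sum())
            ps.append(hwe_exact_test(n_AA_, n_het, n_aa_))
        fails = [p < hwe_alpha for p in ps]
        if (all(fails) if hwe_rule == "both" else any(fails)):
            keep[j] = False
    report.removed_variants += [(v, "hwe") for v, k in zip(gm.variant_ids, keep) if not k]
    gm = gm.subset(variant_mask=keep)

    return gm, report
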