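"""Shared fixtures and independent oracles for the test-suite.

The oracles here (exhaustive haplotype-likelihood grid search, brute-force
HWE enumeration) deliberately avoid the package's own algorithms so they
can serve as independent cross-checks.
"""

from __future__ import annotations

import itertools
from math import comb, log

import numpy as np
import pytest

from ccfinemap import GenotypeMatrix, HLACallTable
from ccfinemap.io_qc import CASE, CONTROL


# ---------------------------------------------------------------------------
# published-scale HLA chromosome counts (two-field alleles, two loci)
# ---------------------------------------------------------------------------

# case chromosomes 428 / control 1226
DRB1_COUNTS = {
    "DRB1*15:01": (91, 100),
    "DRB1*14:54": (22, 38),
    "DRB1*11:01": (20, 31),
    "DRB1*14:05": (20, 25),
    "DRB1*08:03": (50, 180),
    "DRB1*09:01": (60, 200),
    "DRB1*04:05": (55, 190),
    "DRB1*13:02": (40, 150),
    "DRB1*01:01": (30, 112),
    "DRB1*12:01": (40, 200),
}
# case chromosomes 427 (one case sample has a single missing call) / control 1226
DQB1_COUNTS = {
    "DQB1*06:02": (84, 96),
    "DQB1*05:02": (18, 22),
    "DQB1*03:01": (66, 141),
    "DQB1*05:03": (22, 48),
    "DQB1*06:04": (47, 179),
    "DQB1*03:02": (60, 210),
    "DQB1*04:01": (50, 190),
    "DQB1*06:01": (40, 160),
    "DQB1*05:01": (40, 180),
}


def hla_table_from_counts(locus: str, counts: dict[str, tuple[int, int]]) -> HLACallTable:
    """Build per-sample calls whose chromosome tallies match given counts.

    Chromosomes are laid out deterministically and paired sequentially;
    an odd case total leaves the last case sample with one missing call.
    """
    sample_ids, a1, a2, pheno = [], [], [], []
    idx = 0
    for group, gi, tag in ((CASE, 0, "case"), (CONTROL, 1, "ctrl")):
        chroms: list[str] = []
        for allele, pair in counts.items():
            chroms += [allele] * pair[gi]
        for i in range(0, len(chroms) - 1, 2):
            sample_ids.append(f"{tag}{idx:04d}")
            a1.append(chroms[i])
            a2.append(chroms[i + 1])
            pheno.append(group)
            idx += 1
        if len(chroms) % 2 == 1:
            sample_ids.append(f"{tag}{idx:04d}")
            a1.append(chroms[-1])
            a2.append(None)
            pheno.append(group)
            idx += 1
    return HLACallTable(locus, sample_ids, a1, a2, np.asarray(pheno, object))


@pytest.fixture
def drb1_table() -> HLACallTable:
    return hla_table_from_counts("DRB1", DRB1_COUNTS)


@pytest.fixture
def dqb1_table() -> HLACallTable:
    return hla_table_from_counts("DQB1", DQB1_COUNTS)


# ---------------------------------------------------------------------------
# small genotype matrices
# ---------------------------------------------------------------------------

@pytest.fixture
def toy_gm() -> GenotypeMatrix:
    """4 samples x 2 variants with a missing call, hand-checkable."""
    dosage = np.array(
        [
            [2.0, 1.0],
            [1.0, 0.0],
            [0.0, np.nan],
            [1.0, 2.0],
        ]
    )
    return GenotypeMatrix(
        sample_ids=["s1", "s2", "s3", "s4"],
        variant_ids=["v1", "v2"],
        alleles=[("A", "G"), ("C", "T")],
        dosage=dosage,
        phenotype=np.asarray([CASE, CASE, CONTROL, CONTROL], object),
    )


def make_gm(dosage: np.ndarray, phenotype: list[str], variant_ids=None) -> GenotypeMatrix:
    dosage = np.asarray(dosage, float)
    n, m = dosage.shape
    vids = variant_ids or [f"v{j}" for j in range(m)]
    # alt (dosage-counted) allele is the second element: uppercase
    symbols = [("a", "A"), ("b", "B"), ("c", "C"), ("d", "D")]
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        variant_ids=vids,
        alleles=symbols[:m],
        dosage=dosage,
        phenotype=np.asarray(phenotype, object),
    )


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def hwe_enumeration_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Brute-force exact HWE P: enumerate heterozygote counts directly.

    Uses the multivariate-hypergeometric form
    P(h) = C(n, (nA-h)/2, h, (na-h)/2) * 2^h / C(2n, nA)
    computed with exact integer combinatorics, no shared code with the
    implementation under test.
    """
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    if n_A == 0 or n_a == 0:
        return 1.0
    probs = {}
    denom = comb(2 * n, n_A)
    for h in range(n_A % 2, min(n_A, n_a) + 1, 2):
        homA = (n_A - h) // 2
        homa = (n_a - h) // 2
        num = (
            comb(n, homA) * comb(n - homA, h) * 2**h
        )
        probs[h] = num / denom
    p_obs = probs[n_Aa]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))


def _genotype_class_counts(dosage2: np.ndarray) -> np.ndarray:
    """9-vector of counts over genotype classes (g1, g2) in {0,1,2}^2."""
    counts = np.zeros((3, 3))
    for g1, g2 in dosage2.astype(int):
        counts[g1, g2] += 1
    return counts


def em_grid_oracle(dosage2: np.ndarray, coarse: float = 0.02, fine: float = 0.001) -> np.ndarray:
    """Exhaustive maximum-likelihood grid search for 2-SNP haplotype freqs.

    Returns (f00, f01, f10, f11) ordered like itertools.product.  Two-stage
    grid over the 3-simplex: coarse sweep then local refinement at the
    ``fine`` step.  Completely independent of the EM implementation.
    """
    counts = _genotype_class_counts(dosage2)

    def loglik(f00, f01, f10, f11):
        # genotype-class probabilities under random mating
        p = np.empty((3, 3) + f00.shape)
        p[0, 0] = f00**2
        p[0, 1] = 2 * f00 * f01
        p[0, 2] = f01**2
        p[1, 0] = 2 * f00 * f10
        p[1, 1] = 2 * f00 * f11 + 2 * f01 * f10
        p[1, 2] = 2 * f01 * f11
        p[2, 0] = f10**2
        p[2, 1] = 2 * f10 * f11
        p[2, 2] = f11**2
        ll = np.zeros(f00.shape)
        for g1 in range(3):
            for g2 in range(3):
                if counts[g1, g2] > 0:
                    with np.errstate(divide="ignore"):
                        ll += counts[g1, g2] * np.log(p[g1, g2])
        return ll

    def sweep(centers, step, span):
        vals = {}
        for name, c in centers.items():
            lo = max(0.0, c - span)
            hi = min(1.0, c + span)
            vals[name] = np.arange(lo, hi + step / 2, step)
        g00, g01, g10 = np.meshgrid(vals["f00"], vals["f01"], vals["f10"], indexing="ij")
        g11 = 1.0 - g00 - g01 - g10
        ok = g11 >= -1e-12
        g00, g01, g10, g11 = (g[ok] for g in (g00, g01, g10, np.maximum(g11, 0.0)))
        ll = loglik(g00, g01, g10, g11)
        best = np.argmax(ll)
        return {"f00": g00[best], "f01": g01[best], "f10": g10[best]}, g11[best]

    centers = {"f00": 0.5, "f01": 0.5, "f10": 0.5}
    centers, _ = sweep(centers, coarse, 0.5)
    centers, f11 = sweep(centers, fine, 1.5 * coarse)
    return np.array([centers["f00"], centers["f01"], centers["f10"], f11])


def random_two_snp_instance(rng: np.random.Generator, max_n: int = 25) -> np.ndarray:
    """Random small unphased 2-SNP dataset drawn from random haplotype freqs."""
    n = int(rng.integers(2, max_n + 1))
    f = rng.dirichlet(np.ones(4))
    haps = list(itertools.product((0, 1), repeat=2))
    idx = rng.choice(4, size=(n, 2), p=f)
    return np.array([[haps[i][0] + haps[j][0], haps[i][1] + haps[j][1]] for i, j in idx], float)
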