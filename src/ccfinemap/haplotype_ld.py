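"""EM haplotype-frequency estimation and linkage-disequilibrium dissection.

Estimates haplotype frequencies over 2-3 biallelic SNPs from unphased
genotypes with the standard EM algorithm, derives D / D' / r^2 from the
fitted frequencies (optionally stratified by phenotype group), scores a
target haplotype in a case-control 2x2 built from expected chromosome
counts, and calls per-sample posterior haplotype dosages and recessive
state.

The EM treats each sample's pair of haplotypes as the latent variable.
Because every haplotype pair compatible with a genotype carries the same
allele content, the fitted allele frequencies always equal the observed
ones; only the phase of multiply-heterozygous samples is estimated.
Samples heterozygous at every SNP and nothing else are non-identifiable
in isolation (the two phase configurations are exchangeable); exactly
tied phase posteriors make the uniform start a saddle.  The fitter
therefore also runs the EM from a deterministic start per complementary
haplotype pair (the phase-ambiguity directions) and reports the
best-likelihood converged optimum.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .io_qc import GenotypeMatrix, CASE, CONTROL
from .assoc_core import AssociationResult, ContingencyTable2x2, odds_ratio_2x2

__all__ = [
    "HaplotypeDistribution",
    "LDStats",
    "HaplotypeDosage",
    "em_haplotypes",
    "ld_from_haplotypes",
    "ld_from_frequencies",
    "stratified_ld",
    "haplotype_association",
    "haplotype_association_from_frequencies",
    "haplotype_dosage",
    "recessive_state",
]

EM_TOL = 1e-8
EM_MAX_ITER = 1000


@dataclass
class HaplotypeDistribution:
    """EM-fitted haplotype frequencies over a small SNP window."""

    snp_ids: list[str]
    alleles: list[tuple[str, str]]  # (ref, alt) per SNP
    haplotypes: list[tuple[str, ...]]  # allele-symbol tuples, all 2^k
    frequencies: np.ndarray
    log_likelihood: float
    iterations: int
    converged: bool
    n_samples: int
    warning: str | None = None

    def frequency(self, haplotype: tuple[str, ...]) -> float:
        try:
            return float(self.frequencies[self.haplotypes.index(tuple(haplotype))])
        except ValueError:
            raise KeyError(f"haplotype {haplotype!r} not expressible over {self.snp_ids}") from None

    def _bits(self) -> np.ndarray:
        """Haplotypes as 0/1 (alt-allele indicator) rows."""
        idx = []
        for hap in self.haplotypes:
            idx.append([int(sym == alt) for sym, (ref, alt) in zip(hap, self.alleles)])
        return np.asarray(idx, dtype=int)


@dataclass
class LDStats:
    D: float
    D_prime: float
    r2: float
    computed_on: str = "combined"


@dataclass
class HaplotypeDosage:
    """Posterior target-haplotype copies per sample (complete-case)."""

    sample_ids: list[str]
    expected: np.ndarray  # E[copies] in [0, 2]; NaN where untyped
    p_two: np.ndarray  # posterior P(two copies)


def _extract(gm: GenotypeMatrix, snps: list[str], group=None):
    """Complete-case dosage submatrix for a SNP window and group filter."""
    if not (2 <= len(snps) <= 3):
        raise ValueError("haplotype window must span 2 or 3 SNPs")
    cols = [gm.variant_index(s) for s in snps]
    sub = gm.dosage[:, cols]
    if group is None or (isinstance(group, str) and group == "combined"):
        gmask = np.ones(gm.n_samples, bool)
    elif isinstance(group, str) and group in (CASE, CONTROL):
        gmask = np.asarray([p == group for p in gm.phenotype], bool)
    else:
        gmask = np.asarray(group, bool)
    typed = ~np.isnan(sub).any(axis=1)
    keep = gmask & typed
    alleles = [gm.alleles[c] for c in cols]
    return sub[keep].astype(int), alleles, [s for s, k in zip(gm.sample_ids, keep) if k]


def _compatible_pairs(genotype: tuple[int, ...], k: int):
    """Unordered haplotype-index pairs (as bit tuples) compatible with a genotype."""
    het = [i for i, g in enumerate(genotype) if g == 1]
    base = [g // 2 if g != 1 else 0 for g in genotype]
    pairs = []
    if not het:
        h = tuple(base)
        pairs.append((h, h))
        return pairs
    # assign first het site arbitrarily to h1 to enumerate unordered pairs once
    for assignment in itertools.product((0, 1), repeat=len(het) - 1):
        h1 = list(base)
        h2 = list(base)
        h1[het[0]], h2[het[0]] = 1, 0
        for site, bit in zip(het[1:], assignment):
            h1[site], h2[site] = bit, 1 - bit
        pairs.append((tuple(h1), tuple(h2)))
    return pairs


def em_haplotypes(
    gm: GenotypeMatrix,
    snps: list[str],
    group=None,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> HaplotypeDistribution:
    """EM haplotype frequencies from unphased genotypes (uniform start).

    ``group`` may be None/"combined", "case", "control", or a boolean
    sample mask.  Convergence: max frequency change < ``tol``.  Because
    the uniform start can sit on a saddle (exactly tied phase posteriors)
    and the likelihood can hold distinct phase optima, the EM is also run
    from a deterministic start per complementary haplotype pair and the
    best-likelihood converged optimum is reported; when several optima
    tie by symmetry, one is reported along with its log-likelihood.
    """
    data, alleles, _ = _extract(gm, snps, group)
    k = len(snps)
    if data.shape[0] == 0:
        raise ValueError("no complete-case samples after filtering")

    hap_bits = list(itertools.product((0, 1), repeat=k))
    hap_index = {h: i for i, h in enumerate(hap_bits)}
    H = len(hap_bits)

    warning = None
    mono = [j for j in range(k) if len(np.unique(data[:, j])) == 1 and data[0, j] != 1]
    if mono:
        warning = f"monomorphic SNP(s) in window: {[snps[j] for j in mono]}"

    # collapse to distinct genotype configurations
    configs: dict[tuple[int, ...], int] = {}
    for row in map(tuple, data):
        configs[row] = configs.get(row, 0) + 1
    config_pairs = {g: _compatible_pairs(g, k) for g in configs}

    def run(start: np.ndarray):
        freq = start
        loglik = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            new = np.zeros(H)
            ll = 0.0
            for g, cnt in configs.items():
                pairs = config_pairs[g]
                w = np.empty(len(pairs))
                for pi, (h1, h2) in enumerate(pairs):
                    mult = 1.0 if h1 == h2 else 2.0
                    w[pi] = mult * freq[hap_index[h1]] * freq[hap_index[h2]]
                tot = w.sum()
                if tot <= 0:
                    # genotype unexplainable under current freqs (can happen only
                    # if a haplotype frequency collapsed to 0); reseed uniformly
                    w[:] = 1.0
                    tot = float(len(pairs))
                ll += cnt * np.log(tot)
                w /= tot
                for pi, (h1, h2) in enumerate(pairs):
                    new[hap_index[h1]] += cnt * w[pi]
                    new[hap_index[h2]] += cnt * w[pi]
            new /= 2.0 * data.shape[0]
            delta = np.max(np.abs(new - freq))
            freq = new
            loglik = ll
            if delta < tol:
                converged = True
                break
        return freq, loglik, it, converged

    freq, loglik, it, converged = run(np.full(H, 1.0 / H))

    # The uniform start sits on a saddle whenever the phase posteriors of
    # multiply-heterozygous samples tie exactly (f_h f_~h products equal),
    # and the likelihood can hold genuinely distinct phase optima.  Run the
    # EM again from deterministic starts biased toward each complementary
    # haplotype pair -- the phase-ambiguity directions -- and report the
    # best-likelihood converged optimum.
    for hi, h in enumerate(hap_bits):
        comp = tuple(1 - b for b in h)
        if h >= comp:
            continue  # each complementary pair once
        start = np.full(H, 0.3 / (H - 2)) if H > 2 else np.zeros(H)
        start[hi] = 0.35
        start[hap_index[comp]] = 0.35
        start /= start.sum()
        f2, ll2, it2, conv2 = run(start)
        if ll2 > loglik + 1e-9:
            freq, loglik, converged, it = f2, ll2, conv2, it + it2

    haplotypes = [tuple(alleles[j][bit] for j, bit in enumerate(h)) for h in hap_bits]
    return HaplotypeDistribution(
        snp_ids=list(snps),
        alleles=alleles,
        haplotypes=haplotypes,
        frequencies=freq,
        log_likelihood=float(loglik),
        iterations=it,
        converged=converged,
        n_samples=data.shape[0],
        warning=warning,
    )


def ld_from_frequencies(p_AB: float, p_A: float, p_B: float, computed_on: str = "combined") -> LDStats:
    """D, D' and r^2 from a two-SNP haplotype frequency and its margins."""
    q_A, q_B = 1.0 - p_A, 1.0 - p_B
    if min(p_A, q_A, p_B, q_B) <= 0:
        raise ValueError("LD undefined: a SNP is monomorphic")
    D = p_AB - p_A * p_B
    if D >= 0:
        d_max = min(p_A * q_B, q_A * p_B)
    else:
        d_max = min(p_A * p_B, q_A * q_B)
    d_prime = abs(D) / d_max if d_max > 0 else 0.0
    r2 = D * D / (p_A * q_A * p_B * q_B)
    return LDStats(float(D), float(d_prime), float(r2), computed_on)


def ld_from_haplotypes(hd: HaplotypeDistribution, computed_on: str | None = None) -> LDStats:
    """LD statistics of a fitted two-SNP haplotype distribution.

    Allele "A"/"B" refer to the alt (minor) allele at each SNP.
    """
    if len(hd.snp_ids) != 2:
        raise ValueError("LD requires exactly 2 SNPs")
    bits = hd._bits()
    p_A = float(hd.frequencies[bits[:, 0] == 1].sum())
    p_B = float(hd.frequencies[bits[:, 1] == 1].sum())
    p_AB = float(hd.frequencies[(bits[:, 0] == 1) & (bits[:, 1] == 1)].sum())
    return ld_from_frequencies(p_AB, p_A, p_B, computed_on or "combined")


def stratified_ld(gm: GenotypeMatrix, snps: list[str], strata: dict[str, np.ndarray]) -> list[LDStats]:
    """One EM + LD computation per named sample stratum.

    ``strata`` maps a label to a boolean sample mask ("case"/"control"
    string shortcuts are also accepted as mask values).  Empty strata are
    skipped with a warning.
    """
    out = []
    for label, mask in strata.items():
        if isinstance(mask, str):
            sel = np.asarray([p == mask for p in gm.phenotype], bool)
        else:
            sel = np.asarray(mask, bool)
        if sel.sum() == 0:
            warnings.warn(f"stratum {label!r} is empty; skipped")
            continue
        if sel.sum() == 1:
            warnings.warn(f"stratum {label!r} has a single sample")
        hd = em_haplotypes(gm, snps, group=sel)
        out.append(ld_from_haplotypes(hd, computed_on=label))
    return out


def haplotype_association_from_frequencies(
    freq_case: float,
    freq_control: float,
    case_chromosomes: float,
    control_chromosomes: float,
) -> AssociationResult:
    """Score a haplotype from group frequencies via expected chromosome counts.

    Builds the 2x2 of expected target vs non-target chromosomes per group
    (fractional counts allowed) and scores it with the Pearson chi-square
    odds-ratio machinery.
    """
    a = freq_case * case_chromosomes
    b = case_chromosomes - a
    c = freq_control * control_chromosomes
    d = control_chromosomes - c
    return odds_ratio_2x2(ContingencyTable2x2(a, b, c, d))


def haplotype_association(
    gm: GenotypeMatrix,
    snps: list[str],
    target_haplotype: tuple[str, ...],
    n_permutations: int = 0,
    seed: int | None = None,
) -> AssociationResult:
    """Case-control association of a target haplotype.

    EM is run separately in cases and controls; the expected chromosome
    counts of target vs all other haplotypes form a 2x2 scored by the
    Pearson chi-square.  With ``n_permutations`` > 0 an empirical label
    permutation P value is attached under ``extra["perm_p"]``.
    """
    hd_case = em_haplotypes(gm, snps, group=CASE)
    hd_ctrl = em_haplotypes(gm, snps, group=CONTROL)
    f_case = hd_case.frequency(target_haplotype)
    f_ctrl = hd_ctrl.frequency(target_haplotype)
    if f_case == 0 and f_ctrl == 0:
        raise ValueError(f"target haplotype {target_haplotype!r} has zero frequency in both groups")
    res = haplotype_association_from_frequencies(
        f_case, f_ctrl, 2 * hd_case.n_samples, 2 * hd_ctrl.n_samples
    )
    res.extra["freq_case"] = f_case
    res.extra["freq_control"] = f_ctrl

    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        obs = res.chi2
        count = 0
        pheno = np.array(gm.phenotype, object)
        for _ in range(n_permutations):
            perm = rng.permutation(pheno)
            gm_p = GenotypeMatrix(gm.sample_ids, gm.variant_ids, gm.alleles, gm.dosage, perm)
            hc = em_haplotypes(gm_p, snps, group=CASE)
            hk = em_haplotypes(gm_p, snps, group=CONTROL)
            r = haplotype_association_from_frequencies(
                hc.frequency(target_haplotype), hk.frequency(target_haplotype),
                2 * hc.n_samples, 2 * hk.n_samples,
            )
            if r.chi2 >= obs:
                count += 1
        res.extra["perm_p"] = (count + 1) / (n_permutations + 1)
    return res


def haplotype_dosage(
    gm: GenotypeMatrix,
    snps: list[str],
    target_haplotype: tuple[str, ...],
    hd: HaplotypeDistribution | None = None,
) -> HaplotypeDosage:
    """Posterior-expected copies of a target haplotype per sample.

    Uses the EM-fitted frequencies (combined-sample fit unless ``hd`` is
    supplied) to weight the phase configurations of each sample.  Samples
    with missing genotypes in the window get NaN.
    """
    if hd is None:
        hd = em_haplotypes(gm, snps)
    k = len(snps)
    cols = [gm.variant_index(s) for s in snps]
    sub = gm.dosage[:, cols]
    hap_index = {tuple(b): i for i, b in enumerate(hd._bits())}
    target_bits = tuple(
        int(sym == alt) if sym in (ref, alt) else _bad_symbol(sym, snps[j])
        for j, (sym, (ref, alt)) in enumerate(zip(target_haplotype, hd.alleles))
    )

    n = gm.n_samples
    expected = np.full(n, np.nan)
    p_two = np.full(n, np.nan)
    freq = hd.frequencies
    for i in range(n):
        row = sub[i]
        if np.isnan(row).any():
            continue
        pairs = _compatible_pairs(tuple(int(x) for x in row), k)
        w = np.empty(len(pairs))
        copies = np.empty(len(pairs))
        for pi, (h1, h2) in enumerate(pairs):
            mult = 1.0 if h1 == h2 else 2.0
            w[pi] = mult * freq[hap_index[h1]] * freq[hap_index[h2]]
            copies[pi] = (h1 == target_bits) + (h2 == target_bits)
        tot = w.sum()
        if tot <= 0:
            w[:] = 1.0 / len(pairs)
        else:
            w /= tot
        expected[i] = float((w * copies).sum())
        p_two[i] = float(w[copies == 2].sum())
    return HaplotypeDosage(list(gm.sample_ids), expected, p_two)


def _bad_symbol(sym, snp):
    raise KeyError(f"allele symbol {sym!r} not valid for SNP {snp}")


def recessive_state(dosage: HaplotypeDosage, threshold: float = 0.5) -> np.ndarray:
    """Per-sample recessive (two-copy) call: P(2 copies) > threshold.

    NaN posteriors (untyped samples) yield False; use ``dosage.p_two`` to
    distinguish untyped from negative.
    """
    with np.errstate(invalid="ignore"):
        return np.asarray(dosage.p_two > threshold, bool)
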