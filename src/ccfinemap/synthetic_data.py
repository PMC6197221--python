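"""Seedable cohort generators with the LD and risk structure the analyses assume.

Two generator modes are supported per block of linked loci:

* ``group_specific`` — case and control chromosomes are drawn directly
  from separate haplotype frequency vectors (used to plant differential
  case/control LD).
* ``disease_model`` — haplotype pairs are drawn from population
  frequencies tilted exactly by a logistic penetrance
  P(case | pair) = expit(intercept + effect), where the effect combines
  per-haplotype (or per-allele) odds ratios under an additive, dominant
  or recessive coding.  Because case and control counts are fixed by
  design, sampling uses the exact conditional pair distributions
  P(pair | case) and P(pair | control); under the logistic model the
  implied odds ratios are exact, not rare-disease approximations.

When several blocks carry effects, each block is tilted independently
(blocks are independent given phenotype); joint cross-block penetrance is
not modelled.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .io_qc import GenotypeMatrix, HLACallTable, CASE, CONTROL
from .haplotype_ld import ld_from_frequencies, LDStats

__all__ = [
    "SnpBlock",
    "HlaBlock",
    "SimConfig",
    "simulate_cohort",
    "expected_summaries",
    "two_snp_frequencies",
    "three_snp_frequencies",
    "paperlike_config",
    "rpe_locus_config",
    "simulate_risk_states",
]


def _check_freqs(f: np.ndarray, name: str) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name}: frequencies must be nonnegative and sum to 1")
    return f


@dataclass
class SnpBlock:
    """A window of linked biallelic SNPs simulated at the haplotype level.

    Haplotypes are ordered as ``itertools.product((0, 1), repeat=k)``
    with 1 = alt allele.  Exactly one of (case_freqs, control_freqs) /
    (freqs + hap_or) modes must be configured.
    """

    snp_ids: list[str]
    alleles: list[tuple[str, str]]  # (ref, alt) per SNP
    case_freqs: np.ndarray | None = None
    control_freqs: np.ndarray | None = None
    freqs: np.ndarray | None = None
    hap_or: dict[tuple[int, ...], float] = field(default_factory=dict)
    model: str = "additive"

    @property
    def k(self) -> int:
        return len(self.snp_ids)

    @property
    def mode(self) -> str:
        if self.case_freqs is not None and self.control_freqs is not None:
            return "group_specific"
        if self.freqs is not None:
            return "disease_model"
        raise ValueError("SnpBlock: configure group frequencies or population freqs + effects")

    def haplotype_bits(self) -> list[tuple[int, ...]]:
        return list(itertools.product((0, 1), repeat=self.k))

    def validate(self) -> None:
        size = 2 ** self.k
        for name in ("case_freqs", "control_freqs", "freqs"):
            v = getattr(self, name)
            if v is not None:
                v = _check_freqs(v, name)
                if v.size != size:
                    raise ValueError(f"{name}: expected {size} haplotype frequencies for {self.k} SNPs")
                setattr(self, name, v)
        if any(or_ <= 0 for or_ in self.hap_or.values()):
            raise ValueError("haplotype odds ratios must be positive")
        for h in self.hap_or:
            if len(h) != self.k:
                raise ValueError(f"effect haplotype {h} does not match SNP count {self.k}")


@dataclass
class HlaBlock:
    """One or two linked multiallelic HLA loci simulated at the haplotype level.

    ``haplotypes[i]`` is a tuple of per-locus allele names (length =
    number of loci); ``allele_or`` maps (locus, allele) to an odds ratio.
    """

    loci: list[str]
    haplotypes: list[tuple[str, ...]]
    case_freqs: np.ndarray | None = None
    control_freqs: np.ndarray | None = None
    freqs: np.ndarray | None = None
    allele_or: dict[tuple[str, str], float] = field(default_factory=dict)
    model: str = "additive"

    @property
    def mode(self) -> str:
        if self.case_freqs is not None and self.control_freqs is not None:
            return "group_specific"
        if self.freqs is not None:
            return "disease_model"
        raise ValueError("HlaBlock: configure group frequencies or population freqs + effects")

    def validate(self) -> None:
        for h in self.haplotypes:
            if len(h) != len(self.loci):
                raise ValueError(f"haplotype {h} does not match locus count {len(self.loci)}")
        size = len(self.haplotypes)
        for name in ("case_freqs", "control_freqs", "freqs"):
            v = getattr(self, name)
            if v is not None:
                v = _check_freqs(v, name)
                if v.size != size:
                    raise ValueError(f"{name}: expected {size} haplotype frequencies")
                setattr(self, name, v)
        if any(or_ <= 0 for or_ in self.allele_or.values()):
            raise ValueError("allele odds ratios must be positive")


@dataclass
class SimConfig:
    n_cases: int
    n_controls: int
    snp_block: SnpBlock | None = None
    hla_block: HlaBlock | None = None
    # baseline log-odds of disease; the default corresponds to a rare
    # disease (prevalence ~1e-4), under which the group-conditional tilt
    # leaves per-unit odds ratios essentially at their configured values
    missing_rate: float = 0.0
    intercept: float = -9.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.snp_block is not None:
            self.snp_block.validate()
        if self.hla_block is not None:
            self.hla_block.validate()


# ---------------------------------------------------------------------------
# pair-distribution machinery
# ---------------------------------------------------------------------------

def _pair_space(n_hap: int):
    """Unordered pair indices (i <= j) with Hardy-Weinberg multiplicity."""
    pairs = [(i, j) for i in range(n_hap) for j in range(i, n_hap)]
    mult = np.array([1.0 if i == j else 2.0 for i, j in pairs])
    return pairs, mult


def _effect_additive_dom_rec(copies: np.ndarray, log_or: float, model: str) -> np.ndarray:
    if model == "additive":
        return copies * log_or
    if model == "dominant":
        return (copies >= 1) * log_or
    if model == "recessive":
        return (copies == 2) * log_or
    raise ValueError(f"unknown model {model!r}")


def _group_pair_dists(freqs, effects, intercept):
    """Exact P(pair|case), P(pair|control) for a tilted logistic model.

    ``effects[p]`` is the log-odds contribution of pair p.
    """
    pairs, mult = _pair_space(len(freqs))
    base = np.array([freqs[i] * freqs[j] for i, j in pairs]) * mult
    logit = intercept + effects
    pen = 1.0 / (1.0 + np.exp(-logit))
    case = base * pen
    ctrl = base * (1.0 - pen)
    return pairs, case / case.sum(), ctrl / ctrl.sum()


def _pair_dists_group_specific(case_freqs, control_freqs):
    pairs, mult = _pair_space(len(case_freqs))
    case = np.array([case_freqs[i] * case_freqs[j] for i, j in pairs]) * mult
    ctrl = np.array([control_freqs[i] * control_freqs[j] for i, j in pairs]) * mult
    return pairs, case / case.sum(), ctrl / ctrl.sum()


def _snp_pair_effects(block: SnpBlock) -> np.ndarray:
    haps = block.haplotype_bits()
    pairs, _ = _pair_space(len(haps))
    eff = np.zeros(len(pairs))
    for target, or_ in block.hap_or.items():
        copies = np.array([(haps[i] == target) + (haps[j] == target) for i, j in pairs], float)
        eff += _effect_additive_dom_rec(copies, np.log(or_), block.model)
    return eff


def _hla_pair_effects(block: HlaBlock) -> np.ndarray:
    pairs, _ = _pair_space(len(block.haplotypes))
    eff = np.zeros(len(pairs))
    for (locus, allele), or_ in block.allele_or.items():
        li = block.loci.index(locus)
        copies = np.array(
            [
                (block.haplotypes[i][li] == allele) + (block.haplotypes[j][li] == allele)
                for i, j in pairs
            ],
            float,
        )
        eff += _effect_additive_dom_rec(copies, np.log(or_), block.model)
    return eff


def _block_pair_dists(block, intercept):
    if block.mode == "group_specific":
        return _pair_dists_group_specific(block.case_freqs, block.control_freqs)
    if isinstance(block, SnpBlock):
        eff = _snp_pair_effects(block)
    else:
        eff = _hla_pair_effects(block)
    return _group_pair_dists(block.freqs, eff, intercept)


def group_haplotype_frequencies(block, intercept: float = -9.0) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-group chromosome haplotype frequencies implied by a block."""
    pairs, p_case, p_ctrl = _block_pair_dists(block, intercept)
    n_hap = len(block.haplotype_bits()) if isinstance(block, SnpBlock) else len(block.haplotypes)
    f_case = np.zeros(n_hap)
    f_ctrl = np.zeros(n_hap)
    for (i, j), wc, wk in zip(pairs, p_case, p_ctrl):
        f_case[i] += wc / 2.0
        f_case[j] += wc / 2.0
        f_ctrl[i] += wk / 2.0
        f_ctrl[j] += wk / 2.0
    return f_case, f_ctrl


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(cfg: SimConfig) -> tuple[GenotypeMatrix | None, dict[str, HLACallTable], np.ndarray]:
    """Draw a case-control cohort from a :class:`SimConfig`.

    Returns (GenotypeMatrix or None, {locus: HLACallTable}, phenotype).
    The same seed always yields identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cases + cfg.n_controls
    phenotype = np.array([CASE] * cfg.n_cases + [CONTROL] * cfg.n_controls, object)
    sample_ids = [f"S{i:05d}" for i in range(n)]

    gm = None
    if cfg.snp_block is not None:
        blk = cfg.snp_block
        haps = blk.haplotype_bits()
        pairs, p_case, p_ctrl = _block_pair_dists(blk, cfg.intercept)
        idx_case = rng.choice(len(pairs), size=cfg.n_cases, p=p_case)
        idx_ctrl = rng.choice(len(pairs), size=cfg.n_controls, p=p_ctrl)
        dosage = np.empty((n, blk.k))
        for row, pi in enumerate(np.concatenate([idx_case, idx_ctrl])):
            i, j = pairs[pi]
            dosage[row] = np.add(haps[i], haps[j], dtype=float)
        if cfg.missing_rate > 0:
            mask = rng.random(dosage.shape) < cfg.missing_rate
            dosage[mask] = np.nan
        gm = GenotypeMatrix(sample_ids, list(blk.snp_ids), list(blk.alleles), dosage, phenotype)

    hla_tables: dict[str, HLACallTable] = {}
    if cfg.hla_block is not None:
        blk = cfg.hla_block
        pairs, p_case, p_ctrl = _block_pair_dists(blk, cfg.intercept)
        idx_case = rng.choice(len(pairs), size=cfg.n_cases, p=p_case)
        idx_ctrl = rng.choice(len(pairs), size=cfg.n_controls, p=p_ctrl)
        draws = np.concatenate([idx_case, idx_ctrl])
        for li, locus in enumerate(blk.loci):
            a1: list[str | None] = []
            a2: list[str | None] = []
            for pi in draws:
                i, j = pairs[pi]
                x, y = blk.haplotypes[i][li], blk.haplotypes[j][li]
                if cfg.missing_rate > 0 and rng.random() < cfg.missing_rate:
                    x = None
                if cfg.missing_rate > 0 and rng.random() < cfg.missing_rate:
                    y = None
                a1.append(x)
                a2.append(y)
            hla_tables[locus] = HLACallTable(locus, list(sample_ids), a1, a2, phenotype)

    return gm, hla_tables, phenotype


def expected_summaries(cfg: SimConfig) -> dict:
    """Closed-form per-group haplotype/allele frequencies, LD and allelic ORs."""
    cfg.validate()
    out: dict = {}
    if cfg.snp_block is not None:
        blk = cfg.snp_block
        f_case, f_ctrl = group_haplotype_frequencies(blk, cfg.intercept)
        out["snp_hap_freq_case"] = f_case
        out["snp_hap_freq_control"] = f_ctrl
        bits = np.array(blk.haplotype_bits())
        ld = {}
        for (j1, j2) in itertools.combinations(range(blk.k), 2):
            key = (blk.snp_ids[j1], blk.snp_ids[j2])
            ld[key] = {}
            for label, f in (("case", f_case), ("control", f_ctrl)):
                pA = float(f[bits[:, j1] == 1].sum())
                pB = float(f[bits[:, j2] == 1].sum())
                pAB = float(f[(bits[:, j1] == 1) & (bits[:, j2] == 1)].sum())
                ld[key][label] = ld_from_frequencies(pAB, pA, pB, computed_on=label)
        out["snp_ld"] = ld
        # per-haplotype allelic OR from group chromosome frequencies
        ors = {}
        for hi, h in enumerate(blk.haplotype_bits()):
            fc, fk = f_case[hi], f_ctrl[hi]
            if 0 < fc < 1 and 0 < fk < 1:
                ors[h] = (fc / (1 - fc)) / (fk / (1 - fk))
        out["snp_hap_or"] = ors
    if cfg.hla_block is not None:
        blk = cfg.hla_block
        f_case, f_ctrl = group_haplotype_frequencies(blk, cfg.intercept)
        out["hla_hap_freq_case"] = f_case
        out["hla_hap_freq_control"] = f_ctrl
        allele_or: dict[tuple[str, str], float] = {}
        allele_freq: dict[tuple[str, str], tuple[float, float]] = {}
        for li, locus in enumerate(blk.loci):
            alleles = sorted({h[li] for h in blk.haplotypes})
            for a in alleles:
                sel = np.array([h[li] == a for h in blk.haplotypes])
                fc = float(f_case[sel].sum())
                fk = float(f_ctrl[sel].sum())
                allele_freq[(locus, a)] = (fc, fk)
                if 0 < fc < 1 and 0 < fk < 1:
                    allele_or[(locus, a)] = (fc / (1 - fc)) / (fk / (1 - fk))
        out["hla_allele_freq"] = allele_freq
        out["hla_allele_or"] = allele_or
    return out


# ---------------------------------------------------------------------------
# frequency constructors and canonical fixtures
# ---------------------------------------------------------------------------

def two_snp_frequencies(p1: float, p2: float, r2: float, sign: int = 1) -> np.ndarray:
    """Four haplotype frequencies with given alt-allele margins and r^2.

    Order matches ``itertools.product((0,1), repeat=2)``: (00, 01, 10, 11).
    ``sign`` sets the direction of D between the alt alleles.
    """
    if not (0 < p1 < 1 and 0 < p2 < 1 and 0 <= r2 <= 1):
        raise ValueError("margins must be in (0,1) and r2 in [0,1]")
    D = sign * np.sqrt(r2 * p1 * (1 - p1) * p2 * (1 - p2))
    f11 = p1 * p2 + D
    f10 = p1 - f11
    f01 = p2 - f11
    f00 = 1.0 - p1 - p2 + f11
    f = np.array([f00, f01, f10, f11])
    if (f < -1e-12).any():
        raise ValueError("requested (margins, r2) combination is infeasible")
    return np.clip(f, 0.0, 1.0) / np.clip(f, 0.0, 1.0).sum()


def three_snp_frequencies(pair_freqs: np.ndarray, mirror_prob: float = 0.985) -> np.ndarray:
    """Extend a two-SNP haplotype vector with a third SNP shadowing the second.

    The third SNP's allele copies the second's with probability
    ``mirror_prob`` (near-complete LD), producing the 8-vector ordered as
    ``itertools.product((0,1), repeat=3)``.
    """
    f = np.zeros(8)
    for idx, (b1, b2) in enumerate(itertools.product((0, 1), repeat=2)):
        for b3 in (0, 1):
            w = mirror_prob if b3 == b2 else 1.0 - mirror_prob
            f[(b1 << 2) | (b2 << 1) | b3] = pair_freqs[idx] * w
    return f


# canonical study-scale fixture: 222 cases vs 701 controls, a 3-SNP risk
# window with stronger case LD (r^2 0.92 vs 0.77 between the first two SNPs),
# and two linked HLA-like loci with planted allelic odds ratios
PAPERLIKE_N_CASES = 222
PAPERLIKE_N_CONTROLS = 701
PAPERLIKE_CASE_R2 = 0.92
PAPERLIKE_CONTROL_R2 = 0.77
# alt (minor) allele frequencies of the missense-like and intronic-like SNPs
PAPERLIKE_CASE_MAF = (0.23, 0.22)
PAPERLIKE_CONTROL_MAF = (0.42, 0.42)


def paperlike_snp_block() -> SnpBlock:
    case4 = two_snp_frequencies(*PAPERLIKE_CASE_MAF, PAPERLIKE_CASE_R2)
    ctrl4 = two_snp_frequencies(*PAPERLIKE_CONTROL_MAF, PAPERLIKE_CONTROL_R2)
    return SnpBlock(
        snp_ids=["missense", "intronic", "utr5"],
        alleles=[("G", "C"), ("A", "G"), ("C", "T")],
        case_freqs=three_snp_frequencies(case4),
        control_freqs=three_snp_frequencies(ctrl4),
    )


def paperlike_hla_block(
    primary_or: float = 3.0,
    secondary_or: float = 2.0,
    linkage: float = 0.95,
) -> HlaBlock:
    """Two linked HLA-like loci with planted risk alleles.

    Locus "DRB1" carries a primary risk allele (15:01-like, OR
    ``primary_or``) and a secondary one (14:54-like, OR ``secondary_or``);
    each DRB1 allele travels with a matched DQB1 allele with probability
    ``linkage``, placing the DQB1 partners in strong LD with the DRB1
    risk alleles.
    """
    drb = ["DRB1*15:01", "DRB1*14:54", "DRB1*11:01", "DRB1*14:05"] + [
        f"DRB1*{i:02d}:01" for i in range(1, 11)
    ]
    dqb = ["DQB1*06:02", "DQB1*05:02", "DQB1*03:01", "DQB1*05:03"] + [
        f"DQB1*{i:02d}:01" for i in range(1, 11)
    ]
    base = np.array([0.082, 0.031, 0.025, 0.020] + [0.0842] * 10)
    base = base / base.sum()
    haplotypes: list[tuple[str, str]] = []
    freqs: list[float] = []
    off = (1.0 - linkage) / (len(dqb) - 1)
    for i, a in enumerate(drb):
        for j, b in enumerate(dqb):
            w = linkage if i == j else off
            if w > 0:
                haplotypes.append((a, b))
                freqs.append(base[i] * w)
    return HlaBlock(
        loci=["DRB1", "DQB1"],
        haplotypes=haplotypes,
        freqs=np.array(freqs) / np.sum(freqs),
        allele_or={("DRB1", "DRB1*15:01"): primary_or, ("DRB1", "DRB1*14:54"): secondary_or},
        model="additive",
    )


def paperlike_config(seed: int = 0) -> SimConfig:
    """The canonical study-scale fixture used across the test-suite."""
    return SimConfig(
        n_cases=PAPERLIKE_N_CASES,
        n_controls=PAPERLIKE_N_CONTROLS,
        snp_block=paperlike_snp_block(),
        hla_block=paperlike_hla_block(),
        seed=seed,
    )


def rpe_locus_config(
    seed: int = 0,
    n_cases: int = 500,
    n_controls: int = 500,
    n_alleles: int = 20,
    primary_or: float = 3.0,
    secondary_or: float = 2.0,
    primary_freq: float = 0.10,
    secondary_freq: float = 0.08,
) -> SimConfig:
    """Single multiallelic locus with one strong and one weaker planted risk allele."""
    alleles = ["A*01:01", "A*02:01"] + [f"A*{i:02d}:01" for i in range(3, n_alleles + 1)]
    rest = (1.0 - primary_freq - secondary_freq) / (n_alleles - 2)
    freqs = np.array([primary_freq, secondary_freq] + [rest] * (n_alleles - 2))
    blk = HlaBlock(
        loci=["A"],
        haplotypes=[(a,) for a in alleles],
        freqs=freqs,
        allele_or={("A", "A*01:01"): primary_or, ("A", "A*02:01"): secondary_or},
        model="additive",
    )
    return SimConfig(n_cases=n_cases, n_controls=n_controls, hla_block=blk, seed=seed)


def simulate_risk_states(
    n_cases: int,
    n_controls: int,
    or1: float,
    or2: float,
    p1: float = 0.2,
    p2: float = 0.2,
    joint_multiplier: float = 1.0,
    intercept: float = -9.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw two binary risk states under a logistic joint model.

    States are independent in the population with prevalences p1, p2;
    the case log-odds add log(or1), log(or2) and log(joint_multiplier)
    for double positives.  Group sizes are fixed and cells drawn from the
    exact conditional distributions, so the implied group-vs-reference
    odds ratios are exactly or1, or2 and or1*or2*joint_multiplier.
    """
    rng = np.random.default_rng(seed)
    cells = [(0, 0), (1, 0), (0, 1), (1, 1)]
    base = np.array([(p1 if s1 else 1 - p1) * (p2 if s2 else 1 - p2) for s1, s2 in cells])
    logit = intercept + np.array(
        [s1 * np.log(or1) + s2 * np.log(or2) + s1 * s2 * np.log(joint_multiplier) for s1, s2 in cells]
    )
    pen = 1.0 / (1.0 + np.exp(-logit))
    p_case = base * pen / (base * pen).sum()
    p_ctrl = base * (1 - pen) / (base * (1 - pen)).sum()
    idx = np.concatenate([
        rng.choice(4, size=n_cases, p=p_case),
        rng.choice(4, size=n_controls, p=p_ctrl),
    ])
    s1 = np.array([cells[i][0] for i in idx], bool)
    s2 = np.array([cells[i][1] for i in idx], bool)
    pheno = np.array([CASE] * n_cases + [CONTROL] * n_controls, object)
    return s1, s2, pheno
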