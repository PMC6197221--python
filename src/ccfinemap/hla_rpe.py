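"""Multiallelic HLA association and sequential RPE testing.

A classical HLA locus carries many alleles, and a strongly associated one
distorts the case frequencies of every other allele (the denominators are
shared).  The relative-predispositional-effect (RPE) procedure removes
the chromosomes carrying each detected risk allele and re-tests the
remaining alleles, repeating until no allele stays significant after a
Bonferroni correction restricted to alleles with control frequency above
a floor (default 0.5%).

Detected risk alleles can then be collapsed into a single per-sample
dosage (number of chromosomes carrying any risk allele), and two loci's
collapsed risks compared by reciprocal conditional logistic tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_qc import HLACallTable, CASE
from .assoc_core import (
    AssociationResult,
    ContingencyTable2x2,
    odds_ratio_2x2,
    conditional_test,
)

__all__ = [
    "AlleleCountTable",
    "RPERound",
    "CollapsedRisk",
    "allele_counts",
    "per_allele_tests",
    "rpe_sequential",
    "collapse_risk",
    "reciprocal_conditional",
    "rpe_report",
]


@dataclass
class AlleleCountTable:
    """Chromosome counts per allele and phenotype group at one locus."""

    locus: str
    alleles: list[str]
    case_count: np.ndarray
    control_count: np.ndarray

    def __post_init__(self) -> None:
        self.case_count = np.asarray(self.case_count, dtype=float)
        self.control_count = np.asarray(self.control_count, dtype=float)
        if not (len(self.alleles) == self.case_count.size == self.control_count.size):
            raise ValueError("allele names and counts have unequal lengths")
        if (self.case_count < 0).any() or (self.control_count < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def case_total(self) -> float:
        return float(self.case_count.sum())

    @property
    def control_total(self) -> float:
        return float(self.control_count.sum())

    def remove(self, alleles: list[str]) -> "AlleleCountTable":
        """Drop the named alleles' chromosomes from counts and totals."""
        keep = [i for i, a in enumerate(self.alleles) if a not in set(alleles)]
        return AlleleCountTable(
            self.locus,
            [self.alleles[i] for i in keep],
            self.case_count[keep],
            self.control_count[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "allele": self.alleles,
                "case_n": self.case_count,
                "case_pct": 100 * self.case_count / self.case_total,
                "control_n": self.control_count,
                "control_pct": 100 * self.control_count / self.control_total,
            }
        )


@dataclass
class RPERound:
    round_index: int
    removed_alleles: list[str]
    tested: dict[str, AssociationResult]
    n_correction: int
    selected_allele: str | None
    p_corrected: float | None


@dataclass
class CollapsedRisk:
    """Per-sample count of chromosomes carrying any allele of a risk set."""

    locus: str
    risk_alleles: set[str]
    sample_ids: list[str]
    dosage: np.ndarray  # 0/1/2, NaN when both alleles untyped
    phenotype: np.ndarray


def allele_counts(hla: HLACallTable, locus: str | None = None) -> AlleleCountTable:
    """Tally chromosome counts per allele and group from per-sample calls."""
    if locus is not None and locus != hla.locus:
        raise KeyError(f"table holds locus {hla.locus!r}, not {locus!r}")
    case = hla.is_case()
    tally: dict[str, list[float]] = {}
    for i, (a1, a2) in enumerate(zip(hla.allele_1, hla.allele_2)):
        g = 0 if case[i] else 1
        for a in (a1, a2):
            if a is None:
                continue
            tally.setdefault(a, [0.0, 0.0])[g] += 1
    if not tally:
        raise ValueError("no typed chromosomes at locus")
    names = sorted(tally)
    cc = np.array([tally[a][0] for a in names])
    kk = np.array([tally[a][1] for a in names])
    if cc.sum() == 0 or kk.sum() == 0:
        raise ValueError("zero typed chromosomes in one phenotype group")
    return AlleleCountTable(hla.locus, names, cc, kk)


def _allele_2x2(act: AlleleCountTable, allele: str) -> ContingencyTable2x2:
    i = act.alleles.index(allele)
    a = act.case_count[i]
    c = act.control_count[i]
    return ContingencyTable2x2(a, act.case_total - a, c, act.control_total - c)


def per_allele_tests(act: AlleleCountTable, haldane: bool = True) -> dict[str, AssociationResult]:
    """Allele-vs-all-other-alleles 2x2 test for every allele of the locus."""
    if len(act.alleles) < 2:
        raise ValueError("need at least 2 alleles")
    return {a: odds_ratio_2x2(_allele_2x2(act, a), haldane=haldane) for a in act.alleles}


def _expected_deviation_test(act: AlleleCountTable, allele: str) -> AssociationResult:
    """Deviation of an allele's case count from its control-frequency expectation.

    Under the null that the remaining alleles carry no residual risk, the
    case count of each allele should match the control relative frequency
    scaled to the case total.  The squared deviation is scored as a 1-df
    chi-square with the score-test null variance

        Var(obs - exp) = n_case * f * (1 - f) * (1 + n_case/n_control)

    with f estimated from the pooled (case + control) frequency; the
    (1 + n_case/n_control) term accounts for the expectation itself being
    estimated from a finite control sample.  The reported OR is the
    ordinary 2x2 OR.
    """
    i = act.alleles.index(allele)
    obs = act.case_count[i]
    n_case = act.case_total
    f_ctrl = act.control_count[i] / act.control_total
    exp = f_ctrl * n_case
    base = odds_ratio_2x2(_allele_2x2(act, allele), haldane=True)
    f_pool = (act.case_count[i] + act.control_count[i]) / (n_case + act.control_total)
    if exp <= 0 or exp >= n_case or not (0 < f_pool < 1):
        base.p_value, base.chi2 = 1.0, 0.0
        return base
    var = n_case * f_pool * (1.0 - f_pool) * (1.0 + n_case / act.control_total)
    chi2 = (obs - exp) ** 2 / var
    p = float(stats.chi2.sf(chi2, 1))
    return AssociationResult(
        base.odds_ratio, base.ci_low, base.ci_high, float(chi2), p,
        model="allelic", method="expected_deviation",
    )


def rpe_sequential(
    act: AlleleCountTable,
    alpha: float = 0.05,
    freq_threshold: float = 0.005,
    statistic: str = "expected_deviation",
    correction: str = "per_round",
    max_rounds: int | None = None,
) -> list[RPERound]:
    """Sequential RPE testing of a multiallelic locus.

    Round 1 selects the allele with the smallest uncorrected P over the
    full table.  Each later round removes every previously selected
    allele's chromosomes from both groups, re-tests the remaining alleles
    with ``statistic`` ("remaining_2x2" or "expected_deviation"), applies
    Pc = P x n_correction where n_correction counts alleles under test
    with control frequency > ``freq_threshold``, and selects the
    minimum-Pc allele while Pc < ``alpha``.  Ties break by larger OR,
    then allele name.
    """
    if not (0 <= alpha < 1):
        raise ValueError("alpha must be in [0, 1)")
    if statistic not in ("remaining_2x2", "expected_deviation"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if correction not in ("per_round", "initial"):
        raise ValueError(f"unknown correction {correction!r}")

    n_initial = int((act.control_count / act.control_total > freq_threshold).sum())

    removed: list[str] = []
    rounds: list[RPERound] = []
    current = act
    r = 0
    while len(current.alleles) >= 2:
        r += 1
        if max_rounds is not None and r > max_rounds:
            break
        if statistic == "remaining_2x2" or r == 1:
            tested = per_allele_tests(current, haldane=True)
        else:
            tested = {a: _expected_deviation_test(current, a) for a in current.alleles}

        if correction == "per_round":
            n_corr = int((current.control_count / current.control_total > freq_threshold).sum())
        else:
            n_corr = n_initial
        n_corr = max(n_corr, 1)

        # order candidates: smallest P, then larger OR, then name
        def sort_key(a: str):
            res = tested[a]
            return (res.p_value, -res.odds_ratio, a)

        best = min(current.alleles, key=sort_key)
        best_res = tested[best]
        pc = min(best_res.p_value * n_corr, 1.0)

        if r == 1:
            selected = best if best_res.p_value < alpha else None
            rounds.append(RPERound(r, list(removed), tested, n_corr, selected, pc))
        else:
            selected = best if pc < alpha else None
            rounds.append(RPERound(r, list(removed), tested, n_corr, selected, pc))
        if selected is None:
            break
        removed.append(selected)
        current = current.remove([selected])
    return rounds


def rpe_report(act: AlleleCountTable, rounds: list[RPERound]) -> pd.DataFrame:
    """Tab-ready summary: per-allele counts, naive test, and RPE columns."""
    naive = per_allele_tests(act, haldane=True)
    frame = act.to_frame()
    sel_round = {}
    rpe_or, rpe_p, rpe_pc = {}, {}, {}
    for rnd in rounds:
        if rnd.selected_allele:
            a = rnd.selected_allele
            sel_round[a] = rnd.round_index
            res = rnd.tested[a]
            rpe_or[a] = res.odds_ratio
            rpe_p[a] = res.p_value
            rpe_pc[a] = rnd.p_corrected
    frame["OR"] = [naive[a].odds_ratio for a in act.alleles]
    frame["ci_low"] = [naive[a].ci_low for a in act.alleles]
    frame["ci_high"] = [naive[a].ci_high for a in act.alleles]
    frame["P"] = [naive[a].p_value for a in act.alleles]
    frame["rpe_round"] = [sel_round.get(a, np.nan) for a in act.alleles]
    frame["rpe_OR"] = [rpe_or.get(a, np.nan) for a in act.alleles]
    frame["rpe_P"] = [rpe_p.get(a, np.nan) for a in act.alleles]
    frame["rpe_Pc"] = [rpe_pc.get(a, np.nan) for a in act.alleles]
    return frame


def collapse_risk(hla: HLACallTable, risk_alleles: set[str], locus: str | None = None) -> CollapsedRisk:
    """Collapse a risk-allele set to a per-sample 0/1/2 dosage.

    Dosage counts the sample's chromosomes carrying any risk allele,
    treating each allele equally.  Fully untyped samples get NaN; a
    single-missing sample is scored on its one typed chromosome.
    """
    if not risk_alleles:
        raise ValueError("risk_alleles must be nonempty")
    if locus is not None and locus != hla.locus:
        raise KeyError(f"table holds locus {hla.locus!r}, not {locus!r}")
    observed = set(a for pair in zip(hla.allele_1, hla.allele_2) for a in pair if a is not None)
    missing = set(risk_alleles) - observed
    if missing:
        warnings.warn(f"risk allele(s) never observed at {hla.locus}: {sorted(missing)}")

    dosage = np.full(hla.n_samples, np.nan)
    for i, (a1, a2) in enumerate(zip(hla.allele_1, hla.allele_2)):
        typed = [a for a in (a1, a2) if a is not None]
        if typed:
            dosage[i] = sum(a in risk_alleles for a in typed)
    return CollapsedRisk(hla.locus, set(risk_alleles), list(hla.sample_ids), dosage, hla.phenotype)


def reciprocal_conditional(
    riskA: CollapsedRisk,
    riskB: CollapsedRisk,
    pheno: np.ndarray | None = None,
    model: str = "additive",
) -> tuple[AssociationResult, AssociationResult]:
    """Reciprocal conditional tests of two collapsed risk dosages.

    Fits phenotype ~ coded(A) + coded(B) and reports each locus's Wald
    statistics with the other as conditioner.  Sample sets must align.
    """
    if model not in ("additive", "dominant"):
        raise ValueError("model must be 'additive' or 'dominant'")
    if riskA.sample_ids != riskB.sample_ids:
        raise ValueError("collapsed risks cover different sample sets")
    ph = riskA.phenotype if pheno is None else pheno
    res_a = conditional_test(riskA.dosage, [riskB.dosage], ph, model=model)
    res_b = conditional_test(riskB.dosage, [riskA.dosage], ph, model=model)
    return res_a, res_b
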