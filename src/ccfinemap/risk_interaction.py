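"""Combined-risk group analysis for two binary risk states.

Cross-classifies samples by SNP-haplotype recessive state and HLA
risk-allele positivity, scores each group against the least-risk
(double-negative) reference, and summarises departure from a
multiplicative joint effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_qc import CASE
from .assoc_core import AssociationResult, ContingencyTable2x2, odds_ratio_2x2

__all__ = ["RiskGroupTable", "risk_groups", "interaction_summary"]

GROUPS = ("hap-/hla-", "hap+/hla-", "hap-/hla+", "hap+/hla+")


@dataclass
class RiskGroupTable:
    counts: pd.DataFrame  # index GROUPS, columns case/control
    results: dict[str, AssociationResult]
    n_excluded: int = 0
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["OR"] = [1.0 if g == GROUPS[0] else self.results[g].odds_ratio for g in out.index]
        out["ci_low"] = [np.nan if g == GROUPS[0] else self.results[g].ci_low for g in out.index]
        out["ci_high"] = [np.nan if g == GROUPS[0] else self.results[g].ci_high for g in out.index]
        out["P"] = [np.nan if g == GROUPS[0] else self.results[g].p_value for g in out.index]
        return out


def risk_groups(
    hap_state: np.ndarray,
    hla_positive: np.ndarray,
    pheno: np.ndarray,
    haldane: bool = True,
) -> RiskGroupTable:
    """Cross-classify by the two risk states and score each group vs reference.

    ``hap_state`` and ``hla_positive`` are per-sample booleans (NaN/None
    entries are excluded and counted).  The double-negative group is the
    reference; each other group forms a 2x2 against it.
    """
    hap = np.asarray(hap_state, dtype=object)
    hla = np.asarray(hla_positive, dtype=object)
    ph = np.asarray(pheno, dtype=object)
    if not (hap.size == hla.size == ph.size):
        raise ValueError("input vectors have unequal lengths")

    defined = np.array([
        (h is not None and g is not None and h == h and g == g) for h, g in zip(hap, hla)
    ])
    n_excluded = int((~defined).sum())

    counts = pd.DataFrame(0, index=list(GROUPS), columns=["case", "control"])
    for h, g, p in zip(hap[defined], hla[defined], ph[defined]):
        grp = GROUPS[int(bool(h)) + 2 * int(bool(g))]
        counts.loc[grp, "case" if p == CASE else "control"] += 1

    ref_case = counts.loc[GROUPS[0], "case"]
    ref_ctrl = counts.loc[GROUPS[0], "control"]
    if ref_case + ref_ctrl == 0:
        raise ValueError("reference (double-negative) group is empty")

    results: dict[str, AssociationResult] = {}
    degenerate = False
    for g in GROUPS[1:]:
        gc, gk = counts.loc[g, "case"], counts.loc[g, "control"]
        if gc + gk == 0:
            degenerate = True
            results[g] = AssociationResult(np.nan, np.nan, np.nan, np.nan, np.nan, degenerate=True)
            continue
        t = ContingencyTable2x2(gc, ref_case, gk, ref_ctrl)
        # exposed = membership in group g, unexposed = reference membership
        results[g] = odds_ratio_2x2(t, haldane=haldane)
    return RiskGroupTable(counts, results, n_excluded, degenerate)


def interaction_summary(
    table: RiskGroupTable,
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> dict:
    """Departure-from-multiplicativity ratio with a bootstrap CI.

    ratio = OR(hap+,hla+) / (OR(hap+,hla-) x OR(hap-,hla+)); 1.0 under a
    multiplicative joint effect.  The CI is a seeded percentile bootstrap
    over multinomial resamples of the group counts within each phenotype.
    """
    counts = table.counts
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("all four groups must be nonempty")

    def ratio_from(counts_arr: np.ndarray) -> float:
        # counts_arr: 4 x 2 (groups x case/control), Haldane inside
        c = counts_arr.astype(float)
        if (c == 0).any():
            c = c + 0.5
        def or_vs_ref(i):
            return (c[i, 0] * c[0, 1]) / (c[0, 0] * c[i, 1])
        return or_vs_ref(3) / (or_vs_ref(1) * or_vs_ref(2))

    arr = counts.to_numpy()
    point = ratio_from(arr)

    rng = np.random.default_rng(seed)
    n_case, n_ctrl = arr[:, 0].sum(), arr[:, 1].sum()
    p_case = arr[:, 0] / n_case
    p_ctrl = arr[:, 1] / n_ctrl
    boots = np.empty(n_boot)
    for b in range(n_boot):
        rc = rng.multinomial(n_case, p_case)
        rk = rng.multinomial(n_ctrl, p_ctrl)
        boots[b] = ratio_from(np.column_stack([rc, rk]))
    lo = (1 - ci_level) / 2
    ci = (float(np.quantile(boots, lo)), float(np.quantile(boots, 1 - lo)))
    return {
        "ratio": float(point),
        "ci_low": ci[0],
        "ci_high": ci[1],
        "n_boot": n_boot,
        "haldane_applied": bool((arr == 0).any()),
    }
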