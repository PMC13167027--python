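"""Gene presence/absence classification and differential testing.

Each (gene, sample) is classified *present* when breadth >= 65% and raw mean
depth meets the sample group's threshold (>= 20x in luna-dominant samples,
>= 2x in lotti-dominant ones), *absent* when breadth and depth fall below
the absence cutoffs, and *unknown* otherwise; unknown cells are excluded
from testing.  Per gene, present/absent counts are compared between groups
with a two-sided Fisher exact test and BH FDR correction across genes.

The two-sided p-value uses the point-probability ordering: the sum, over all
2x2 tables with the observed margins, of hypergeometric point probabilities
no larger than the observed table's.  It is computed in exact integer
arithmetic (binomial-coefficient numerators over a common denominator), so
ties are exact and no floating-point tolerance is needed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from symprof.io import GROUP_LOTTI, GROUP_LUNA, GROUPS, ParameterError

logger = logging.getLogger("symprof")

STATE_PRESENT = "present"
STATE_ABSENT = "absent"
STATE_UNKNOWN = "unknown"

CALL_A = "A_specific"  # enriched-presence in luna-dominant samples
CALL_B = "B_specific"
CALL_NS = "not_significant"
CALL_UNTESTABLE = "untestable"

#: dominance label -> symbiont group; both luna variants collapse to luna.
_DOMINANCE_TO_GROUP = {
    "T_lotti": GROUP_LOTTI,
    "T_luna_var1": GROUP_LUNA,
    "T_luna_var2": GROUP_LUNA,
}


@dataclass
class ClassificationThresholds:
    """Present/absent cutoffs; the gap between them is the *unknown* buffer."""

    breadth_present: float = 0.65
    depth_present_by_group: dict[str, float] = field(
        default_factory=lambda: {GROUP_LUNA: 20.0, GROUP_LOTTI: 2.0}
    )
    breadth_absent: float = 0.10
    depth_absent: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.breadth_present <= 1:
            raise ParameterError("breadth_present outside (0, 1]")
        if self.breadth_absent >= self.breadth_present:
            raise ParameterError("breadth_absent must be < breadth_present")
        if self.depth_absent >= min(self.depth_present_by_group.values()):
            raise ParameterError("depth_absent must be < every presence depth threshold")


def assign_groups(dominance: Mapping[str, str]) -> dict[str, str]:
    """Map per-sample dominant symbiont types to symbiont groups.

    Samples whose dominant type is "none" (no focal ASV detected) are
    excluded with a warning.
    """
    groups: dict[str, str] = {}
    excluded = []
    for sample, dom in dominance.items():
        if dom in _DOMINANCE_TO_GROUP:
            groups[sample] = _DOMINANCE_TO_GROUP[dom]
        elif dom in ("none", ".", "", None):
            excluded.append(sample)
        else:
            raise ParameterError(f"sample {sample!r}: unknown dominant type {dom!r}")
    if excluded:
        logger.warning(
            "assign_groups: excluded %d samples with no focal symbiont: %s",
            len(excluded), excluded[:5],
        )
    return groups


def classify_gene_state(
    breadth: float, mean_depth: float, group: str, thresholds: ClassificationThresholds
) -> str:
    """Classify one (gene, sample) as present / absent / unknown."""
    if group not in thresholds.depth_present_by_group:
        raise ParameterError(f"unknown group {group!r}; expected one of {GROUPS}")
    if not 0 <= breadth <= 1 or mean_depth < 0:
        raise ParameterError(f"invalid (breadth, depth) = ({breadth}, {mean_depth})")
    if breadth >= thresholds.breadth_present and (
        mean_depth >= thresholds.depth_present_by_group[group]
    ):
        return STATE_PRESENT
    if breadth < thresholds.breadth_absent and mean_depth < thresholds.depth_absent:
        return STATE_ABSENT
    return STATE_UNKNOWN


def classify_states(
    coverage: pd.DataFrame,
    groups: Mapping[str, str],
    thresholds: ClassificationThresholds | None = None,
    depth_column: str = "mean_depth",
) -> pd.DataFrame:
    """Genes x samples state matrix from a long-form coverage table.

    ``coverage`` needs sample_id, gene_id, breadth and the chosen depth
    column (raw ``mean_depth`` by default; ``normalized_depth`` as the
    configurable override).  Samples absent from ``groups`` are dropped.
    """
    thresholds = thresholds or ClassificationThresholds()
    cov = coverage[coverage["sample_id"].isin(groups)].copy()
    if cov.empty:
        raise ParameterError("no coverage rows for any grouped sample")
    group_arr = cov["sample_id"].map(groups)
    depth_thr = group_arr.map(thresholds.depth_present_by_group).to_numpy(dtype=float)
    breadth = cov["breadth"].to_numpy(dtype=float)
    depth = cov[depth_column].to_numpy(dtype=float)
    present = (breadth >= thresholds.breadth_present) & (depth >= depth_thr)
    absent = (breadth < thresholds.breadth_absent) & (depth < thresholds.depth_absent)
    cov["state"] = np.select([present, absent], [STATE_PRESENT, STATE_ABSENT], STATE_UNKNOWN)
    states = cov.pivot(index="gene_id", columns="sample_id", values="state")
    if states.isna().any().any():
        raise ParameterError("coverage table is not complete over genes x samples")
    return states


def gene_contingency(
    states: pd.DataFrame, groups: Mapping[str, str], gene_id: str
) -> tuple[int, int, int, int]:
    """(a, b, c, d): present/absent counts in group A (luna) and B (lotti).

    Unknown cells contribute to no margin.
    """
    if gene_id not in states.index:
        raise ParameterError(f"gene {gene_id!r} not in state matrix")
    row = states.loc[gene_id]
    a = b = c = d = 0
    for sample, state in row.items():
        g = groups.get(sample)
        if state == STATE_PRESENT:
            if g == GROUP_LUNA:
                a += 1
            elif g == GROUP_LOTTI:
                c += 1
        elif state == STATE_ABSENT:
            if g == GROUP_LUNA:
                b += 1
            elif g == GROUP_LOTTI:
                d += 1
    return a, b, c, d


@lru_cache(maxsize=200_000)
def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact p-value and odds ratio of a 2x2 table.

    Enumeration over all tables with the observed margins in exact integer
    arithmetic.  Returns (p, odds_ratio); the odds ratio (a*d)/(b*c) is
    ``inf`` when b*c = 0 with a*d > 0 and NaN when both products are 0.
    A zero margin makes the table untestable: p = 1, odds NaN.
    """
    if min(a, b, c, d) < 0:
        raise ParameterError("contingency counts must be nonnegative")
    if a * d > 0 and b * c == 0:
        odds = math.inf
    elif a * d == 0 and b * c == 0:
        odds = math.nan
    else:
        odds = (a * d) / (b * c)
    r1, r2 = a + b, c + d
    k = a + c  # first-column margin
    n = r1 + r2
    if r1 == 0 or r2 == 0 or k == 0 or k == n:
        return 1.0, odds
    observed = math.comb(r1, a) * math.comb(r2, c)
    numerator = 0
    for i in range(max(0, k - r2), min(k, r1) + 1):
        w = math.comb(r1, i) * math.comb(r2, k - i)
        if w <= observed:
            numerator += w
    return numerator / math.comb(n, k), odds


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_presence(
    states: pd.DataFrame,
    groups: Mapping[str, str],
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene differential presence between symbiont groups.

    Genes with an empty present+absent margin in either group are
    *untestable*, excluded before BH (they do not count toward m), and
    reported with q = NaN.  A testable gene is called A_specific when
    q < alpha and its present-fraction is higher among luna-dominant
    samples, symmetrically B_specific.  Output is sorted by q then gene_id.
    """
    present_groups = set(groups.values())
    if GROUP_LUNA not in present_groups or GROUP_LOTTI not in present_groups:
        raise ParameterError(
            "differential_presence requires samples in both symbiont groups"
        )
    sample_group = pd.Series({s: g for s, g in groups.items() if s in states.columns})
    luna_cols = sample_group[sample_group == GROUP_LUNA].index
    lotti_cols = sample_group[sample_group == GROUP_LOTTI].index
    if len(luna_cols) == 0 or len(lotti_cols) == 0:
        raise ParameterError("state matrix lacks samples from one group")

    sub = states[list(luna_cols) + list(lotti_cols)]
    a = (sub[luna_cols] == STATE_PRESENT).sum(axis=1).to_numpy()
    b = (sub[luna_cols] == STATE_ABSENT).sum(axis=1).to_numpy()
    c = (sub[lotti_cols] == STATE_PRESENT).sum(axis=1).to_numpy()
    d = (sub[lotti_cols] == STATE_ABSENT).sum(axis=1).to_numpy()
    n_unknown = len(luna_cols) + len(lotti_cols) - (a + b + c + d)

    results = pd.DataFrame(
        {"gene_id": states.index, "a": a, "b": b, "c": c, "d": d, "n_unknown": n_unknown}
    )
    testable = (a + b > 0) & (c + d > 0)
    p_odds = [
        fisher_exact_two_sided(int(ai), int(bi), int(ci), int(di))
        for ai, bi, ci, di in zip(a, b, c, d)
    ]
    results["odds_ratio"] = [o for _, o in p_odds]
    results["p_value"] = [p for p, _ in p_odds]
    results.loc[~testable, "p_value"] = 1.0

    q = np.full(len(results), np.nan)
    if testable.any():
        q[testable] = bh_fdr(results.loc[testable, "p_value"])
    results["q_value"] = q

    with np.errstate(invalid="ignore", divide="ignore"):
        frac_a = np.where(a + b > 0, a / np.maximum(a + b, 1), np.nan)
        frac_b = np.where(c + d > 0, c / np.maximum(c + d, 1), np.nan)
    call = np.full(len(results), CALL_NS, dtype=object)
    sig = testable & (q < fdr_alpha)
    call[sig & (frac_a > frac_b)] = CALL_A
    call[sig & (frac_b > frac_a)] = CALL_B
    call[~testable] = CALL_UNTESTABLE
    results["call"] = call

    n_untestable = int((~testable).sum())
    if n_untestable:
        logger.info(
            "differential_presence: %d untestable genes excluded from FDR (m=%d)",
            n_untestable, int(testable.sum()),
        )
    return results.sort_values(
        ["q_value", "gene_id"], na_position="last"
    ).reset_index(drop=True)


def write_diff_presence(
    results: pd.DataFrame,
    out_path,
    thresholds: ClassificationThresholds | None = None,
    fdr_alpha: float = 0.05,
) -> None:
    """Write diff_presence.tsv plus a run-metadata block alongside."""
    results.to_csv(out_path, sep="\t", index=False, float_format="%.6g", na_rep=".")
    thresholds = thresholds or ClassificationThresholds()
    meta_path = str(out_path).rsplit(".", 1)[0] + ".meta.txt"
    m = int((results["call"] != CALL_UNTESTABLE).sum())
    with open(meta_path, "w") as fh:
        fh.write(f"breadth_present\t{thresholds.breadth_present}\n")
        for g, v in sorted(thresholds.depth_present_by_group.items()):
            fh.write(f"depth_present[{g}]\t{v}\n")
        fh.write(f"breadth_absent\t{thresholds.breadth_absent}\n")
        fh.write(f"depth_absent\t{thresholds.depth_absent}\n")
        fh.write(f"fdr_alpha\t{fdr_alpha}\n")
        fh.write(f"n_tests_m\t{m}\n")
        fh.write(f"n_untestable\t{len(results) - m}\n")
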