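"""Per-ICD-code significance testing against the Global Distribution.

For each sex × age stratum, test results are grouped by each ICD-10 category
code they carry and every group with more than five members is tested
two-sidedly against the stratum's Global Distribution (GD): Welch's t-test
when both samples look Gaussian (Shapiro-Wilk), Mann-Whitney-U otherwise.
P-values are converted to Storey-Tibshirani q-values to control the false
discovery rate across the many codes of a slice.  The Differential
Distribution (DD) is the GD with every result that carries at least one
significant code removed.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import Stratum, TestResult

logger = logging.getLogger("ddri")

T_TEST = "t_test"
MANN_WHITNEY = "mann_whitney"

#: largest combined sample size for which the Mann-Whitney p-value is
#: computed by exact enumeration of rank assignments (C(16,8) = 12870)
EXACT_MWU_LIMIT = 16

#: Shapiro-Wilk is applied to at most this many points; larger samples are
#: subsampled (seeded) before testing
SHAPIRO_MAX_N = 5000

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.95, 0.05), 2)


@dataclass(frozen=True)
class DiagnosisRow:
    """One line of the per-slice diagnosis table."""

    code_or_cluster: str
    n: int
    mean: float
    sd: float
    p_value: float
    q_value: float
    test_used: str
    significant: bool
    member_codes: tuple[str, ...] = ()


@dataclass
class DiagnosisTable:
    """Per-code (or per-cluster) significance table for one stratum."""

    stratum: Stratum
    rows: list[DiagnosisRow] = field(default_factory=list)
    pi0: float = 1.0
    alpha: float = 0.05

    @property
    def significant_codes(self) -> set[str]:
        out: set[str] = set()
        for row in self.rows:
            if row.significant:
                out.update(row.member_codes or (row.code_or_cluster,))
        return out

    def to_frame(self) -> pd.DataFrame:
        s = self.stratum
        return pd.DataFrame(
            [
                {
                    "stratum_sex": s.sex,
                    "stratum_age_lo": s.age_lo,
                    "stratum_age_hi": s.age_hi,
                    "code": r.code_or_cluster,
                    "n": r.n,
                    "mean": r.mean,
                    "sd": r.sd,
                    "p_value": r.p_value,
                    "q_value": r.q_value,
                    "test_used": r.test_used,
                    "significant": r.significant,
                    "member_codes": "|".join(r.member_codes),
                }
                for r in self.rows
            ]
        )


@dataclass
class DifferentialDistribution:
    """The GD of a stratum after removal of significantly differing code groups."""

    stratum: Stratum
    removed_codes: set[str]
    dd_values: np.ndarray
    removed_results: list[TestResult]

    @property
    def removed_count(self) -> int:
        return len(self.removed_results)

    @property
    def removal_fraction(self) -> float:
        n = len(self.stratum.results)
        return self.removed_count / n if n else 0.0

    def manifest_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.removed_results:
            trig = [c for c in r.codes if c in self.removed_codes]
            rows.append(
                {
                    "case_id": r.case_id,
                    "value": r.value,
                    "codes": "|".join(r.codes),
                    "triggering_codes": "|".join(trig),
                }
            )
        return pd.DataFrame(rows, columns=["case_id", "value", "codes", "triggering_codes"])


# ---------------------------------------------------------------------------
# grouping


def group_by_code(stratum: Stratum) -> dict[str, np.ndarray]:
    """Group values by each individual ICD-10 code mentioned on a result.

    A result carrying k codes contributes its value to k groups; uncoded
    results appear in no group but remain part of the GD.
    """
    groups: dict[str, list[float]] = {}
    for r in stratum.results:
        for c in r.codes:
            groups.setdefault(c, []).append(r.value)
    return {c: np.asarray(v, dtype=float) for c, v in sorted(groups.items())}


# ---------------------------------------------------------------------------
# test selection and execution


def _shapiro_p(x: np.ndarray, rng: np.random.Generator) -> float:
    if x.size > SHAPIRO_MAX_N:
        x = rng.choice(x, size=SHAPIRO_MAX_N, replace=False)
    if np.ptp(x) == 0:
        return 0.0  # constant sample: normality untestable, treat as failed
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(x).pvalue)


def choose_test(
    group_values: np.ndarray,
    gd_values: np.ndarray,
    normality_alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    _gd_normal_p: float | None = None,
) -> str:
    """Pick Welch's t-test iff both samples pass Shapiro-Wilk normality.

    Degenerate (zero-variance) samples fail normality by definition and fall
    back to Mann-Whitney.  ``_gd_normal_p`` lets callers reuse one GD
    normality check across many groups of the same stratum.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    group_values = np.asarray(group_values, float)
    gd_values = np.asarray(gd_values, float)
    if group_values.size < 3 or np.ptp(group_values) == 0:
        return MANN_WHITNEY
    if _shapiro_p(group_values, rng) <= normality_alpha:
        return MANN_WHITNEY
    gd_p = _gd_normal_p if _gd_normal_p is not None else _shapiro_p(gd_values, rng)
    return T_TEST if gd_p > normality_alpha else MANN_WHITNEY


def _midrank_u(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U statistic of x (midranks for ties)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = x.size
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided Mann-Whitney p by enumeration of rank assignments.

    Enumerates all C(n1+n2, n1) assignments of the pooled (midranked) values
    and returns the permutation probability of a U statistic at least as far
    from its null mean n1*n2/2 as the observed one.  Handles ties naturally;
    coincides with the classical exact two-sided p when there are none.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    rank_sum_obs = ranks[:n1].sum()
    center = n1 * (n1 + n2 + 1) / 2.0  # null mean of the rank sum
    d_obs = abs(rank_sum_obs - center)
    total = math.comb(n1 + n2, n1)
    hits = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        if abs(ranks[list(idx)].sum() - center) >= d_obs - 1e-9:
            hits += 1
    return hits / total


def test_group(group_values: np.ndarray, gd_values: np.ndarray, test: str) -> float:
    """Two-sided p-value of a code group against the Global Distribution."""
    x = np.asarray(group_values, float)
    y = np.asarray(gd_values, float)
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0  # all values identical in both samples
    if test == T_TEST:
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            return 1.0 if x[0] == y[0] else 0.0
        p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
        return 1.0 if np.isnan(p) else p
    if test == MANN_WHITNEY:
        if x.size + y.size <= EXACT_MWU_LIMIT:
            return mann_whitney_exact_p(x, y)
        return float(stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)
    raise ValueError(f"unknown test {test!r}")


# ---------------------------------------------------------------------------
# Storey-Tibshirani FDR


def storey_qvalues(
    p_values, lambda_grid=None, pi0: float | None = None
) -> tuple[np.ndarray, float]:
    """Storey-Tibshirani q-values with smoother pi0 estimation.

    pi0(λ) = #{p > λ} / (m (1 − λ)) is evaluated on the λ grid, smoothed by a
    cubic least-squares fit, and read off at the largest λ; the estimate is
    clamped to (0, 1].  With fewer than 20 p-values the estimator is unstable
    and pi0 falls back to 1 (making the result the Benjamini-Hochberg
    adjustment).  ``pi0`` may be forced explicitly.

    Returns (q-values in input order, pi0).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("storey_qvalues requires at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if m < 20:
            logger.warning(
                "only %d p-values: pi0 estimation unstable, falling back to pi0=1", m
            )
            pi0 = 1.0
        else:
            lam = np.asarray(
                DEFAULT_LAMBDA_GRID if lambda_grid is None else lambda_grid, float
            )
            if lam.size < 4 or np.any(np.diff(lam) <= 0) or lam.min() < 0 or lam.max() >= 0.95 + 1e-12:
                raise ValueError("lambda_grid must be strictly increasing within [0, 0.95]")
            pi0_lam = np.array([(p > l).mean() / (1.0 - l) for l in lam])
            coef = np.polyfit(lam, pi0_lam, 3)
            pi0 = float(np.polyval(coef, lam.max()))
    pi0 = min(1.0, max(pi0, 1.0 / m))
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    q_sorted = pi0 * m * p_sorted / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, pi0


# ---------------------------------------------------------------------------
# diagnosis table and DD construction


def _build_table_from_groups(
    stratum: Stratum,
    groups: dict[str, np.ndarray],
    members: dict[str, tuple[str, ...]],
    min_n: int,
    alpha: float,
    normality_alpha: float,
    seed: int,
    compare_to_complement: bool,
    threshold_on: str,
) -> DiagnosisTable:
    """Shared table builder for per-code and per-cluster testing."""
    if threshold_on not in ("q", "p"):
        raise ValueError("threshold_on must be 'q' or 'p'")
    gd = stratum.gd_values
    rng = np.random.default_rng(seed)
    gd_normal_p = _shapiro_p(gd, rng) if gd.size >= 3 else 0.0

    labels, stats_rows, pvals = [], [], []
    for label in sorted(groups):
        g = groups[label]
        if g.size < min_n:
            continue
        if compare_to_complement:
            # remove one GD occurrence per group value (multiset difference)
            ref = _multiset_difference(gd, g)
            gd_p = None  # complement differs per group; re-test normality
        else:
            ref = gd
            gd_p = gd_normal_p
        test = choose_test(g, ref, normality_alpha, rng, _gd_normal_p=gd_p)
        p = test_group(g, ref, test)
        labels.append(label)
        stats_rows.append((g.size, float(np.mean(g)), float(np.std(g, ddof=1)), test))
        pvals.append(p)

    table = DiagnosisTable(stratum=stratum, alpha=alpha)
    if not labels:
        return table
    q, pi0 = storey_qvalues(pvals)
    table.pi0 = pi0
    for label, (n, mean, sd, test), p, qv in zip(labels, stats_rows, pvals, q):
        crit = qv if threshold_on == "q" else p
        table.rows.append(
            DiagnosisRow(
                code_or_cluster=label,
                n=n,
                mean=mean,
                sd=sd,
                p_value=float(p),
                q_value=float(qv),
                test_used=test,
                significant=bool(crit < alpha),
                member_codes=members[label],
            )
        )
    table.rows.sort(key=lambda r: (r.q_value, r.p_value, r.code_or_cluster))
    return table


def _multiset_difference(gd: np.ndarray, group: np.ndarray) -> np.ndarray:
    out = list(gd)
    counts: dict[float, int] = {}
    for v in group:
        counts[v] = counts.get(v, 0) + 1
    kept = []
    for v in out:
        if counts.get(v, 0) > 0:
            counts[v] -= 1
        else:
            kept.append(v)
    return np.asarray(kept, float)


def build_diagnosis_table(
    stratum: Stratum,
    min_n: int = 6,
    alpha: float = 0.05,
    normality_alpha: float = 0.05,
    seed: int = 0,
    compare_to_complement: bool = False,
    threshold_on: str = "q",
) -> DiagnosisTable:
    """Build the per-code significance table of a stratum.

    Only codes with group size >= ``min_n`` (default 6, i.e. more than five
    results) are tested; smaller groups are absent from the table but their
    results stay in the dataset.  Significance is judged on the q-value by
    default (``threshold_on='p'`` switches to raw p).
    """
    groups = group_by_code(stratum)
    members = {c: (c,) for c in groups}
    return _build_table_from_groups(
        stratum, groups, members, min_n, alpha, normality_alpha, seed,
        compare_to_complement, threshold_on,
    )


def differential_distribution(
    stratum: Stratum, table: DiagnosisTable, alpha: float | None = None
) -> DifferentialDistribution:
    """Remove every result carrying at least one significant code (any-code rule)."""
    if alpha is not None and alpha != table.alpha:
        # re-threshold the existing rows at a different alpha
        sig = {
            c
            for r in table.rows
            if r.q_value < alpha
            for c in (r.member_codes or (r.code_or_cluster,))
        }
    else:
        sig = table.significant_codes
    kept_vals, removed = [], []
    for r in stratum.results:
        if any(c in sig for c in r.codes):
            removed.append(r)
        else:
            kept_vals.append(r.value)
    return DifferentialDistribution(
        stratum=stratum,
        removed_codes=sig,
        dd_values=np.asarray(kept_vals, float),
        removed_results=removed,
    )
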