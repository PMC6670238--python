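"""Densities, per-retina aggregation, and the study's statistical toolkit.

Counts become densities (cells/mm²) per 350 × 350 μm segment; the 12 segments
of a retina are averaged into one value per eye, with per-eccentricity
regional means alongside. Group contrasts use the unpaired two-tailed t test
(equal-variance by default, Welch optional) or one-way ANOVA with Tukey's HSD;
severity–density association uses Spearman rank correlation; automated and
manual counts are compared with a paired t test on per-segment counts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import ECCENTRICITIES, AnimalRecord, CountTable

AGREEMENT_KEYS = ["animal_id", "eye", "timepoint", "quadrant", "eccentricity"]


def density(count: int, side_um: float) -> float:
    """Cells/mm² for ``count`` cells in a square segment of side ``side_um``."""
    if count < 0:
        raise ValueError("count must be non-negative")
    if not side_um > 0:
        raise ValueError("side_um must be positive")
    return count / (side_um / 1000.0) ** 2


@dataclass(frozen=True)
class RetinaSummary:
    """Twelve segment densities and their per-retina / per-region means."""

    animal_id: str
    eye: str
    densities: dict  # (quadrant, eccentricity) -> cells/mm²
    mean_density: float
    regional_means: dict  # eccentricity -> cells/mm²


def summarize_retina(
    counts: Mapping[tuple[int, str], int],
    side_um: float = 350.0,
    animal_id: str = "",
    eye: str = "left",
) -> RetinaSummary:
    """Average the 12 labeled segment counts into one retina summary.

    ``counts`` maps (quadrant, eccentricity) → cell count; exactly the 12
    labels {1..4} × {central, middle, peripheral} must be present.
    """
    expected = {(q, e) for q in (1, 2, 3, 4) for e in ECCENTRICITIES}
    got = set(counts)
    if got != expected:
        raise ValueError(
            f"need exactly one count per (quadrant, eccentricity); "
            f"missing {sorted(expected - got)}, unexpected {sorted(got - expected)}"
        )
    dens = {k: density(int(v), side_um) for k, v in counts.items()}
    regional = {
        e: float(np.mean([dens[(q, e)] for q in (1, 2, 3, 4)])) for e in ECCENTRICITIES
    }
    return RetinaSummary(
        animal_id=animal_id,
        eye=eye,
        densities=dens,
        mean_density=float(np.mean(list(dens.values()))),
        regional_means=regional,
    )


def summarize_count_table(table: CountTable, side_um: float = 350.0) -> list[RetinaSummary]:
    """One :class:`RetinaSummary` per (animal, eye, timepoint) in a table."""
    out = []
    for (animal, eye, _tp), grp in table.frame.groupby(["animal_id", "eye", "timepoint"]):
        counts = {
            (int(r.quadrant), r.eccentricity): int(r.count) for r in grp.itertuples()
        }
        out.append(summarize_retina(counts, side_um=side_um, animal_id=animal, eye=eye))
    return out


@dataclass(frozen=True)
class GroupComparison:
    group_labels: tuple[str, ...]
    means: tuple[float, ...]
    sems: tuple[float, ...]
    n_per_group: tuple[int, ...]
    statistic: float
    degrees_of_freedom: tuple[float, ...]
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if any(s < 0 for s in self.sems):
            raise ValueError("SEMs must be non-negative")


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0


def compare_two_groups(
    a: Sequence[float],
    b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
    equal_var: bool = True,
) -> GroupComparison:
    """Unpaired two-tailed t test with per-group mean ± SEM.

    Two identical zero-variance groups give t = 0, p = 1 by convention (no
    evidence of a difference); zero variance with different means gives p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        same = float(a.mean()) == float(b.mean())
        stat, p = (0.0, 1.0) if same else (math.inf, 0.0)
        df = len(a) + len(b) - 2.0
    else:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        stat, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return GroupComparison(
        group_labels=labels,
        means=(float(a.mean()), float(b.mean())),
        sems=(_sem(a), _sem(b)),
        n_per_group=(len(a), len(b)),
        statistic=stat,
        degrees_of_freedom=(df,),
        p_value=p,
    )


@dataclass(frozen=True)
class MultiGroupComparison:
    anova: GroupComparison
    tukey: pd.DataFrame  # columns: group1, group2, mean_diff, p_adj, lower, upper, reject


def compare_multi_groups(groups: Mapping[str, Sequence[float]]) -> MultiGroupComparison:
    """One-way ANOVA plus Tukey's HSD over ≥ 3 groups.

    Identical groups (zero between- and within-variance) give F = 0 and all
    Tukey p = 1 by the same convention as :func:`compare_two_groups`.
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 groups (use compare_two_groups for 2)")
    labels = tuple(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if any(len(x) < 2 for x in arrays):
        raise ValueError("each group needs at least two observations")
    pooled = np.concatenate(arrays)
    codes = np.concatenate([[g] * len(groups[g]) for g in labels])
    k, n = len(labels), len(pooled)
    if np.var(pooled) == 0:
        f_stat, p = 0.0, 1.0
        tk = pd.DataFrame(
            [
                {"group1": g1, "group2": g2, "mean_diff": 0.0, "p_adj": 1.0,
                 "lower": 0.0, "upper": 0.0, "reject": False}
                for g1, g2 in itertools.combinations(labels, 2)
            ]
        )
    else:
        res = sps.f_oneway(*arrays)
        f_stat, p = float(res.statistic), float(res.pvalue)
        hsd = pairwise_tukeyhsd(pooled, codes)
        tk = pd.DataFrame(
            hsd.summary().data[1:],
            columns=["group1", "group2", "mean_diff", "p_adj", "lower", "upper", "reject"],
        )
        tk["p_adj"] = hsd.pvalues
    anova = GroupComparison(
        group_labels=labels,
        means=tuple(float(x.mean()) for x in arrays),
        sems=tuple(_sem(x) for x in arrays),
        n_per_group=tuple(len(x) for x in arrays),
        statistic=f_stat,
        degrees_of_freedom=(float(k - 1), float(n - k)),
        p_value=p,
    )
    return MultiGroupComparison(anova=anova, tukey=tk)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n_pairs: int

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12):
            raise ValueError("rho outside [-1, 1]")


def _spearman_exact_p(x_ranks: np.ndarray, y_ranks: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rho (small cohorts).

    Enumerates all orderings of one rank vector; ties are carried through as
    average ranks. The null is exchangeability, so the two-sided p is the
    fraction of permutations with |rho| at least the observed |rho|.
    """
    n = len(x_ranks)
    xs = (x_ranks - x_ranks.mean()) / x_ranks.std()
    ys = y_ranks - y_ranks.mean()
    ys = ys / ys.std()
    perms = np.array(list(itertools.permutations(range(n))))
    rhos = (xs[None, :] * ys[perms]).mean(axis=1)
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def correlate_with_score(
    densities: Mapping[str, float],
    records: Sequence[AnimalRecord],
    exact_below: int = 10,
) -> CorrelationResult:
    """Spearman rank correlation between per-animal density and peak score.

    Animals are matched by id. Average ranks handle ties; the p-value uses
    the exact permutation distribution for cohorts smaller than
    ``exact_below`` and the t approximation otherwise.
    """
    by_id = {r.animal_id: r for r in records}
    unmatched = set(densities) - set(by_id)
    if unmatched:
        raise ValueError(f"animals without records: {sorted(unmatched)}")
    ids = sorted(densities)
    d = np.array([densities[i] for i in ids], dtype=float)
    s = np.array([by_id[i].peak_behavior_score for i in ids], dtype=float)
    if len(d) < 3:
        raise ValueError("need at least 3 matched (density, score) pairs")
    if np.all(s == s[0]) or np.all(d == d[0]):
        raise ValueError("degenerate ranks: one variable is constant, rho undefined")
    rho = float(sps.spearmanr(d, s).statistic)
    if len(d) < exact_below:
        p = _spearman_exact_p(sps.rankdata(d), sps.rankdata(s), rho)
    else:
        p = float(sps.spearmanr(d, s).pvalue)
    return CorrelationResult(rho=rho, p_value=p, n_pairs=len(d))


@dataclass(frozen=True)
class AgreementResult:
    """Automated-vs-manual count agreement on matched segments."""

    differences: pd.DataFrame  # per-key auto − manual
    mean_bias: float
    paired_p_value: float
    regional: pd.DataFrame  # per-eccentricity mean bias and paired p


def _paired_p(diff: np.ndarray) -> float:
    if np.allclose(diff, 0):
        return 1.0
    if len(diff) < 2 or np.std(diff, ddof=1) == 0:
        return 0.0
    return float(sps.ttest_rel(diff, np.zeros_like(diff)).pvalue)


def agreement_auto_vs_manual(auto: CountTable, manual: CountTable) -> AgreementResult:
    """Paired two-tailed t test of auto − manual per-segment counts.

    Tables must cover identical segment keys. Zero-variance differences fall
    back to the convention p = 1 when all differences vanish and p = 0 for a
    constant non-zero offset.
    """
    a = auto.frame.set_index(AGREEMENT_KEYS)
    m = manual.frame.set_index(AGREEMENT_KEYS)
    if set(a.index) != set(m.index):
        only_a = sorted(set(a.index) - set(m.index))[:3]
        only_m = sorted(set(m.index) - set(a.index))[:3]
        raise ValueError(f"segment keys differ (auto-only {only_a}, manual-only {only_m})")
    m = m.loc[a.index]
    diff = (a["count"] - m["count"]).astype(float)
    table = diff.rename("difference").reset_index()
    regional_rows = []
    for ecc, grp in table.groupby("eccentricity"):
        dd = grp["difference"].to_numpy()
        regional_rows.append(
            {"eccentricity": ecc, "n": len(dd), "mean_bias": float(dd.mean()),
             "paired_p_value": _paired_p(dd)}
        )
    return AgreementResult(
        differences=table,
        mean_bias=float(diff.mean()),
        paired_p_value=_paired_p(diff.to_numpy()),
        regional=pd.DataFrame(regional_rows),
    )


def comparison_report(result: GroupComparison) -> dict:
    """JSON-friendly rendering of a group comparison."""
    return {
        "groups": list(result.group_labels),
        "means": list(result.means),
        "sems": list(result.sems),
        "n": list(result.n_per_group),
        "statistic": result.statistic,
        "df": list(result.degrees_of_freedom),
        "p_value": result.p_value,
    }
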