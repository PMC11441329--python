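"""Nonparametric group statistics for the quantification tables.

The comparisons mirror how measurements of this kind are analyzed: single
factor, multiple-group comparisons with Kruskal–Wallis followed by Dunn's
post hoc tests (unit of analysis: synapses for STED peaks, images for
confocal ROI means, cells for somata and electrophysiology); within-cell
pharmacology series with Friedman plus Dunn; matched pairs with the
Wilcoxon signed-rank test (exact by enumeration at small n); and a
two-way repeated-measures (mixed) ANOVA with Dunnett's comparisons against
a control group for blocker series normalized to the pre-drug baseline.

Dunn's z statistics are computed on mean ranks with the tie-corrected
pooled variance; the multiplicity adjustment defaults to the
Bonferroni-type rule p_adj = min(1, m·p), exposed so alternates can be
swapped in.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, DegenerateInputError, ValidationError

ANALYSIS_UNITS = ("synapse", "image", "cell")


@dataclass
class GroupData:
    """Tidy one-observation-per-row container with an enforced unit of
    analysis; mixing units in one test is an error."""

    values: np.ndarray
    conditions: np.ndarray
    unit: str
    subjects: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.conditions = np.asarray(self.conditions)
        if self.unit not in ANALYSIS_UNITS:
            raise ValidationError(
                f"unit must be one of {ANALYSIS_UNITS}, got {self.unit!r}"
            )
        if self.values.shape != self.conditions.shape:
            raise ValidationError("values and conditions must align")
        if self.subjects is not None:
            self.subjects = np.asarray(self.subjects)
            if self.subjects.shape != self.values.shape:
                raise ValidationError("subjects must align with values")

    def groups(self) -> dict:
        return {
            c: self.values[self.conditions == c]
            for c in pd.unique(self.conditions)
        }

    @staticmethod
    def concat(parts):
        units = {p.unit for p in parts}
        if len(units) != 1:
            raise ValidationError(
                f"cannot mix units of analysis in one test: {sorted(units)}"
            )
        return GroupData(
            values=np.concatenate([p.values for p in parts]),
            conditions=np.concatenate([p.conditions for p in parts]),
            unit=parts[0].unit,
        )


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    df: float | None = None
    posthoc: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)


def _as_groups(groups) -> dict:
    if isinstance(groups, GroupData):
        return groups.groups()
    if isinstance(groups, dict):
        return {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    return {i: np.asarray(v, dtype=float) for i, v in enumerate(groups)}


# ---------------------------------------------------------------------------
# Kruskal–Wallis + Dunn
# ---------------------------------------------------------------------------


def kruskal_wallis(groups) -> TestResult:
    """Tie-corrected Kruskal–Wallis H with a chi-square (k−1) p-value."""
    g = _as_groups(groups)
    if len(g) < 2:
        raise ValidationError("need >= 2 groups")
    arrays = list(g.values())
    if any(len(a) < 1 for a in arrays):
        raise ValidationError("every group needs >= 1 observation")
    if sum(len(a) for a in arrays) < 3:
        raise ValidationError("need >= 3 observations in total")
    allv = np.concatenate(arrays)
    if np.all(allv == allv[0]):
        return TestResult("kruskal_wallis", 0.0, 1.0, df=len(g) - 1)
    h, p = sps.kruskal(*arrays)
    return TestResult("kruskal_wallis", float(h), float(p), df=len(g) - 1)


def _bonferroni(p: np.ndarray, m: int) -> np.ndarray:
    return np.minimum(1.0, p * m)


def dunn_posthoc(groups, reference=None, adjustment: str = "bonferroni") -> pd.DataFrame:
    """Dunn's rank-based multiple comparisons after Kruskal–Wallis.

    z = (R̄_i − R̄_j) / sqrt([N(N+1)/12 − Σ(t³−t)/(12(N−1))]·(1/n_i + 1/n_j))
    on the mean ranks of the pooled sample.  With ``reference`` set, only
    comparisons against that group are made; otherwise all pairs.  Adjusted
    p is min(1, m·p) under the default Bonferroni-type rule.
    """
    g = _as_groups(groups)
    labels = list(g)
    if reference is not None and reference not in g:
        raise ConfigurationError(f"reference group {reference!r} not found")
    if adjustment not in ("bonferroni", "none"):
        raise ConfigurationError(f"unknown adjustment {adjustment!r}")
    pooled = np.concatenate([g[l] for l in labels])
    n = {l: len(g[l]) for l in labels}
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_rank = {}
    start = 0
    for l in labels:
        mean_rank[l] = ranks[start : start + n[l]].mean()
        start += n[l]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (N - 1)) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term

    if reference is not None:
        pairs = [(reference, l) for l in labels if l != reference]
    else:
        pairs = list(itertools.combinations(labels, 2))
    rows = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / n[a] + 1.0 / n[b]))
        z = (mean_rank[b] - mean_rank[a]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z)) if se > 0 else 1.0
        rows.append({"group_a": a, "group_b": b, "z": z, "p_unadjusted": p})
    df = pd.DataFrame(rows)
    m = len(df)
    if adjustment == "bonferroni":
        df["p_adjusted"] = _bonferroni(df["p_unadjusted"].to_numpy(), m)
    else:
        df["p_adjusted"] = df["p_unadjusted"]
    return df


def kruskal_dunn(groups, reference=None, alpha: float = 0.05) -> TestResult:
    """Omnibus Kruskal–Wallis plus Dunn's comparisons (vs reference or all
    pairs) with rejection flags at ``alpha``."""
    res = kruskal_wallis(groups)
    post = dunn_posthoc(groups, reference=reference)
    post["reject"] = post["p_adjusted"] < alpha
    res.posthoc = post
    return res


# ---------------------------------------------------------------------------
# Friedman + Dunn
# ---------------------------------------------------------------------------


def friedman(blocks: np.ndarray) -> TestResult:
    """Friedman within-subject rank test on a complete (subjects ×
    conditions) block matrix, tie-corrected, chi-square p."""
    blocks = np.asarray(blocks, dtype=float)
    if blocks.ndim != 2:
        raise ValidationError("blocks must be subjects x conditions")
    if np.isnan(blocks).any():
        raise ValidationError("missing cell in block design (no imputation)")
    nsub, k = blocks.shape
    if k < 2 or nsub < 2:
        raise ValidationError("need >= 2 conditions and >= 2 subjects")
    ranks = np.vstack([sps.rankdata(row) for row in blocks])
    ssbn = np.sum(ranks.sum(axis=0) ** 2)
    ties = 0.0
    for row in blocks:
        _, t = np.unique(row, return_counts=True)
        ties += np.sum(t**3 - t)
    c = 1.0 - ties / (nsub * k * (k * k - 1))
    if c <= 0:  # every block fully tied
        return TestResult("friedman", 0.0, 1.0, df=k - 1)
    stat = (12.0 / (nsub * k * (k + 1)) * ssbn - 3.0 * nsub * (k + 1)) / c
    stat = max(0.0, float(stat))
    p = float(sps.chi2.sf(stat, k - 1))
    return TestResult("friedman", stat, p, df=k - 1)


def friedman_dunn(blocks, labels=None, reference=None, alpha: float = 0.05) -> TestResult:
    """Friedman omnibus plus Dunn's comparisons on within-block mean ranks:
    z = (R̄_i − R̄_j) / sqrt(k(k+1)/(6n))."""
    blocks = np.asarray(blocks, dtype=float)
    res = friedman(blocks)
    nsub, k = blocks.shape
    labels = list(labels) if labels is not None else list(range(k))
    ranks = np.vstack([sps.rankdata(row) for row in blocks])
    mean_rank = ranks.mean(axis=0)
    if reference is not None:
        if reference not in labels:
            raise ConfigurationError(f"reference {reference!r} not in labels")
        ref_i = labels.index(reference)
        pairs = [(ref_i, j) for j in range(k) if j != ref_i]
    else:
        pairs = list(itertools.combinations(range(k), 2))
    se = np.sqrt(k * (k + 1) / (6.0 * nsub))
    rows = []
    for a, b in pairs:
        z = (mean_rank[b] - mean_rank[a]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append(
            {"group_a": labels[a], "group_b": labels[b], "z": z, "p_unadjusted": p}
        )
    post = pd.DataFrame(rows)
    post["p_adjusted"] = _bonferroni(post["p_unadjusted"].to_numpy(), len(post))
    post["reject"] = post["p_adjusted"] < alpha
    res.posthoc = post
    return res


# ---------------------------------------------------------------------------
# Wilcoxon matched-pairs signed rank
# ---------------------------------------------------------------------------


def _signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Null distribution of W+ over all sign assignments, by polynomial
    convolution.  ``ranks2`` are ranks doubled to integers (ties give .5
    ranks).  Returns counts indexed by doubled rank-sum."""
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        new = counts.copy()
        new[r:] += counts[: len(counts) - r]
        counts = new
    return counts


def wilcoxon_signed_rank(x, y=None, exact_max_n: int = 12) -> TestResult:
    """Wilcoxon matched-pairs signed-rank test.

    Zero differences are discarded; |differences| are ranked with average
    ranks.  For n ≤ ``exact_max_n`` the two-sided p is exact over all 2ⁿ
    sign assignments (two-sided p = 2·min tail probability, capped at 1);
    above that a tie-corrected normal approximation with continuity
    correction is used.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateInputError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        ranks2 = np.round(ranks * 2).astype(int)
        counts = _signed_rank_distribution(ranks2)
        total = counts.sum()  # 2**n
        w2 = int(round(w_plus * 2))
        p_low = counts[: w2 + 1].sum() / total
        p_high = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
            tie_counts**3 - tie_counts
        ) / 48.0
        z = (w_plus - mean - np.sign(w_plus - mean) * 0.5) / np.sqrt(var)
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        method = "normal"
    return TestResult(
        "wilcoxon_signed_rank", w_plus, float(p), df=None, extra={"n": n, "method": method}
    )


# ---------------------------------------------------------------------------
# two-way repeated-measures (mixed) ANOVA + Dunnett
# ---------------------------------------------------------------------------


def rm_anova_two_way(
    data: pd.DataFrame,
    dv: str = "value",
    between: str = "group",
    within: str = "stage",
    subject: str = "subject",
    control=None,
    alpha: float = 0.05,
) -> TestResult:
    """Two-way repeated-measures ANOVA with one between-subject factor
    (e.g. genotype) and one within-subject factor (e.g. drug stage),
    backed by a vetted mixed-ANOVA routine, plus Dunnett's comparisons of
    every group against ``control`` on per-subject means.

    Requires a complete, balanced design (every subject measured at every
    within level)."""
    import pingouin as pg

    counts = data.groupby([subject, within], observed=True)[dv].count().unstack()
    if counts.isna().any().any() or not (counts == 1).all().all():
        raise ValidationError("design must be complete and balanced")
    per_group = data.groupby(between, observed=True)[subject].nunique()
    if per_group.nunique() != 1:
        raise ValidationError("design must be balanced across groups")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(
            data=data, dv=dv, within=within, subject=subject, between=between
        )
    inter = aov.loc[aov["Source"] == "Interaction"].iloc[0]
    p_col = "p-unc" if "p-unc" in aov.columns else "p_unc"
    res = TestResult(
        "rm_anova_two_way",
        statistic=float(inter["F"]),
        p_value=float(inter[p_col]),
        df=float(inter["DF1"]),
        extra={"anova_table": aov},
    )
    if control is not None:
        levels = [g for g in pd.unique(data[between]) if g != control]
        if control not in set(data[between]):
            raise ConfigurationError(f"control group {control!r} not found")
        subj_means = data.groupby([between, subject], observed=True)[dv].mean()
        treat = [subj_means[g].to_numpy() for g in levels]
        ctrl = subj_means[control].to_numpy()
        dres = sps.dunnett(*treat, control=ctrl)
        res.posthoc = pd.DataFrame(
            {
                "group_a": control,
                "group_b": levels,
                "statistic": np.atleast_1d(dres.statistic),
                "p_adjusted": np.atleast_1d(dres.pvalue),
            }
        )
        res.posthoc["reject"] = res.posthoc["p_adjusted"] < alpha
    return res


# ---------------------------------------------------------------------------
# normalized blocker series
# ---------------------------------------------------------------------------


def normalized_blocker_series(amplitudes: pd.DataFrame, before: str = "before") -> pd.DataFrame:
    """Per-cell response series as fractions of the pre-drug baseline.

    ``amplitudes`` has one row per cell and one column per stage; the
    ``before`` column becomes 1 everywhere.  Cells with a nonpositive
    baseline cannot be normalized and are excluded (with a warning)."""
    if before not in amplitudes.columns:
        raise ConfigurationError(f"no {before!r} column")
    ok = amplitudes[before] > 0
    if (~ok).any():
        warnings.warn(
            f"excluding {int((~ok).sum())} cell(s) with nonpositive baseline"
        )
    sub = amplitudes.loc[ok]
    return sub.div(sub[before], axis=0)
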