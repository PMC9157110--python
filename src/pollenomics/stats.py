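"""Condition statistics: one-way ANOVA, Tukey HSD, compact letter display.

Multi-condition comparisons use one-way ANOVA (α = 0.05) followed by post
hoc Tukey HSD (Tukey–Kramer for unbalanced groups); all pairwise results
are summarized as a compact letter display (CLD), where two conditions
share a letter iff they are not significantly different.  Two-condition
comparisons use an unpaired two-sample Student's t test (pooled variance;
Welch available) with star coding * P<0.05, ** P<0.01, *** P<0.005.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ALPHA_DEFAULT",
    "GroupStats",
    "one_way_anova",
    "tukey_hsd",
    "tukey_q",
    "compact_letter_display",
    "two_sample_t",
    "star_code",
    "fold_change",
    "group_stats",
    "group_stats_table",
]

ALPHA_DEFAULT = 0.05


def _as_groups(groups: Sequence) -> list:
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(a) < 2 for a in arrs):
        raise ValueError("each group needs n >= 2")
    return arrs


def one_way_anova(groups: Sequence) -> tuple[float, float]:
    """Classical one-way ANOVA; returns ``(F, p)``.

    With zero within-group variance the statistic is degenerate: equal
    means give ``(nan, nan)``, unequal means ``(inf, 0)``.
    """
    arrs = _as_groups(groups)
    n_tot = sum(len(a) for a in arrs)
    grand = np.concatenate(arrs).mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrs)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_b, df_w = len(arrs) - 1, n_tot - len(arrs)
    if ssw == 0.0:
        if ssb == 0.0:
            return float("nan"), float("nan")
        return float("inf"), 0.0
    f = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), p


def tukey_hsd(groups: Sequence) -> pd.DataFrame:
    """All-pairs Tukey HSD (Tukey–Kramer) adjusted p-values.

    For groups i, j the studentized-range statistic is
    ``q = |mean_i - mean_j| / sqrt(MSE/2 * (1/n_i + 1/n_j))`` and the
    adjusted p comes from the studentized-range distribution with k groups
    and N-k error degrees of freedom.  Returns a symmetric k×k DataFrame
    (diagonal 1).  A zero MSE is degenerate: p=0 for unequal means, 1 for
    equal means.
    """
    arrs = _as_groups(groups)
    k = len(arrs)
    n = np.array([len(a) for a in arrs])
    means = np.array([a.mean() for a in arrs])
    df_w = int(n.sum()) - k
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    mse = ssw / df_w

    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            diff = abs(means[i] - means[j])
            if mse == 0.0:
                pij = 1.0 if diff == 0.0 else 0.0
            else:
                se = np.sqrt(mse / 2.0 * (1.0 / n[i] + 1.0 / n[j]))
                q = diff / se
                pij = float(sps.studentized_range.sf(q, k, df_w))
            p[i, j] = p[j, i] = min(max(pij, 0.0), 1.0)
    return pd.DataFrame(p, index=range(k), columns=range(k))


def tukey_q(groups: Sequence, i: int, j: int) -> float:
    """The raw studentized-range statistic for one contrast (diagnostics)."""
    arrs = _as_groups(groups)
    k = len(arrs)
    n = [len(a) for a in arrs]
    df_w = sum(n) - k
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrs) / df_w
    se = np.sqrt(mse / 2.0 * (1.0 / n[i] + 1.0 / n[j]))
    return float(abs(arrs[i].mean() - arrs[j].mean()) / se)


def compact_letter_display(
    pairwise_p,
    alpha: float = ALPHA_DEFAULT,
    means: Optional[Sequence[float]] = None,
    labels: Optional[Sequence] = None,
) -> dict:
    """Insert-and-absorb compact letter display.

    Two groups share at least one letter iff their adjusted p > alpha.
    Letters are ordered a, b, c, … by descending group mean (ties broken by
    input order); without means, input order is used.  Returns
    ``{label: letter-string}``.
    """
    p = np.asarray(pairwise_p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("pairwise p must be a square matrix")
    if not np.allclose(p, p.T, equal_nan=True):
        raise ValueError("pairwise p matrix must be symmetric")
    k = p.shape[0]
    if labels is None:
        labels = (
            list(pairwise_p.index)
            if isinstance(pairwise_p, pd.DataFrame)
            else list(range(k))
        )

    # insert-and-absorb over significant pairs
    letters: list[frozenset] = [frozenset(range(k))]
    sig_pairs = [
        (i, j) for i in range(k) for j in range(i + 1, k) if p[i, j] <= alpha
    ]
    for i, j in sig_pairs:
        nxt: list[frozenset] = []
        for group_set in letters:
            if i in group_set and j in group_set:
                nxt.append(group_set - {i})
                nxt.append(group_set - {j})
            else:
                nxt.append(group_set)
        # absorb sets contained in another; drop duplicates/empties
        nxt = [s for s in set(nxt) if s]
        letters = [
            s for s in nxt if not any(s < t for t in nxt)
        ]

    # deterministic letter order: by the best-ranked group each set contains
    if means is not None:
        order = sorted(range(k), key=lambda g: (-float(means[g]), g))
    else:
        order = list(range(k))
    rank = {g: r for r, g in enumerate(order)}
    letters.sort(key=lambda s: (min(rank[g] for g in s), sorted(rank[g] for g in s)))

    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assignment: dict = {lab: "" for lab in labels}
    for idx, group_set in enumerate(letters):
        ch = alphabet[idx % len(alphabet)]
        for g in group_set:
            assignment[labels[g]] += ch
    return {lab: "".join(sorted(s)) for lab, s in assignment.items()}


def two_sample_t(
    a: Sequence[float],
    b: Sequence[float],
    variant: str = "student",
) -> tuple[float, float]:
    """Unpaired two-sample t test; returns ``(t, p)`` (two-sided).

    ``variant='student'`` pools the variances; ``'welch'`` does not.
    Zero pooled variance is degenerate: equal means give (0, 1), separated
    means (±inf, 0).
    """
    x, y = np.asarray(a, float), np.asarray(b, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0
    t, p = sps.ttest_ind(x, y, equal_var=(variant == "student"))
    return float(t), float(p)


def star_code(p: float) -> str:
    """Significance stars: * P<0.05, ** P<0.01, *** P<0.005."""
    if p < 0.005:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def fold_change(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Ratio of condition means, ``mean(a)/mean(b)``, with its log2.

    A zero denominator mean is undefined and returns ``(nan, nan)``.
    """
    ma, mb = float(np.mean(a)), float(np.mean(b))
    if mb <= 0:
        return float("nan"), float("nan")
    ratio = ma / mb
    return ratio, float(np.log2(ratio)) if ratio > 0 else float("nan")


@dataclass
class GroupStats:
    """ANOVA + Tukey + CLD summary for one feature across conditions."""

    labels: list
    means: list
    sds: list
    ns: list
    f_statistic: float
    anova_p: float
    pairwise_p: pd.DataFrame
    letters: dict
    alpha: float = ALPHA_DEFAULT
    flags: list = field(default_factory=list)


def group_stats(
    groups: Sequence,
    labels: Optional[Sequence] = None,
    alpha: float = ALPHA_DEFAULT,
) -> GroupStats:
    """Run the full ANOVA → Tukey → CLD chain on one feature."""
    arrs = _as_groups(groups)
    if labels is None:
        labels = list(range(len(arrs)))
    f, p_anova = one_way_anova(arrs)
    pw = tukey_hsd(arrs)
    pw.index = pw.columns = list(labels)
    means = [float(a.mean()) for a in arrs]
    letters = compact_letter_display(
        pw.to_numpy(), alpha=alpha, means=means, labels=list(labels)
    )
    flags = []
    if np.isnan(f):
        flags.append("anova_degenerate")
    return GroupStats(
        labels=list(labels),
        means=means,
        sds=[float(a.std(ddof=1)) for a in arrs],
        ns=[len(a) for a in arrs],
        f_statistic=f,
        anova_p=p_anova,
        pairwise_p=pw,
        letters=letters,
        alpha=alpha,
        flags=flags,
    )


def group_stats_table(
    values: pd.DataFrame,
    sheet: pd.DataFrame,
    feature_columns: Sequence[str],
    value_column: str,
    alpha: float = ALPHA_DEFAULT,
    min_n: int = 2,
) -> pd.DataFrame:
    """Per-feature ANOVA/Tukey/CLD over the conditions of a tidy table.

    ``values`` must carry ``sample_id`` plus the feature key columns and the
    value column; conditions come from the sample sheet.  Features whose
    groups are too small or contain NaN-only conditions are skipped.
    """
    merged = values.drop(columns=["condition"], errors="ignore").merge(
        sheet[["sample_id", "condition"]], on="sample_id", how="left"
    )
    records = []
    for key, grp in merged.groupby(list(feature_columns)):
        key = key if isinstance(key, tuple) else (key,)
        by_cond = {
            c: sub[value_column].dropna().to_numpy()
            for c, sub in grp.groupby("condition")
        }
        by_cond = {c: v for c, v in by_cond.items() if len(v) >= min_n}
        if len(by_cond) < 2:
            continue
        labels = sorted(by_cond)
        gs = group_stats([by_cond[c] for c in labels], labels, alpha=alpha)
        rec = dict(zip(feature_columns, key))
        rec.update(
            {
                "F": gs.f_statistic,
                "anova_p": gs.anova_p,
                "letters": ";".join(
                    f"{lab}={gs.letters[lab]}" for lab in labels
                ),
            }
        )
        for lab, m, sd, n in zip(labels, gs.means, gs.sds, gs.ns):
            rec[f"mean[{lab}]"] = m
        records.append(rec)
    return pd.DataFrame.from_records(records)
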