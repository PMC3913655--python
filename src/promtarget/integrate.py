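"""Combining direct (binding) and functional (knockdown) target sets.

A direct target is a replicate-consensus binding call; a functional
target is a gene whose expression responds to silencing. The collective
expression shift of the direct set is tested against all other measured
genes, the overlay table pairs each gene's baseline expression with its
knockdown response, and intersections with the expanded top-N response
lists give the direct-and-functional partition.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError
from .expression import ExpressionMatrix, top_n_lists

DEFAULT_EXPANDED_N = 2000


def arm_log_ratios(matrix: ExpressionMatrix) -> pd.Series:
    """Per-gene mean(silenced) - mean(control) in log2 units."""
    s = matrix.values[matrix.samples("silenced")].mean(axis=1)
    c = matrix.values[matrix.samples("control")].mean(axis=1)
    return (s - c).rename("log_ratio")


def set_shift_test(log_ratios: pd.Series, direct: set[str]) -> dict:
    """Does the direct set shift collectively relative to all other genes?

    Compares the knockdown log-ratios of direct genes against those of
    every other measured gene. The primary test is the two-sided Wilcoxon
    rank-sum; Welch's t and Kolmogorov-Smirnov are reported alongside so
    the conclusion does not hang on one statistic. Direction is the sign
    of the median difference.
    """
    measured_direct = [g for g in log_ratios.index if g in direct]
    rest = [g for g in log_ratios.index if g not in direct]
    if not measured_direct:
        raise ValidationError("direct set has no measured genes")
    if not rest:
        raise ValidationError("direct set must be a strict subset of measured genes")
    x = log_ratios.loc[measured_direct].to_numpy(float)
    y = log_ratios.loc[rest].to_numpy(float)
    u = stats.mannwhitneyu(x, y, alternative="two-sided")
    t = stats.ttest_ind(x, y, equal_var=False)
    ks = stats.ks_2samp(x, y)
    median_diff = float(np.median(x) - np.median(y))
    return {
        "rank_sum": {"statistic": float(u.statistic), "p_value": float(u.pvalue)},
        "welch_t": {"statistic": float(t.statistic), "p_value": float(t.pvalue)},
        "ks": {"statistic": float(ks.statistic), "p_value": float(ks.pvalue)},
        "median_difference": median_diff,
        "direction": "down" if median_diff < 0 else "up",
        "n_direct": len(x),
        "n_rest": len(y),
    }


def ma_overlay(
    baseline: pd.Series,
    log_ratios: pd.Series,
    direct: set[str],
    order_by_baseline: bool = True,
) -> pd.DataFrame:
    """Per-gene table for the binding/response overlay plot.

    A is the gene's baseline (untreated) expression — the control-arm
    mean serves as the untreated proxy when no separate baseline exists —
    or its rank when ``order_by_baseline``; M is the knockdown log-ratio;
    is_direct flags consensus binding targets.
    """
    genes = log_ratios.index
    if baseline.reindex(genes).isna().any():
        raise ValidationError("baseline missing for some measured genes")
    a = baseline.reindex(genes)
    if order_by_baseline:
        a = a.rank(method="first")
    return pd.DataFrame(
        {
            "A": a,
            "M": log_ratios,
            "is_direct": [g in direct for g in genes],
        },
        index=genes,
    )


def plot_ma(overlay: pd.DataFrame, path: str) -> None:
    """Render the overlay: all genes grey, direct targets highlighted."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    rest = overlay[~overlay["is_direct"]]
    hits = overlay[overlay["is_direct"]]
    ax.scatter(rest["A"], rest["M"], s=4, c="0.7", label="all genes")
    ax.scatter(hits["A"], hits["M"], s=12, c="crimson", label="direct targets")
    ax.axhline(0.0, lw=0.8, c="k")
    ax.set_xlabel("baseline expression (rank)")
    ax.set_ylabel("log2 change on silencing (M)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass
class TargetPartition:
    """Direct, functional and intersection gene sets with direction labels."""

    direct: set[str]
    functional: set[str]
    expanded_up: set[str]
    expanded_down: set[str]
    both_up: set[str]
    both_down: set[str]
    direct_and_functional: set[str]

    def venn_counts(self) -> dict[str, int]:
        return {
            "n_direct": len(self.direct),
            "n_functional": len(self.functional),
            "n_direct_and_functional": len(self.direct_and_functional),
            "n_expanded_up": len(self.expanded_up),
            "n_expanded_down": len(self.expanded_down),
            "n_both_up": len(self.both_up),
            "n_both_down": len(self.both_down),
            "n_both_total": len(self.both_up | self.both_down),
        }


def intersect_targets(
    direct: set[str],
    de: pd.DataFrame,
    n_expanded: int = DEFAULT_EXPANDED_N,
    significance_alpha: float = 0.01,
) -> TargetPartition:
    """Build the direct/functional partition.

    The strict functional set is the DE-significant genes (p below
    ``significance_alpha``); the relaxed analysis intersects the direct
    set with the top-``n_expanded`` up- and down-regulated lists. Both
    routes are kept because a strict intersection can legitimately be
    empty while the expanded one is not.
    """
    up, down = top_n_lists(de, n_expanded)
    functional = set(de.index[de["p_value"] < significance_alpha])
    measured_direct = direct & set(de.index)
    return TargetPartition(
        direct=set(direct),
        functional=functional,
        expanded_up=up,
        expanded_down=down,
        both_up=measured_direct & up,
        both_down=measured_direct & down,
        direct_and_functional=measured_direct & functional,
    )
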