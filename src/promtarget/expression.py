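"""Expression-array preprocessing, sample QC and differential expression.

The design is a small two-arm comparison: a handful of knockdown
(silenced) samples against matched controls. Columns are quantile
normalized, silenced samples are screened by correlation of their
control-referenced log-ratios, and per-gene differences are ranked with
a variance-moderated t statistic (or an exact label-permutation test).
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ConfigError, ValidationError

logger = logging.getLogger("promtarget")

DEFAULT_QC_THRESHOLD = 0.5
DEFAULT_QC_MARGIN = 0.2


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 intensities with silenced/control arm labels."""

    values: pd.DataFrame
    arms: pd.Series

    def __post_init__(self) -> None:
        self.arms = self.arms.loc[self.values.columns]
        bad = set(self.arms.unique()) - {"silenced", "control"}
        if bad:
            raise ValidationError(f"unknown arm labels {sorted(bad)}")
        if self.arms.isna().any():
            raise ValidationError("missing arm labels")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def samples(self, arm: str) -> list[str]:
        return list(self.arms.index[self.arms == arm])

    def drop_samples(self, sample_ids) -> "ExpressionMatrix":
        keep = [s for s in self.values.columns if s not in set(sample_ids)]
        return ExpressionMatrix(self.values[keep], self.arms.loc[keep])

    def log2_transform(self) -> "ExpressionMatrix":
        """For matrices on the linear scale; all downstream math is log2."""
        return ExpressionMatrix(np.log2(self.values), self.arms)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the mean order-statistic distribution.

    Each column's sorted values are replaced by the across-column mean of
    order statistics; tied values within a column receive the mean of the
    normalized values their positions would have received. Rank order
    within each column is preserved.
    """
    if values.shape[1] < 2:
        raise ConfigError("quantile normalization needs >= 2 samples")
    arr = values.to_numpy(float)
    mean_sorted = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        order = np.argsort(arr[:, j], kind="mergesort")
        col = np.empty(arr.shape[0])
        col[order] = mean_sorted
        # average within exact-tie groups
        col = pd.Series(col).groupby(pd.Series(arr[:, j]), sort=False).transform("mean").to_numpy()
        out[:, j] = col
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def control_referenced_log_ratios(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene log-ratios of each silenced sample versus the control mean."""
    controls = matrix.samples("control")
    silenced = matrix.samples("silenced")
    if not controls or not silenced:
        raise ValidationError("both arms must be present")
    ref = matrix.values[controls].mean(axis=1)
    return matrix.values[silenced].sub(ref, axis=0)


@dataclass
class QCResult:
    """Outcome of correlation-based silenced-sample screening."""

    correlations: pd.DataFrame
    mean_pairwise: pd.Series
    flagged: list[str] = field(default_factory=list)
    log: list[str] = field(default_factory=list)


def qc_correlations(
    matrix: ExpressionMatrix,
    threshold: float = DEFAULT_QC_THRESHOLD,
    margin: float = DEFAULT_QC_MARGIN,
) -> QCResult:
    """Flag discordant silenced samples by pairwise log-ratio correlation.

    Each silenced sample's control-referenced log-ratios are correlated
    with those of its peers. The sample with the lowest mean pairwise
    correlation is flagged when that mean falls below ``threshold``, or
    when it trails the arm mean by more than ``margin``; flagging repeats
    on the remaining samples until no sample qualifies. Flagged samples
    are meant to be excluded from differential expression (with a logged
    record), mirroring the visual pairs-plot screening such experiments
    use.
    """
    ratios = control_referenced_log_ratios(matrix)
    corr_full = ratios.corr()
    active = list(ratios.columns)
    flagged: list[str] = []
    log: list[str] = []
    mean_pairwise = pd.Series(dtype=float)
    while len(active) >= 2:
        corr = corr_full.loc[active, active]
        n = len(active)
        means = (corr.sum(axis=1) - 1.0) / (n - 1)
        mean_pairwise = means.combine_first(mean_pairwise) if not mean_pairwise.empty else means
        mean_pairwise.loc[means.index] = means
        worst = means.sort_values(kind="mergesort").index[0]
        arm_mean = float(means.mean())
        if means[worst] < threshold:
            reason = f"mean pairwise r={means[worst]:.3f} < threshold {threshold}"
        elif arm_mean - means[worst] > margin:
            reason = (
                f"mean pairwise r={means[worst]:.3f} trails arm mean "
                f"{arm_mean:.3f} by more than {margin}"
            )
        else:
            break
        flagged.append(str(worst))
        log.append(f"flagged {worst}: {reason}")
        logger.warning("QC flagged silenced sample %s (%s)", worst, reason)
        active.remove(worst)
    return QCResult(correlations=corr_full, mean_pairwise=mean_pairwise, flagged=flagged, log=log)


def _moderated_t(
    silenced: np.ndarray, control: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled-variance t with the per-gene SD shifted by the median SD.

    With two or three samples per arm the raw per-gene variance is an
    unstable denominator; adding the median pooled SD to every gene's SD
    shrinks small-variance genes toward the typical noise level and keeps
    zero-variance genes finite.
    """
    n1, n2 = silenced.shape[1], control.shape[1]
    diff = silenced.mean(axis=1) - control.mean(axis=1)
    ss1 = ((silenced - silenced.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss2 = ((control - control.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    pooled_sd = np.sqrt((ss1 + ss2) / df)
    s0 = float(np.median(pooled_sd))
    if s0 <= 0:
        s0 = 1e-12  # variance floor when most genes are constant
    tilde_sd = pooled_sd + s0
    t = diff / (tilde_sd * np.sqrt(1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return diff, t, p


def _permutation_p(silenced: np.ndarray, control: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact permutation of arm labels on the mean-difference statistic.

    All partitions of the samples into arms of the observed sizes are
    enumerated (10 at 2 vs 3); the p-value is the fraction of partitions
    with an absolute mean difference at least as large as observed,
    including the identity.
    """
    data = np.hstack([silenced, control])
    n1 = silenced.shape[1]
    n_total = data.shape[1]
    observed = silenced.mean(axis=1) - control.mean(axis=1)
    count = np.zeros(data.shape[0])
    n_perm = 0
    for combo in itertools.combinations(range(n_total), n1):
        mask = np.zeros(n_total, dtype=bool)
        mask[list(combo)] = True
        diff = data[:, mask].mean(axis=1) - data[:, ~mask].mean(axis=1)
        count += np.abs(diff) >= np.abs(observed) - 1e-12
        n_perm += 1
    return observed, observed, count / n_perm


def differential_expression(
    matrix: ExpressionMatrix,
    method: str = "modt",
    rank_by: str = "statistic",
) -> pd.DataFrame:
    """Per-gene silenced-vs-control comparison after QC.

    Returns a DataFrame indexed by gene with columns log_ratio (mean
    silenced minus mean control, log2), statistic, p_value, rank_up and
    rank_down. Ranks are permutations of 1..n_genes with deterministic
    ties (statistic, then gene id); rank_down=1 is the most down-regulated
    gene. ``rank_by`` may be "statistic" or "log_ratio".
    """
    silenced = matrix.samples("silenced")
    control = matrix.samples("control")
    if len(silenced) < 2 or len(control) < 2:
        raise ValidationError(
            f"differential expression needs >= 2 samples per arm "
            f"(have {len(silenced)} silenced, {len(control)} control)"
        )
    s = matrix.values[silenced].to_numpy(float)
    c = matrix.values[control].to_numpy(float)
    if method == "modt":
        diff, t, p = _moderated_t(s, c)
    elif method == "rank":
        diff, t, p = _permutation_p(s, c)
    else:
        raise ConfigError(f"unknown DE method {method!r}")
    df = pd.DataFrame(
        {"log_ratio": diff, "statistic": t, "p_value": p}, index=matrix.genes
    )
    key = df["statistic"] if rank_by == "statistic" else df["log_ratio"]
    if rank_by not in ("statistic", "log_ratio"):
        raise ConfigError(f"unknown ranking key {rank_by!r}")
    order_down = sorted(df.index, key=lambda g: (key[g], g))
    df["rank_down"] = pd.Series({g: i + 1 for i, g in enumerate(order_down)})
    order_up = sorted(df.index, key=lambda g: (-key[g], g))
    df["rank_up"] = pd.Series({g: i + 1 for i, g in enumerate(order_up)})
    return df


def top_n_lists(de: pd.DataFrame, n: int) -> tuple[set[str], set[str]]:
    """(up-regulated, down-regulated) gene sets of size n from the DE ranks."""
    if n > len(de):
        raise ConfigError(f"n={n} exceeds gene count {len(de)}")
    up = set(de.index[de["rank_up"] <= n])
    down = set(de.index[de["rank_down"] <= n])
    return up, down


def run_expression_stage(
    matrix: ExpressionMatrix,
    method: str = "modt",
    qc_threshold: float = DEFAULT_QC_THRESHOLD,
    qc_margin: float = DEFAULT_QC_MARGIN,
    normalize: bool = True,
) -> tuple[pd.DataFrame, QCResult, ExpressionMatrix]:
    """Quantile normalize, QC the silenced arm, and rank genes.

    Returns (DE table, QC result, post-QC matrix).
    """
    work = matrix
    if normalize:
        work = ExpressionMatrix(quantile_normalize(work.values), work.arms)
    qc = qc_correlations(work, threshold=qc_threshold, margin=qc_margin)
    if qc.flagged:
        work = work.drop_samples(qc.flagged)
    de = differential_expression(work, method=method)
    return de, qc, work
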