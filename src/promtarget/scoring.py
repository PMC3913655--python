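"""Replicate tiling-array scoring: normalization, windowed-median
smoothing, per-promoter Max400 scores and replicate-consensus calls.

The binding score of a promoter in one replicate is the maximum, over
its probes, of the median log-ratio within a 400-bp window centred on
each probe (the "Max400" score). Direct targets are promoters whose
score ranks in the top k in at least m of the replicates.
"""
from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ConfigError, ConsensusCall, Max400Record, PromoterModel, TilingProbe, ValidationError

DEFAULT_WINDOW = 400
DEFAULT_TOP_K = 500
DEFAULT_MIN_SUPPORT = 2


def global_median_normalize(
    values: pd.Series,
    control_ids: Iterable[str],
    fallback_all_probes: bool = False,
) -> pd.Series:
    """Subtract the median log-ratio of the control probes from every probe.

    After normalization the control-probe median is exactly 0 (even
    counts use the mean of the two middle values, the numpy convention).
    With no control probes present an error is raised unless
    ``fallback_all_probes`` explicitly authorizes using the all-probe
    median instead.
    """
    control_ids = [c for c in control_ids if c in values.index]
    if control_ids:
        shift = float(np.median(values.loc[control_ids].to_numpy()))
    elif fallback_all_probes:
        shift = float(np.median(values.to_numpy()))
    else:
        raise ValidationError(
            "no control probes found; pass fallback_all_probes=True to "
            "normalize on the all-probe median"
        )
    return values - shift


def _window_medians(midpoints: np.ndarray, values: np.ndarray, window: float) -> np.ndarray:
    """Median of values whose midpoint lies in [p - w/2, p + w/2], per probe.

    ``midpoints`` must be ascending (one chromosome). Boundary-inclusive;
    the probe itself is always a member of its own window.
    """
    half = window / 2.0
    left = np.searchsorted(midpoints, midpoints - half, side="left")
    right = np.searchsorted(midpoints, midpoints + half, side="right")
    out = np.empty_like(values, dtype=float)
    widths = right - left
    for w in np.unique(widths):
        sel = np.flatnonzero(widths == w)
        idx = left[sel, None] + np.arange(w)
        out[sel] = np.median(values[idx], axis=1)
    return out


def smooth_window_median(
    probes: Sequence[TilingProbe],
    values: Mapping[str, float] | pd.Series,
    window: float = DEFAULT_WINDOW,
) -> pd.Series:
    """Windowed-median smoothing along the genome, per chromosome.

    Probes must already be sorted by (chrom, midpoint); unsorted input is
    an error rather than silently reordered. Control probes take no part
    in smoothing. Windows never span chromosomes; an isolated probe
    smooths to its own value.
    """
    if window <= 0:
        raise ConfigError("window must be positive")
    values = pd.Series(values)
    work = [p for p in probes if not p.is_control]
    key = [(p.chrom, p.midpoint) for p in work]
    if key != sorted(key):
        raise ValidationError("probes must be sorted by (chrom, midpoint)")
    out = {}
    i = 0
    while i < len(work):
        j = i
        while j < len(work) and work[j].chrom == work[i].chrom:
            j += 1
        chunk = work[i:j]
        mids = np.array([p.midpoint for p in chunk])
        vals = np.array([values[p.probe_id] for p in chunk], dtype=float)
        sm = _window_medians(mids, vals, window)
        for p, v in zip(chunk, sm):
            out[p.probe_id] = v
        i = j
    return pd.Series(out, name="smoothed")


def max400_score(
    promoter: PromoterModel,
    probes: Sequence[TilingProbe],
    smoothed: Mapping[str, float] | pd.Series,
    replicate_id: str,
) -> Max400Record | None:
    """Highest smoothed value among the promoter's probes.

    Ties go to the probe nearest the TSS, then to the smallest genomic
    coordinate. A promoter with no probes yields None, not a zero score.
    """
    own = [p for p in probes if p.promoter_id == promoter.gene_id and not p.is_control]
    if not own:
        return None
    best = None
    best_key = None
    for p in own:
        v = float(smoothed[p.probe_id])
        key = (-v, abs(p.midpoint - promoter.tss), p.midpoint)
        if best_key is None or key < best_key:
            best, best_key = p, key
    assert best is not None
    return Max400Record(promoter.gene_id, replicate_id, float(smoothed[best.probe_id]), best.probe_id, best.midpoint)


def max400_table(
    promoters: Sequence[PromoterModel],
    probes: Sequence[TilingProbe],
    smoothed: Mapping[str, float] | pd.Series,
    replicate_id: str,
) -> list[Max400Record]:
    """Max400 records for every promoter with at least one probe."""
    by_promoter: dict[str, list[TilingProbe]] = {}
    for p in probes:
        if p.promoter_id is not None and not p.is_control:
            by_promoter.setdefault(p.promoter_id, []).append(p)
    records = []
    for prom in promoters:
        own = by_promoter.get(prom.gene_id, [])
        rec = max400_score(prom, own, smoothed, replicate_id)
        if rec is not None:
            records.append(rec)
    return records


def top_k(records: Sequence[Max400Record], k: int = DEFAULT_TOP_K) -> set[str]:
    """Promoter ids of the k highest Max400 scores in one replicate.

    Boundary ties break by (score desc, promoter_id asc) so the output is
    deterministic; if k exceeds the number of promoters, all are returned.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    ordered = sorted(records, key=lambda r: (-r.max400, r.promoter_id))
    return {r.promoter_id for r in ordered[:k]}


def consensus(
    top_sets: Sequence[set[str]],
    m: int = DEFAULT_MIN_SUPPORT,
) -> list[ConsensusCall]:
    """Membership counts over the union of per-replicate top-k sets.

    A promoter is a consensus member iff it appears in at least m of the
    n sets. Calls are reported for every promoter in the union, sorted by
    promoter id.
    """
    n = len(top_sets)
    if not 1 <= m <= n:
        raise ConfigError(f"min support m={m} must satisfy 1 <= m <= n={n}")
    counts: Counter[str] = Counter()
    for s in top_sets:
        counts.update(set(s))
    return [
        ConsensusCall(pid, c, c >= m)
        for pid, c in sorted(counts.items())
    ]


def consensus_members(calls: Iterable[ConsensusCall]) -> set[str]:
    return {c.promoter_id for c in calls if c.member}


def score_replicates(
    promoters: Sequence[PromoterModel],
    probes: Sequence[TilingProbe],
    replicates: Mapping[str, pd.Series],
    window: float = DEFAULT_WINDOW,
    k: int = DEFAULT_TOP_K,
    m: int = DEFAULT_MIN_SUPPORT,
    normalize: str = "control-median",
) -> tuple[dict[str, list[Max400Record]], dict[str, pd.Series], list[ConsensusCall]]:
    """End-to-end replicate scoring.

    For each replicate: optional control-median normalization, windowed
    median smoothing, Max400 per promoter; then top-k sets and the
    m-of-n consensus. Returns (records by replicate, smoothed values by
    replicate, consensus calls).
    """
    if normalize not in ("control-median", "none"):
        raise ConfigError(f"unknown normalize mode {normalize!r}")
    control_ids = [p.probe_id for p in probes if p.is_control]
    records: dict[str, list[Max400Record]] = {}
    smoothed_by_rep: dict[str, pd.Series] = {}
    for rep_id, values in replicates.items():
        if normalize == "control-median":
            values = global_median_normalize(values, control_ids)
        smoothed = smooth_window_median(probes, values, window)
        smoothed_by_rep[rep_id] = smoothed
        records[rep_id] = max400_table(promoters, probes, smoothed, rep_id)
    top_sets = [top_k(records[rep], k) for rep in records]
    calls = consensus(top_sets, m)
    return records, smoothed_by_rep, calls


def max400_frame(records: Mapping[str, list[Max400Record]]) -> pd.DataFrame:
    """Long-format DataFrame of Max400 records across replicates."""
    rows = [
        (r.promoter_id, r.replicate_id, r.max400, r.peak_probe_id, r.peak_position)
        for recs in records.values()
        for r in recs
    ]
    return pd.DataFrame(
        rows, columns=["promoter_id", "replicate_id", "max400", "peak_probe_id", "peak_position"]
    )
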