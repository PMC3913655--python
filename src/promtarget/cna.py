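"""Copy-number side analysis: thresholded state calling on binned probe
log-ratios, hierarchical sample clustering, and the commonly deleted
region (the interval covered by loss segments of the most samples).

The caller is deliberately minimal — bin medians against fixed log2
thresholds — because the downstream question is positional (which
region do losses share), not a segmentation benchmark.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .core import CNSegment, ConfigError, ValidationError

# log2-ratio thresholds: <= hom -> homozygous loss, <= het -> hemizygous
# loss, >= gain -> gain, otherwise neutral
DEFAULT_THRESHOLDS = (-1.2, -0.3, 0.3)
DEFAULT_BIN_SIZE = 10_000
LOSS_STATES = ("loss_hom", "loss_het")


def _state(median: float, thresholds: tuple[float, float, float]) -> str:
    hom, het, gain = thresholds
    if median <= hom:
        return "loss_hom"
    if median <= het:
        return "loss_het"
    if median >= gain:
        return "gain"
    return "neutral"


def call_states(
    probes: pd.DataFrame,
    sample_id: str,
    bin_size: int = DEFAULT_BIN_SIZE,
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
) -> list[CNSegment]:
    """Threshold-on-binned-median copy-number states for one sample.

    ``probes`` has columns (probe_id, chrom, pos, log2ratio) and must be
    sorted by (chrom, pos). Probes are grouped into fixed genomic bins,
    each bin's median log-ratio is mapped to a state, and runs of
    adjacent same-state bins merge into segments. An empty table yields
    an empty list.
    """
    hom, het, gain = thresholds
    if not hom < het < gain:
        raise ConfigError("thresholds must be ordered hom < het < gain")
    if bin_size <= 0:
        raise ConfigError("bin_size must be positive")
    if probes.empty:
        return []
    key = list(zip(probes["chrom"], probes["pos"]))
    if key != sorted(key):
        raise ValidationError("probes must be sorted by (chrom, pos)")
    segments: list[CNSegment] = []
    for chrom, group in probes.groupby("chrom", sort=False):
        bins = (group["pos"] // bin_size).astype(int)
        medians = group.groupby(bins)["log2ratio"].median()
        run_state, run_start, prev_bin = None, None, None
        for b, med in medians.items():
            st = _state(float(med), thresholds)
            contiguous = prev_bin is not None and b == prev_bin + 1
            if st != run_state or not contiguous:
                if run_state is not None:
                    segments.append(
                        CNSegment(sample_id, str(chrom), run_start, (prev_bin + 1) * bin_size, run_state)
                    )
                run_state, run_start = st, b * bin_size
            prev_bin = b
        segments.append(
            CNSegment(sample_id, str(chrom), run_start, (prev_bin + 1) * bin_size, run_state)
        )
    return segments


def state_matrix(
    samples: Mapping[str, pd.DataFrame],
    bin_size: int = DEFAULT_BIN_SIZE,
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Samples x bins matrix of integer state codes for clustering.

    Codes: loss_hom=-2, loss_het=-1, neutral=0, gain=1. Bins absent from
    a sample are neutral.
    """
    codes = {"loss_hom": -2, "loss_het": -1, "neutral": 0, "gain": 1}
    rows: dict[str, dict[tuple[str, int], int]] = {}
    for sid in sorted(samples):
        segs = call_states(samples[sid], sid, bin_size, thresholds)
        row: dict[tuple[str, int], int] = {}
        for seg in segs:
            for b in range(seg.start // bin_size, seg.end // bin_size):
                row[(seg.chrom, b)] = codes[seg.state]
        rows[sid] = row
    all_bins = sorted({b for row in rows.values() for b in row})
    mat = pd.DataFrame(
        [[rows[sid].get(b, 0) for b in all_bins] for sid in sorted(samples)],
        index=sorted(samples),
        columns=pd.MultiIndex.from_tuples(all_bins, names=["chrom", "bin"]),
    )
    return mat


def cluster_samples(states: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Average-linkage hierarchical clustering on Hamming distance.

    Returns (leaf-order sample ids, scipy linkage matrix). Sample rows
    are pre-sorted by id so equal-distance merges resolve
    deterministically.
    """
    if len(states) < 2:
        raise ConfigError("clustering needs >= 2 samples")
    states = states.sort_index()
    dist = pdist(states.to_numpy(), metric="hamming")
    z = linkage(dist, method="average")
    order = [states.index[i] for i in leaves_list(z)]
    return order, z


def commonly_deleted_region(
    segments: Sequence[CNSegment],
) -> tuple[str, int, int, int] | None:
    """Interval covered by loss segments of the most distinct samples.

    Sweep-line interval stabbing over the per-sample union of loss
    segments; ties on support resolve to the leftmost interval
    (chromosome name, then coordinate). Returns (chrom, start, end,
    support) or None when there are no losses.
    """
    losses = [s for s in segments if s.state in LOSS_STATES]
    if not losses:
        return None
    # union per (sample, chrom) so overlapping segments of one sample count once
    events: dict[str, list[tuple[int, int]]] = {}
    per_sample: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for s in losses:
        per_sample.setdefault((s.sample_id, s.chrom), []).append((s.start, s.end))
    for (sid, chrom), ivals in per_sample.items():
        ivals.sort()
        merged: list[list[int]] = []
        for a, b in ivals:
            if merged and a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        for a, b in merged:
            events.setdefault(chrom, []).append((a, +1))
            events.setdefault(chrom, []).append((b, -1))
    best: tuple[int, str, int, int] | None = None  # (support, chrom, start, end)
    for chrom in sorted(events):
        ev = sorted(events[chrom])
        depth = 0
        for i, (pos, delta) in enumerate(ev):
            depth += delta
            if i + 1 < len(ev) and ev[i + 1][0] > pos and depth > 0:
                if best is None or depth > best[0]:
                    best = (depth, chrom, pos, ev[i + 1][0])
    if best is None:
        return None
    support, chrom, start, end = best
    return chrom, start, end, support
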