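"""Synthetic inputs with the statistical structure the pipeline assumes.

Three things are emulated. (1) Replicated promoter tiling arrays:
promoters spanning -2200..+500 bp around each TSS, probes every 100 bp,
i.i.d. Gaussian background log-ratios plus, at a designated bound
subset, a Gaussian-shaped enrichment bump centred near -500 bp upstream
of the TSS, re-noised independently per replicate, with a per-array
global offset that control-median normalization should remove. (2)
Paired expression arrays where bound genes are down-regulated on
silencing (activator model), a sparse set of indirect responders moves
with random sign, and an optional corrupted silenced sample exercises
QC. (3) Copy-number samples whose deletions share a seeded core region.

Truth sets are returned alongside the data; no analysis stage reads
them — they exist for tests and calibration.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ConfigError, PromoterModel, TilingProbe
from .expression import ExpressionMatrix
from . import formats

_CHROMS = [f"chr{i}" for i in range(1, 23)]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the tiling design (100-bp spacing over -2200..+500,
    three replicates), a bound fraction of 108 promoters out of 2000, a
    binding bump of 1.0 log2 units (four background SDs) centred 500 bp
    upstream of the TSS, and a 1.0-log2 knockdown of bound genes in a
    3-vs-3 silenced/control expression comparison.
    """

    n_genes: int = 2000
    n_bound: int = 108
    probe_spacing: int = 100
    upstream: int = 2200
    downstream: int = 500
    n_replicates: int = 3
    noise_sd: float = 0.25
    peak_amplitude: float = 1.0
    peak_center_offset: int = -500
    peak_width_sd: float = 300.0
    probe_length_range: tuple[int, int] = (50, 64)
    n_control_probes: int = 200
    array_offset_sd: float = 0.1
    # expression arm
    n_silenced: int = 3
    n_control: int = 3
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    expr_noise_sd: float = 0.25
    knockdown_effect: float = 1.0
    indirect_fraction: float = 0.05
    bad_sample: bool = False
    bad_sample_noise_factor: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_bound <= self.n_genes:
            raise ConfigError("need 0 <= n_bound <= n_genes")
        if self.noise_sd <= 0 or self.expr_noise_sd <= 0:
            raise ConfigError("noise SDs must be positive")
        if min(self.n_genes, self.probe_spacing, self.n_replicates, self.n_silenced, self.n_control) < 1:
            raise ConfigError("counts must be positive")
        if self.probes_per_promoter < 3:
            raise ConfigError(
                "promoter span and probe spacing give fewer than 3 probes per promoter"
            )

    @property
    def probes_per_promoter(self) -> int:
        return (self.upstream + self.downstream) // self.probe_spacing


@dataclass
class TilingDataset:
    promoters: list[PromoterModel]
    probes: list[TilingProbe]
    replicates: dict[str, pd.Series]
    bound: set[str]


def _gene_layout(config: SimulationConfig) -> list[tuple[str, str, str, int]]:
    """(gene_id, chrom, strand, tss) with genes spread over 22 chromosomes.

    TSSs are spaced 50 kb apart so neighbouring promoters never share a
    smoothing window, and strands alternate to exercise the strand-aware
    transforms.
    """
    layout = []
    per_chrom: dict[str, int] = {c: 0 for c in _CHROMS}
    for i in range(config.n_genes):
        chrom = _CHROMS[i % len(_CHROMS)]
        slot = per_chrom[chrom]
        per_chrom[chrom] += 1
        tss = 10_000 + slot * 50_000
        strand = "+" if i % 2 == 0 else "-"
        layout.append((f"g{i:05d}", chrom, strand, tss))
    return layout


def simulate_tiling_arrays(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> TilingDataset:
    """Generate promoters, probes, per-replicate log-ratios and the truth set.

    Probe midpoints sit at TSS offsets -upstream, -upstream+spacing, ...
    (strand-aware). Background values are i.i.d. Normal(0, noise_sd); a
    bound promoter adds amplitude * exp(-(offset - center)^2 / (2 w^2))
    at each probe, identical across replicates, while the noise and the
    per-array global offset are redrawn per replicate. Deterministic for
    a fixed seed.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    layout = _gene_layout(config)
    bound = {gid for gid, *_ in [layout[i] for i in rng.choice(config.n_genes, size=config.n_bound, replace=False)]}

    promoters = [
        PromoterModel.from_tss(gid, chrom, strand, tss, config.upstream, config.downstream)
        for gid, chrom, strand, tss in layout
    ]
    n_probes = config.probes_per_promoter
    offsets = np.array([-config.upstream + i * config.probe_spacing for i in range(n_probes)])

    lo, hi = config.probe_length_range
    # even lengths keep probe midpoints on the designed offset grid
    lengths = rng.integers(lo // 2, hi // 2 + 1, size=(config.n_genes, n_probes)) * 2

    probes: list[TilingProbe] = []
    bump_by_probe: dict[str, float] = {}
    for g, prom in enumerate(promoters):
        sign = 1 if prom.strand == "+" else -1
        for i, off in enumerate(offsets):
            mid = prom.tss + sign * off
            length = int(lengths[g, i])
            start = mid - length // 2
            pid = f"{prom.gene_id}_p{i:02d}"
            probes.append(TilingProbe(pid, prom.chrom, start, start + length, prom.gene_id, False))
            if prom.gene_id in bound:
                bump_by_probe[pid] = config.peak_amplitude * float(
                    np.exp(-((off - config.peak_center_offset) ** 2) / (2 * config.peak_width_sd**2))
                )
    for i in range(config.n_control_probes):
        probes.append(TilingProbe(f"ctrl_{i:04d}", "chrUn", i * 200, i * 200 + 50, None, True))
    probes.sort(key=lambda p: (p.chrom, p.midpoint, p.probe_id))

    probe_ids = [p.probe_id for p in probes]
    bumps = np.array([bump_by_probe.get(pid, 0.0) for pid in probe_ids])
    replicates: dict[str, pd.Series] = {}
    for r in range(config.n_replicates):
        noise = rng.normal(0.0, config.noise_sd, size=len(probes))
        array_offset = rng.normal(0.0, config.array_offset_sd)
        replicates[f"rep{r + 1}"] = pd.Series(
            bumps + noise + array_offset, index=probe_ids, name="value"
        )
    return TilingDataset(promoters, probes, replicates, bound)


@dataclass
class ExpressionTruth:
    bound: set[str]
    indirect_effects: dict[str, float]
    bad_sample: str | None


def simulate_expression(
    config: SimulationConfig,
    bound: set[str],
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, ExpressionTruth]:
    """Silenced/control expression arrays under the activator model.

    Controls are Normal(mu_g, expr_noise_sd) around a gene baseline; the
    silenced arm subtracts ``knockdown_effect`` from bound genes and adds
    a random-sign effect of the same magnitude to an ``indirect_fraction``
    of unbound genes. With ``bad_sample`` set, the last silenced sample's
    noise is inflated by ``bad_sample_noise_factor`` for QC exercises.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    unknown = bound - set(genes)
    if unknown:
        raise ConfigError(f"truth set contains unknown genes, e.g. {sorted(unknown)[:3]}")
    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)

    effect = np.zeros(config.n_genes)
    bound_mask = np.array([g in bound for g in genes])
    effect[bound_mask] = -config.knockdown_effect
    unbound_idx = np.flatnonzero(~bound_mask)
    n_indirect = int(round(config.indirect_fraction * len(unbound_idx)))
    indirect_idx = rng.choice(unbound_idx, size=n_indirect, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_indirect)
    effect[indirect_idx] = signs * config.knockdown_effect
    indirect_effects = {genes[i]: float(effect[i]) for i in indirect_idx}

    columns: dict[str, np.ndarray] = {}
    arms: dict[str, str] = {}
    for c in range(config.n_control):
        sid = f"ctl{c + 1}"
        columns[sid] = mu + rng.normal(0.0, config.expr_noise_sd, size=config.n_genes)
        arms[sid] = "control"
    bad_id = None
    for s in range(config.n_silenced):
        sid = f"sil{s + 1}"
        sd = config.expr_noise_sd
        if config.bad_sample and s == config.n_silenced - 1:
            sd *= config.bad_sample_noise_factor
            bad_id = sid
        columns[sid] = mu + effect + rng.normal(0.0, sd, size=config.n_genes)
        arms[sid] = "silenced"
    values = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    matrix = ExpressionMatrix(values, pd.Series(arms, name="arm"))
    return matrix, ExpressionTruth(set(bound), indirect_effects, bad_id)


def simulate_cna(
    n_samples: int = 22,
    n_deleted: int = 10,
    core: tuple[str, int, int] = ("chr9", 21_600_000, 22_000_000),
    max_extension: int = 300_000,
    n_homozygous: int = 1,
    probe_spacing: int = 5_000,
    flank: int = 1_000_000,
    noise_sd: float = 0.2,
    rng: np.random.Generator | int | None = None,
) -> tuple[dict[str, pd.DataFrame], tuple[str, int, int], dict[str, tuple[int, int, str]]]:
    """Per-sample copy-number probe tables with deletions sharing a core.

    Each deleted sample's interval is the core extended on both sides by
    independent uniform amounts up to ``max_extension``; the first
    ``n_homozygous`` deleted samples lose both copies (-2 in log2), the
    rest one (-1). Returns (tables by sample, truth core, deletion truth
    per sample as (start, end, state)).
    """
    if core[1] >= core[2]:
        raise ConfigError("core interval must be non-empty")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    chrom, cs, ce = core
    positions = np.arange(cs - flank, ce + flank, probe_spacing)
    samples: dict[str, pd.DataFrame] = {}
    truth: dict[str, tuple[int, int, str]] = {}
    for k in range(n_samples):
        sid = f"pt{k + 1:02d}"
        values = rng.normal(0.0, noise_sd, size=len(positions))
        if k < n_deleted:
            left = cs - int(rng.integers(0, max_extension + 1))
            right = ce + int(rng.integers(0, max_extension + 1))
            shift = -2.0 if k < n_homozygous else -1.0
            state = "loss_hom" if k < n_homozygous else "loss_het"
            mask = (positions >= left) & (positions < right)
            values[mask] += shift
            truth[sid] = (left, right, state)
        samples[sid] = pd.DataFrame(
            {
                "probe_id": [f"{sid}_cn{j:05d}" for j in range(len(positions))],
                "chrom": chrom,
                "pos": positions,
                "log2ratio": values,
            }
        )
    return samples, core, truth


def write_dataset(dataset: TilingDataset, outdir: str | Path) -> None:
    """Write a tiling dataset in the package's on-disk dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    formats.write_promoters(dataset.promoters, outdir / "promoters.bed")
    formats.write_probe_table(dataset.probes, outdir / "probes.tsv")
    for rep_id, values in dataset.replicates.items():
        formats.write_log_ratios(values, outdir / f"logratio.{rep_id}.tsv")
    with open(outdir / "truth_bound.txt", "w") as handle:
        for gid in sorted(dataset.bound):
            handle.write(gid + "\n")
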