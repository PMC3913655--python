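# promtarget

Direct-target calling from replicated promoter tiling arrays
(ChIP-chip), with integration of knockdown expression data.

## The problem

A chimeric transcription factor — for example a leukemia-associated
fusion protein — binds gene promoters and rewires their expression. Two
complementary experiments identify its targets:

* **ChIP-chip on a promoter tiling array.** Chromatin immunoprecipitated
  with an antibody against the factor is hybridized against total input
  on an array tiling every promoter (−2200 bp to +500 bp around each
  TSS, probes of 50–75 bp every 100 bp). Each probe reports a
  log2(IP/input) ratio; promoters the factor occupies show a localized
  enrichment peak. Genes called this way are **direct** targets.
* **siRNA knockdown expression arrays.** Silencing the factor and
  comparing expression against control-transfected samples identifies
  genes whose expression depends on it — **functional** targets.

`promtarget` implements the full analysis connecting the two: per-probe
smoothing and per-promoter binding scores, replicate-consensus target
calling, TSS-relative peak localization, expression QC and differential
expression, and the intersection of direct and functional target sets.
A synthetic-data generator produces inputs with the assumed statistical
structure so every stage is testable without array downloads. A small
copy-number module (state calling, sample clustering, commonly deleted
region) covers the accompanying patient-sample analysis.

## The statistic at the core

For each replicate array, probe log-ratios are normalized by
subtracting the median of the control probes, then smoothed along the
genome with a windowed median: for probe *i* at position *p(i)*,

    s(i) = median{ x(j) : |p(j) − p(i)| ≤ w/2, same chromosome },  w = 400 bp

A promoter's binding score is the maximum smoothed value over its
probes (the **Max400** score), and its peak position is the probe
attaining it. Direct targets are promoters whose Max400 score ranks in
the top *k* (default 500) in at least *m* of *n* replicates (default 2
of 3). A peak call additionally requires ≥ *m* replicates to place the
peak within one probe spacing, and the collective expression response
of the direct set is tested against all other genes with a Wilcoxon
rank-sum (Welch t and Kolmogorov–Smirnov reported alongside).

## Worked example

```python
from promtarget import simulate, scoring, peaks, integrate
from promtarget.expression import run_expression_stage

cfg = simulate.SimulationConfig(seed=1)          # 2000 promoters, 108 bound
ds = simulate.simulate_tiling_arrays(cfg)
records, smoothed, calls = scoring.score_replicates(
    ds.promoters, ds.probes, ds.replicates, k=2 * cfg.n_bound)
direct = scoring.consensus_members(calls)
print(len(direct), len(direct & ds.bound))       # 125 108

peak_calls = peaks.call_peaks(ds.promoters, records, restrict_to=direct)
print(len(peak_calls))                           # 111

matrix, _ = simulate.simulate_expression(cfg, ds.bound)
de, qc, post = run_expression_stage(matrix)
res = integrate.set_shift_test(integrate.arm_log_ratios(post), direct)
print(res["direction"], res["rank_sum"]["p_value"])   # down 2.55e-58
```

Of the 2000 simulated promoters, the 2-of-3 consensus over per-replicate
top-216 lists recovers all 108 truly bound promoters (plus ~17 promoters
carried in by chance rank overlap between replicates); 111 of the calls
also agree on peak location across replicates. After silencing, the
direct set shows a collective down-shift in expression relative to all
other genes (rank-sum p ≈ 10⁻⁵⁸ here) — the signature of a
transcriptional activator.

The same stages are exposed as CLI subcommands (`promtarget simulate`,
`chip-score`, `peaks`, `expr`, `integrate`, `cna`); see `--help`.

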