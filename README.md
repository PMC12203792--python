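# oriskew

Analysis of DNA replication-origin maps and MCM2–7 licensing, built for
comparing SNS-seq origin profiles between a wild-type cell line and
ORC-subunit-knockout lines. Cells lacking individual ORC subunits still
replicate, which raises quantitative questions this package answers from peak
calls, annotation tracks, a timing profile and flow-cytometry event tables:
Where are the origins, and how much do the maps overlap? Which origins gain or
lose activity in *all* knockouts (CommonKO_up / CommonKO_down)? Do origin sets
differ in length, GC content, or GC/TA strand skew? Are they enriched in
genomic features beyond chance? Do they replicate earlier? And how fast is MCM
loaded onto chromatin in G1?

The statistical core, in the field's standard notation:

- **Origins** are peaks present in both replicates; peaks with inter-peak gaps
  below the genome-wide median are merged into initiation zones. Origin-set
  overlaps are counted with the minimum-count ("connectedPeaks = min")
  convention.
- **Differential origins**: RPM = count/library × 10⁶ on replicate-merged
  counts; up/down when RPM changes ≥ 1.5-fold vs wild type; direction shared by
  all three knockouts defines CommonKO_up / CommonKO_down.
- **Skews**: GC skew = (G−C)/(G+C), TA skew = (T−A)/(T+A) on the plus strand.
  Group comparisons are gated by Shapiro–Wilk: Welch t + Hedges' *g* when
  normal (n ≤ 5000), otherwise Wilcoxon rank-sum + Cliff's δ; families are
  Benjamini–Hochberg corrected.
- **Permutation colocalization**: query regions are randomized across the
  unmasked genome preserving lengths; fold = observed/mean(random),
  z = (obs − mean)/sd, empirical p with the +1 correction. Two query sets are
  compared through their per-permutation enrichment vectors by Welch's t.
- **Timing**: origin timing distributions are compared with the two-sample KS
  statistic and the 1-Wasserstein distance (area between ECDFs).
- **Ergodic rate analysis**: for an exponentially growing population, per-bin
  MCM loading rates are W_n = α(2−F)/f_n with α = ln2/T_doubling, F the
  G1-MCM⁺ fraction of all cells and f_n the occupancy of ten equal-width MCM
  bins; the mean rate averages the W_n.

A synthetic-study generator (`oriskew.synthetic`) produces every input with
known ground truth — shared and line-specific origins, planted fold changes,
planted skew and (ATCC)ₙ repeats, annotation enrichment, an early-timing shift
at origins, and an age-structured flow population loading MCM at a known rate —
so the whole pipeline is testable offline. See `docs/methods.md` for models,
conventions and limitations.

## Worked example

Run the full pipeline on a synthetic study (seed 7, 200 permutations):

```python
from oriskew.pipeline import RunConfig, run_pipeline
from oriskew.synthetic import SyntheticConfig

summary = run_pipeline(RunConfig(synthetic=SyntheticConfig(seed=7), n_perm=200))
```

Selected output, and what it means:

```text
origin_counts  {'WT': 204, 'ORC1KO': 202, 'ORC2KO': 203, 'ORC5KO': 200}
venn ORC2KO    {'overlap': 180, 'wt_only': 22, 'ORC2KO_only': 22}
zones          {'median_interpeak_bp': 6654.0, 'n_zones': 103}
common_ko      {'up': 20, 'down': 20}
perm WT        {'observed': 78, 'fold': 1.933, 'zscore': 7.151, 'p_greater': 0.005}
timing WT      {'ks': 0.27, 'ks_p': 0.1209, 'wasserstein': 0.5273}
ergodic        {'alpha_per_h': 0.0355, 'F': 0.5374, 'mean_rate_per_h': 0.6098,
                'expected_mean_rate_per_h': 0.6166}
gc_skew WT vs CommonKO_up: wilcoxon p=1.25e-11 cliffs_delta -0.919
```

Each line recovers the planted truth: the four lines share most of their ~200
origins with ~10% line-specific turnover (Venn row); all 20 planted 2-fold-up
and 20 planted down origins land in CommonKO_up/CommonKO_down; the annotation
track planted at 5× odds shows ~1.9-fold enrichment at z ≈ 7; planted-up
origins carry higher GC skew than wild-type origins (negative δ for WT vs up);
and the ergodic mean MCM loading rate (0.610 h⁻¹) matches the analytic value
implied by the configured cell cycle (0.617 h⁻¹) within ~1%.

The same stages are available as shell commands (`oriskew simulate`, `origins`,
`venn`, `zones`, `classify`, `props`, `compare`, `permtest`, `timing`, `era`,
`run`); `oriskew --help` lists them.

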