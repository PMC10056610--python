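# fibermir

miRNome–transcriptome analysis of human skeletal muscle with distinct
fiber-type composition.

Human skeletal muscle is a mixture of slow-twitch (type I, oxidative) and
fast-twitch (type II, glycolytic) fibers, and a biopsy's expression profile
is a weighted blend of the two fiber-type programs. `fibermir` implements a
complete, testable small-RNA / total-RNA integration workflow for
comparing athletes (or any two cohorts) with slow- versus fast-fiber
predominance:

- **isomiR quantification** — small-RNA reads are length-filtered
  (16–28 nt), assigned to mature miRNA references by exhaustive ungapped
  alignment over bounded 5′/3′ offsets, and classified into isomiR
  categories (canonical, 3′ trimming, 3′ extension, 5′ shift,
  polymorphic), with prevalence filters (mean count ≥ 10; major isoforms
  carrying > 10% of their miRNA's expression);
- **normalization** — a noise filter (mean ≤ 2 and ≥ 90% missing),
  trimmed-mean-of-M-values (TMM) factors, counts per million on effective
  library sizes, and group-mean CPM expression filters (> 10 CPM for
  miRNA, > 4 CPM for genes);
- **differential expression** — a two-group negative-binomial
  likelihood-ratio test with trend-shrunk method-of-moments dispersions,
  Benjamini–Hochberg FDR, and calls at FDR < 0.05 with |log2FC| > 1
  (miRNA) or |FC| > 1.5 (genes), fold changes oriented type2/type1
  (fast over slow);
- **integration** — Spearman correlations of miRtronic miRNAs with their
  host genes (miR-208b-3p→*MYH7*, miR-499a-5p→*MYH7B*, miR-501-3p→*CLCN5*,
  miR-185-5p→*TANGO2*) and of miRNAs with their experimentally validated
  targets (reporter assay + Western blot + qPCR), each with a two-sided
  t-approximation p (t = ρ·√((n−2)/(1−ρ²)), n−2 df) and a seeded
  1000-permutation p; strong pairs are |ρ| > 0.8 strict;
- **exploration** — PCA of non-scaled log2 CPM (genes pre-filtered by
  dropping the lowest 10% variance), cross-dataset abundance ranking by
  mean CPM, and deterministic report assembly;
- **synthetic data with ground truth** — mature-reference generation,
  isomiR-structured read simulation, and negative-binomial fiber-mixture
  count matrices in which each sample's expectation is
  `slow_fraction·E_slow + (1−slow_fraction)·E_fast`, with latent
  log-scale coupling between miRNAs and host/target genes, so every
  stage of the pipeline can be scored against known truth.

## Worked example

```python
import fibermir as fm
from fibermir.study_data import FIBER_COMPOSITION, TARGET_CORRELATIONS
from fibermir.integration import nearest_attainable_rho

# cohort fiber-type composition: five endurance vs five power athletes
by_group = {g: s["slow_pct"].to_numpy() for g, s in FIBER_COMPOSITION.groupby("group")}
stats, p = fm.group_stats(by_group)
for s in stats:
    print(f"{s.group}: slow fibers {s.mean:.1f} +/- {s.sd:.1f}% (range {s.range[0]}-{s.range[1]})")
print(f"Welch two-sided p = {p:.2e}")

# two-sided p for a reported host-gene correlation at n = 10
rho = nearest_attainable_rho(0.903, 10)   # de-round the printed coefficient
print(f"rho=0.903 (n=10): two-sided p = {fm.t_approx_p(rho, 10):.5f}")

# strong-pair calling on the reported miRNA-target coefficients
neg, pos = fm.strong_pairs(TARGET_CORRELATIONS["rho"])
print(f"strong target correlations: {int(neg.sum())} negative, {int(pos.sum())} positive")
```

prints

```
type1: slow fibers 68.4 +/- 5.0% (range 61.6-72.8)
type2: slow fibers 30.3 +/- 5.3% (range 22.1-35.4)
Welch two-sided p = 2.83e-06
rho=0.903 (n=10): two-sided p = 0.00034
strong target correlations: 11 negative, 18 positive
```

The endurance cohort carries twice the slow-fiber share of the power
cohort (68.4% vs 30.3%, Welch p ≪ 0.0001); the miR-208b-3p/*MYH7*
coupling is significant at p = 0.00034; and 11 of the 29 strong
miRNA–target correlations are negative, the direction expected of
repressive miRNA regulation.

A full synthetic run from reads to DE tables is available from the
command line:

```sh
fibermir simulate --out-dir sim --seed 3
fibermir de --counts sim/counts.tsv --meta sim/metadata.tsv --out de.tsv
```

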