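"""Bundled study-cohort measurements.

Small published summary tables from the ten-athlete skeletal-muscle
cohort the pipeline was designed around: per-participant fiber-type
percentages (immunohistochemistry of vastus lateralis biopsies) and
the reported miRNA-host-gene / miRNA-target Spearman correlation
coefficients at n = 10 samples.  They serve as desk-scale inputs for
the descriptive statistics, the two-sided p recomputation and the
strong-pair calling; every derived number is computed at run time by
the package's own operations.
"""

from __future__ import annotations

import pandas as pd

#: Per-participant muscle fiber composition: five endurance athletes
#: (type1, slow-twitch predominant) and five power athletes (type2,
#: fast-twitch predominant).  Percentages of slow and fast fibers.
FIBER_COMPOSITION = pd.DataFrame(
    [
        ("s059", "type1", 72.8, 30.8),
        ("s072", "type1", 61.6, 39.6),
        ("s090", "type1", 70.9, 35.4),
        ("s093", "type1", 64.4, 38.9),
        ("s110", "type1", 72.1, 30.0),
        ("s036", "type2", 27.9, 72.4),
        ("s042", "type2", 33.1, 69.6),
        ("s079", "type2", 22.1, 80.7),
        ("s088", "type2", 32.9, 69.3),
        ("s103", "type2", 35.4, 69.6),
    ],
    columns=["sample", "group", "slow_pct", "fast_pct"],
)

#: Number of samples underlying the reported correlations.
CORRELATION_N = 10

#: miRtronic miRNA / host-gene correlations: Spearman rho and the
#: reported two-sided p (string exactly as printed, "<0.001" included).
HOST_GENE_CORRELATIONS = pd.DataFrame(
    [
        ("miR-208b-3p", "MYH7", 0.903, "<0.001"),
        ("miR-499a-5p", "MYH7B", 0.855, "0.002"),
        ("miR-501-3p", "CLCN5", 0.564, "0.090"),
        ("miR-185-5p", "TANGO2", 0.442, "0.200"),
    ],
    columns=["mirna", "host_gene", "rho", "p_two_sided"],
)

#: miRNA / validated-target correlations that passed the |rho| > 0.8
#: screen, with the reported two-sided and permutation p-values.
TARGET_CORRELATIONS = pd.DataFrame(
    [
        ("miR-20a-5p", "FBXO31", -0.879, "0.00081", 0.005),
        ("miR-152-3p", "MAFB", -0.867, "0.00117", 0.005),
        ("miR-143-3p", "DNMT3A", -0.842, "0.00222", 0.004),
        ("miR-17-5p", "FBXO31", -0.842, "0.00222", 0.004),
        ("miR-208b-3p", "CDKN1A", -0.842, "0.00222", 0.005),
        ("miR-25-3p", "MTF1", -0.830, "0.00294", 0.005),
        ("miR-340-5p", "DNMT3A", -0.830, "0.00294", 0.005),
        ("miR-148a-3p", "RPS6KA5", -0.818, "0.00381", 0.001),
        ("miR-1-3p", "TAGLN2", -0.806, "0.00486", 0.005),
        ("miR-186-5p", "HOXA9", -0.806, "0.00486", 0.006),
        ("miR-499a-5p", "FOXO4", -0.806, "0.00486", 0.006),
        ("miR-126-3p", "BCL2", 0.806, "0.00486", 0.010),
        ("miR-126-3p", "CRK", 0.806, "0.00486", 0.009),
        ("miR-126-3p", "FOXO3", 0.806, "0.00486", 0.011),
        ("miR-185-5p", "HMGA1", 0.806, "0.00486", 0.008),
        ("miR-21-5p", "TP63", 0.806, "0.00486", 0.006),
        ("miR-22-3p", "ZFP91", 0.806, "0.00486", 0.006),
        ("miR-143-3p", "ITM2B", 0.818, "0.00381", 0.011),
        ("miR-195-5p", "CCND1", 0.818, "0.00381", 0.009),
        ("miR-98-5p", "CASP3", 0.830, "0.00294", 0.004),
        ("miR-126-3p", "KLF10", 0.842, "0.00222", 0.003),
        ("miR-210-3p", "ALDH5A1", 0.842, "0.00222", 0.004),
        ("miR-126-3p", "RHOU", 0.855, "0.00164", 0.003),
        ("miR-199a-5p", "CAV1", 0.867, "0.00117", 0.005),
        ("miR-27a-3p", "ZBTB10", 0.867, "0.00117", 0.001),
        ("miR-210-3p", "HIF3A", 0.879, "0.00081", 0.002),
        ("miR-30b-5p", "CAT", 0.879, "0.00081", 0.004),
        ("miR-499a-5p", "PDCD4", 0.891, "0.00054", 0.002),
        ("miR-30b-5p", "PDGFRB", 0.903, "0.00034", 0.001),
    ],
    columns=["mirna", "target_gene", "rho", "p_two_sided", "p_permutation"],
)
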