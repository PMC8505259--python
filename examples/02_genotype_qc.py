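"""Genotype and sample QC on a simulated cohort.

Applies the full QC ladder — MAF > 0.05 and exact Hardy-Weinberg p > 0.001
variant filters, LD pruning, PLINK-style PI_HAT relatedness exclusion
(threshold 0.185, patients kept over healthy controls), and PC1/PC2
ancestry-outlier removal (3 and 5 SDs) — and prints the survivor counts at
each stage.  The final principal components are the covariates used by the
association stage.

Note the large "related" exclusion count: with only ~100 independent LD
blocks in this toy panel, the PI_HAT estimator's noise floor sits near the
0.185 threshold, so many truly unrelated pairs are flagged.  This is a
property of the printed threshold at scaled-down marker counts (see
docs/methods.md); on realistic panels (~100k pruned markers) it vanishes.
"""

import polypgas as pg
from polypgas import gqc

cfg = pg.SimConfig(n_patients=500, n_controls=500, n_snps=2000, seed=11)
cohort = pg.simulate_phenotypes(pg.simulate_genotypes(cfg), cfg)

result = gqc.run_qc(cohort, gqc.QCParams(), seed=11)

print("stage counts (survivors after each QC stage):")
for stage, count in result.report.stage_counts.items():
    print(f"  {stage}: {count}")

vt = result.report.variant_table
print("variant failures:", vt.loc[~vt["pass"], "reason"].value_counts().to_dict())
st = result.report.sample_table
print("sample exclusions:",
      st["exclusion_reason"].value_counts().to_dict())
print("PC score matrix:", result.pcs.shape,
      "(10 PCs recomputed on the final sample set)")
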