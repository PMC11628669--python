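"""Treat the chromosome number as one extra locus and test whether it
surfaces as an environmental outlier.

Builds a small cohort whose 2n rides a temperature gradient, appends it
to a random SNP matrix, and scans loadings: the pseudo-locus should land
in the extreme tail and be assigned the temperature predictor.
"""

import numpy as np
import pandas as pd

from karyorda import (GenotypeMatrix, PredictorTable, SampleTable,
                      append_karyotype, assign_predictor, detect_outliers,
                      fit_rda, karyotype_status)

rng = np.random.default_rng(3)
n = 80
temp = np.linspace(-2, 2, n) + 0.1 * rng.normal(size=n)
two_n = np.clip(np.round(76 + 3 * temp + rng.normal(0, 1, n)), 69, 84)

snps = rng.integers(0, 3, size=(n, 60)).astype(np.int8)
genotypes = GenotypeMatrix(
    snps,
    pd.DataFrame({"locus_id": [f"L{j}" for j in range(60)],
                  "contig": "chr1", "position": np.arange(60) * 1000 + 1}),
    [f"S{i}" for i in range(n)])
samples = SampleTable(pd.DataFrame({
    "sample_id": genotypes.sample_ids, "population": "P1",
    "species": "C_laevigata", "lat": np.linspace(36, 44, n),
    "lon": -5.0, "two_n": two_n}))
predictors = PredictorTable(pd.DataFrame({
    "sample_id": genotypes.sample_ids,
    "TEMP": temp, "NOISE": rng.normal(size=n)}))

with_karyo = append_karyotype(genotypes, samples)  # standardized 2n column
model = fit_rda(with_karyo, predictors)
report = assign_predictor(detect_outliers(model, [1], tail=0.025),
                          with_karyo, predictors)
print(karyotype_status(report, with_karyo).summary())
# With random SNPs, only the karyotype tracks TEMP, so it dominates the
# first constrained axis and is retrieved as the outlier.
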