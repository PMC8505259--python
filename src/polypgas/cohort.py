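"""In-memory containers for genotype/phenotype cohorts.

Genotypes are stored sample-major as an ``int8`` matrix of alternate-allele
dosages (0/1/2) with ``-1`` marking a missing call.  Variant and sample
metadata live in plain :class:`pandas.DataFrame` tables so that downstream
code can use ordinary pandas idioms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

#: Required columns of the variant table, in order.
VARIANT_COLUMNS = ["chrom", "id", "pos", "a1", "a2"]

#: Columns always present in the sample table.
SAMPLE_CORE_COLUMNS = ["fid", "iid", "sex", "diagnosis"]


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort, for truth-recovery scoring.

    Attributes
    ----------
    variant_class : pandas.Series
        Per-variant label, one of ``{"polytox", "disease", "pleiotropic",
        "null"}``, indexed like the variant table.
    drug_liability : numpy.ndarray
        Per-sample shared drug-use liability (genetic + environmental part,
        excluding per-class noise).
    disease_liability : numpy.ndarray
        Per-sample disease liability (genetic part plus logistic noise).
    onsets : pandas.DataFrame
        Per-sample, per-drug-class onset label in
        ``{"never", "preadult", "adult"}`` (one column per class).
    """

    variant_class: pd.Series
    drug_liability: np.ndarray
    disease_liability: np.ndarray
    onsets: pd.DataFrame

    def planted_index(self, label: str) -> np.ndarray:
        """Positional indices of planted variants with the given class label."""
        return np.flatnonzero((self.variant_class == label).to_numpy())


@dataclass
class Cohort:
    """A genotyped cohort: dosage matrix plus variant and sample tables."""

    genotypes: np.ndarray  # (n_samples, n_variants) int8, -1 = missing
    variants: pd.DataFrame
    samples: pd.DataFrame
    truth: Optional[SimTruth] = None

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=np.int8)
        if g.ndim != 2:
            raise ValueError("genotypes must be a 2-D (samples x variants) matrix")
        n, m = g.shape
        if len(self.samples) != n:
            raise ValueError(
                f"sample table has {len(self.samples)} rows but genotype matrix has {n}"
            )
        if len(self.variants) != m:
            raise ValueError(
                f"variant table has {len(self.variants)} rows but genotype matrix has {m}"
            )
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise ValueError(f"variant table lacks columns {missing_cols}")
        self.genotypes = g

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def dosages(self, dtype=np.float64) -> np.ndarray:
        """Genotypes as float with missing calls as NaN."""
        g = self.genotypes.astype(dtype)
        g[self.genotypes == MISSING] = np.nan
        return g

    def subset(self, sample_idx=None, variant_idx=None) -> "Cohort":
        """Positional subset of samples and/or variants (order preserved)."""
        g = self.genotypes
        samples = self.samples
        variants = self.variants
        truth = self.truth
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            g = g[sample_idx, :]
            samples = samples.iloc[sample_idx].reset_index(drop=True)
            if truth is not None:
                truth = SimTruth(
                    variant_class=truth.variant_class,
                    drug_liability=truth.drug_liability[sample_idx],
                    disease_liability=truth.disease_liability[sample_idx],
                    onsets=truth.onsets.iloc[sample_idx].reset_index(drop=True),
                )
        if variant_idx is not None:
            variant_idx = np.asarray(variant_idx)
            g = g[:, variant_idx]
            variants = variants.iloc[variant_idx].reset_index(drop=True)
            if truth is not None:
                truth = SimTruth(
                    variant_class=truth.variant_class.iloc[variant_idx].reset_index(
                        drop=True
                    ),
                    drug_liability=truth.drug_liability,
                    disease_liability=truth.disease_liability,
                    onsets=truth.onsets,
                )
        return Cohort(np.ascontiguousarray(g), variants, samples, truth)

    def drug_class_names(self) -> list[str]:
        """Drug-class names inferred from ``onset_<class>`` sample columns."""
        return [
            c[len("onset_"):] for c in self.samples.columns if c.startswith("onset_")
        ]

    def risk_names(self) -> list[str]:
        return [c[len("risk_"):] for c in self.samples.columns if c.startswith("risk_")]
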