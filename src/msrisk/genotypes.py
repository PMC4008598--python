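"""Genotype matrices of risk-allele dosages.

Dosages are stored as a float array with values 0/1/2 and ``NaN`` for missing
calls. Rows are samples (each carrying a case/control/unknown label), columns
are variants matched to an association panel by ``variant_id``.

Text round-trip format: TSV with columns ``sample_id``, ``label``, then one
column per variant holding 0/1/2 or ``NA``. A simple VCF reader is provided
for convenience; it counts copies of the panel's risk allele in each GT call
and treats half-calls as missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .panel_io import AssociationPanel

__all__ = ["GenotypeMatrix", "GenotypeFormatError", "LABELS", "CASE", "CONTROL", "UNKNOWN"]

CASE = "case"
CONTROL = "control"
UNKNOWN = "unknown"
LABELS = (CASE, CONTROL, UNKNOWN)


class GenotypeFormatError(ValueError):
    """A genotype file cannot be parsed or violates the dosage domain."""


@dataclass
class GenotypeMatrix:
    """Samples x variants risk-allele dosages in {0, 1, 2, NaN}."""

    sample_ids: list[str]
    variant_ids: list[str]
    dosages: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.dosages.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise GenotypeFormatError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_ids)} variants"
            )
        if self.labels.shape != (len(self.sample_ids),):
            raise GenotypeFormatError("labels must have one entry per sample")
        bad_labels = set(self.labels) - set(LABELS)
        if bad_labels:
            raise GenotypeFormatError(f"unknown sample labels: {sorted(bad_labels)}")
        finite = self.dosages[~np.isnan(self.dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise GenotypeFormatError("dosages must be 0, 1, 2 or missing (NaN)")

    # ---------------------------------------------------------------- shape
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def sample_missingness(self) -> np.ndarray:
        """Fraction of missing calls per sample."""
        return np.isnan(self.dosages).mean(axis=1)

    def label_mask(self, label: str) -> np.ndarray:
        return self.labels == label

    # -------------------------------------------------------------- subsets
    def subset_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            variant_ids=list(self.variant_ids),
            dosages=self.dosages[idx, :].copy(),
            labels=self.labels[idx].copy(),
        )

    def subset_variants(self, variant_ids: list[str]) -> "GenotypeMatrix":
        pos = {v: i for i, v in enumerate(self.variant_ids)}
        unknown = [v for v in variant_ids if v not in pos]
        if unknown:
            raise KeyError(f"variants not in matrix: {unknown}")
        idx = [pos[v] for v in variant_ids]
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variant_ids=list(variant_ids),
            dosages=self.dosages[:, idx].copy(),
            labels=self.labels.copy(),
        )

    # ------------------------------------------------------------------- IO
    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.dosages, columns=self.variant_ids)
        df = df.map(lambda x: "NA" if np.isnan(x) else str(int(x)))
        df.insert(0, "label", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=True)
        for col in ("sample_id", "label"):
            if col not in df.columns:
                raise GenotypeFormatError(f"genotype file {path} is missing column {col!r}")
        variant_cols = [c for c in df.columns if c not in ("sample_id", "label")]
        if not variant_cols:
            raise GenotypeFormatError(f"genotype file {path} has no variant columns")
        try:
            dosages = df[variant_cols].astype(float).to_numpy()
        except ValueError as exc:
            raise GenotypeFormatError(f"genotype file {path}: non-numeric dosage ({exc})") from exc
        return cls(
            sample_ids=df["sample_id"].astype(str).tolist(),
            variant_ids=variant_cols,
            dosages=dosages,
            labels=df["label"].fillna(UNKNOWN).to_numpy(dtype=object),
        )

    @classmethod
    def from_vcf(
        cls,
        path: str | Path,
        panel: "AssociationPanel",
        labels: Mapping[str, str] | None = None,
    ) -> "GenotypeMatrix":
        """Extract risk-allele dosages for a panel's variants from a VCF.

        Records are matched to panel variants by VCF ``ID``. The dosage is the
        number of GT alleles equal to the panel's risk allele; genotypes with
        any no-call allele (half-calls included) are missing. Panel variants
        absent from the VCF become all-missing columns (with a warning).
        """
        import pysam

        labels = dict(labels or {})
        with pysam.VariantFile(str(path)) as vcf:
            samples = list(vcf.header.samples)
            dosages = np.full((len(samples), len(panel)), np.nan)
            col = {v.variant_id: j for j, v in enumerate(panel)}
            seen: set[str] = set()
            for rec in vcf:
                if rec.id is None or rec.id not in col:
                    continue
                j = col[rec.id]
                seen.add(rec.id)
                risk = panel.variants[j].risk_allele
                for i, sample in enumerate(samples):
                    alleles = rec.samples[sample].alleles
                    if alleles is None or any(a is None for a in alleles):
                        continue
                    dosages[i, j] = float(sum(a == risk for a in alleles))
        absent = [v for v in panel.variant_ids if v not in seen]
        if absent:
            warnings.warn(f"panel variants not found in VCF (set to missing): {absent}")
        return cls(
            sample_ids=samples,
            variant_ids=panel.variant_ids,
            dosages=dosages,
            labels=np.array([labels.get(s, UNKNOWN) for s in samples], dtype=object),
        )
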