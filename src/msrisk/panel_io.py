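"""Summary-statistics panels of disease-associated risk variants.

A panel is an ordered collection of biallelic risk loci, each described by the
quantities a case-control GWAS reports: the risk allele, its per-allele odds
ratio, its frequency in controls, and the source study's sample sizes. From
these the two derived quantities that drive everything downstream are computed
once per variant:

* ``weight`` — the natural log of the odds ratio, the per-allele contribution
  to the weighted genetic risk score (wGRS);
* ``se_log_or`` — the standard error of ln(OR), reconstructed by Woolf's
  method from the expected allele counts of the source study's 2x2 table.

Nested genetic models (e.g. HLA-DRB1 alone, HLA-DRB1 plus older known loci,
HLA-DRB1 plus all known loci) are expressed as sub-panels sharing variant
definitions.

The file dialect is tab-separated text with a header row; lines starting with
``#`` are ignored.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantAssociation",
    "AssociationPanel",
    "PanelFormatError",
    "PanelValidationError",
    "load_panel",
    "save_panel",
    "log_or_se",
    "build_nested_models",
    "MODEL_HLA_ONLY",
    "MODEL_HLA_PLUS_OLD",
    "MODEL_HLA_PLUS_ALL",
]

MODEL_HLA_ONLY = "HLA_only"
MODEL_HLA_PLUS_OLD = "HLA_plus_old"
MODEL_HLA_PLUS_ALL = "HLA_plus_all"

#: Columns that must be present in a panel file.
REQUIRED_COLUMNS = ("variant_id", "risk_allele", "odds_ratio", "raf", "n_cases", "n_controls")

#: Optional columns, written in this order when saving.
OPTIONAL_COLUMNS = ("chrom", "pos", "other_allele")


class PanelFormatError(ValueError):
    """A panel file cannot be parsed (missing column, non-numeric field)."""


class PanelValidationError(ValueError):
    """Panel contents violate a domain invariant (duplicate id, OR <= 0, ...)."""


def _case_raf(raf: float, odds_ratio: float) -> float:
    # Allele-level tilt: frequency among case chromosomes implied by the OR.
    return odds_ratio * raf / (1.0 - raf + odds_ratio * raf)


def log_or_se(variant: "VariantAssociation") -> float:
    """Woolf-method standard error of ln(OR) from expected allele counts.

    The source study's 2x2 allele table is reconstructed from the control
    risk-allele frequency ``p``, the case frequency ``p' = OR*p/(1-p+OR*p)``
    implied by the odds ratio, and the case/control sample sizes (each sample
    contributes two chromosomes). The SE is then the usual
    ``sqrt(1/a + 1/b + 1/c + 1/d)`` over the four expected counts.

    Raises
    ------
    PanelValidationError
        If any expected allele count is not strictly positive.
    """
    p = variant.raf
    p_case = _case_raf(p, variant.odds_ratio)
    a = 2.0 * variant.n_cases * p_case
    b = 2.0 * variant.n_cases * (1.0 - p_case)
    c = 2.0 * variant.n_controls * p
    d = 2.0 * variant.n_controls * (1.0 - p)
    if min(a, b, c, d) <= 0.0:
        raise PanelValidationError(
            f"variant {variant.variant_id!r}: non-positive expected allele count "
            f"(a={a:.3g}, b={b:.3g}, c={c:.3g}, d={d:.3g})"
        )
    return math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)


@dataclass
class VariantAssociation:
    """One risk locus as reported by a case-control GWAS.

    ``weight`` (ln OR) and ``se_log_or`` (Woolf SE of ln OR) are derived on
    construction and must not be supplied.
    """

    variant_id: str
    risk_allele: str
    odds_ratio: float
    raf: float
    n_cases: int
    n_controls: int
    chrom: str | None = None
    pos: int | None = None
    other_allele: str | None = None
    weight: float = field(init=False, repr=False)
    se_log_or: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise PanelValidationError("variant_id must be non-empty")
        if not (self.odds_ratio > 0.0 and math.isfinite(self.odds_ratio)):
            raise PanelValidationError(
                f"variant {self.variant_id!r}: odds_ratio must be finite and > 0, got {self.odds_ratio}"
            )
        if not (0.0 < self.raf < 1.0):
            raise PanelValidationError(
                f"variant {self.variant_id!r}: raf must lie in (0, 1), got {self.raf}"
            )
        for name in ("n_cases", "n_controls"):
            n = getattr(self, name)
            if int(n) != n or n <= 0:
                raise PanelValidationError(
                    f"variant {self.variant_id!r}: {name} must be a positive integer, got {n}"
                )
            setattr(self, name, int(n))
        self.weight = math.log(self.odds_ratio)
        self.se_log_or = log_or_se(self)


@dataclass
class AssociationPanel:
    """Ordered collection of :class:`VariantAssociation` defining a genetic model."""

    variants: list[VariantAssociation]
    model_name: str = "custom"

    def __post_init__(self) -> None:
        if not self.variants:
            raise PanelValidationError("panel must contain at least one variant")
        ids = [v.variant_id for v in self.variants]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise PanelValidationError(f"duplicate variant_id in panel: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    @property
    def weights(self) -> np.ndarray:
        """Per-variant ln(OR), panel order."""
        return np.array([v.weight for v in self.variants], dtype=float)

    @property
    def se_log_or(self) -> np.ndarray:
        return np.array([v.se_log_or for v in self.variants], dtype=float)

    @property
    def rafs(self) -> np.ndarray:
        return np.array([v.raf for v in self.variants], dtype=float)

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.array([v.odds_ratio for v in self.variants], dtype=float)

    @property
    def checksum(self) -> str:
        """Stable digest of the panel content (ids, alleles, ORs, RAFs)."""
        h = hashlib.md5()
        for v in self.variants:
            h.update(f"{v.variant_id}\t{v.risk_allele}\t{v.odds_ratio!r}\t{v.raf!r}\n".encode())
        return h.hexdigest()

    def get(self, variant_id: str) -> VariantAssociation:
        for v in self.variants:
            if v.variant_id == variant_id:
                return v
        raise KeyError(variant_id)

    def subset(self, variant_ids: Iterable[str], model_name: str | None = None) -> "AssociationPanel":
        """Sub-panel restricted to ``variant_ids``, preserving panel order."""
        wanted = set(variant_ids)
        unknown = wanted - set(self.variant_ids)
        if unknown:
            raise PanelValidationError(f"variant ids not in panel: {sorted(unknown)}")
        kept = [v for v in self.variants if v.variant_id in wanted]
        return AssociationPanel(kept, model_name=model_name or f"{self.model_name}_subset")


def load_panel(path: str | Path, model_name: str = "custom") -> AssociationPanel:
    """Read and validate a summary-statistics panel from a TSV file.

    Raises :class:`PanelFormatError` for structural problems (missing required
    column, non-numeric odds ratio or frequency — the message names the column
    and 1-based data row) and :class:`PanelValidationError` for domain
    violations (duplicate variant ids, out-of-range values). Row order is
    preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, skip_blank_lines=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PanelFormatError(f"panel file {path} is missing required column(s): {missing}")

    numeric_cols = {"odds_ratio": float, "raf": float, "n_cases": int, "n_controls": int}
    parsed: dict[str, pd.Series] = {}
    for col in numeric_cols:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise PanelFormatError(
                f"panel file {path}: non-numeric or empty {col!r} at data row {row}"
            )
        parsed[col] = values

    variants = []
    for i in range(len(df)):
        row = df.iloc[i]
        pos_raw = row.get("pos")
        variants.append(
            VariantAssociation(
                variant_id=str(row["variant_id"]).strip(),
                risk_allele=str(row["risk_allele"]).strip(),
                odds_ratio=float(parsed["odds_ratio"].iloc[i]),
                raf=float(parsed["raf"].iloc[i]),
                n_cases=int(parsed["n_cases"].iloc[i]),
                n_controls=int(parsed["n_controls"].iloc[i]),
                chrom=None if pd.isna(row.get("chrom")) else str(row.get("chrom")),
                pos=None if pos_raw is None or pd.isna(pos_raw) else int(float(pos_raw)),
                other_allele=None
                if pd.isna(row.get("other_allele"))
                else str(row.get("other_allele")),
            )
        )
    return AssociationPanel(variants, model_name=model_name)


def save_panel(panel: AssociationPanel, path: str | Path) -> None:
    """Write a panel in the TSV dialect understood by :func:`load_panel`."""
    rows = []
    for v in panel:
        rows.append(
            {
                "variant_id": v.variant_id,
                "chrom": v.chrom or "",
                "pos": "" if v.pos is None else v.pos,
                "risk_allele": v.risk_allele,
                "other_allele": v.other_allele or "",
                "odds_ratio": repr(v.odds_ratio),
                "raf": repr(v.raf),
                "n_cases": v.n_cases,
                "n_controls": v.n_controls,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def build_nested_models(
    panel: AssociationPanel,
    hla_variant_id: str,
    old_variant_ids: Sequence[str],
) -> dict[str, AssociationPanel]:
    """Split a full panel into the three nested models of the analysis.

    ``HLA_only`` contains just the HLA variant; ``HLA_plus_old`` adds the loci
    known before the latest GWAS; ``HLA_plus_all`` is the full panel. The
    nesting invariants (HLA_only has one variant; HLA_plus_old a subset of
    HLA_plus_all) hold by construction.
    """
    old = list(dict.fromkeys(old_variant_ids))
    if hla_variant_id in old:
        raise PanelValidationError("hla_variant_id must not appear in old_variant_ids")
    return {
        MODEL_HLA_ONLY: panel.subset([hla_variant_id], MODEL_HLA_ONLY),
        MODEL_HLA_PLUS_OLD: panel.subset([hla_variant_id, *old], MODEL_HLA_PLUS_OLD),
        MODEL_HLA_PLUS_ALL: AssociationPanel(list(panel.variants), MODEL_HLA_PLUS_ALL),
    }
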