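"""Cohort QC, weighted genetic risk scores, and per-sample risk categories.

The weighted genetic risk score (wGRS) of a sample is the sum over panel
variants of risk-allele dosage times the variant weight ln(OR) — for a fully
typed sample it is numerically identical to the population engine's
``profile_log_risk``. Sample QC drops samples above a missingness threshold
(default 10%, strictly greater excluded). A per-variant QC report gives
allele frequencies, missingness and a Hardy-Weinberg chi-square test in
controls.

Per-sample risk categories are looked up against the RR boundaries realized
by a simulated population (:class:`~msrisk.population_sim.RiskDistribution`),
so a genotyped cohort can be placed inside the simulated general population's
risk distribution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import CASE, CONTROL, GenotypeMatrix
from .panel_io import AssociationPanel
from .population_sim import RiskDistribution

__all__ = [
    "qc_samples",
    "variant_qc_report",
    "compute_wgrs",
    "categorize_cohort",
    "MISSING_POLICIES",
    "GenotypeMatrix",
]

#: Supported treatments of missing dosages when scoring.
#: ``impute_expected`` substitutes the HWE expectation 2*raf; ``skip`` drops
#: the term (equivalent to dosage 0).
MISSING_POLICIES = ("impute_expected", "skip")


def qc_samples(matrix: GenotypeMatrix, max_missing_fraction: float = 0.10) -> GenotypeMatrix:
    """Drop samples whose missing-call fraction exceeds the threshold.

    A sample is retained iff its missing fraction is <= the threshold
    (strictly greater excluded); order is preserved.
    """
    if matrix.n_samples == 0:
        raise ValueError("matrix has no samples")
    if not (0.0 <= max_missing_fraction <= 1.0):
        raise ValueError("max_missing_fraction must lie in [0, 1]")
    return matrix.subset_samples(matrix.sample_missingness() <= max_missing_fraction)


def _hwe_chi2_p(counts: np.ndarray) -> float:
    """1-df chi-square HWE test p-value from genotype counts (n0, n1, n2)."""
    n = counts.sum()
    if n == 0:
        return float("nan")
    p = (counts[1] + 2 * counts[2]) / (2 * n)
    if p in (0.0, 1.0):
        return float("nan")
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def variant_qc_report(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant allele frequency, missingness, and HWE test in controls.

    The allele frequency is the mean non-missing dosage / 2 over all samples
    (NaN when every call is missing, never 0). The HWE p-value is a 1-df
    chi-square of control genotype counts against HWE expectations.
    """
    if not matrix.label_mask(CONTROL).any():
        raise ValueError("HWE testing requires at least one control sample")
    rows = []
    controls = matrix.dosages[matrix.label_mask(CONTROL), :]
    for j, vid in enumerate(matrix.variant_ids):
        col = matrix.dosages[:, j]
        obs = col[~np.isnan(col)]
        freq = float(obs.mean() / 2.0) if obs.size else float("nan")
        ctrl = controls[:, j]
        ctrl = ctrl[~np.isnan(ctrl)]
        geno_counts = np.array([(ctrl == g).sum() for g in (0.0, 1.0, 2.0)])
        rows.append(
            {
                "variant_id": vid,
                "allele_freq": freq,
                "missing_fraction": float(np.isnan(col).mean()),
                "hwe_p_controls": _hwe_chi2_p(geno_counts),
            }
        )
    return pd.DataFrame(rows)


def compute_wgrs(
    matrix: GenotypeMatrix,
    panel: AssociationPanel,
    missing_policy: str = "impute_expected",
) -> np.ndarray:
    """Per-sample weighted genetic risk score over the panel's variants.

    Dosage columns are aligned to the panel by variant id; panel variants
    absent from the matrix are treated as missing for every sample. Missing
    dosages are handled per ``missing_policy``.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"unknown missing_policy {missing_policy!r}; choose from {MISSING_POLICIES}")
    col = {v: i for i, v in enumerate(matrix.variant_ids)}
    dosages = np.full((matrix.n_samples, len(panel)), np.nan)
    for j, vid in enumerate(panel.variant_ids):
        if vid in col:
            dosages[:, j] = matrix.dosages[:, col[vid]]
    missing = np.isnan(dosages)
    if missing_policy == "impute_expected":
        fill = np.broadcast_to(2.0 * panel.rafs, dosages.shape)
    else:
        fill = np.zeros_like(dosages)
    dosages = np.where(missing, fill, dosages)
    return dosages @ panel.weights


def categorize_cohort(
    matrix: GenotypeMatrix,
    panel: AssociationPanel,
    distribution: RiskDistribution,
    missing_policy: str = "impute_expected",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place each sample in the simulated population's risk categories.

    Each sample's RR is ``exp(wGRS - baseline log risk)`` using the baseline
    recorded by the population run; the category is the one whose realized RR
    boundaries contain it. The distribution must come from the same panel
    (checked via the panel checksum).

    Returns ``(per_sample, counts)``: a per-sample table with wGRS, RR and
    category, and a label x category cross-tabulation.
    """
    if distribution.panel_checksum is not None and distribution.panel_checksum != panel.checksum:
        raise ValueError(
            "distribution was simulated from a different panel "
            f"(checksum {distribution.panel_checksum} != {panel.checksum})"
        )
    scores = compute_wgrs(matrix, panel, missing_policy=missing_policy)
    rr = np.exp(scores - distribution.baseline_log_risk)
    cats = distribution.category_of(rr)
    per_sample = pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "label": matrix.labels,
            "wgrs": scores,
            "rr": rr,
            "category": [c.value for c in cats],
        }
    )
    cat_order = ["reduced", "average", "elevated", "high"]
    counts = (
        per_sample.groupby(["label", "category"], observed=False)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=cat_order, fill_value=0)
    )
    counts.columns.name = "category"
    return per_sample, counts
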