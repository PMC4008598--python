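"""Synthetic case/control cohorts under the multiplicative risk model.

Generates genotype data with exactly the statistical structure the scoring
and performance stages assume: control dosages are Hardy-Weinberg draws at
the panel's risk-allele frequencies; case dosages are Hardy-Weinberg draws at
the *tilted* case allele frequency ``p' = OR*p / (1 - p + OR*p)`` implied by
each locus's per-allele odds ratio (the rare-disease approximation of the
multiplicative model — adequate here since the disease prevalence is of order
1/1,000); loci are independent; missingness is injected uniformly at random
(MCAR).

The module also provides the analytic AUC of the weighted genetic risk score
under this generative model, used as an oracle for the empirical ROC
machinery, and a fixture panel/cohort bundled with the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import stats

from .genotypes import CASE, CONTROL, GenotypeMatrix
from .panel_io import AssociationPanel, VariantAssociation
from .population_sim import hwe_genotype_distribution

__all__ = [
    "CohortSpec",
    "case_allele_frequency",
    "simulate_case_control",
    "expected_auc",
    "make_synthetic_panel",
    "example_panel_path",
    "example_cohort_path",
]


@dataclass
class CohortSpec:
    """Recipe for one synthetic cohort (sizes follow the study's 70 MS / 79 HC)."""

    panel: AssociationPanel
    n_cases: int = 70
    n_controls: int = 79
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")


def case_allele_frequency(raf: float, odds_ratio: float) -> float:
    """Risk-allele frequency among case chromosomes implied by the OR.

    ``p' = OR*p / (1 - p + OR*p)``: the allele-level 2x2 table built from
    (p', p) returns exactly the input odds ratio.
    """
    if not (0.0 < raf < 1.0):
        raise ValueError("raf must lie in (0, 1)")
    if odds_ratio <= 0.0:
        raise ValueError("odds_ratio must be > 0")
    return odds_ratio * raf / (1.0 - raf + odds_ratio * raf)


def simulate_case_control(spec: CohortSpec) -> GenotypeMatrix:
    """Draw a labelled case/control dosage matrix per the cohort spec.

    Cases come first, then controls. Reproducible for a given seed.
    """
    panel = spec.panel
    rng = np.random.default_rng(spec.seed)
    p_ctrl = panel.rafs
    p_case = np.array([case_allele_frequency(v.raf, v.odds_ratio) for v in panel])
    cases = rng.binomial(2, p_case[None, :], size=(spec.n_cases, len(panel)))
    controls = rng.binomial(2, p_ctrl[None, :], size=(spec.n_controls, len(panel)))
    dosages = np.vstack([cases, controls]).astype(float)
    if spec.missing_rate > 0.0:
        dosages[rng.random(dosages.shape) < spec.missing_rate] = np.nan
    width_c = len(str(spec.n_cases))
    width_k = len(str(spec.n_controls))
    return GenotypeMatrix(
        sample_ids=[f"case_{i + 1:0{width_c}d}" for i in range(spec.n_cases)]
        + [f"control_{i + 1:0{width_k}d}" for i in range(spec.n_controls)],
        variant_ids=panel.variant_ids,
        dosages=dosages,
        labels=np.array([CASE] * spec.n_cases + [CONTROL] * spec.n_controls, dtype=object),
    )


#: Largest panel for which expected_auc enumerates the exact score distribution.
_EXACT_ENUMERATION_MAX_LOCI = 12


def expected_auc(panel: AssociationPanel) -> float:
    """AUC of the wGRS under the generative model (no missingness).

    For panels of up to 12 loci the discrete score distributions of cases and
    controls are enumerated exactly and the AUC is
    ``P(case > control) + 0.5 P(tie)``. For larger panels a normal
    approximation ``Phi(dmu / sqrt(var_case + var_control))`` on the exact
    per-locus moments is used (loci independent). A panel with zero score
    variance returns 0.5 with a warning.
    """
    w = panel.weights
    p_ctrl = panel.rafs
    p_case = np.array([case_allele_frequency(v.raf, v.odds_ratio) for v in panel])
    var_ctrl = (w**2 * 2.0 * p_ctrl * (1.0 - p_ctrl)).sum()
    var_case = (w**2 * 2.0 * p_case * (1.0 - p_case)).sum()
    if var_ctrl + var_case == 0.0:
        warnings.warn("panel wGRS has zero variance; AUC is 0.5")
        return 0.5
    if len(panel) <= _EXACT_ENUMERATION_MAX_LOCI:
        return _exact_auc(panel, p_case)
    dmu = (w * 2.0 * (p_case - p_ctrl)).sum()
    return float(stats.norm.cdf(dmu / np.sqrt(var_case + var_ctrl)))


def _exact_auc(panel: AssociationPanel, p_case: np.ndarray) -> float:
    # Enumerate the 3^L joint dosage space (shared support for both groups).
    values = np.zeros(1)
    prob_case = np.ones(1)
    prob_ctrl = np.ones(1)
    g = np.array([0.0, 1.0, 2.0])
    for j, v in enumerate(panel):
        pc = np.array([stats.binom.pmf(k, 2, p_case[j]) for k in range(3)])
        pk = hwe_genotype_distribution(v.raf)
        values = (values[:, None] + g[None, :] * v.weight).ravel()
        prob_case = (prob_case[:, None] * pc[None, :]).ravel()
        prob_ctrl = (prob_ctrl[:, None] * pk[None, :]).ravel()
    # Collapse numerically equal scores, then AUC with midrank tie handling.
    key = np.round(values, 12)
    uniq, inv = np.unique(key, return_inverse=True)
    pc = np.bincount(inv, weights=prob_case)
    pk = np.bincount(inv, weights=prob_ctrl)
    cum_ctrl_below = np.concatenate([[0.0], np.cumsum(pk)[:-1]])
    return float((pc * (cum_ctrl_below + 0.5 * pk)).sum())


def make_synthetic_panel(
    n_loci: int = 111,
    seed: int = 0,
    or_range: tuple[float, float] = (1.05, 1.25),
    raf_range: tuple[float, float] = (0.05, 0.95),
    include_hla: bool = True,
    n_cases: int = 14_498,
    n_controls: int = 24_091,
) -> AssociationPanel:
    """Panel with the shape of the full known-variant model.

    ``n_loci`` independent biallelic loci: one strong HLA-like locus
    (OR 3.08, risk-allele frequency 0.2013, the published HLA-DRB1*15
    statistics) plus modest-effect loci with odds ratios drawn uniformly from
    ``or_range`` and risk-allele frequencies from ``raf_range``. Sample sizes
    default to a large GWAS scale.
    """
    rng = np.random.default_rng(seed)
    variants = []
    if include_hla:
        variants.append(
            VariantAssociation(
                variant_id="HLA_DRB1_1501",
                risk_allele="DRB1*15",
                odds_ratio=3.08,
                raf=0.2013,
                n_cases=9_772,
                n_controls=17_376,
                chrom="6",
            )
        )
    n_snps = n_loci - len(variants)
    ors = rng.uniform(*or_range, size=n_snps)
    rafs = rng.uniform(*raf_range, size=n_snps)
    for i in range(n_snps):
        variants.append(
            VariantAssociation(
                variant_id=f"rs_synth_{i + 1:04d}",
                risk_allele="A",
                other_allele="G",
                odds_ratio=float(ors[i]),
                raf=float(rafs[i]),
                n_cases=n_cases,
                n_controls=n_controls,
            )
        )
    return AssociationPanel(variants, model_name=f"synthetic_{n_loci}_loci")


def example_panel_path() -> Path:
    """Path of the bundled three-locus example panel (TSV)."""
    return Path(str(resources.files("msrisk").joinpath("data/example_panel.tsv")))


def example_cohort_path() -> Path:
    """Path of the bundled synthetic 70-case / 79-control cohort (TSV)."""
    return Path(str(resources.files("msrisk").joinpath("data/synthetic_cohort.tsv")))
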