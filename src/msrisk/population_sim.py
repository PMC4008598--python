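"""Population risk stratification from GWAS summary statistics.

The engine emulates the risk-profiling approach of REGENT-style analyses: a
large general population (100,000 individuals by default) is simulated under
Hardy-Weinberg equilibrium from published risk-allele frequencies, each
individual's genetic risk is computed under a multiplicative (log-additive)
model from published per-allele odds ratios, and relative risks (RR) are
expressed against a *baseline* profile — the profile whose risk is closest to
the population mean.

Each profile carries a 95% confidence interval for its risk, driven by the
sampling error of the source study's ln(OR) estimates (Woolf standard errors
from odds ratio, allele frequency and sample sizes — the only inputs a
summary-statistics panel provides). Risk categories follow CI-overlap rules:

* **average** — the profile's 95% CI overlaps the baseline profile's CI;
* **reduced** — its CI lies entirely below the baseline CI;
* **elevated** — its CI lies entirely above the baseline CI;
* **high** — its CI lies entirely above the CI of the *first elevated*
  profile (the elevated profile of lowest RR).

The summary of a run is a :class:`RiskDistribution`: the realized RR
boundaries between adjacent categories and the fraction of the simulated
population in each category.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import UNKNOWN, GenotypeMatrix
from .panel_io import AssociationPanel

__all__ = [
    "RiskCategory",
    "RiskProfile",
    "RiskDistribution",
    "hwe_genotype_distribution",
    "simulate_population",
    "profile_log_risk",
    "profile_log_risk_variance",
    "select_baseline_profile",
    "assign_risk_categories",
    "simulate_risk_distribution",
    "Z95",
]

#: Normal quantile used for all 95% confidence intervals.
Z95 = 1.96


class RiskCategory(str, Enum):
    """Risk category relative to the baseline profile, ordered by risk."""

    REDUCED = "reduced"
    AVERAGE = "average"
    ELEVATED = "elevated"
    HIGH = "high"

    @property
    def rank(self) -> int:
        return _CATEGORY_ORDER.index(self)


_CATEGORY_ORDER = [
    RiskCategory.REDUCED,
    RiskCategory.AVERAGE,
    RiskCategory.ELEVATED,
    RiskCategory.HIGH,
]


@dataclass
class RiskProfile:
    """One (possibly shared) genotype profile's relative risk and 95% CI.

    ``log_rr`` is the natural-log risk relative to the baseline profile;
    ``var_log_rr`` is the variance of the profile's own log risk, from the
    Woolf SEs of the panel's ln(OR) estimates. The CI is on the RR scale.
    """

    log_rr: float
    var_log_rr: float
    rr: float
    ci_low: float
    ci_high: float
    category: RiskCategory | None = None

    @classmethod
    def from_log_risk(cls, log_rr: float, var_log_rr: float) -> "RiskProfile":
        if var_log_rr < 0:
            raise ValueError("variance must be non-negative")
        sd = np.sqrt(var_log_rr)
        return cls(
            log_rr=float(log_rr),
            var_log_rr=float(var_log_rr),
            rr=float(np.exp(log_rr)),
            ci_low=float(np.exp(log_rr - Z95 * sd)),
            ci_high=float(np.exp(log_rr + Z95 * sd)),
        )


@dataclass
class RiskDistribution:
    """Population-level risk-category boundaries and proportions.

    ``boundaries`` are the RR values separating reduced|average,
    average|elevated and elevated|high: the baseline profile's CI bounds and
    the first elevated profile's upper CI bound. They are non-decreasing;
    the first two coincide only when the baseline profile carries no sampling
    variance (e.g. the zero-dosage profile of a single-locus model).
    ``proportions`` are the population fractions (reduced, average, elevated,
    high) and sum to one.
    """

    boundaries: tuple[float, float, float]
    proportions: np.ndarray
    n_simulated: int
    seed: int | None
    baseline_log_risk: float = 0.0
    panel_checksum: str | None = None
    model_name: str = "custom"
    category_counts: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.shape != (4,):
            raise ValueError("proportions must have four entries")
        if abs(self.proportions.sum() - 1.0) > 1e-12:
            raise ValueError("proportions must sum to 1 within 1e-12")
        b1, b2, b3 = self.boundaries
        if not (b1 <= b2 <= b3) or b2 == b3:
            raise ValueError(f"boundaries must be non-decreasing with b2 < b3, got {self.boundaries}")

    def category_of(self, rr: float | np.ndarray) -> np.ndarray:
        """Map RR values to categories via the realized boundaries.

        ``[b1, b2]`` is the average band (the baseline CI); values below are
        reduced, values in ``(b2, b3]`` elevated, values above ``b3`` high.
        """
        rr = np.asarray(rr, dtype=float)
        b1, b2, b3 = self.boundaries
        code = np.ones(rr.shape, dtype=int)
        code[rr < b1] = 0
        code[rr > b3] = 3
        code[(rr > b2) & (rr <= b3)] = 2
        out = np.empty(rr.shape, dtype=object)
        for k, cat in enumerate(_CATEGORY_ORDER):
            out[code == k] = cat
        return out

    # ------------------------------------------------------------ serialization
    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "boundaries": [_json_float(b) for b in self.boundaries],
            "proportions": self.proportions.tolist(),
            "n_simulated": int(self.n_simulated),
            "seed": self.seed,
            "baseline_log_risk": self.baseline_log_risk,
            "panel_checksum": self.panel_checksum,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "RiskDistribution":
        return cls(
            boundaries=tuple(_parse_float(b) for b in d["boundaries"]),
            proportions=np.asarray(d["proportions"], dtype=float),
            n_simulated=int(d["n_simulated"]),
            seed=d.get("seed"),
            baseline_log_risk=float(d.get("baseline_log_risk", 0.0)),
            panel_checksum=d.get("panel_checksum"),
            model_name=d.get("model_name", "custom"),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskDistribution":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_table(self) -> pd.DataFrame:
        """Tidy per-category table: RR interval and population percentage."""
        b1, b2, b3 = self.boundaries
        lows = [0.0, b1, b2, b3]
        highs = [b1, b2, b3, np.inf]
        return pd.DataFrame(
            {
                "category": [c.value for c in _CATEGORY_ORDER],
                "rr_low": lows,
                "rr_high": highs,
                "proportion_pct": np.round(self.proportions * 100.0, 1),
            }
        )


def _json_float(x: float):
    return {float("inf"): "inf", float("-inf"): "-inf"}.get(x, x) if np.isinf(x) else float(x)


def _parse_float(x) -> float:
    return float(x)


def hwe_genotype_distribution(raf: float) -> np.ndarray:
    """Genotype probabilities ((1-p)^2, 2p(1-p), p^2) under Hardy-Weinberg.

    ``raf`` in [0, 1]; the endpoints give a degenerate (monomorphic) locus.
    """
    if not (0.0 <= raf <= 1.0) or not np.isfinite(raf):
        raise ValueError(f"raf must lie in [0, 1], got {raf}")
    q = 1.0 - raf
    return np.array([q * q, 2.0 * raf * q, raf * raf])


def simulate_population(
    panel: AssociationPanel, n_individuals: int, seed: int | np.random.Generator
) -> GenotypeMatrix:
    """Draw a population of dosage profiles under HWE, loci independent.

    Each variant's dosage is Binomial(2, raf), which is exactly the HWE
    genotype distribution. No missing values are produced. Reproducible for a
    given integer seed.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    dosages = rng.binomial(2, panel.rafs[None, :], size=(n_individuals, len(panel))).astype(float)
    return GenotypeMatrix(
        sample_ids=[f"sim_{i}" for i in range(n_individuals)],
        variant_ids=panel.variant_ids,
        dosages=dosages,
        labels=np.array([UNKNOWN] * n_individuals, dtype=object),
    )


def _check_dosages(dosages: np.ndarray, panel: AssociationPanel) -> np.ndarray:
    d = np.asarray(dosages, dtype=float)
    if d.shape[-1] != len(panel):
        raise ValueError(f"dosage vector length {d.shape[-1]} != panel size {len(panel)}")
    if np.isnan(d).any():
        raise ValueError("dosages must not contain missing values")
    if not np.isin(d, (0.0, 1.0, 2.0)).all():
        raise ValueError("dosages must be 0, 1 or 2")
    return d


def profile_log_risk(dosages: Sequence[float] | np.ndarray, panel: AssociationPanel) -> float:
    """Log genetic risk of one profile: sum of dosage x ln(OR) over loci."""
    d = _check_dosages(dosages, panel)
    return float(d @ panel.weights)


def profile_log_risk_variance(
    dosages: Sequence[float] | np.ndarray, panel: AssociationPanel
) -> float:
    """Variance of a profile's log risk: sum of dosage^2 x SE^2.

    Treats the per-allele ln(OR) estimates as independent across loci and the
    dosages as fixed, so the only uncertainty is the source studies' sampling
    error.
    """
    d = _check_dosages(dosages, panel)
    return float((d**2) @ (panel.se_log_or**2))


def select_baseline_profile(
    log_risks: Sequence[float] | np.ndarray, weights: Sequence[float] | np.ndarray | None = None
) -> int:
    """Index of the profile closest to the population mean risk.

    The mean is taken on the risk (exponentiated) scale, weighted by profile
    multiplicities when the population has been grouped into distinct
    profiles. Ties are broken by lower risk, then lower index.
    """
    lr = np.asarray(log_risks, dtype=float)
    if lr.size == 0:
        raise ValueError("population must be non-empty")
    risks = np.exp(lr)
    mean = float(np.average(risks, weights=weights))
    dist = np.abs(risks - mean)
    candidates = np.flatnonzero(dist == dist.min())
    order = np.lexsort((candidates, risks[candidates]))
    return int(candidates[order[0]])


def assign_risk_categories(
    profiles: Sequence[RiskProfile],
    baseline: RiskProfile,
    weights: Sequence[float] | np.ndarray | None = None,
    *,
    n_simulated: int | None = None,
    seed: int | None = None,
    baseline_log_risk: float = 0.0,
    panel_checksum: str | None = None,
    model_name: str = "custom",
) -> RiskDistribution:
    """Assign CI-overlap risk categories and summarize the population.

    Every profile gets exactly one category (stored on the profile and
    reflected in the returned proportions): average if its 95% CI overlaps
    the baseline's CI, reduced/elevated if its CI lies entirely below/above,
    and high if its CI lies entirely above the CI of the lowest-RR elevated
    profile. ``weights`` are profile multiplicities (population counts).
    """
    if not any(p is baseline for p in profiles):
        raise ValueError("baseline must be one of the supplied profiles")
    lo = np.array([p.ci_low for p in profiles])
    hi = np.array([p.ci_high for p in profiles])
    rr = np.array([p.rr for p in profiles])
    if np.isnan(lo).any() or np.isnan(hi).any():
        raise ValueError("every profile must carry a finite CI")

    reduced = hi < baseline.ci_low
    elevated = lo > baseline.ci_high
    high = np.zeros_like(elevated)
    if elevated.any():
        elev_idx = np.flatnonzero(elevated)
        first = elev_idx[np.argmin(rr[elev_idx])]
        first_hi = hi[first]
        high = elevated & (lo > first_hi)
        b3 = float(first_hi)
    else:
        b3 = float("inf")

    code = np.ones(len(profiles), dtype=int)  # average
    code[reduced] = 0
    code[elevated] = 2
    code[high] = 3
    for p, c in zip(profiles, code):
        p.category = _CATEGORY_ORDER[c]

    w = np.ones(len(profiles)) if weights is None else np.asarray(weights, dtype=float)
    counts = np.array([w[code == k].sum() for k in range(4)])
    total = counts.sum()
    return RiskDistribution(
        boundaries=(float(baseline.ci_low), float(baseline.ci_high), b3),
        proportions=counts / total,
        n_simulated=int(total if n_simulated is None else n_simulated),
        seed=seed,
        baseline_log_risk=baseline_log_risk,
        panel_checksum=panel_checksum,
        model_name=model_name,
        category_counts=counts,
    )


def simulate_risk_distribution(
    panel: AssociationPanel,
    n_individuals: int = 100_000,
    seed: int = 0,
    return_profiles: bool = False,
):
    """Full population run: simulate, scale by baseline, categorize.

    Simulates ``n_individuals`` genotype profiles under HWE, groups identical
    dosage vectors (identical genotypes share one risk profile), picks the
    baseline as the profile closest to the weighted mean risk, converts every
    profile to an RR with 95% CI, and applies the CI-overlap category rules.

    Returns the :class:`RiskDistribution`; with ``return_profiles=True``,
    returns ``(distribution, profiles, counts)`` where profiles carry their
    assigned categories and counts their population multiplicities.
    """
    gm = simulate_population(panel, n_individuals, seed)
    genotypes = gm.dosages.astype(np.int8)
    uniq, counts = np.unique(genotypes, axis=0, return_counts=True)
    uniq = uniq.astype(float)
    log_risk = uniq @ panel.weights
    var = (uniq**2) @ (panel.se_log_or**2)

    b = select_baseline_profile(log_risk, weights=counts)
    scaled = log_risk - log_risk[b]
    profiles = [RiskProfile.from_log_risk(s, v) for s, v in zip(scaled, var)]
    dist = assign_risk_categories(
        profiles,
        profiles[b],
        weights=counts,
        n_simulated=n_individuals,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        baseline_log_risk=float(log_risk[b]),
        panel_checksum=panel.checksum,
        model_name=panel.model_name,
    )
    if return_profiles:
        return dist, profiles, counts
    return dist
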