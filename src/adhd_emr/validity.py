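"""Chart-review validation statistics for a case-finding algorithm.

A chart-review validation of an EMR phenotyping algorithm typically reviews
all algorithm-flagged patients plus a random sample of unflagged patients.
That design measures the predictive values directly:

    PPV = TP / (TP + FP)        NPV = TN / (TN + FN)

but not sensitivity or specificity, because the unflagged sample is not a
random sample of the population. Given the algorithm's apparent prevalence
p (flagged fraction of the source clinic), the misclassification identities
underlying the Rogan-Gladen estimator recover them analytically:

    pi = p * PPV + (1 - p) * (1 - NPV)          (true prevalence)
    Se = p * PPV / pi
    Sp = (1 - p) * NPV / (1 - pi)

Binomial point estimates carry exact (Clopper-Pearson) 95% confidence
intervals. The derived Se/Sp have no closed-form exact interval here; a
seeded parametric bootstrap propagates the binomial uncertainty of the three
inputs instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ConfusionCounts:
    """Chart-review 2×2 for a flagged-vs-sampled-unflagged design.

    ``clinic_total`` / ``clinic_flagged`` give the apparent prevalence of the
    source clinic, needed to derive Se/Sp.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    clinic_total: int | None = None
    clinic_flagged: int | None = None

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if (
            self.clinic_total is not None
            and self.clinic_flagged is not None
            and self.clinic_flagged > self.clinic_total
        ):
            raise ValueError("clinic_flagged cannot exceed clinic_total")

    @property
    def n_flagged(self) -> int:
        return self.tp + self.fp

    @property
    def n_unflagged_sampled(self) -> int:
        return self.tn + self.fn

    @property
    def apparent_prevalence(self) -> float:
        if not self.clinic_total:
            raise ValueError("clinic_total/clinic_flagged not set")
        return self.clinic_flagged / self.clinic_total


@dataclass(frozen=True)
class ValidityIndices:
    """Point estimates and 95% intervals of the validity indices."""

    ppv: float
    npv: float
    sensitivity: float
    specificity: float
    ci_ppv: tuple[float, float]
    ci_npv: tuple[float, float]
    ci_se: tuple[float, float] | None
    ci_sp: tuple[float, float] | None
    apparent_prevalence: float
    true_prevalence_clinic: float

    def __post_init__(self):
        for v in (self.ppv, self.npv, self.sensitivity, self.specificity):
            if not 0 <= v <= 1:
                raise ValueError("indices must lie in [0, 1]")


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval via Beta quantiles."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def ppv_npv(
    counts: ConfusionCounts, alpha: float = 0.05
) -> tuple[float, tuple[float, float], float, tuple[float, float]]:
    """PPV and NPV with exact 95% intervals: (ppv, ci_ppv, npv, ci_npv)."""
    if counts.n_flagged == 0 or counts.n_unflagged_sampled == 0:
        raise ValueError("both review arms must be non-empty")
    ppv = counts.tp / counts.n_flagged
    npv = counts.tn / counts.n_unflagged_sampled
    return (
        ppv,
        clopper_pearson(counts.tp, counts.n_flagged, alpha),
        npv,
        clopper_pearson(counts.tn, counts.n_unflagged_sampled, alpha),
    )


def derive_se_sp(ppv: float, npv: float, p: float) -> tuple[float, float, float]:
    """Sensitivity, specificity and clinic true prevalence from (PPV, NPV, p).

    ``p`` is the apparent prevalence (flagged fraction). Raises when the
    implied true prevalence is degenerate (0 or 1).
    """
    if not 0 < p < 1:
        raise ValueError("apparent prevalence must lie strictly in (0, 1)")
    if not (0 < ppv <= 1 and 0 < npv <= 1):
        raise ValueError("ppv and npv must lie in (0, 1]")
    pi = p * ppv + (1 - p) * (1 - npv)
    if pi <= 0 or pi >= 1:
        raise ValueError(f"implied true prevalence {pi} is degenerate")
    se = p * ppv / pi
    sp = (1 - p) * npv / (1 - pi)
    return se, sp, pi


def se_sp_uncertainty(
    counts: ConfusionCounts,
    n_boot: int = 2000,
    seed: int = 0,
    ppv_override: float | None = None,
    npv_override: float | None = None,
    alpha: float = 0.05,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Percentile-bootstrap 95% intervals for the derived Se and Sp.

    Resamples tp ~ Bin(n_flagged, PPV), tn ~ Bin(n_unflagged, NPV) and
    flagged ~ Bin(clinic_total, p), re-derives (Se, Sp) per replicate, and
    takes percentiles. Deterministic given ``seed``. Replicates with a
    degenerate implied prevalence are dropped (rare unless counts are
    extreme).
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be at least 1000 for stable percentiles")
    ppv = ppv_override if ppv_override is not None else counts.tp / counts.n_flagged
    npv = npv_override if npv_override is not None else counts.tn / counts.n_unflagged_sampled
    p = counts.apparent_prevalence

    rng = np.random.default_rng(seed)
    tp_b = rng.binomial(counts.n_flagged, ppv, n_boot)
    tn_b = rng.binomial(counts.n_unflagged_sampled, npv, n_boot)
    fl_b = rng.binomial(counts.clinic_total, p, n_boot)

    ppv_b = tp_b / counts.n_flagged
    npv_b = tn_b / counts.n_unflagged_sampled
    p_b = fl_b / counts.clinic_total
    pi_b = p_b * ppv_b + (1 - p_b) * (1 - npv_b)
    ok = (pi_b > 0) & (pi_b < 1) & (p_b > 0) & (p_b < 1)
    se_b = p_b[ok] * ppv_b[ok] / pi_b[ok]
    sp_b = (1 - p_b[ok]) * npv_b[ok] / (1 - pi_b[ok])
    if se_b.size == 0:
        raise ValueError("all bootstrap replicates degenerate; counts too extreme")
    qs = [100 * alpha / 2, 100 * (1 - alpha / 2)]
    ci_se = tuple(float(x) for x in np.percentile(se_b, qs))
    ci_sp = tuple(float(x) for x in np.percentile(np.clip(sp_b, 0, 1), qs))
    return ci_se, ci_sp


def validity_from_counts(
    counts: ConfusionCounts,
    ppv_override: float | None = None,
    npv_override: float | None = None,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> ValidityIndices:
    """Full set of validity indices from a chart-review 2×2.

    PPV/NPV come from the counts unless explicit overrides are given (some
    reports quote externally rounded predictive values; the derived Se/Sp
    then follow the quoted pair rather than the raw counts — overrides make
    that choice explicit, never silent).
    """
    ppv_c, ci_ppv, npv_c, ci_npv = ppv_npv(counts, alpha)
    ppv = ppv_override if ppv_override is not None else ppv_c
    npv = npv_override if npv_override is not None else npv_c
    p = counts.apparent_prevalence
    se, sp, pi = derive_se_sp(ppv, npv, p)
    ci_se, ci_sp = se_sp_uncertainty(
        counts, n_boot=n_boot, seed=seed,
        ppv_override=ppv_override, npv_override=npv_override, alpha=alpha,
    )
    return ValidityIndices(
        ppv=ppv,
        npv=npv,
        sensitivity=se,
        specificity=min(sp, 1.0),
        ci_ppv=ci_ppv,
        ci_npv=ci_npv,
        ci_se=ci_se,
        ci_sp=ci_sp,
        apparent_prevalence=p,
        true_prevalence_clinic=pi,
    )
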