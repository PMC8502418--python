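"""Diagnostic performance and assay QC.

Sensitivity and specificity of the methylation classifier with exact
(Clopper-Pearson) binomial confidence intervals, ROC AUC as the rank-based
Mann-Whitney probability with a stratified percentile bootstrap interval,
and ordinary-least-squares linearity of a dilution series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .calling import CallResult
from .records import DegenerateDataError, ValidationError

__all__ = [
    "DiagnosticSummary",
    "AucEstimate",
    "LinearityResult",
    "clopper_pearson",
    "diagnostic_performance",
    "roc_auc",
    "linearity",
]


@dataclass(frozen=True)
class AucEstimate:
    auc: float
    ci: Optional[Tuple[float, float]]
    n_cases: int
    n_controls: int
    n_boot: int


@dataclass(frozen=True)
class DiagnosticSummary:
    """Confusion counts and the derived metrics with exact binomial CIs."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    sens_ci: Optional[Tuple[float, float]]
    spec_ci: Optional[Tuple[float, float]]
    conf: float
    n_cases: int
    n_controls: int
    auc: Optional[float] = None
    auc_ci: Optional[Tuple[float, float]] = None

    def rounded(self) -> dict:
        """Display rounding: metric to 1 decimal in percent, CI bounds to
        whole percent. Full precision stays on the dataclass fields."""
        def pct(x, nd):
            return None if x is None else round(100 * x, nd)

        return {
            "sensitivity_pct": pct(self.sensitivity, 1),
            "sensitivity_ci_pct": None
            if self.sens_ci is None
            else [pct(self.sens_ci[0], 0), pct(self.sens_ci[1], 0)],
            "specificity_pct": pct(self.specificity, 1),
            "specificity_ci_pct": None
            if self.spec_ci is None
            else [pct(self.spec_ci[0], 0), pct(self.spec_ci[1], 0)],
        }


@dataclass(frozen=True)
class LinearityResult:
    slope: float
    intercept: float
    r_squared: float
    concentrations: Tuple[float, ...]
    counts: Tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValidationError("r_squared outside [0, 1]")


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> Tuple[float, float]:
    """Exact binomial confidence interval for a proportion.

    The bounds are Beta-distribution quantiles: the interval that inverts the
    exact binomial test, guaranteeing at least nominal coverage. ``k = 0``
    pins the lower bound to 0 and ``k = n`` the upper bound to 1.
    """
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ValidationError("k and n must be integers")
    if n < 1 or not 0 <= k <= n:
        raise ValidationError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not 0 < conf < 1:
        raise ValidationError("confidence level must be in (0, 1)")
    alpha = 1.0 - conf
    low = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return (low, high)


def diagnostic_performance(
    calls: Sequence[CallResult],
    truth: Mapping[str, bool],
    conf: float = 0.95,
) -> DiagnosticSummary:
    """Confusion counts, sensitivity and specificity with exact CIs.

    ``truth`` maps sample_id to True for cases and False for controls; every
    call must have a label. A metric whose denominator is empty (no cases,
    or no controls) is reported as None, never as zero.
    """
    if not calls:
        raise ValidationError("no calls supplied")
    missing = [c.sample_id for c in calls if c.sample_id not in truth]
    if missing:
        raise ValidationError(f"samples without truth labels: {missing}")

    tp = fp = tn = fn = 0
    for c in calls:
        if truth[c.sample_id]:
            tp += c.combined_call
            fn += not c.combined_call
        else:
            fp += c.combined_call
            tn += not c.combined_call
    n_cases, n_controls = tp + fn, tn + fp

    sens = sens_ci = spec = spec_ci = None
    if n_cases > 0:
        sens = tp / n_cases
        sens_ci = clopper_pearson(tp, n_cases, conf)
    if n_controls > 0:
        spec = tn / n_controls
        spec_ci = clopper_pearson(tn, n_controls, conf)
    return DiagnosticSummary(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec,
        sens_ci=sens_ci, spec_ci=spec_ci,
        conf=conf, n_cases=n_cases, n_controls=n_controls,
    )


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[bool],
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> AucEstimate:
    """AUC as the probability a random case outscores a random control.

    Computed from mid-ranks (ties weighted one half), which is the scaled
    Mann-Whitney U statistic; invariant under strictly monotone score
    transforms. With ``n_boot > 0`` a percentile bootstrap interval is
    attached, resampling cases and controls separately so both classes stay
    present in every replicate.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("scores and labels must be equal-length 1-D")
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("both classes must be present for ROC analysis")
    if n_boot < 0:
        raise ValidationError("n_boot must be >= 0")

    def _auc(sc: np.ndarray, lab: np.ndarray) -> float:
        r = sps.rankdata(sc)
        k = int(lab.sum())
        return (float(r[lab].sum()) - k * (k + 1) / 2) / (k * (lab.size - k))

    point = _auc(s, y)
    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        cases, controls = s[y], s[~y]
        vals = np.empty(n_boot)
        for b in range(n_boot):
            sc = np.concatenate(
                [rng.choice(cases, n1, replace=True), rng.choice(controls, n0, replace=True)]
            )
            lab = np.concatenate([np.ones(n1, bool), np.zeros(n0, bool)])
            vals[b] = _auc(sc, lab)
        ci = (float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5)))
    return AucEstimate(auc=point, ci=ci, n_cases=n1, n_controls=n0, n_boot=n_boot)


def linearity(
    concentrations: Sequence[float], counts: Sequence[float]
) -> LinearityResult:
    """OLS fit of positive-droplet counts on input DNA concentration.

    The dilution-series QC: a well-behaved assay gives a near-proportional
    response, summarized by the regression R².
    """
    x = np.asarray(concentrations, dtype=float)
    yv = np.asarray(counts, dtype=float)
    if x.shape != yv.shape or x.ndim != 1:
        raise ValidationError("concentrations and counts must be equal-length 1-D")
    if x.size < 3:
        raise ValidationError("linearity needs at least 3 points")
    if np.ptp(x) == 0:
        raise DegenerateDataError("all concentrations identical: degenerate design")
    fit = sps.linregress(x, yv)
    return LinearityResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        concentrations=tuple(x.tolist()),
        counts=tuple(yv.tolist()),
    )
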