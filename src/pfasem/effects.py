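"""Percent-change-per-doubling effect reporting and effect-homogeneity tests.

All exposures and outcomes are modeled on the log2 scale, so a structural
coefficient beta is the change in log2 antibody per doubling of exposure,
and the percent change in antibody concentration per doubling is

    100 * (2**beta - 1).

Confidence intervals are built as Wald intervals on the beta scale and then
pushed through the (monotone) transform, which respects the > -100 % support
and yields the asymmetric intervals characteristic of this reporting scale.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .estimation import FitResult, likelihood_ratio_test

__all__ = [
    "EffectEstimate",
    "percent_change_per_doubling",
    "beta_from_percent_change",
    "joint_effect",
    "test_equal_effects",
]


@dataclass
class EffectEstimate:
    """A log2-scale coefficient and its percent-change-per-doubling reading."""

    beta: float
    se: float
    percent: float
    ci_low: float
    ci_high: float
    level: float

    def describe(self) -> str:
        """Prose rendering; negative changes read as a decrease."""
        direction = "decrease" if self.percent < 0 else "increase"
        pct = int(round(self.level * 100))
        return (f"{direction} by {abs(self.percent):.1f} % "
                f"({pct} % CI: {self.ci_low:.1f} %, {self.ci_high:.1f} %) "
                "per doubling of exposure")


def percent_change_per_doubling(beta: float, se: float,
                                level: float = 0.95) -> EffectEstimate:
    """Transform a log2-log2 coefficient to percent change per doubling."""
    if se < 0:
        raise ValueError("se must be nonnegative")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2)
    point = 100.0 * (2.0 ** beta - 1.0)
    lo = 100.0 * (2.0 ** (beta - z * se) - 1.0)
    hi = 100.0 * (2.0 ** (beta + z * se) - 1.0)
    lo, hi = min(lo, hi), max(lo, hi)
    return EffectEstimate(beta=beta, se=se, percent=point,
                          ci_low=lo, ci_high=hi, level=level)


def beta_from_percent_change(percent: float) -> float:
    """Invert the transform: the beta whose percent change equals ``percent``."""
    import math
    return math.log2(1.0 + percent / 100.0)


def joint_effect(fit: FitResult, outcome_labels, level: float = 0.95) -> EffectEstimate:
    """The shared exposure coefficient of an equality-constrained fit.

    ``outcome_labels`` names the two structural-coefficient labels (or their
    common equality-group label) tied together in the fitted spec.
    """
    groups = {p.group for s, t, p in fit.spec.directed
              if p.group is not None and p.label in outcome_labels}
    groups |= {g for g in outcome_labels if g in fit.labels}
    if len(groups) != 1:
        raise ValueError(
            "fit does not carry a single equality group tying "
            f"{outcome_labels}; found {sorted(g for g in groups if g)}")
    group = groups.pop()
    if group not in fit.labels:
        raise ValueError(f"equality group {group!r} is not a free parameter")
    i = fit.labels.index(group)
    beta = float(fit.theta[i])
    se = float(fit.vcov()[i, i] ** 0.5)
    return percent_change_per_doubling(beta, se, level)


def test_equal_effects(fit_free: FitResult, fit_equal: FitResult):
    """LRT of one equality constraint tying the two antibody effects (df = 1)."""
    out = likelihood_ratio_test(fit_equal, fit_free)
    if out["df"] != 1:
        raise ValueError(
            f"models differ by {out['df']} parameters, not the single "
            "equality constraint")
    return out
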