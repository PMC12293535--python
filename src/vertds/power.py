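"""Post hoc power of the overall regression F-test.

Given an observed coefficient of determination, Cohen's effect size is
``f2 = R2 / (1 - R2)``; the non-centrality parameter of the F statistic is
``lambda = f2 * df2`` with ``df2 = n - k - 1``; achieved power is the upper
tail of the non-central F distribution beyond the central-F critical value
at the chosen significance level.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import f as f_dist
from scipy.stats import ncf

from .errors import ValidationError

__all__ = ["PowerReport", "cohens_f2", "noncentrality", "achieved_power", "power_report"]


@dataclass(frozen=True)
class PowerReport:
    """Everything the power computation consumed and produced."""

    r2: float
    f2: float
    df1: int
    df2: int
    alpha: float
    lambda_nc: float
    f_crit: float
    power: float

    def summary(self) -> str:
        return (
            f"R2 = {self.r2:.3f}  ->  Cohen's f2 = {self.f2:.3f}\n"
            f"df = ({self.df1}, {self.df2}), alpha = {self.alpha}\n"
            f"non-centrality lambda = {self.lambda_nc:.1f}\n"
            f"critical F = {self.f_crit:.2f}\n"
            f"achieved power = {self.power:.3f}"
        )


def cohens_f2(r2: float) -> float:
    """Effect size ``f2 = R2 / (1 - R2)``."""
    if not 0 <= r2 < 1:
        raise ValidationError("R2 must lie in [0, 1)")
    return r2 / (1.0 - r2)


def noncentrality(f2: float, df2: float) -> float:
    """Non-centrality parameter ``lambda = f2 * df2``."""
    if f2 < 0 or df2 <= 0:
        raise ValidationError("need f2 >= 0 and df2 > 0")
    return f2 * df2


def achieved_power(df1: int, df2: int, lambda_nc: float, alpha: float = 0.05) -> float:
    """Power of the overall F-test at the given non-centrality.

    ``power = P(F' > F_crit)`` with ``F'`` non-central F(df1, df2, lambda)
    and ``F_crit`` the central upper-alpha quantile. At ``lambda = 0`` the
    power equals ``alpha`` exactly.
    """
    if df1 <= 0 or df2 <= 0:
        raise ValidationError("degrees of freedom must be positive")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    if lambda_nc < 0:
        raise ValidationError("lambda must be >= 0")
    f_crit = float(f_dist.ppf(1.0 - alpha, df1, df2))
    if lambda_nc == 0:
        return alpha
    return float(ncf.sf(f_crit, df1, df2, lambda_nc))


def power_report(r2: float, n: int, k: int, alpha: float = 0.05) -> PowerReport:
    """Convenience wrapper: from (R2, n, k) to the full power report."""
    df1, df2 = k, n - k - 1
    if df2 <= 0:
        raise ValidationError(f"n = {n}, k = {k} leaves df2 = {df2} <= 0")
    f2 = cohens_f2(r2)
    lam = noncentrality(f2, df2)
    return PowerReport(
        r2=r2, f2=f2, df1=df1, df2=df2, alpha=alpha, lambda_nc=lam,
        f_crit=float(f_dist.ppf(1.0 - alpha, df1, df2)),
        power=achieved_power(df1, df2, lam, alpha),
    )
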