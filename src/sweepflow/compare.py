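"""Agreement analysis between 2D PCMRI and SVR 4D-flow mean flows.

Paired vessel-level mean flows are compared by ordinary least squares
(SVR 4D flow regressed on 2D PCMRI, with t-based 95% confidence intervals)
and by Bland–Altman analysis of the paired differences, taken as
M_2D - M_SVR (configurable).  Linear mixed models over patient covariates
are out of scope for the simulated cohort; the report notes this.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class RegressionResult:
    slope: float
    intercept_ml_s: float
    slope_ci95: tuple
    intercept_ci95: tuple
    r_squared: float
    n: int


@dataclass
class BlandAltmanResult:
    bias_ml_s: float
    sd_ml_s: float
    loa_low_ml_s: float
    loa_high_ml_s: float
    n: int


@dataclass
class AgreementReport:
    pairs: pd.DataFrame  # columns vessel_id, m_2d_ml_s, m_svr_ml_s
    regression: Optional[RegressionResult]  # None below 3 pairs
    bland_altman: BlandAltmanResult
    difference_convention: str = "2D - SVR"
    notes: str = field(
        default="Mixed-model covariate analysis (participant random effects) is not "
        "applicable to a single simulated phantom and is omitted."
    )

    def to_table(self) -> pd.DataFrame:
        t = self.pairs.copy()
        t["difference_ml_s"] = t["m_2d_ml_s"] - t["m_svr_ml_s"]
        t["mean_ml_s"] = 0.5 * (t["m_2d_ml_s"] + t["m_svr_ml_s"])
        return t


def linear_agreement(m_2d: Sequence[float], m_svr: Sequence[float]) -> RegressionResult:
    """OLS of M_SVR on M_2D with 95% CIs from the t(n-2) distribution."""
    x = np.asarray(m_2d, dtype=float)
    y = np.asarray(m_svr, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs for regression")
    if np.var(x) == 0:
        raise ValueError("degenerate regression: zero variance in M_2D")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return RegressionResult(
        slope=float(model.params[1]),
        intercept_ml_s=float(model.params[0]),
        slope_ci95=(float(ci[1, 0]), float(ci[1, 1])),
        intercept_ci95=(float(ci[0, 0]), float(ci[0, 1])),
        r_squared=float(model.rsquared),
        n=int(x.size),
    )


def bland_altman(
    m_2d: Sequence[float], m_svr: Sequence[float], sign: str = "2d_minus_svr"
) -> BlandAltmanResult:
    """Bias and 1.96-SD limits of agreement of the paired differences."""
    x = np.asarray(m_2d, dtype=float)
    y = np.asarray(m_svr, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = x - y if sign == "2d_minus_svr" else y - x
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(
        bias_ml_s=bias,
        sd_ml_s=sd,
        loa_low_ml_s=bias - 1.96 * sd,
        loa_high_ml_s=bias + 1.96 * sd,
        n=int(x.size),
    )


def agreement_report(pairs: pd.DataFrame) -> AgreementReport:
    """Full agreement analysis from a pairs table (vessel_id, m_2d_ml_s, m_svr_ml_s)."""
    reg = (
        linear_agreement(pairs["m_2d_ml_s"], pairs["m_svr_ml_s"])
        if len(pairs) >= 3
        else None
    )
    return AgreementReport(
        pairs=pairs.reset_index(drop=True),
        regression=reg,
        bland_altman=bland_altman(pairs["m_2d_ml_s"], pairs["m_svr_ml_s"]),
    )


def plot_agreement(report: AgreementReport, path_regression, path_bland_altman) -> None:
    """Regression (with identity line) and Bland–Altman plots."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = report.pairs["m_2d_ml_s"].to_numpy()
    y = report.pairs["m_svr_ml_s"].to_numpy()
    reg = report.regression

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(x, y, color="k")
    lim = np.array([min(x.min(), y.min()), max(x.max(), y.max())])
    ax.plot(lim, lim, "b--", label="identity")
    if reg is not None:
        ax.plot(lim, reg.intercept_ml_s + reg.slope * lim, "r-",
                label=f"fit: y = {reg.slope:.2f}x + {reg.intercept_ml_s:.2f}")
        ax.set_title(f"$r^2$ = {reg.r_squared:.3f} (n = {reg.n})")
    ax.set_xlabel("$M_{2D}$ mean flow (mL/s)")
    ax.set_ylabel("$M_{SVR}$ mean flow (mL/s)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path_regression, dpi=120)
    plt.close(fig)

    ba = report.bland_altman
    mean = 0.5 * (x + y)
    diff = x - y
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean, diff, color="k")
    ax.axhline(ba.bias_ml_s, color="r", label=f"bias = {ba.bias_ml_s:.2f} mL/s")
    ax.axhline(ba.loa_low_ml_s, color="r", linestyle="--")
    ax.axhline(ba.loa_high_ml_s, color="r", linestyle="--",
               label=f"LoA [{ba.loa_low_ml_s:.2f}, {ba.loa_high_ml_s:.2f}]")
    ax.set_xlabel("mean of techniques (mL/s)")
    ax.set_ylabel("2D $-$ SVR (mL/s)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path_bland_altman, dpi=120)
    plt.close(fig)
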