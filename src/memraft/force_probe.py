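"""Detachment-force extraction from constant-velocity pulling traces.

A pulling trace carries the time series of the spring force and of the
center-of-mass separation ``d_COM`` of the two pulled groups.  Both series
are denoised with an order-0 Gaussian filter (default sigma 100 ps); the
detachment force is the highest smoothed force recorded while the smoothed
``d_COM`` is still below a cutoff (default 7.3 nm) and before the first
cutoff crossing.  Force-vs-log-velocity fits and the two statistical
comparisons used on detachment-force samples (Mann-Whitney U per velocity,
two-way ANOVA across velocities) round out the module.

Forces are kept in kJ/mol/nm throughout; reports may convert to pN
(1 kJ/mol/nm = 1.6606 pN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ForceTrace",
    "DetachmentResult",
    "gaussian_smooth",
    "detachment_force",
    "fit_log_velocity",
    "mann_whitney_u",
    "two_way_anova",
    "KJ_PER_MOL_NM_TO_PN",
]

KJ_PER_MOL_NM_TO_PN = 1.6606


@dataclass
class ForceTrace:
    """Time series of force (kJ/mol/nm) and COM distance (nm) plus metadata."""

    times: np.ndarray            # ps, strictly increasing
    force: np.ndarray            # kJ/mol/nm
    d_com: np.ndarray            # nm
    v_pull: float | None = None  # m/s
    k_s: float | None = None     # kJ/mol/nm^2
    replica: int = 0
    condition: str = ""
    presmoothed: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.d_com = np.asarray(self.d_com, dtype=float)
        if not (len(self.times) == len(self.force) == len(self.d_com)):
            raise ValueError("times, force and d_com must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def dt(self) -> float:
        if len(self.times) < 2:
            raise ValueError("trace too short to define dt")
        return float(self.times[1] - self.times[0])


@dataclass
class DetachmentResult:
    f_detach: float              # kJ/mol/nm
    t_detach: float              # ps
    index: int
    cutoff: float                # nm
    crossed: bool
    crossing_time: float | None  # ps, first cutoff crossing (None if never)


def gaussian_smooth(series, sigma_time: float = 100.0, dt: float | None = None):
    """Order-0 Gaussian filter with a mass-preserving edge policy.

    The kernel (sigma = ``sigma_time / dt`` samples) is truncated at 4 sigma;
    at the trace ends the truncated kernel is renormalized instead of
    zero-padding, so a constant series passes through unchanged and force
    peaks near the ends are not suppressed.
    """
    if sigma_time <= 0:
        raise ValueError("sigma_time must be positive")
    if dt is None or dt <= 0:
        raise ValueError("dt must be positive")
    x = np.asarray(series, dtype=float)
    sigma = sigma_time / dt
    half = max(1, int(math.ceil(4.0 * sigma)))
    k = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (k / sigma) ** 2)
    kernel /= kernel.sum()
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def detachment_force(
    trace: ForceTrace,
    cutoff: float = 7.3,
    sigma_time: float = 100.0,
) -> DetachmentResult:
    """Detachment force: the smoothed-force maximum before the d_COM cutoff.

    The force and d_COM series are smoothed (unless the trace is flagged as
    already smooth); the maximum is taken over frames at which the smoothed
    d_COM is below ``cutoff`` and no later than the first cutoff crossing.
    Ties go to the earliest frame.  If d_COM never crosses the cutoff the
    whole-trace maximum is returned with ``crossed=False``.
    """
    if len(trace.times) == 0:
        raise ValueError("empty trace")
    if trace.presmoothed or len(trace.times) < 3:
        f_s, d_s = trace.force, trace.d_com
    else:
        f_s = gaussian_smooth(trace.force, sigma_time, trace.dt)
        d_s = gaussian_smooth(trace.d_com, sigma_time, trace.dt)

    above = d_s >= cutoff
    if np.any(above):
        cross = int(np.argmax(above))
        if cross == 0:
            raise ValueError("cutoff exceeded at start: d_COM >= cutoff at t=0")
        window = np.arange(cross)  # strictly before first crossing
        window = window[d_s[window] < cutoff]
        crossed, crossing_time = True, float(trace.times[cross])
    else:
        window = np.arange(len(f_s))
        crossed, crossing_time = False, None
    idx = int(window[np.argmax(f_s[window])])
    return DetachmentResult(
        f_detach=float(f_s[idx]),
        t_detach=float(trace.times[idx]),
        index=idx,
        cutoff=cutoff,
        crossed=crossed,
        crossing_time=crossing_time,
    )


def fit_log_velocity(records, log_base="e"):
    """Ordinary least squares of ``F_detach = A + B * log(V_pull)``.

    ``records`` is a sequence of ``(v_pull, f_detach)`` pairs; ``log_base``
    is ``"e"`` or ``10`` (the base is part of the reported coefficients and
    must be stated alongside them).  Returns ``(A, B, residuals)``.
    """
    records = [(float(v), float(f)) for v, f in records]
    if len({v for v, _ in records}) < 2:
        raise ValueError("need at least 2 distinct pulling velocities")
    v = np.array([r[0] for r in records])
    f = np.array([r[1] for r in records])
    if np.any(v <= 0):
        raise ValueError("pulling velocities must be positive")
    if log_base in ("e", math.e):
        x = np.log(v)
    elif log_base in (10, "10"):
        x = np.log10(v)
    else:
        raise ValueError("log_base must be 'e' or 10")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, f, rcond=None)
    residuals = f - X @ beta
    return float(beta[0]), float(beta[1]), residuals


@dataclass
class MannWhitneyResult:
    u: float
    p: float
    method: str  # "exact" or "asymptotic"


def mann_whitney_u(x, y, alternative: str = "two-sided") -> MannWhitneyResult:
    """Mann-Whitney U test (scipy backend).

    The exact null distribution is used for small samples
    (``min(n, m) <= 8``) without ties; otherwise the normal approximation
    with tie correction.  The method used is recorded in the result.
    """
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(len(x), len(y)) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue), method=method)


def two_way_anova(table, response="force", factor_a="interface",
                  factor_b="velocity", interaction: bool = False):
    """Two-way ANOVA of a response on two categorical factors.

    Uses type-II sums of squares (robust for unbalanced designs without
    interaction).  Returns a DataFrame indexed by effect with columns
    ``F`` and ``p``.
    """
    import pandas as pd
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(table)
    for col in (response, factor_a, factor_b):
        if col not in df.columns:
            raise ValueError(f"table lacks column {col!r}")
    for col in (factor_a, factor_b):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs at least 2 levels")
    op = "*" if interaction else "+"
    formula = f"{response} ~ C({factor_a}) {op} C({factor_b})"
    model = smf.ols(formula, data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    out = aov.rename(columns={"PR(>F)": "p"})[["F", "p"]]
    out = out.rename(index={f"C({factor_a})": factor_a, f"C({factor_b})": factor_b})
    return out
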