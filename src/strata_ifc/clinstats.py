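"""Clinical group statistics and power-derived screening thresholds.

Implements the summary statistics a clinical table reports — pooled-variance
two-sample t-tests (computable from printed means/SDs/ns alone), pooled-SD
Cohen's d, and the 2x2 Pearson chi-square — together with two analysis-stream
prerequisites: the pooled z-normalization fitted on the baseline (M1) sample
and re-applied, frozen, to follow-up data; and the criterion alpha at which a
two-sample t-test reaches a requested power for a given effect size, obtained
from the noncentral t distribution.

Conventions: sample SD uses the n-1 denominator; the t-test is the pooled
(Student) test, not Welch — a reported df of n1+n2-2 identifies it; the
chi-square carries no continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "TwoSampleResult",
    "NormalizationModel",
    "PowerSpec",
    "two_sample_t_from_summary",
    "chi_square_2x2",
    "fit_normalization",
    "screening_alpha",
    "table_report",
    "FEATURE_COLUMNS",
]

#: The eight clinical feature dimensions used throughout the analysis stream:
#: DSM-IV symptom counts from the diagnostic interview (criterion A1 =
#: inattention, A2 = hyperactivity/impulsivity) and six CAARS DSM-oriented
#: subscale scores (self- and observer-rated inattention,
#: hyperactivity/impulsivity, and total).
FEATURE_COLUMNS = (
    "DSM_IV_A1",
    "DSM_IV_A2",
    "CAARS_DSM_IA_S",
    "CAARS_DSM_HYI_S",
    "CAARS_DSM_ADHD_S",
    "CAARS_DSM_IA_O",
    "CAARS_DSM_HYI_O",
    "CAARS_DSM_ADHD_O",
)


@dataclass(frozen=True)
class GroupSummary:
    """Mean, sample SD (n-1 denominator) and size of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group size must be >= 2, got n={self.n}")
        if self.sd < 0:
            raise ValueError(f"sd must be nonnegative, got sd={self.sd}")


@dataclass(frozen=True)
class TwoSampleResult:
    """Pooled two-sample t-test result with Cohen's d."""

    t: float
    df: int
    p: float
    cohens_d: float


@dataclass(frozen=True)
class PowerSpec:
    """Design of a two-group power computation.

    ``effect_size_d`` is the standardized mean difference (Cohen's d) the test
    should detect; ``power`` the requested probability of detecting it;
    ``tails`` one of ``"one"`` or ``"two"``.
    """

    n1: int
    n2: int
    effect_size_d: float
    power: float = 0.8
    tails: str = "one"

    def __post_init__(self) -> None:
        if not (0 < self.power < 1):
            raise ValueError(f"power must lie in (0,1), got {self.power}")
        if self.effect_size_d <= 0:
            raise ValueError(f"effect_size_d must be > 0, got {self.effect_size_d}")
        if self.tails not in ("one", "two"):
            raise ValueError(f"tails must be 'one' or 'two', got {self.tails!r}")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("both group sizes must be >= 2")


def two_sample_t_from_summary(g1: GroupSummary, g2: GroupSummary) -> TwoSampleResult:
    """Pooled-variance Student t-test computed from group summaries alone.

    Equivalent to the raw-data test whenever raw data reproduce the summaries
    exactly.  Cohen's d uses the pooled SD as the standardizer, so
    ``sign(t) == sign(d)`` and d is invariant under common affine rescaling of
    both groups.

    Raises
    ------
    ValueError
        If both SDs are zero while the means coincide (0/0 statistic).
    """
    n1, n2 = g1.n, g2.n
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * g1.sd**2 + (n2 - 1) * g2.sd**2) / df
    diff = g1.mean - g2.mean
    if pooled_var == 0.0:
        if diff == 0.0:
            raise ValueError("undefined statistic: zero pooled variance and zero mean difference")
        # Degenerate but directional: infinite separation.
        t = np.inf if diff > 0 else -np.inf
        return TwoSampleResult(t=t, df=df, p=0.0, cohens_d=t)
    sd_pooled = float(np.sqrt(pooled_var))
    t = diff / (sd_pooled * np.sqrt(1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    d = diff / sd_pooled
    return TwoSampleResult(t=float(t), df=df, p=float(p), cohens_d=float(d))


def chi_square_2x2(counts) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table, without continuity correction.

    Parameters
    ----------
    counts : array-like of shape (2, 2)
        Nonnegative integer counts; every row and column sum must be positive.

    Returns
    -------
    (chi2, p) with p from the chi-square distribution with 1 df.
    """
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {table.shape}")
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("every row and column marginal must be positive")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


@dataclass
class NormalizationModel:
    """Per-feature z-scoring parameters estimated once and then frozen.

    Fitted on the pooled baseline (M1) sample — patients and controls together —
    and re-applied unchanged to follow-up (M2) data, so follow-up scores are
    expressed on the baseline scale.
    """

    means: pd.Series
    sds: pd.Series
    features: tuple[str, ...] = field(default_factory=tuple)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        """z-score the feature columns of ``table`` with the stored parameters."""
        missing = [f for f in self.features if f not in table.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        out = table.copy()
        for f in self.features:
            out[f] = (table[f] - self.means[f]) / self.sds[f]
        return out


def fit_normalization(
    table: pd.DataFrame, features: tuple[str, ...] = FEATURE_COLUMNS
) -> NormalizationModel:
    """Fit pooled z-normalization on a baseline feature table.

    ``table`` should contain the M1 rows of both groups.  SDs use the n-1
    denominator.  A constant feature (SD 0) is an error — it cannot be z-scored.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 subjects to fit normalization")
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    means = table[list(features)].mean()
    sds = table[list(features)].std(ddof=1)
    constant = [f for f in features if sds[f] == 0 or not np.isfinite(sds[f])]
    if constant:
        raise ValueError(f"constant feature(s), cannot z-score: {constant}")
    return NormalizationModel(means=means, sds=sds, features=tuple(features))


def screening_alpha(spec: PowerSpec) -> float:
    """Criterion alpha at which a two-sample t-test attains the requested power.

    For the design ``(n1, n2, d)`` the test statistic under the alternative is
    noncentral t with df = n1+n2-2 and noncentrality ncp = d*sqrt(n1*n2/(n1+n2)).
    The alpha returned is the significance level whose critical value the
    noncentral distribution exceeds with probability ``power`` — i.e. the
    loosest threshold guaranteeing that sensitivity.  Used to derive the
    voxelwise screening threshold for group-difference maps.
    """
    df = spec.n1 + spec.n2 - 2
    ncp = spec.effect_size_d * np.sqrt(spec.n1 * spec.n2 / (spec.n1 + spec.n2))
    # Critical value below which the noncentral t falls with prob 1 - power.
    t_crit = stats.nct.ppf(1.0 - spec.power, df, ncp)
    if not np.isfinite(t_crit):
        raise ValueError("requested power unreachable for this design")
    if spec.tails == "one":
        alpha = stats.t.sf(t_crit, df)
    else:
        # Two-tailed: power mass in the wrong tail is negligible for d > 0 but
        # the bisection below accounts for it exactly.
        alpha = _two_tailed_alpha(df, ncp, spec.power)
    alpha = float(alpha)
    if not (0 < alpha < 1):
        raise ValueError(f"no attainable alpha in (0,1) for this design (got {alpha})")
    return alpha


def _two_tailed_alpha(df: int, ncp: float, power: float) -> float:
    from scipy.optimize import brentq

    def power_at(alpha: float) -> float:
        tc = stats.t.isf(alpha / 2.0, df)
        return stats.nct.sf(tc, df, ncp) + stats.nct.cdf(-tc, df, ncp)

    return brentq(lambda a: power_at(a) - power, 1e-12, 1 - 1e-12, xtol=1e-15)


def table_report(
    table: pd.DataFrame,
    features: tuple[str, ...] = FEATURE_COLUMNS,
    group_col: str = "group",
    patient_label: str = "patient",
    control_label: str = "control",
) -> pd.DataFrame:
    """Per-feature group comparison in the layout of a clinical Table 1.

    One row per feature with patient and control mean (SD), pooled t, df,
    two-tailed p and Cohen's d (patients minus controls).
    """
    rows = []
    for f in features:
        pat = table.loc[table[group_col] == patient_label, f]
        hc = table.loc[table[group_col] == control_label, f]
        res = two_sample_t_from_summary(
            GroupSummary(pat.mean(), pat.std(ddof=1), len(pat)),
            GroupSummary(hc.mean(), hc.std(ddof=1), len(hc)),
        )
        rows.append(
            {
                "feature": f,
                "mean_patient": pat.mean(),
                "sd_patient": pat.std(ddof=1),
                "mean_control": hc.mean(),
                "sd_control": hc.std(ddof=1),
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "cohens_d": res.cohens_d,
            }
        )
    return pd.DataFrame(rows)
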