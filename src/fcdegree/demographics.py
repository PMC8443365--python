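"""Group-comparison statistics for the demographics table.

Continuous variables are compared with the pooled-variance two-sample t test
(computable from either raw vectors or printed mean/SD/n summaries);
categorical variables with Pearson's chi-square without continuity
correction. These are the variants that reproduce the printed statistics of
the emulated study's demographics table; Welch's t and the Yates-corrected
chi-square are available behind flags.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

#: variables summarized as mean +/- sd and compared with the pooled t test
CONTINUOUS_VARS = (
    "age",
    "education",
    "ybocs_total",
    "ybocs_obsession",
    "ybocs_compulsion",
    "hamd",
    "hama",
)


def two_sample_t_from_summary(
    m1: float, s1: float, n1: int,
    m2: float, s2: float, n2: int,
    welch: bool = False,
) -> tuple[float, float, float]:
    """Two-sample t test from group summaries; returns ``(t, df, p)``.

    Pooled variant (default): ``t = (m1 - m2) / (s_p sqrt(1/n1 + 1/n2))``
    with ``s_p^2 = ((n1-1)s1^2 + (n2-1)s2^2) / (n1 + n2 - 2)`` and
    ``df = n1 + n2 - 2``. ``welch=True`` uses the unequal-variance statistic
    with Satterthwaite df.
    """
    if n1 < 2 or n2 < 2:
        raise DataError("both groups need n >= 2")
    if s1 < 0 or s2 < 0 or (s1 == 0 and s2 == 0):
        raise DataError("standard deviations must be >= 0 and not both zero")
    if welch:
        v1, v2 = s1**2 / n1, s2**2 / n2
        t = (m1 - m2) / np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = n1 + n2 - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def two_sample_t(
    x1: np.ndarray, x2: np.ndarray, welch: bool = False
) -> tuple[float, float, float]:
    """Pooled (or Welch) two-sample t from raw vectors."""
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    return two_sample_t_from_summary(
        x1.mean(), x1.std(ddof=1), x1.size,
        x2.mean(), x2.std(ddof=1), x2.size,
        welch=welch,
    )


def chi_square_2x2(
    a: int, b: int, c: int, d: int, yates: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table ``[[a, b], [c, d]]``.

    Without continuity correction (default):
    ``chi2 = N (ad - bc)^2 / (r1 r2 c1 c2)``. Returns ``(chi2, df=1, p)``.
    """
    if min(a, b, c, d) < 0:
        raise DataError("counts must be non-negative")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = a + b + c + d
    if min(r1, r2, c1, c2) == 0:
        raise DataError("chi-square undefined: a table margin is zero")
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2.0)
    chi2 = n * diff**2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(chi2, 1))
    return float(chi2), 1, p


def demographics_table(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Demographics-table-shaped group comparison from a phenotype table.

    One row per variable with per-group mean +/- sd (or male/female counts),
    the test statistic and its p value. Illness duration is patient-only and
    reported without a test.
    """
    pat = phenotypes[phenotypes["group"] == "patient"]
    ctl = phenotypes[phenotypes["group"] == "control"]
    if len(pat) < 2 or len(ctl) < 2:
        raise DataError("need at least 2 subjects per group")
    rows = []
    for var in CONTINUOUS_VARS:
        x1 = pat[var].astype(float).dropna().to_numpy()
        x2 = ctl[var].astype(float).dropna().to_numpy()
        t, df, p = two_sample_t(x1, x2)
        rows.append(
            {
                "variable": var,
                "patients": f"{x1.mean():.2f} ± {x1.std(ddof=1):.2f}",
                "controls": f"{x2.mean():.2f} ± {x2.std(ddof=1):.2f}",
                "statistic": round(t, 2),
                "test": "pooled_t",
                "df": df,
                "p": p,
            }
        )
    a = int((pat["sex"] == "male").sum())
    b = int((pat["sex"] == "female").sum())
    c = int((ctl["sex"] == "male").sum())
    d = int((ctl["sex"] == "female").sum())
    chi2, df_chi, p_chi = chi_square_2x2(a, b, c, d)
    rows.append(
        {
            "variable": "sex",
            "patients": f"{a}/{b}",
            "controls": f"{c}/{d}",
            "statistic": round(chi2, 3),
            "test": "chi_square",
            "df": df_chi,
            "p": p_chi,
        }
    )
    dur = pat["illness_duration"].astype(float).dropna().to_numpy()
    if dur.size:
        rows.append(
            {
                "variable": "illness_duration",
                "patients": f"{dur.mean():.2f} ± {dur.std(ddof=1):.2f}",
                "controls": "",
                "statistic": np.nan,
                "test": "",
                "df": np.nan,
                "p": np.nan,
            }
        )
    return pd.DataFrame(rows)
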