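"""Questionnaire scores, Pearson correlation analyses and the generic
two-group comparison used for assay-level measures (protein carbonyls,
steroids).

Instruments: FSMC (motor and cognitive fatigue subscales, 10-50 each;
total = motor + cognitive, severe fatigue above 63), the SF-36 health
survey (0-100 domain scores) and the COMPASS-31 weighted autonomic
symptom score (0-100, taken as input — the weighting scheme is not
recomputed here). Correlations are Pearson's r with two-sided p from the
exact t transform, computed pairwise-complete per variable pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("mecfs_omics")

FSMC_SEVERE_CUTOFF = 63.0
SUBSCALE_RANGE = (10.0, 50.0)


class ScoreValidationError(ValueError):
    pass


@dataclass(frozen=True)
class CorrelationResult:
    x: str
    y: str
    n: int
    r: float
    p: float
    subset: str = "all"
    defined: bool = True


def score_fsmc(motor: float, cognitive: float) -> tuple[float, str]:
    """FSMC total = motor + cognitive; label 'severe' above 63."""
    lo, hi = SUBSCALE_RANGE
    for name, value in (("motor", motor), ("cognitive", cognitive)):
        if not lo <= value <= hi:
            raise ScoreValidationError(
                f"FSMC {name} subscale {value} outside the range [{lo}, {hi}]"
            )
    total = motor + cognitive
    return total, ("severe" if total > FSMC_SEVERE_CUTOFF else "not severe")


def pearson(x, y, x_name: str = "x", y_name: str = "y", subset: str = "all") -> CorrelationResult:
    """Pearson correlation with two-sided p from t = r sqrt((n-2)/(1-r^2)).

    Pairs with a missing member are dropped (pairwise-complete). Fewer than
    3 complete pairs or zero variance in either argument yields a flagged
    undefined result rather than NaN propagation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        if n >= 3:
            logger.warning("zero-variance input for pair (%s, %s)", x_name, y_name)
        return CorrelationResult(x_name, y_name, n, np.nan, np.nan, subset, defined=False)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(x_name, y_name, n, float(r), float(p), subset)


def correlation_matrix(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]],
    subset: str = "all",
    fdr: bool = False,
) -> pd.DataFrame:
    """Pearson correlations for a declared list of variable pairs.

    ``subset`` is 'all' or 'patients'; duplicate pair requests (in either
    order) are de-duplicated. Each pair uses its own complete cases, so n
    can differ between pairs. Raw p-values are reported; pass ``fdr=True``
    for an additional Benjamini-Hochberg column.
    """
    if subset not in ("all", "patients"):
        raise ValueError("subset must be 'all' or 'patients'")
    frame = table if subset == "all" else table[table["group"] == "patient"]
    seen, unique_pairs = set(), []
    for x_name, y_name in pairs:
        key = frozenset((x_name, y_name))
        if key not in seen:
            seen.add(key)
            unique_pairs.append((x_name, y_name))
    rows = []
    for x_name, y_name in unique_pairs:
        res = pearson(frame[x_name], frame[y_name], x_name, y_name, subset)
        if not res.defined:
            logger.warning("pair (%s, %s) skipped: %s", x_name, y_name,
                           "fewer than 3 complete cases" if res.n < 3 else "zero variance")
        rows.append(res.__dict__)
    out = pd.DataFrame(rows)
    if fdr and len(out):
        from statsmodels.stats.multitest import multipletests

        mask = out["p"].notna()
        adj = np.full(len(out), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
        out["p_fdr"] = adj
    return out


def group_compare(values, groups) -> dict:
    """Two-group comparison of a per-subject measure.

    Returns fold change (patient mean / control mean), Student t raw p and
    the per-group coefficient of variation (SD/mean). A non-positive group
    mean leaves the fold change flagged undefined (NaN).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    pat = values[groups == "patient"]
    con = values[groups == "control"]
    pat, con = pat[~np.isnan(pat)], con[~np.isnan(con)]
    if len(pat) < 2 or len(con) < 2:
        raise ValueError("need >= 2 subjects per group")
    _, p = stats.ttest_ind(pat, con, equal_var=True)
    fc = pat.mean() / con.mean() if pat.mean() > 0 and con.mean() > 0 else np.nan
    return {
        "fc": float(fc) if not np.isnan(fc) else np.nan,
        "raw_p": float(p),
        "cv_patient": float(pat.std(ddof=1) / pat.mean()) if pat.mean() != 0 else np.nan,
        "cv_control": float(con.std(ddof=1) / con.mean()) if con.mean() != 0 else np.nan,
        "n_patient": int(len(pat)),
        "n_control": int(len(con)),
    }


#: Correlation pairs mirroring the study's reported analyses.
DEFAULT_PAIRS = [
    ("fsmc_total", "compass31_weighted"),
    ("fsmc_total", "sf36_physical_functioning"),
    ("fsmc_total", "sf36_general_health"),
    ("compass31_weighted", "sf36_physical_functioning"),
]
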