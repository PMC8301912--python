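"""Targeted-metabolomics preprocessing and two-group screening.

Pipeline order is fixed: QC filter -> minimum/5 imputation -> generalised
log transform -> Pareto scaling; the fold-change screen runs on the raw
(pre-transform) concentrations while t-tests with Benjamini-Hochberg FDR
and PCA run on the transformed/scaled matrix. The QC filter is a
deliberately simple two-rule surrogate (QC replicate CV and per-compound
missingness, applied independently per acquisition platform) for the much
richer vendor QC cascade used upstream of tables like these.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("mecfs_omics")

META_COLUMNS = ("compound", "class", "platform")


@dataclass
class MetabolitePanel:
    """Wide compound x sample concentration table with QC replicates.

    ``data`` holds one row per compound with metadata columns (compound,
    class, platform) followed by sample and QC columns. Concentrations are
    positive where present; missing cells are NaN (left-censored below the
    limit of detection).
    """

    data: pd.DataFrame
    sample_cols: list[str]
    qc_cols: list[str]

    @classmethod
    def from_frame(cls, data: pd.DataFrame, qc_prefix: str = "QC") -> "MetabolitePanel":
        qc_cols = [c for c in data.columns if c.startswith(qc_prefix)]
        sample_cols = [c for c in data.columns if c not in META_COLUMNS and c not in qc_cols]
        missing_platform = data["platform"].isna()
        if missing_platform.any():
            bad = list(data.loc[missing_platform, "compound"].head())
            raise ValueError(f"compounds without platform assignment: {bad}")
        return cls(data=data.reset_index(drop=True), sample_cols=sample_cols, qc_cols=qc_cols)

    def values(self) -> np.ndarray:
        return self.data[self.sample_cols].to_numpy(dtype=float)

    def with_values(self, values: np.ndarray) -> "MetabolitePanel":
        data = self.data.copy()
        data[self.sample_cols] = values
        return MetabolitePanel(data=data, sample_cols=list(self.sample_cols),
                               qc_cols=list(self.qc_cols))


@dataclass
class PreprocessReport:
    n_input: int = 0
    n_retained: int = 0
    n_dropped_qc_cv: int = 0
    n_dropped_missing: int = 0
    missing_fraction_before: float = 0.0
    missing_fraction_after: float = 0.0
    imputation_constants: dict = field(default_factory=dict)
    glog_a: float | None = None
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_dropped_qc_cv": self.n_dropped_qc_cv,
            "n_dropped_missing": self.n_dropped_missing,
            "missing_fraction_before": self.missing_fraction_before,
            "missing_fraction_after": self.missing_fraction_after,
            "glog_a": self.glog_a,
            "notes": self.notes,
        }


def read_panel(path: str | Path) -> MetabolitePanel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    return MetabolitePanel.from_frame(pd.read_csv(path))


def qc_filter(
    panel: MetabolitePanel, max_qc_cv: float = 0.25, max_missing: float = 0.3
) -> tuple[MetabolitePanel, PreprocessReport]:
    """Drop compounds failing QC-replicate CV or missingness thresholds.

    LC and FIA compounds are filtered independently (the thresholds are the
    same, but drop counts are logged per platform). Without QC columns the
    CV rule is skipped with a warning.
    """
    data = panel.data
    report = PreprocessReport(n_input=len(data))
    values = panel.values()
    missing_frac = np.isnan(values).mean(axis=1)
    report.missing_fraction_before = float(np.isnan(values).mean())

    if panel.qc_cols:
        qc = data[panel.qc_cols].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            qc_cv = np.nanstd(qc, axis=1, ddof=1) / np.nanmean(qc, axis=1)
        fail_cv = qc_cv > max_qc_cv
    else:
        logger.warning("no QC columns present; QC-CV rule skipped")
        fail_cv = np.zeros(len(data), dtype=bool)
    fail_missing = missing_frac > max_missing
    keep = ~(fail_cv | fail_missing)

    for platform in data["platform"].unique():
        on = (data["platform"] == platform).to_numpy()
        logger.info(
            "platform %s: %d/%d compounds retained", platform, int((keep & on).sum()),
            int(on.sum()),
        )
    report.n_dropped_qc_cv = int(fail_cv.sum())
    report.n_dropped_missing = int((fail_missing & ~fail_cv).sum())
    report.n_retained = int(keep.sum())
    filtered = MetabolitePanel(
        data=data.loc[keep].reset_index(drop=True),
        sample_cols=list(panel.sample_cols),
        qc_cols=list(panel.qc_cols),
    )
    return filtered, report


def impute_min5(
    panel: MetabolitePanel, report: PreprocessReport | None = None
) -> MetabolitePanel:
    """Replace each missing cell by 1/5 of its compound's minimal positive
    observed value. Observed cells are untouched; a fully missing compound
    is an error."""
    values = panel.values()
    all_missing = np.isnan(values).all(axis=1)
    if all_missing.any():
        bad = list(panel.data.loc[all_missing, "compound"])
        raise ValueError(f"compound(s) with no observed value cannot be imputed: {bad}")
    with np.errstate(invalid="ignore"):
        fill = np.nanmin(np.where(values > 0, values, np.nan), axis=1) / 5.0
    out = np.where(np.isnan(values), fill[:, None], values)
    if report is not None:
        report.imputation_constants = {
            c: float(f)
            for c, f, had in zip(panel.data["compound"], fill, np.isnan(values).any(axis=1))
            if had
        }
        report.missing_fraction_after = float(np.isnan(out).mean())
    return panel.with_values(out)


def glog_transform(
    panel: MetabolitePanel, a: float | None = None, report: PreprocessReport | None = None
) -> MetabolitePanel:
    """Generalised log transform x -> log2((x + sqrt(x^2 + a^2)) / 2).

    Strictly increasing in x and ~log2(x) for x >> a. The offset ``a``
    defaults to one tenth of the smallest positive value in the matrix.
    """
    values = panel.values()
    if np.isnan(values).any():
        raise ValueError("glog requires an imputed (missing-free) panel")
    if a is None:
        positive = values[values > 0]
        if positive.size == 0:
            raise ValueError("no positive values to derive the glog offset from")
        a = float(positive.min()) / 10.0
    if a <= 0:
        raise ValueError(f"glog offset a must be > 0, got {a}")
    out = np.log2((values + np.sqrt(values**2 + a**2)) / 2.0)
    if report is not None:
        report.glog_a = float(a)
    return panel.with_values(out)


def pareto_scale(panel: MetabolitePanel) -> MetabolitePanel:
    """Per-compound mean-centring and division by sqrt(SD).

    After scaling a compound's values have mean 0 and SD equal to the
    square root of the original SD. A zero-variance compound is centred
    but left unscaled, with a warning.
    """
    values = panel.values()
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    zero_var = (sd == 0) | np.isnan(sd)
    if zero_var.any():
        logger.warning(
            "%d zero-variance compound(s) centred but not scaled", int(zero_var.sum())
        )
    denom = np.where(zero_var, 1.0, np.sqrt(sd))
    return panel.with_values((values - mean) / denom)


def preprocess(
    panel: MetabolitePanel,
    max_qc_cv: float = 0.25,
    max_missing: float = 0.3,
    glog_a: float | None = None,
) -> tuple[MetabolitePanel, MetabolitePanel, PreprocessReport]:
    """QC filter -> impute -> glog -> Pareto. Returns
    ``(raw_filtered, scaled, report)``: the QC-passing raw panel (for the
    fold-change screen) and the transformed/scaled panel (for t/FDR and
    PCA)."""
    filtered, report = qc_filter(panel, max_qc_cv=max_qc_cv, max_missing=max_missing)
    imputed = impute_min5(filtered, report)
    transformed = glog_transform(imputed, a=glog_a, report=report)
    scaled = pareto_scale(transformed)
    return imputed, scaled, report


def _group_columns(panel: MetabolitePanel, groups: pd.DataFrame) -> tuple[list[str], list[str]]:
    lookup = groups.set_index("sample")["group"]
    patients = [c for c in panel.sample_cols if lookup.get(c) == "patient"]
    controls = [c for c in panel.sample_cols if lookup.get(c) == "control"]
    return patients, controls


def fc_screen(
    panel: MetabolitePanel,
    groups: pd.DataFrame,
    upper: float = 1.3,
    lower: float = 0.77,
) -> pd.DataFrame:
    """Flag compounds whose patient/control ratio of group means on the raw
    concentration scale is strictly > upper or strictly < lower."""
    patients, controls = _group_columns(panel, groups)
    pat = panel.data[patients].to_numpy(dtype=float)
    con = panel.data[controls].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.nanmean(pat, axis=1) / np.nanmean(con, axis=1)
    flagged = (fc > upper) | (fc < lower)
    return pd.DataFrame(
        {
            "compound": panel.data["compound"].to_numpy(),
            "platform": panel.data["platform"].to_numpy(),
            "fc": fc,
            "flagged": flagged,
        }
    )


def t_fdr_screen(panel: MetabolitePanel, groups: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """Two-sample t per compound on the transformed/scaled values with
    Benjamini-Hochberg adjustment.

    Compounds with raw p < 0.05 but adjusted p >= q are labelled
    ``nominal_only`` — nominally different but not surviving FDR.
    """
    patients, controls = _group_columns(panel, groups)
    pat = panel.data[patients].to_numpy(dtype=float)
    con = panel.data[controls].to_numpy(dtype=float)
    _, p = stats.ttest_ind(pat, con, axis=1, equal_var=True)
    p = np.where(np.isnan(p), 1.0, p)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "compound": panel.data["compound"].to_numpy(),
            "raw_p": p,
            "p_fdr": p_adj,
            "significant": p_adj < q,
            "nominal_only": (p < 0.05) & (p_adj >= q),
        }
    )


def pca(panel: MetabolitePanel, k: int = 2) -> dict:
    """Principal components of the scaled matrix by SVD.

    Samples are observations (columns of the panel become rows of the data
    matrix), compounds are features. Returns scores (samples x k),
    orthonormal loadings (compounds x k) and explained-variance fractions.
    """
    X = panel.values().T  # samples x compounds, already column-centred per compound
    n, m = X.shape
    if not 1 <= k <= min(n, m):
        raise ValueError(f"k must lie in [1, {min(n, m)}], got {k}")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    explained = (s**2) / (s**2).sum()
    return {
        "scores": pd.DataFrame(
            scores, index=panel.sample_cols, columns=[f"PC{i + 1}" for i in range(k)]
        ),
        "loadings": pd.DataFrame(
            loadings, index=panel.data["compound"], columns=[f"PC{i + 1}" for i in range(k)]
        ),
        "explained_variance": explained[:k],
    }


def cluster_linkage(panel: MetabolitePanel) -> np.ndarray:
    """Ward linkage on Euclidean sample distances (rendering is out of
    scope; this exposes the computation only)."""
    from scipy.cluster.hierarchy import linkage

    return linkage(panel.values().T, method="ward", metric="euclidean")
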