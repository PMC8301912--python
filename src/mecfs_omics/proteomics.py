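"""Differential protein-abundance screen for TMT-style quantification tables.

The screen follows common small-cohort TMT practice: proteins are first
filtered on identification quality (minimum unique peptides and
quantitative scans), fold-change thresholds are derived from the control
group's own technical variability (upper = 1 + 2 x median control CV,
lower = its reciprocal), and a protein is called differentially altered
(DAP) when it passes both the fold-change criterion and a Student t-test
on log2 abundances at alpha. Subset summaries cover the mitochondrial
proteome (gene-list match), pathway group tests (one-sample t of member
log2 fold changes) and CD surface-marker reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("mecfs_omics")

META_COLUMNS = ("accession", "gene", "unique_peptides", "quant_scans", "mitochondrial")


class ThresholdError(ValueError):
    pass


@dataclass(frozen=True)
class FcThresholds:
    """Control-CV-derived fold-change thresholds.

    ``upper = 1 + 2 * median(control CV)``; ``lower = 1 / upper`` so the
    criterion is symmetric on the log scale. Full precision is used for
    classification; rounding to two decimals is display-only.
    """

    upper: float
    lower: float
    source_median_cv: float

    def __post_init__(self) -> None:
        if self.upper < 1 or not 0 < self.lower <= 1:
            raise ThresholdError(
                f"invalid thresholds upper={self.upper}, lower={self.lower}"
            )

    def display(self) -> tuple[float, float]:
        return round(self.upper, 2), round(self.lower, 2)


def sample_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def _split_groups(groups: pd.DataFrame) -> tuple[list[str], list[str]]:
    patients = list(groups.loc[groups["group"] == "patient", "sample"])
    controls = list(groups.loc[groups["group"] == "control", "sample"])
    return patients, controls


def filter_quantifiable(
    table: pd.DataFrame, min_peptides: int = 2, min_scans: int = 5
) -> pd.DataFrame:
    """Keep proteins with >= min_peptides unique peptides and >= min_scans
    quantitative scans (both bounds inclusive). Idempotent."""
    keep = (table["unique_peptides"] >= min_peptides) & (table["quant_scans"] >= min_scans)
    removed = int((~keep).sum())
    if removed:
        logger.info("inclusion filter removed %d of %d proteins", removed, len(table))
    return table.loc[keep].reset_index(drop=True)


def derive_fc_thresholds(table: pd.DataFrame, groups: pd.DataFrame) -> FcThresholds:
    """Fold-change thresholds from the control group's per-protein CVs.

    CV = SD / mean over control samples per protein; the upper threshold is
    one plus twice the median CV, the lower its reciprocal.
    """
    _, controls = _split_groups(groups)
    if len(controls) < 2:
        raise ThresholdError("need >= 2 control samples to derive CV-based thresholds")
    block = table[controls].to_numpy(dtype=float)
    mean = np.nanmean(block, axis=1)
    sd = np.nanstd(block, axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    median_cv = float(np.nanmedian(cv))
    upper = 1.0 + 2.0 * median_cv
    if median_cv == 0:
        logger.warning("median control CV is 0; degenerate thresholds (1, 1)")
    return FcThresholds(upper=upper, lower=1.0 / upper, source_median_cv=median_cv)


def test_protein(
    row: pd.Series,
    thresholds: FcThresholds,
    patients: list[str],
    controls: list[str],
    alpha: float = 0.05,
) -> dict:
    """Fold change and Student t for one protein row.

    FC is the ratio of arithmetic group means on the linear scale; the t
    test runs on log2 abundances. Threshold comparisons are inclusive
    (FC >= upper or FC <= lower) at full precision.
    """
    pat = row[patients].astype(float).dropna().to_numpy()
    con = row[controls].astype(float).dropna().to_numpy()
    out = {
        "accession": row.get("accession"),
        "gene": row.get("gene"),
        "fc": np.nan,
        "raw_p": np.nan,
        "passes_fc": False,
        "passes_p": False,
        "is_dap": False,
        "direction": "none",
        "testable": True,
    }
    if len(pat) < 2 or len(con) < 2:
        out["testable"] = False
        return out
    fc = pat.mean() / con.mean()
    _, p = stats.ttest_ind(np.log2(pat), np.log2(con), equal_var=True)
    out["fc"] = float(fc)
    out["raw_p"] = float(p)
    out["passes_fc"] = bool(fc >= thresholds.upper or fc <= thresholds.lower)
    out["passes_p"] = bool(p < alpha)
    out["is_dap"] = out["passes_fc"] and out["passes_p"]
    if out["is_dap"]:
        out["direction"] = "up" if fc >= thresholds.upper else "down"
    return out


def screen_proteins(
    table: pd.DataFrame,
    groups: pd.DataFrame,
    thresholds: FcThresholds | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run :func:`test_protein` over a (filtered) table; vectorised.

    If ``thresholds`` is None they are derived from the controls first.
    """
    patients, controls = _split_groups(groups)
    if thresholds is None:
        thresholds = derive_fc_thresholds(table, groups)
    pat = table[patients].to_numpy(dtype=float)
    con = table[controls].to_numpy(dtype=float)
    pat_mean = np.nanmean(pat, axis=1)
    con_mean = np.nanmean(con, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = pat_mean / con_mean
        _, p = stats.ttest_ind(np.log2(pat), np.log2(con), axis=1, equal_var=True)
    n_pat = np.sum(~np.isnan(pat), axis=1)
    n_con = np.sum(~np.isnan(con), axis=1)
    testable = (n_pat >= 2) & (n_con >= 2)
    passes_fc = testable & ((fc >= thresholds.upper) | (fc <= thresholds.lower))
    passes_p = testable & (p < alpha)
    is_dap = passes_fc & passes_p
    direction = np.where(is_dap & (fc >= thresholds.upper), "up",
                         np.where(is_dap, "down", "none"))
    return pd.DataFrame(
        {
            "accession": table["accession"].to_numpy(),
            "gene": table["gene"].to_numpy(),
            "fc": fc,
            "raw_p": p,
            "passes_fc": passes_fc,
            "passes_p": passes_p,
            "is_dap": is_dap,
            "direction": direction,
            "testable": testable,
        }
    )


def classify_daps(results: pd.DataFrame) -> dict:
    """Summarise a screen: total/up/down counts and the DAP table sorted by
    ascending raw p."""
    daps = results[results["is_dap"]].sort_values("raw_p", kind="stable").reset_index(drop=True)
    return {
        "n_total": int(len(daps)),
        "n_up": int((daps["direction"] == "up").sum()),
        "n_down": int((daps["direction"] == "down").sum()),
        "daps": daps,
    }


def apply_dap_criteria(
    results: pd.DataFrame, thresholds: FcThresholds, alpha: float = 0.05
) -> pd.DataFrame:
    """Re-classify an existing (fc, raw_p) table against thresholds.

    Used for externally reported fold-change/p tables where the underlying
    abundances are unavailable. Comparisons are inclusive, like
    :func:`test_protein`.
    """
    out = results.copy()
    out["passes_fc"] = (out["fc"] >= thresholds.upper) | (out["fc"] <= thresholds.lower)
    out["passes_p"] = out["raw_p"] < alpha
    out["is_dap"] = out["passes_fc"] & out["passes_p"]
    out["direction"] = np.where(
        out["is_dap"] & (out["fc"] >= thresholds.upper),
        "up",
        np.where(out["is_dap"], "down", "none"),
    )
    return out


def mito_summary(results: pd.DataFrame, mito_genes: list[str] | set[str]) -> dict:
    """Median fold change of the mitochondrial subset (gene-symbol match)."""
    mito_genes = set(mito_genes)
    subset = results[results["gene"].isin(mito_genes)].copy()
    if subset.empty:
        logger.warning("no quantified protein matched the mitochondrial gene list")
        return {"n_mito": 0, "median_fc": np.nan, "table": subset}
    return {
        "n_mito": int(len(subset)),
        "median_fc": float(np.nanmedian(subset["fc"])),
        "table": subset.reset_index(drop=True),
    }


def pathway_group_test(results: pd.DataFrame, pathways: dict[str, list[str]]) -> pd.DataFrame:
    """One-sample Student t of member proteins' log2 fold changes against 0.

    One row per pathway (pathway, n_proteins, mean_log2_fc, t, p); pathways
    with fewer than two members carrying a defined FC are skipped.
    """
    by_gene = results.dropna(subset=["fc"]).set_index("gene")["fc"]
    rows = []
    for pathway, genes in pathways.items():
        fcs = by_gene.reindex([g for g in genes if g in by_gene.index]).dropna()
        if len(fcs) < 2:
            logger.warning("pathway %s skipped: <2 mapped proteins with defined FC", pathway)
            continue
        log_fc = np.log2(fcs.to_numpy())
        if np.allclose(log_fc.std(ddof=1), 0) and np.allclose(log_fc.mean(), 0):
            t, p = 0.0, 1.0  # exactly-null members: no evidence of effect
        else:
            t, p = stats.ttest_1samp(log_fc, 0.0)
        rows.append(
            {
                "pathway": pathway,
                "n_proteins": len(fcs),
                "mean_log2_fc": float(log_fc.mean()),
                "t": float(t),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def cd_marker_check(
    table: pd.DataFrame, groups: pd.DataFrame, cd_genes: list[str]
) -> pd.DataFrame:
    """Per-marker group comparison for CD surface proteins; report-only.

    Markers absent from the table are listed with ``present=False``.
    """
    patients, controls = _split_groups(groups)
    by_gene = table.set_index("gene")
    rows = []
    for gene in cd_genes:
        if gene not in by_gene.index:
            rows.append({"gene": gene, "present": False, "fc": np.nan, "raw_p": np.nan})
            continue
        row = by_gene.loc[gene]
        if isinstance(row, pd.DataFrame):
            row = row.iloc[0]
        pat = row[patients].astype(float).to_numpy()
        con = row[controls].astype(float).to_numpy()
        _, p = stats.ttest_ind(np.log2(pat), np.log2(con), equal_var=True)
        rows.append(
            {
                "gene": gene,
                "present": True,
                "fc": float(pat.mean() / con.mean()),
                "raw_p": float(p),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_protein_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    return pd.read_csv(path, sep="\t")


def read_groups(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    return pd.read_csv(path)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene list file not found: {path}")
    out = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_pathway_map(path: str | Path) -> dict[str, list[str]]:
    """TSV of (pathway, gene) rows -> mapping pathway -> gene list."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"pathway map file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    return {p: list(sub["gene"]) for p, sub in df.groupby("pathway")}
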