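"""Extracellular-flux analysis: from per-well OCR/ECAR traces to a
14-parameter bioenergetic profile and group statistics.

The assay measures oxygen consumption rate (OCR, pmol O2/min) and
extracellular acidification rate (ECAR, mpH/min) in three measurement
cycles per section (basal, after injection 1, after injection 2) under
three injection schemes:

* scheme A — oligomycin, then rotenone/antimycin A (mito stress, part 1)
* scheme B — FCCP, then rotenone/antimycin A (mito stress, part 2)
* scheme C — oligomycin, then 2-deoxy-D-glucose (glycolysis stress)

Scheme A yields basal mitochondrial respiration, ATP-linked respiration,
proton leak and coupling efficiency; scheme B maximal respiration and
spare capacity; scheme C the glycolytic parameters from ECAR. Replicate
wells are pooled per subject (mean and sample SD), and the two groups are
compared per parameter by Student's t with Bonferroni correction across
the 14-parameter family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("mecfs_omics")

SCHEMES = ("A", "B", "C")
SECTIONS = ("basal", "inj1", "inj2")

#: The canonical 14-parameter bioenergetic profile, in reporting order.
PARAMETERS = (
    "basal_respiration",
    "nonmito_respiration",
    "atp_linked_respiration",
    "proton_leak",
    "coupling_efficiency",
    "maximal_respiration",
    "spare_respiratory_capacity",
    "atp_linked_to_maximal",
    "basal_ecar",
    "glycolysis",
    "glycolytic_capacity",
    "glycolytic_reserve",
    "nonglycolytic_acidification",
    "ocr_ecar_ratio",
)

#: Parameters computable per well, by scheme.
SCHEME_PARAMETERS = {
    "A": (
        "nonmito_respiration",
        "basal_respiration",
        "atp_linked_respiration",
        "proton_leak",
        "coupling_efficiency",
    ),
    "B": ("maximal_respiration", "spare_respiratory_capacity"),
    "C": (
        "basal_ecar",
        "nonglycolytic_acidification",
        "glycolysis",
        "glycolytic_capacity",
        "glycolytic_reserve",
    ),
}

#: Cross-scheme parameters computed from subject-level means.
CROSS_SCHEME_PARAMETERS = ("atp_linked_to_maximal", "ocr_ecar_ratio")


class FluxValidationError(ValueError):
    """Trace/layout tables violate the plate contract."""


class ParameterContractError(KeyError):
    """A parameter was requested from a scheme that cannot provide it."""


@dataclass(frozen=True)
class SummaryPolicy:
    """How the 3 cycles of each section are collapsed to one number.

    The default follows report-generator convention: the basal section is
    averaged, the plateau after each inhibitor is taken at its extreme
    (minimum after oligomycin, rotenone/antimycin and 2-DG; maximum after
    FCCP), which is robust to injection lag.
    """

    rules: dict = field(
        default_factory=lambda: {
            ("A", "basal"): "mean",
            ("A", "inj1"): "min",
            ("A", "inj2"): "min",
            ("B", "basal"): "mean",
            ("B", "inj1"): "max",
            ("B", "inj2"): "min",
            ("C", "basal"): "mean",
            ("C", "inj1"): "min",
            ("C", "inj2"): "min",
        }
    )

    def __post_init__(self) -> None:
        allowed = {"mean", "min", "max"}
        for key, rule in self.rules.items():
            if rule not in allowed:
                raise ValueError(f"summary rule for {key} must be one of {allowed}, got {rule!r}")

    @classmethod
    def mean_everywhere(cls) -> "SummaryPolicy":
        return cls({(s, sec): "mean" for s in SCHEMES for sec in SECTIONS})

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SummaryPolicy":
        base = cls().rules.copy()
        for key, rule in mapping.items():
            scheme, section = (key.split(":") if isinstance(key, str) else key)
            base[(scheme, section)] = rule
        return cls(base)


@dataclass
class FluxPlate:
    """Validated per-well traces plus the well -> (subject, group, scheme) layout."""

    traces: pd.DataFrame
    layout: pd.DataFrame
    n_cycles: int = 3

    @classmethod
    def from_frames(
        cls, traces: pd.DataFrame, layout: pd.DataFrame, allow_negative: bool = False
    ) -> "FluxPlate":
        traces = traces.copy()
        layout = layout.copy()
        required_trace = {"well", "scheme", "section", "cycle", "ocr", "ecar"}
        required_layout = {"well", "subject", "group", "scheme"}
        if missing := required_trace - set(traces.columns):
            raise FluxValidationError(f"trace table is missing columns {sorted(missing)}")
        if missing := required_layout - set(layout.columns):
            raise FluxValidationError(f"layout table is missing columns {sorted(missing)}")

        bad_schemes = set(traces["scheme"]) - set(SCHEMES)
        if bad_schemes:
            raise FluxValidationError(f"unknown schemes {sorted(bad_schemes)}")
        bad_sections = set(traces["section"]) - set(SECTIONS)
        if bad_sections:
            raise FluxValidationError(f"unknown sections {sorted(bad_sections)}")

        trace_wells = set(traces["well"])
        layout_wells = set(layout["well"])
        if orphans := sorted(layout_wells - trace_wells):
            raise FluxValidationError(f"layout references wells with no trace: {orphans}")
        if orphans := sorted(trace_wells - layout_wells):
            raise FluxValidationError(f"trace contains wells absent from layout: {orphans}")
        if layout["well"].duplicated().any():
            dupes = sorted(layout.loc[layout["well"].duplicated(), "well"])
            raise FluxValidationError(f"duplicate wells in layout: {dupes}")

        counts = traces.groupby(["well", "section"], observed=True).size()
        for well in trace_wells:
            present = set(counts.loc[well].index) if well in counts.index.levels[0] else set()
            if absent := set(SECTIONS) - present:
                raise FluxValidationError(
                    f"well {well} is missing section(s) {sorted(absent)}"
                )
        cycle_counts = counts.unique()
        if len(cycle_counts) != 1:
            raise FluxValidationError(
                f"ragged cycle counts across well sections: {sorted(cycle_counts)}"
            )
        n_cycles = int(cycle_counts[0])
        if n_cycles < 1:
            raise FluxValidationError("at least one cycle per section is required")

        if not allow_negative and (traces["ocr"] < 0).any():
            bad = traces.loc[traces["ocr"] < 0, "well"].unique()[:5]
            raise FluxValidationError(
                f"negative OCR values (e.g. wells {list(bad)}); pass allow_negative=True "
                "to tolerate small instrument-noise negatives"
            )
        return cls(traces=traces, layout=layout, n_cycles=n_cycles)


def read_flux_plate(
    trace_path: str | Path, layout_path: str | Path, allow_negative: bool = False
) -> FluxPlate:
    """Read and validate a flux plate from a trace CSV and a layout CSV."""
    trace_path, layout_path = Path(trace_path), Path(layout_path)
    for path in (trace_path, layout_path):
        if not path.exists():
            raise FileNotFoundError(f"no such file: {path}")
    traces = pd.read_csv(trace_path)
    layout = pd.read_csv(layout_path)
    return FluxPlate.from_frames(traces, layout, allow_negative=allow_negative)


def summarise_sections(plate: FluxPlate, policy: SummaryPolicy | None = None) -> pd.DataFrame:
    """Collapse each well's cycles to one OCR and one ECAR value per section.

    Returns a long frame (well, subject, group, scheme, section, ocr, ecar);
    the same rule is applied to both signals of a section.
    """
    policy = policy or SummaryPolicy()
    traces = plate.traces.drop(columns=["subject", "group"], errors="ignore")
    merged = traces.merge(plate.layout[["well", "subject", "group"]], on="well", how="left")
    pieces = []
    for (scheme, section), rule in policy.rules.items():
        sub = merged[(merged["scheme"] == scheme) & (merged["section"] == section)]
        if sub.empty:
            continue
        agg = sub.groupby(["well", "subject", "group", "scheme"], as_index=False, observed=True)[
            ["ocr", "ecar"]
        ].agg(rule)
        agg["section"] = section
        pieces.append(agg)
    out = pd.concat(pieces, ignore_index=True)
    return out[["well", "subject", "group", "scheme", "section", "ocr", "ecar"]].sort_values(
        ["well", "section"], kind="stable"
    ).reset_index(drop=True)


def _safe_ratio(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    return out


def well_parameters(
    scheme: str,
    basal_ocr: float,
    inj1_ocr: float,
    inj2_ocr: float,
    basal_ecar: float,
    inj1_ecar: float,
    inj2_ecar: float,
    parameters: tuple[str, ...] | None = None,
) -> dict[str, float]:
    """Scheme-level bioenergetic parameters from one well's section summaries.

    Scheme A (rot/AA plateau = non-mito respiration):
    ``basal_respiration = basal - nonmito``, ``atp_linked = basal - post-oligo``,
    ``proton_leak = post-oligo - nonmito``,
    ``coupling_efficiency = 100 * atp_linked / basal_respiration``.
    Scheme B: ``maximal = post-FCCP - nonmito``, ``spare = maximal /
    basal_respiration`` (both corrected with B's own rot/AA plateau).
    Scheme C (ECAR): ``nonglycolytic = post-2DG``, ``glycolysis = basal -
    nonglycolytic``, ``capacity = post-oligo - nonglycolytic``,
    ``reserve = capacity / glycolysis``.

    A ratio with a non-positive denominator is returned as NaN (flagged
    undefined), never as a silent number. Requesting a parameter a scheme
    cannot provide raises :class:`ParameterContractError`.
    """
    if scheme not in SCHEME_PARAMETERS:
        raise ParameterContractError(f"unknown scheme {scheme!r}")
    if scheme == "A":
        nonmito = inj2_ocr
        basal_resp = basal_ocr - nonmito
        atp_linked = basal_ocr - inj1_ocr
        values = {
            "nonmito_respiration": nonmito,
            "basal_respiration": basal_resp,
            "atp_linked_respiration": atp_linked,
            "proton_leak": inj1_ocr - nonmito,
            "coupling_efficiency": float(_safe_ratio(100.0 * atp_linked, basal_resp)),
        }
    elif scheme == "B":
        nonmito = inj2_ocr
        basal_resp = basal_ocr - nonmito
        maximal = inj1_ocr - nonmito
        values = {
            "maximal_respiration": maximal,
            "spare_respiratory_capacity": float(_safe_ratio(maximal, basal_resp)),
        }
    else:
        nonglyco = inj2_ecar
        glycolysis = basal_ecar - nonglyco
        capacity = inj1_ecar - nonglyco
        values = {
            "basal_ecar": basal_ecar,
            "nonglycolytic_acidification": nonglyco,
            "glycolysis": glycolysis,
            "glycolytic_capacity": capacity,
            "glycolytic_reserve": float(_safe_ratio(capacity, glycolysis)),
        }
    if parameters is not None:
        foreign = set(parameters) - set(values)
        if foreign:
            raise ParameterContractError(
                f"parameter(s) {sorted(foreign)} are not computable from scheme {scheme}"
            )
        values = {name: values[name] for name in parameters}
    return values


def compute_well_parameters(summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-well parameters for every well in a section-summary frame.

    Returns a long frame (well, subject, group, scheme, parameter, value).
    Helper rows ``_basal_ocr`` / ``_basal_ecar`` (schemes A and B only) carry
    the raw basal signals forward for the cross-scheme OCR/ECAR ratio and
    are consumed by :func:`aggregate_subject`.
    """
    wide = summaries.pivot_table(
        index=["well", "subject", "group", "scheme"],
        columns="section",
        values=["ocr", "ecar"],
        observed=True,
    )
    wide.columns = [f"{sig}_{sec}" for sig, sec in wide.columns]
    wide = wide.reset_index()
    rows = []
    for rec in wide.itertuples(index=False):
        values = well_parameters(
            rec.scheme,
            rec.ocr_basal,
            rec.ocr_inj1,
            rec.ocr_inj2,
            rec.ecar_basal,
            rec.ecar_inj1,
            rec.ecar_inj2,
        )
        if rec.scheme in ("A", "B"):
            values["_basal_ocr"] = rec.ocr_basal
            values["_basal_ecar"] = rec.ecar_basal
        for name, value in values.items():
            rows.append((rec.well, rec.subject, rec.group, rec.scheme, name, value))
    return pd.DataFrame(
        rows, columns=["well", "subject", "group", "scheme", "parameter", "value"]
    )


def aggregate_subject(well_params: pd.DataFrame) -> pd.DataFrame:
    """Pool replicate wells into one profile row per subject and parameter.

    Per-well parameters get their mean and sample SD (ddof=1; SD is NaN for
    a single well). Cross-scheme ratios are computed from the subject-level
    means, since the schemes live in different wells and admit no pairing:
    ``atp_linked_to_maximal`` = mean ATP-linked (A) / mean maximal (B), and
    ``ocr_ecar_ratio`` = mean basal OCR / mean basal ECAR over A and B wells.
    A subject missing a whole scheme keeps its other parameters; the absent
    ones are logged and omitted.
    """
    stats_df = (
        well_params.groupby(["subject", "group", "parameter"], as_index=False, observed=True)[
            "value"
        ]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n_wells="count")
    )
    helper = stats_df[stats_df["parameter"].str.startswith("_")]
    profile = stats_df[~stats_df["parameter"].str.startswith("_")].copy()

    cross_rows = []
    for (subject, group), sub in profile.groupby(["subject", "group"], observed=True):
        by_param = sub.set_index("parameter")["mean"]
        hsub = helper[(helper["subject"] == subject)].set_index("parameter")["mean"]
        atp = by_param.get("atp_linked_respiration", np.nan)
        maximal = by_param.get("maximal_respiration", np.nan)
        ratio = atp / maximal if maximal and maximal > 0 else np.nan
        cross_rows.append((subject, group, "atp_linked_to_maximal", ratio, np.nan, 0))
        bo, be = hsub.get("_basal_ocr", np.nan), hsub.get("_basal_ecar", np.nan)
        oe = bo / be if be and be > 0 else np.nan
        cross_rows.append((subject, group, "ocr_ecar_ratio", oe, np.nan, 0))
        if absent := set(PARAMETERS) - set(by_param.index) - set(CROSS_SCHEME_PARAMETERS):
            logger.warning(
                "subject %s lacks wells for parameter(s) %s; omitted", subject, sorted(absent)
            )
    cross = pd.DataFrame(
        cross_rows, columns=["subject", "group", "parameter", "mean", "sd", "n_wells"]
    )
    out = pd.concat([profile, cross], ignore_index=True)
    out["parameter"] = pd.Categorical(out["parameter"], categories=PARAMETERS, ordered=True)
    out = out.dropna(subset=["parameter"])
    return out.sort_values(["subject", "parameter"], kind="stable").reset_index(drop=True)


def compare_groups(
    profiles: pd.DataFrame, welch: bool = False, n_family: int = len(PARAMETERS)
) -> pd.DataFrame:
    """Patient-vs-control comparison of every profile parameter.

    For each parameter: group means/SDs over subject-level means, fold
    change = patient mean / control mean, two-sample Student t (equal
    variance; Welch behind the flag) raw p, and Bonferroni-adjusted p
    across the 14-parameter family (``min(1, p * 14)``). Subjects in
    groups other than patient/control (e.g. a calibrator sample) are
    excluded from the statistics. Parameters with fewer than two defined
    subjects in either group are skipped with a warning.
    """
    usable = profiles[profiles["group"].isin(["patient", "control"])]
    rows = []
    for parameter, sub in usable.groupby("parameter", observed=True):
        pat = sub.loc[sub["group"] == "patient", "mean"].dropna().to_numpy()
        con = sub.loc[sub["group"] == "control", "mean"].dropna().to_numpy()
        if len(pat) < 2 or len(con) < 2:
            logger.warning(
                "parameter %s skipped: fewer than 2 defined values in a group", parameter
            )
            continue
        t, p = stats.ttest_ind(pat, con, equal_var=not welch)
        fc = pat.mean() / con.mean() if con.mean() > 0 else np.nan
        rows.append(
            {
                "parameter": parameter,
                "control_mean": con.mean(),
                "control_sd": con.std(ddof=1),
                "patient_mean": pat.mean(),
                "patient_sd": pat.std(ddof=1),
                "fold_change": fc,
                "t": float(t),
                "p_raw": float(p),
                "p_bonferroni": min(1.0, float(p) * n_family),
                "n_patient": len(pat),
                "n_control": len(con),
            }
        )
    return pd.DataFrame(rows)


def profile_plate(
    plate: FluxPlate, policy: SummaryPolicy | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full pipeline: summarise sections, derive well parameters, pool per
    subject and compare groups. Returns ``(profiles, comparison)``."""
    summaries = summarise_sections(plate, policy)
    params = compute_well_parameters(summaries)
    profiles = aggregate_subject(params)
    comparison = compare_groups(profiles)
    return profiles, comparison
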