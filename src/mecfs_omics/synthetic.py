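"""Synthetic cohort generator for the four data layers of the pipeline.

Emulates a small ME/CFS case-control study: extracellular-flux plates
(OCR/ECAR traces under three injection schemes), a TMT-style protein
quantification table with spiked differential proteins, a targeted
metabolomics panel with left-censored missingness, and questionnaire
domain scores driven by a latent disease-severity variable.

Every generator is deterministic given :class:`CohortSpec` (including its
seed) and returns a :class:`GroundTruth` alongside the data so that
downstream estimators can be checked by parameter recovery.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("mecfs_omics")

SCHEMES = ("A", "B", "C")
SECTIONS = ("basal", "inj1", "inj2")
N_CYCLES = 3

#: What is injected in each scheme; inj2 of A and B leaves only
#: non-mitochondrial respiration, inj2 of C only non-glycolytic acidification.
SCHEME_INJECTIONS = {
    "A": ("oligomycin", "rotenone/antimycin"),
    "B": ("FCCP", "rotenone/antimycin"),
    "C": ("oligomycin", "2-DG"),
}

# Questionnaire instrument calibration: (control mean, patient mean, lo, hi).
# Group means mirror a small published ME/CFS cohort; ranges are the
# instruments' score ranges (FSMC subscales 10-50, SF-36 domains 0-100,
# COMPASS-31 weighted total 0-100).
INSTRUMENT_CALIBRATION = {
    "fsmc_motor": (10.3, 37.8, 10.0, 50.0),
    "fsmc_cognitive": (11.8, 37.0, 10.0, 50.0),
    "sf36_physical_functioning": (100.0, 34.0, 0.0, 100.0),
    "sf36_role_physical": (100.0, 5.0, 0.0, 100.0),
    "sf36_role_emotional": (100.0, 100.0, 0.0, 100.0),
    "sf36_energy_fatigue": (75.0, 24.0, 0.0, 100.0),
    "sf36_emotional_wellbeing": (93.0, 62.0, 0.0, 100.0),
    "sf36_social_functioning": (97.0, 35.0, 0.0, 100.0),
    "sf36_pain": (91.0, 45.0, 0.0, 100.0),
    "sf36_general_health": (85.0, 25.0, 0.0, 100.0),
    "sf36_health_change": (50.0, 55.0, 0.0, 100.0),
    "compass31_weighted": (1.6, 35.5, 0.0, 100.0),
}


class SpecValidationError(ValueError):
    """A CohortSpec field violates its invariant."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror the study conditions this simulator emulates:
    6 patients vs 4 controls, a 0.87 multiplicative effect on the patients'
    ATP-linked respiration fraction, 13 up- and 9 down-spiked proteins among
    ~3300 quantified, 1.2% metabolite missingness, and questionnaire scores
    whose between-instrument correlation targets 0.93.
    """

    n_patients: int = 6
    n_controls: int = 4
    seed: int = 0
    # --- flux layer ---
    coupling_effect: float = 0.87
    wells_per_subject_per_scheme: int = 8
    noise_cv: float = 0.05
    between_subject_cv: float = 0.0
    # --- proteomics layer ---
    n_proteins: int = 3300
    n_dap_up: int = 13
    n_dap_down: int = 9
    dap_fc_up: float = 1.5
    dap_fc_down: float = 0.7
    protein_noise_cv: float = 0.06
    mito_fraction: float = 0.085
    filter_fail_rate: float = 0.08
    # --- metabolomics layer ---
    n_metabolites: int = 408
    missing_rate: float = 0.012
    lc_fraction: float = 42 / 408
    met_sample_cv: float = 0.2
    qc_cv: float = 0.05
    n_fail_qc: int = 0
    n_met_spiked: int = 0
    met_spike_fc: float = 0.6
    # --- clinical layer ---
    questionnaire_corr: float = 0.93
    severity_gap: float = 3.0

    def __post_init__(self) -> None:
        counts = {
            "n_patients": self.n_patients,
            "n_controls": self.n_controls,
            "wells_per_subject_per_scheme": self.wells_per_subject_per_scheme,
            "n_proteins": self.n_proteins,
            "n_metabolites": self.n_metabolites,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise SpecValidationError(f"{name} must be a positive integer, got {value!r}")
        for name in ("n_dap_up", "n_dap_down", "n_fail_qc", "n_met_spiked"):
            if getattr(self, name) < 0:
                raise SpecValidationError(f"{name} must be >= 0")
        if self.noise_cv < 0:
            raise SpecValidationError("noise_cv must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise SpecValidationError("missing_rate must lie in [0, 1)")
        if self.coupling_effect <= 0:
            raise SpecValidationError("coupling_effect must be > 0")
        if self.dap_fc_up <= 1:
            raise SpecValidationError("dap_fc_up must be > 1")
        if not 0 < self.dap_fc_down < 1:
            raise SpecValidationError("dap_fc_down must lie in (0, 1)")
        if self.n_dap_up + self.n_dap_down > self.n_proteins:
            raise SpecValidationError("spiked protein counts exceed n_proteins")
        if not abs(self.questionnaire_corr) < 1:
            raise SpecValidationError("questionnaire_corr must lie in (-1, 1)")

    # Independent, reproducible substream per data layer.
    def rng(self, layer: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), layer])

    def subjects(self) -> pd.DataFrame:
        ids = [f"P{i + 1:02d}" for i in range(self.n_patients)]
        ids += [f"C{i + 1:02d}" for i in range(self.n_controls)]
        groups = ["patient"] * self.n_patients + ["control"] * self.n_controls
        return pd.DataFrame({"subject": ids, "group": groups})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """True generating quantities, for parameter-recovery tests.

    Any subset of the fields may be populated depending on which generators
    ran; :func:`merge_truth` combines the pieces from a full cohort run.
    """

    section_means: pd.DataFrame | None = None  # subject, group, scheme, section, ocr, ecar
    flux_subjects: pd.DataFrame | None = None  # subject, group, atp_fraction, expected CE ...
    dap_truth: pd.DataFrame | None = None      # accession, gene, true_fc, direction
    severity: pd.DataFrame | None = None       # subject, group, severity
    spec: dict | None = None

    def to_json(self) -> str:
        out: dict = {"spec": self.spec}
        for key in ("section_means", "flux_subjects", "dap_truth", "severity"):
            frame = getattr(self, key)
            out[key] = None if frame is None else frame.to_dict(orient="list")
        return json.dumps(out, indent=2)


def merge_truth(spec: CohortSpec, *parts: GroundTruth) -> GroundTruth:
    merged = GroundTruth(spec=spec.to_dict())
    for part in parts:
        for key in ("section_means", "flux_subjects", "dap_truth", "severity"):
            value = getattr(part, key)
            if value is not None:
                setattr(merged, key, value)
    return merged


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-(sigma**2) / 2, sigma, size=size))


# ---------------------------------------------------------------------------
# Flux plates
# ---------------------------------------------------------------------------

# Control-group true rates. OCR in pmol O2/min, ECAR in mpH/min; magnitudes
# typical of ~80k PBMC per well. The patient effect enters only through the
# ATP-linked fraction of mitochondrial basal respiration.
_BASAL_OCR = 100.0
_NONMITO_FRACTION = 0.20
_ATP_FRACTION = 0.75
_MAXIMAL_RATIO = 2.0          # maximal / basal mitochondrial respiration
_BASAL_ECAR = 30.0
_NONGLYCO_FRACTION = 0.25
_GLYCO_CAPACITY_RATIO = 1.6   # glycolytic capacity / glycolysis


def generate_flux_plate(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate per-well OCR/ECAR traces for three injection schemes.

    Returns ``(traces, layout, truth)``: a long-format trace table
    (well, subject, group, scheme, section, cycle, ocr, ecar), a plate
    layout (well, subject, group, scheme), and the generating truth.

    Each well measurement is the subject's true section mean times
    independent log-normal noise with CV ``spec.noise_cv``; patients' true
    ATP-linked fraction is scaled by ``spec.coupling_effect`` so the group
    coupling-efficiency fold change equals it in expectation.
    """
    rng = spec.rng(1)
    subjects = spec.subjects()
    n_sub = len(subjects)

    jitter = lambda: _lognormal_factor(rng, spec.between_subject_cv, n_sub)  # noqa: E731
    basal_ocr = _BASAL_OCR * jitter()
    nonmito = _NONMITO_FRACTION * basal_ocr
    atp_frac = _ATP_FRACTION * jitter()
    atp_frac = np.where(subjects["group"] == "patient", atp_frac * spec.coupling_effect, atp_frac)
    atp_frac = np.clip(atp_frac, 0.02, 0.98)
    oligo_ocr = basal_ocr - atp_frac * (basal_ocr - nonmito)
    maximal = _MAXIMAL_RATIO * jitter() * (basal_ocr - nonmito)
    fccp_ocr = nonmito + maximal
    basal_ecar = _BASAL_ECAR * jitter()
    nonglyco = _NONGLYCO_FRACTION * basal_ecar
    cap_ecar = nonglyco + _GLYCO_CAPACITY_RATIO * (basal_ecar - nonglyco)

    # True (ocr, ecar) section means per scheme. ECAR responses in schemes
    # A/B and OCR in scheme C are plausible bystander signals; no parameter
    # is computed from them.
    means = {
        ("A", "basal"): (basal_ocr, basal_ecar),
        ("A", "inj1"): (oligo_ocr, 1.3 * basal_ecar),
        ("A", "inj2"): (nonmito, 1.1 * basal_ecar),
        ("B", "basal"): (basal_ocr, basal_ecar),
        ("B", "inj1"): (fccp_ocr, 1.2 * basal_ecar),
        ("B", "inj2"): (nonmito, 1.1 * basal_ecar),
        ("C", "basal"): (basal_ocr, basal_ecar),
        ("C", "inj1"): (oligo_ocr, cap_ecar),
        ("C", "inj2"): (0.9 * oligo_ocr, nonglyco),
    }
    section_rows = []
    for (scheme, section), (ocr, ecar) in means.items():
        section_rows.append(
            pd.DataFrame(
                {
                    "subject": subjects["subject"],
                    "group": subjects["group"],
                    "scheme": scheme,
                    "section": section,
                    "ocr": ocr,
                    "ecar": ecar,
                }
            )
        )
    section_means = (
        pd.concat(section_rows, ignore_index=True)
        .sort_values(["subject", "scheme", "section"], kind="stable")
        .reset_index(drop=True)
    )

    n_wells = spec.wells_per_subject_per_scheme
    well_meta = []
    wid = 0
    for i in range(n_sub):
        for scheme in SCHEMES:
            for _ in range(n_wells):
                wid += 1
                well_meta.append(
                    (f"W{wid:04d}", subjects["subject"][i], subjects["group"][i], scheme, i)
                )
    layout = pd.DataFrame(well_meta, columns=["well", "subject", "group", "scheme", "_si"])

    rows = []
    for scheme in SCHEMES:
        meta = layout[layout["scheme"] == scheme]
        si = meta["_si"].to_numpy()
        for section in SECTIONS:
            ocr_mean, ecar_mean = means[(scheme, section)]
            shape = (len(meta), N_CYCLES)
            ocr = ocr_mean[si, None] * _lognormal_factor(rng, spec.noise_cv, shape)
            ecar = ecar_mean[si, None] * _lognormal_factor(rng, spec.noise_cv, shape)
            for cycle in range(1, N_CYCLES + 1):
                rows.append(
                    pd.DataFrame(
                        {
                            "well": meta["well"].to_numpy(),
                            "subject": meta["subject"].to_numpy(),
                            "group": meta["group"].to_numpy(),
                            "scheme": scheme,
                            "section": section,
                            "cycle": cycle,
                            "ocr": ocr[:, cycle - 1],
                            "ecar": ecar[:, cycle - 1],
                        }
                    )
                )
    traces = (
        pd.concat(rows, ignore_index=True)
        .sort_values(["well", "section", "cycle"], kind="stable")
        .reset_index(drop=True)
    )
    # restore section order basal, inj1, inj2 within each well
    traces["section"] = pd.Categorical(traces["section"], categories=SECTIONS, ordered=True)
    traces = traces.sort_values(["well", "section", "cycle"], kind="stable").reset_index(drop=True)
    traces["section"] = traces["section"].astype(str)
    layout = layout.drop(columns="_si")

    flux_subjects = subjects.assign(
        atp_fraction=atp_frac,
        expected_coupling_efficiency=100 * atp_frac,
        basal_ocr=basal_ocr,
        nonmito_ocr=nonmito,
        maximal_ocr=fccp_ocr,
        basal_ecar=basal_ecar,
        nonglyco_ecar=nonglyco,
    )
    truth = GroundTruth(
        section_means=section_means, flux_subjects=flux_subjects, spec=spec.to_dict()
    )
    return traces, layout, truth


# ---------------------------------------------------------------------------
# Protein quantification table
# ---------------------------------------------------------------------------

def _load_gene_pool() -> list[str]:
    from .report import load_mito_list  # local import to avoid a cycle

    return load_mito_list()


def generate_protein_table(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a protein abundance table with spiked differential proteins.

    Returns ``(table, groups, truth)``. Baseline abundances are log-normal
    across proteins; per-sample values add multiplicative log-normal noise
    with CV ``spec.protein_noise_cv``. The first ``n_dap_up``/``n_dap_down``
    proteins (after a seeded shuffle) have patients' channels multiplied by
    the spiked fold changes, and always pass the peptide/scan inclusion
    filter. A ``mito_fraction`` of proteins is flagged mitochondrial and
    given gene symbols from the packaged mitochondrial list so gene-based
    subsetting is exercisable.
    """
    rng = spec.rng(2)
    n = spec.n_proteins
    order = rng.permutation(n)
    accession = np.array([f"ACC{i + 1:05d}" for i in range(n)])
    gene = np.array([f"GENE{i + 1:05d}" for i in range(n)])

    true_fc = np.ones(n)
    direction = np.full(n, "none", dtype=object)
    up_idx = order[: spec.n_dap_up]
    down_idx = order[spec.n_dap_up : spec.n_dap_up + spec.n_dap_down]
    true_fc[up_idx] = spec.dap_fc_up
    true_fc[down_idx] = spec.dap_fc_down
    direction[up_idx] = "up"
    direction[down_idx] = "down"
    spiked = true_fc != 1.0

    mito = np.zeros(n, dtype=bool)
    n_mito = int(round(spec.mito_fraction * n))
    mito_idx = order[::-1][:n_mito]  # disjoint-ish from spikes for small counts
    mito[mito_idx] = True
    pool = _load_gene_pool()
    gene[mito_idx] = [pool[i % len(pool)] for i in range(n_mito)]

    baseline = np.exp(rng.normal(np.log(1e6), 1.0, n))
    subjects = spec.subjects()
    sample_cols = list(subjects["subject"])
    is_patient = (subjects["group"] == "patient").to_numpy()
    values = baseline[:, None] * _lognormal_factor(
        rng, spec.protein_noise_cv, (n, len(sample_cols))
    )
    values = values * np.where(is_patient[None, :], true_fc[:, None], 1.0)

    unique_peptides = 2 + rng.poisson(5, n)
    quant_scans = 5 + rng.poisson(20, n)
    fail = rng.random(n) < spec.filter_fail_rate
    fail &= ~spiked
    fail_pep = fail & (rng.random(n) < 0.5)
    fail_scan = fail & ~fail_pep
    unique_peptides[fail_pep] = 1
    quant_scans[fail_scan] = rng.integers(0, 5, fail_scan.sum())

    table = pd.DataFrame(
        {
            "accession": accession,
            "gene": gene,
            "unique_peptides": unique_peptides,
            "quant_scans": quant_scans,
            "mitochondrial": mito,
        }
    )
    for j, col in enumerate(sample_cols):
        table[col] = values[:, j]
    groups = subjects.rename(columns={"subject": "sample"})

    dap_truth = pd.DataFrame(
        {"accession": accession, "gene": gene, "true_fc": true_fc, "direction": direction}
    )
    truth = GroundTruth(dap_truth=dap_truth, spec=spec.to_dict())
    return table, groups, truth


# ---------------------------------------------------------------------------
# Metabolite panel
# ---------------------------------------------------------------------------

_LC_CLASSES = ("amino acids", "biogenic amines")
_FIA_CLASSES = (
    "acylcarnitines",
    "glycerophospholipids",
    "sphingolipids",
    "hexoses",
    "cholesterol esters",
    "glycerides",
)


def generate_metabolite_table(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a targeted-metabolomics panel with left-censored missingness.

    Concentrations are log-normal per compound; any value below the
    compound's limit of detection (set at the ``missing_rate`` quantile of
    its sampling distribution) is recorded as missing, so the marginal
    missing probability per cell is ``missing_rate``. Compounds are split
    into LC and FIA platforms; three QC replicate columns are emitted with
    CV ``qc_cv``. ``n_fail_qc`` compounds are engineered to fail a
    QC-CV/missingness filter (half each way); ``n_met_spiked`` compounds get
    patients' concentrations multiplied by ``met_spike_fc``.
    """
    rng = spec.rng(3)
    n = spec.n_metabolites
    n_lc = int(round(spec.lc_fraction * n))
    name = np.array([f"M{i + 1:04d}" for i in range(n)])
    platform = np.array(["LC"] * n_lc + ["FIA"] * (n - n_lc))
    cls = np.array(
        [_LC_CLASSES[i % len(_LC_CLASSES)] for i in range(n_lc)]
        + [_FIA_CLASSES[i % len(_FIA_CLASSES)] for i in range(n - n_lc)]
    )

    subjects = spec.subjects()
    sample_cols = list(subjects["subject"])
    is_patient = (subjects["group"] == "patient").to_numpy()
    baseline = np.exp(rng.uniform(np.log(0.1), np.log(100.0), n))
    sigma = np.sqrt(np.log1p(spec.met_sample_cv**2))
    values = baseline[:, None] * np.exp(
        rng.normal(-(sigma**2) / 2, sigma, (n, len(sample_cols)))
    )

    spiked = np.zeros(n, dtype=bool)
    if spec.n_met_spiked:
        spiked[rng.permutation(n)[: spec.n_met_spiked]] = True
        values = values * np.where(
            spiked[:, None] & is_patient[None, :], spec.met_spike_fc, 1.0
        )

    # left-censoring at the per-compound LOD
    if spec.missing_rate > 0 and sigma > 0:
        from scipy.stats import norm

        lod = baseline * np.exp(sigma * norm.ppf(spec.missing_rate) - sigma**2 / 2)
        censored = values < lod[:, None]
        # spiked patients' cells keep their censoring rule (MNAR by value)
        values = np.where(censored, np.nan, values)

    qc = baseline[:, None] * _lognormal_factor(rng, spec.qc_cv, (n, 3))

    fail_idx = rng.permutation(n)[: spec.n_fail_qc]
    half = len(fail_idx) // 2
    bad_cv, bad_missing = fail_idx[:half], fail_idx[half:]
    # deterministic spread so the engineered failures always exceed any
    # sensible QC-CV threshold (CV ~ 0.68 here)
    qc[bad_cv] = baseline[bad_cv, None] * np.array([0.7, 1.0, 2.5])
    if len(bad_missing):
        drop = rng.random((len(bad_missing), len(sample_cols))) < 0.5
        # guarantee well above any missingness threshold
        drop[:, : max(1, int(0.4 * len(sample_cols)))] = True
        block = values[bad_missing]
        block[drop] = np.nan
        values[bad_missing] = block

    panel = pd.DataFrame({"compound": name, "class": cls, "platform": platform})
    for j, col in enumerate(sample_cols):
        panel[col] = values[:, j]
    for k in range(3):
        panel[f"QC{k + 1}"] = qc[:, k]
    groups = subjects.rename(columns={"subject": "sample"})
    truth = GroundTruth(spec=spec.to_dict())
    return panel, groups, truth


# ---------------------------------------------------------------------------
# Questionnaires
# ---------------------------------------------------------------------------

def generate_questionnaires(spec: CohortSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate questionnaire domain scores driven by a latent severity.

    Controls' severity is N(0, 1), patients' N(severity_gap, 1). Each
    instrument score is an affine function of severity (anchored at the
    calibrated group means) plus Gaussian noise sized so that any two
    instruments correlate at ``questionnaire_corr`` in the population
    (each instrument therefore correlates with severity at its square
    root). Scores are clamped to instrument ranges; if clamping moves the
    realised correlation structure away from the target a warning is
    logged, not raised. FSMC total is emitted as motor + cognitive.
    """
    rng = spec.rng(4)
    subjects = spec.subjects()
    n = len(subjects)
    is_patient = (subjects["group"] == "patient").to_numpy()
    gap = spec.severity_gap
    severity = rng.normal(0.0, 1.0, n) + np.where(is_patient, gap, 0.0)

    p = is_patient.mean()
    sd_sev = np.sqrt(1.0 + p * (1 - p) * gap**2)
    rho_instrument = np.sqrt(abs(spec.questionnaire_corr))
    # FSMC is scored as the sum of its two subscales, which averages their
    # noise; inflate subscale noise so the *total* carries rho_instrument.
    if rho_instrument > 0:
        k = 1.0 / rho_instrument**2 - 1.0
        rho_subscale = 1.0 / np.sqrt(1.0 + 2.0 * k)
    else:
        rho_subscale = 0.0
    table = subjects.copy()
    clamped_cells = 0
    for inst, (cm, pm, lo, hi) in INSTRUMENT_CALIBRATION.items():
        b = (pm - cm) / gap if gap != 0 else 0.0
        rho = rho_subscale if inst.startswith("fsmc_") else rho_instrument
        if b != 0 and rho > 0:
            noise_sd = abs(b) * sd_sev * np.sqrt(1.0 / rho**2 - 1.0)
            score = cm + b * severity + rng.normal(0.0, noise_sd, n)
        else:
            # zero target correlation (or a flat instrument): pure noise,
            # carrying no severity signal at all
            scale = abs(b) * sd_sev if b != 0 else 1.0
            score = cm + rng.normal(0.0, scale, n)
        clipped = np.clip(score, lo, hi)
        clamped_cells += int((clipped != score).sum())
        table[inst] = np.round(clipped, 2)
    table["fsmc_total"] = table["fsmc_motor"] + table["fsmc_cognitive"]

    if clamped_cells and n >= 10:
        r_obs = np.corrcoef(table["fsmc_total"], table["compass31_weighted"])[0, 1]
        if abs(r_obs) < abs(spec.questionnaire_corr) - 0.1:
            logger.warning(
                "questionnaire clamping attenuated the realised correlation "
                "(target %.2f, observed %.2f)",
                spec.questionnaire_corr,
                r_obs,
            )

    table["age"] = np.round(
        np.clip(rng.normal(np.where(is_patient, 39.0, 42.0), np.where(is_patient, 5.0, 11.0)),
                30, 50), 1
    )
    duration = np.round(np.clip(rng.normal(12.0, 5.3, n), 1.0, 40.0), 1)
    table["disease_duration"] = np.where(is_patient, duration, np.nan)

    truth = GroundTruth(
        severity=subjects.assign(severity=severity), spec=spec.to_dict()
    )
    return table, truth


# ---------------------------------------------------------------------------
# Whole-cohort convenience + disk I/O
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """All four data layers of one simulated cohort plus the merged truth."""

    flux_traces: pd.DataFrame
    flux_layout: pd.DataFrame
    protein_table: pd.DataFrame
    protein_groups: pd.DataFrame
    metabolite_panel: pd.DataFrame
    metabolite_groups: pd.DataFrame
    cohort_table: pd.DataFrame
    truth: GroundTruth


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    traces, layout, t1 = generate_flux_plate(spec)
    proteins, pgroups, t2 = generate_protein_table(spec)
    panel, mgroups, t3 = generate_metabolite_table(spec)
    cohort, t4 = generate_questionnaires(spec)
    return SyntheticCohort(
        flux_traces=traces,
        flux_layout=layout,
        protein_table=proteins,
        protein_groups=pgroups,
        metabolite_panel=panel,
        metabolite_groups=mgroups,
        cohort_table=cohort,
        truth=merge_truth(spec, t1, t2, t3, t4),
    )


def write_cohort(spec: CohortSpec, outdir: str | Path) -> dict[str, Path]:
    """Generate a cohort and write every layer to ``outdir``.

    Flux traces/layout, cohort and metabolite tables are CSV, the protein
    table is TSV, and a JSON sidecar stores the spec (including the seed)
    and the ground truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(spec)
    paths = {
        "flux_traces": outdir / "flux_traces.csv",
        "flux_layout": outdir / "flux_layout.csv",
        "protein_table": outdir / "protein_table.tsv",
        "protein_groups": outdir / "protein_groups.csv",
        "metabolite_panel": outdir / "metabolite_panel.csv",
        "metabolite_groups": outdir / "metabolite_groups.csv",
        "cohort_table": outdir / "cohort.csv",
        "truth": outdir / "ground_truth.json",
    }
    cohort.flux_traces.to_csv(paths["flux_traces"], index=False)
    cohort.flux_layout.to_csv(paths["flux_layout"], index=False)
    cohort.protein_table.to_csv(paths["protein_table"], sep="\t", index=False)
    cohort.protein_groups.to_csv(paths["protein_groups"], index=False)
    cohort.metabolite_panel.to_csv(paths["metabolite_panel"], index=False)
    cohort.metabolite_groups.to_csv(paths["metabolite_groups"], index=False)
    cohort.cohort_table.to_csv(paths["cohort_table"], index=False)
    paths["truth"].write_text(cohort.truth.to_json())
    return paths
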