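# mecfs-omics

A reusable, tested implementation of a multi-layer molecular profiling
analysis for small case-control cohorts, of the kind used in exploratory
ME/CFS (myalgic encephalomyelitis / chronic fatigue syndrome) studies. It
covers four data layers end to end:

1. **Bioenergetics** (`mecfs_omics.flux`) — parses per-well extracellular-flux
   traces (OCR, pmol O₂/min; ECAR, mpH/min) recorded under three injection
   schemes (A: oligomycin → rotenone/antimycin A; B: FCCP →
   rotenone/antimycin A; C: oligomycin → 2-deoxy-D-glucose), computes a
   14-parameter bioenergetic profile per subject (mean ± SD over replicate
   wells), and compares groups by Student's *t* with Bonferroni correction.
   The core parameters follow standard mito/glyco stress-test algebra, e.g.

   - basal respiration = basal OCR − non-mitochondrial OCR (post rot/AA)
   - ATP-linked respiration = basal OCR − post-oligomycin OCR
   - proton leak = post-oligomycin OCR − non-mitochondrial OCR
   - coupling efficiency (%) = 100 × ATP-linked / basal respiration
   - maximal respiration = post-FCCP OCR − non-mitochondrial OCR
   - spare respiratory capacity = maximal / basal respiration

2. **Proteomics** (`mecfs_omics.proteomics`) — filters a TMT-style protein
   quantification table (≥2 unique peptides, ≥5 quantitative scans), derives
   fold-change thresholds from the control group's own variability
   (upper = 1 + 2 × median control CV, lower = 1/upper), and calls
   differentially altered proteins (DAPs) that pass both the FC criterion
   (inclusive) and a Student *t*-test on log₂ abundances at p < 0.05, plus
   mitochondrial-subset, pathway and CD-marker summaries.

3. **Metabolomics** (`mecfs_omics.metabolomics`) — targeted-panel
   preprocessing (QC-CV/missingness filter per platform, minimum/5
   imputation of left-censored values, generalised log transform
   `log2((x + √(x² + a²))/2)`, Pareto scaling) followed by a fold-change
   screen (>1.3 or <0.77 on raw concentrations), *t*-tests with
   Benjamini–Hochberg FDR, and PCA.

4. **Clinical scores** (`mecfs_omics.clinical`) — FSMC / SF-36 / COMPASS-31
   questionnaire handling, Pearson correlation analyses (full cohort and
   patients-only, pairwise-complete), and a generic two-group comparison
   (fold change, Student *t*, per-group CV) for assay-level measures such as
   protein carbonyl content.

A synthetic-cohort generator (`mecfs_omics.synthetic`) emulates all four
layers — flux plates with a group-level coupling-efficiency effect, protein
tables with spiked DAPs, metabolite panels with limit-of-detection
censoring, questionnaire scores driven by a latent severity — so that every
stage is testable by parameter recovery without any data download.

## Worked example

```python
import mecfs_omics as m
from mecfs_omics import flux, proteomics

spec = m.CohortSpec(seed=42)          # 6 patients vs 4 controls, effect 0.87
cohort = m.generate_cohort(spec)

plate = flux.FluxPlate.from_frames(cohort.flux_traces, cohort.flux_layout)
profiles, comparison = flux.profile_plate(plate)
print(comparison[["parameter", "fold_change", "p_raw", "p_bonferroni"]].round(3))
```

prints (abridged):

```
                 parameter  fold_change  p_raw  p_bonferroni
    atp_linked_respiration        0.881  0.000         0.000
               proton_leak        1.376  0.000         0.000
       coupling_efficiency        0.881  0.000         0.000
       maximal_respiration        0.997  0.780         1.000
spare_respiratory_capacity        1.002  0.899         1.000
                glycolysis        1.011  0.309         1.000
```

The simulated patients' ATP-linked fraction was scaled by 0.87, and the
estimated group coupling-efficiency fold change comes back at 0.881 — the
effect enters ATP-linked respiration and proton leak with opposite signs,
while maximal respiration and the glycolytic parameters stay null. The
protein screen on the same cohort recovers the spiked proteins:

```python
table = proteomics.filter_quantifiable(cohort.protein_table)
th = proteomics.derive_fc_thresholds(table, cohort.protein_groups)
summary = proteomics.classify_daps(
    proteomics.screen_proteins(table, cohort.protein_groups, th)
)
print(th.display(), summary["n_total"], summary["n_up"], summary["n_down"])
# (1.11, 0.9) 46 24 22
```

All 22 spiked proteins (13 up at FC 1.5, 9 down at FC 0.7) are among the 46
calls; the remainder are the false positives expected from screening ~3300
proteins at raw p < 0.05 with n = 6 vs 4.

Command-line equivalents:

```
mecfs-omics simulate --seed 42 --outdir run/sim
mecfs-omics flux --traces run/sim/flux_traces.csv --layout run/sim/flux_layout.csv --out run/flux
mecfs-omics proteomics --table run/sim/protein_table.tsv --groups run/sim/protein_groups.csv --out run/prot
mecfs-omics metabolomics --panel run/sim/metabolite_panel.csv --groups run/sim/metabolite_groups.csv --out run/met
mecfs-omics clinical --cohort run/sim/cohort.csv --out run/clin
```

or one orchestrated run from a YAML/JSON config via `mecfs-omics report
--config run.yaml`, which writes a combined `report.json` and a `MANIFEST.json`
with content hashes (reruns under the same config and seed are bit-identical).

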