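# qplexflow

QC and dose-response analysis for multiplex bead-based gene-expression plates
(bDNA / Luminex xMAP style readouts).

## The problem

A multiplex bead assay measures the expression of 10–30 genes in every well of
a 96-well plate at once: each gene is carried by a bead region, and the reader
reports a median fluorescence intensity (MFI) plus a bead count per well and
gene. Turning those raw MFI values into trustworthy compound potencies takes a
fixed chain of quality-control and normalization decisions, each with a
quantitative rule:

1. **Bead-count filter** — a median built on too few beads is unstable.
   Readings with fewer than **37 beads** are discarded (the default comes from
   a breakpoint analysis of median stability vs bead count; the package ships
   the tooling to re-derive the threshold for your own instrument, see
   `examples/02_bead_stability.py`).
2. **Background correction** — per-gene background mean and SD are estimated
   from dedicated no-sample wells; the mean is subtracted from every reading
   (clamped at zero).
3. **Limit of quantification (LOQ)** — a well whose *housekeeping-gene* (HKG)
   signal stays below background mean + 10 SD carries too little material;
   the whole well is removed.
4. **HKG stability filter** — normalization only works if the HKGs are really
   unaffected by treatment. HKGs whose own fold change leaves **[0.8, 1.2]**
   in sample wells are removed iteratively, worst offender first.
5. **Normalization / fold change (FC)** — each gene is divided by the
   geometric mean of the retained HKGs in its well, then by the median of the
   untreated negative-control wells. FC is scale-invariant: pipetting and
   input differences cancel.
6. **Cytotoxicity flag** — a compound that kills cells suppresses HKGs too,
   and normalization divides the damage away. Conditions whose corrected HKG
   signal drops below 30 % of the negative-control mean (a **70 % reduction**)
   are flagged before anyone trusts their fold changes.
7. **Dose-response modelling** — per gene × compound, a constant model, a
   three-parameter log-logistic (3PL, upper plateau fixed at FC 1) and a
   1/FC²-weighted 3PL compete on AIC. The winner reports the **absolute
   AC50**: the dose where the *fitted curve* crosses FC 0.5 (suppression) or
   1.5 (induction), with a delta-method standard error; estimates with
   SE(log10 AC50) > 0.3 are marked `~` (uncertain).

`docs/methods.md` states every formula, default and caveat precisely.

## Worked example

`examples/01_simulate_and_run.py` builds a fully synthetic screening plate
(20 target genes, 2 HKGs, 10 compounds × 6 half-log doses, 5 % multiplicative
MFI noise) with a known ground truth, writes the template/raw file pair,
reads them back and runs the cascade:

```text
$ python examples/01_simulate_and_run.py
wells annotated:        72
gene x compound fits:   200 (105 dose-dependent, 95 uninformative/constant)
HKG retained:           ['HKG01', 'HKG02']
cytotoxic conditions:   0

  gene compound        model  ac50_abs  se_log10_ac50  max_effect_c
GENE01    CPD01 pl3_weighted  1.842415       0.024537      0.139612
GENE03    CPD01          pl3  2.834136       0.022821      2.067746
GENE06    CPD01          pl3  2.826218       0.092549      3.312875
GENE10    CPD01 pl3_weighted  6.112638       0.037707      0.084633
GENE11    CPD01          pl3  6.945892       0.076175      1.747316
GENE12    CPD01 pl3_weighted  1.563812       0.093914      2.070352
GENE14    CPD01 pl3_weighted  2.530411       0.025213      0.227882
GENE15    CPD01 pl3_weighted  2.376975       0.044558      2.409655

ac50_abs is the dose where the fitted curve crosses fold change 0.5
(suppression) or 1.5 (induction); max_effect_c is the far asymptote;
an SE(log10 AC50) above 0.3 would mark the estimate '~' (uncertain).
```

A single fit with the numbers spelled out (`examples/03_dose_response_fit.py`):

```text
selected model:  pl3_weighted  (AIC -14.21)
Hill slope b:    0.943  (true 1.0)
max effect c:    0.184  (true 0.2)
absolute AC50:   1.386  (true 1.667)
SE(log10 AC50):  0.096  -> uncertain: False
FC at top dose:  0.210
```

## Command line

```bash
# simulate a plate with known ground truth
qplexflow simulate --seed 11 --out sim/

# process a template + raw file pair into a report directory
qplexflow run --template sim/template.xlsx --raw sim/raw.csv --out report/

# re-derive a bead-count threshold from bead-level fluorescence data
qplexflow bead-stability --beads beads.csv --out bead_report/
```

`run` writes `results.csv` (one row per gene × compound, with model kind,
absolute AC50, SE and `~` marker), QC tables for every removal or flag
(`qc_discarded.csv`, `qc_background.csv`, `qc_removed_wells.csv`,
`qc_hkg_stability.csv`, `qc_cytotox.csv`), `summary.json` and `run.log`.
Input formats: an xlsx template (sheet `Plate` with well annotations, sheet
`HKG` naming the housekeeping genes) and a delimited long-format raw table
(`well,gene,mfi,bead_count`). All thresholds can be overridden through a YAML
config (`--config`), see `qplexflow.RunConfig`.

## Library

All pipeline stages are importable functions operating on pandas frames —
`read_template` / `read_raw` / `merge`, `filter_by_bead_count`,
`background_stats` / `background_correct` / `remove_wells_below_loq`,
`hkg_stability_filter` / `compute_fc`, `cytotox_flags`,
`select_model` / `absolute_ac50`, and `run_plate` to chain them. The
`make_truth` / `simulate_plate` generator produces plates with a planted,
exactly known ground truth (deterministic per seed) for validation.

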