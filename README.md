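# cbtc-circuits

Individual-level analysis of **cortico–basal ganglia–thalamo–cortical (CBTC)
circuits** for post-stroke motor impairment studies: connectivity-profile-based
subcortical parcellation, loop-structured functional connectivity (FC),
edge-wise case–control statistics, linear-SVM classification, and
connectome-based predictive modeling (CPM) of upper-limb motor scores —
exercised end-to-end on a seeded synthetic cohort generator, so every stage is
testable without imaging data.

## Who this is for

Researchers analysing resting-state fMRI of stroke patients who want to move
beyond whole-structure atlas connectivity: the subcortical nuclei (caudate,
putamen, pallidum, thalamus) are subdivided by their dominant cortical target
(probabilistic-tractography connection probabilities), and FC is computed on
the resulting individual-specific loop edges. Two parallel intrahemispheric
loops are modelled per hemisphere — the *long*
cortico–striato–pallido–thalamo–cortical loop (21 connections) and the *short*
cortico–striato–thalamo–cortical loop (19 connections, no pallidal relay) —
alongside a conventional 26-edge atlas set (5 cortical × 4 subcortical pairs
plus the 6 subcortical–subcortical pairs).

## The methods at the core

- **Winner-take-all parcellation.** Each subcortical voxel carries a vector of
  connection probabilities to the cortical targets (MPFC, DLPFC, M1, premotor,
  orbitofrontal). The voxel joins the subdivision of the maximal-probability
  target, provided max *p* ≥ τ (default 0.01); ties break deterministically.
- **FC extraction.** Pearson *r* between region mean time series, Fisher
  transformed *z* = arctanh *r*; 40 loop values and 26 atlas values per
  hemisphere per subject.
- **Group comparison.** Per-edge two-sample *t*-tests on *z* (Welch by
  default), Benjamini–Hochberg FDR over the edge family; demographics use the
  Pearson χ² (no continuity correction) and the Mann–Whitney *U* test.
- **Classification.** Edges ranked by the two-class Fisher criterion
  F = ((x̄₊−x̄)² + (x̄₋−x̄)²)/(s₊²+s₋²); linear SVM (+1 patient, −1 control),
  leave-one-out CV, accuracy curve over the number of top-ranked edges,
  ROC/AUC from held-out decision values, label-permutation test of the AUC.
- **CPM.** Per fold, edges correlated with the behavior score (p < 0.05) are
  split into positive/negative networks; each network strength (sum of member
  *z* values) feeds a linear model predicting the held-out subject's score.
  Performance is Spearman *r* (predicted vs observed) with a
  behavior-shuffling permutation test, plus the fold-stable ("well
  represented") contributing connections.

All patients are pooled into one lateralised frame: imaging of left-lesion
patients is mirrored across the mid-sagittal plane so the right hemisphere is
ipsilesional for everyone (`cbtc.volumes.flip_lr`).

## Worked example

```bash
python examples/03_group_differences.py
```

```
planted attenuated edges: ['long:R:DLPFC-THA_DLPFC', 'short:R:CAU_M1-M1', 'short:R:DLPFC-PUT_DLPFC']
6/80 edges FDR-significant (adjusted p < 0.05):
  short:R:DLPFC-PUT_DLPFC      t= -12.17  p_fdr=1.76e-16  patients<controls
  short:R:DLPFC-THA_DLPFC      t= -10.72  p_fdr=2.22e-14  patients<controls
  short:R:CAU_M1-M1            t= -10.84  p_fdr=2.07e-14  patients<controls
  long:R:DLPFC-PUT_DLPFC       t= -12.17  p_fdr=1.76e-16  patients<controls
  long:R:DLPFC-THA_DLPFC       t= -10.72  p_fdr=2.22e-14  patients<controls
  long:R:CAU_M1-M1             t= -10.84  p_fdr=2.07e-14  patients<controls
```

The generator attenuated three right-hemisphere (ipsilesional) loop
correlations in patients; the edge-wise tests recover exactly those region
pairs, with direction patients < controls. A pair shared by both loops (e.g.
caudate_M1–M1) carries one physical correlation, so it surfaces once per loop
block. The other examples (`examples/01…05`) walk through simulation,
parcellation, classification (ACC/SEN/SPE/AUC with a permutation *p*), and
CPM prediction the same way.

The same stages are scriptable from a shell:

```bash
cbtc simulate --n-patients 32 --n-controls 32 --seed 1 --out cohort/
cbtc fc --series-dir cohort/series --phenotype cohort/phenotype.tsv --scheme loops --out fc.tsv
cbtc compare --fc fc.tsv --phenotype cohort/phenotype.tsv --out stats.tsv
cbtc run-all --seed 1 --out run/        # whole pipeline, reproducible summary.json
```

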