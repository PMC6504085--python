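# cellsim

Simulator for benchmarking time-course omics analysis methods.  An
off-lattice, cell-center Monte Carlo model of a growing, dividing,
mechanically interacting 2-D cell population is coupled to a
pathway-activity model of transcription, producing time-course **bulk
microarray**, **bulk RNA-seq** and **single-cell RNA-seq** matrices with a
fully known ground truth (per-sample pathway activities, cell types, phases
and event history).

## How it works

1. **Cell model** (`cellsim.cell_model`) — cells are disks (two-disk
   dumbbells during mitosis) interacting through a quadratic overlap penalty
   plus a short-range adhesion well.  Migration, growth and dumbbell
   deformation are Metropolis trials accepted with probability
   `min(1, exp(-dE))`.  Interphase growth follows an area-linear schedule
   that doubles the cell's area over its drawn cycle length; phases
   (G1/S/G2/M) are read off the area ratio; crowded cells stall and stop
   dividing (contact inhibition).
2. **Pathways** (`cellsim.pathways`) — named gene sets with an activity rule
   mapping a cell at a time point to P in [0, 1] (phase transitions, local
   density, growth rate, cell-type identity), calibrated per gene to an
   expression range (gmin, gmax) from a statistical distribution or a
   reference matrix.
3. **Expression** (`cellsim.expression`) — mean expression interpolates each
   gene's range by its pathways' activity (averaged over sampled cells for
   bulk, per cell for single-cell), then platform noise is applied:
   Gaussian (microarray), negative binomial (bulk RNA-seq), or negative
   binomial + logistic dropout with per-cell library sizes (single-cell).
4. **Scenarios** (`cellsim.scenarios`) — ready-made generators:
   `bulk_timecourse` (150 genes x 43 samples), `two_type_singlecell`
   (12 h vs 36 h cycle types), `confounded_growth` (paired datasets that
   differ only in pathway-gene overlap).

## CLI

```sh
cellsim simulate --config examples/minimal.yaml --seed 7 --out out/
cellsim cell-model --config examples/minimal.yaml --out traj/
cellsim expression --config examples/minimal.yaml \
    --trajectory traj/trajectory.jsonl --events traj/events.jsonl --out out/
cellsim scenario bulk_timecourse --seed 1 --out out_bulk/
cellsim scenario confounded_growth --confounded --seed 1 --out out_cg/
```

Outputs: dense TSV matrices (genes x samples) for bulk platforms, a Matrix
Market triplet (`matrix.mtx` + `features.tsv` + `barcodes.tsv`) for
single-cell counts, plus `mean_expression.tsv`, ground-truth `activity.tsv`,
`sample_meta.tsv`, the trajectory as JSON Lines and the effective config.
Every run is bitwise reproducible from (config, seed); one seed drives named
sub-streams for the model, calibration, sampling and noise stages.

## Configuration

YAML or JSON, validated strictly (unknown keys rejected).  See
`examples/minimal.yaml`; all model, pathway, calibration and noise
parameters are exposed.  Noise defaults (microarray SD, library sizes, NB
dispersion, dropout midpoint/shape) are package conventions chosen for
plausible output, not literature-derived values.
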