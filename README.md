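# smdrank

Adaptive steered-pulling affinity ranking on coarse-grained ligand–receptor
toy systems, with the complete downstream calibration statistics.

The package has five parts:

- **`smdrank.toy_complex`** — synthetic-data generator: point ligands bound
  in radially symmetric Morse wells whose depth is a monotone map of a
  designed pKi series (plus weak-binding decoys), and the bundled FABP4
  inhibitor reference score tables (checksummed CSV resources) used as the
  fixture surface.
- **`smdrank.smd_engine`** — Langevin (BAOAB) dynamics with an adaptive
  pulling controller: a constant external acceleration applied to the
  ligand is boosted by 500 pm/ps² whenever the maximum ligand–receptor
  separation stagnates for 400 steps, and damped by `1 − (1 − cap/speed)²`
  (never below the 2000 pm/ps² floor) once the separation grows faster than
  4000 m/s; checks run every 20 steps and the pull stops after 20 Å of
  travel. Records per-step force/distance, peak force (Fmax) and total
  pulling work; also provides a stiff-spring constant-velocity pull and a
  log-sum-exp-stable Jarzynski free-energy estimator over replicate works.
- **`smdrank.affinity_stats`** — Ki/pKi/ΔG conversions (RT = 0.592
  kcal/mol), simple-OLS calibration fits with the full goodness-of-fit
  suite (R², adjusted R², MSE/RMSE, MAPE, Durbin–Watson, Cp, AIC/SBC,
  Amemiya PC, PRESS/Q²), the ANOVA table, studentized deleted residuals and
  Cook's distances, and active/decoy Fmax separation.
- **`smdrank.ligand_similarity`** — ECFP6-style Morgan fingerprints
  (radius 3, 2048 bits) with bit-vector Tanimoto and pairwise similarity
  matrices.
- **`smdrank.pipeline_cli`** — orchestration: replication of the reference
  statistics from the bundled tables, and the end-to-end toy experiment
  (generate series → pull in replicate → score Fmax → calibrate → report),
  fully seeded with a JSON run manifest.

## CLI

```bash
smdrank replicate-paper --out report/        # recompute the reference statistics
smdrank calibrate --scores scores.csv --response pki --predictor mmpbsa --out rep/
smdrank similarity --smiles compounds.smi --radius 3 --bits 2048 --out sim/
smdrank pull --config cfg.json --seed 7 --out run/
smdrank toy-e2e --config e2e.json --seed 1 --out e2e/
```

`pull` config example:

```json
{
  "system": {"well_depth": 5.0, "ligand_mass": 50.0, "well_width": 0.15,
             "temperature": 298.0, "friction": 1.0},
  "steering": {"timestep": 2.0, "stop_distance": 20.0}
}
```

## Notes

- The bundled tables are transcribed verbatim; their printed rounding
  limits which statistics are exactly recoverable. Scale-invariant
  statistics (R², adjusted R², F, PC, Q², DW) reproduce the reference
  values within last-digit tolerance; SSE-scale quantities (MSE, AIC, SBC,
  PRESS, intercepts) do not, and `replicate-paper` reports them with a
  warning instead of a verdict.
- "Total SMD energy" is defined operationally as the pulling work
  (trapezoidal integral of applied force over the pulling coordinate).
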