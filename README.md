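# ppisite

Prediction of protein–protein interaction sites from protein complex
structures and per-chain sequence profiles.  The pipeline:

1. **structure** — read PDB complexes into a heavy-atom residue model.
2. **sasa** — Shrake–Rupley accessible surface area per atom and residue, in
   the bound complex (CASA) and for each chain in isolation (MASA), with
   total / backbone / side-chain / polar / non-polar components and relative
   areas (RASA).  DSSP files can supply total areas as an optional bypass.
3. **geometry** — average residue depth (DPX, distance to the nearest
   solvent-accessible atom) and protrusion (CX, empty-to-occupied volume
   ratio in a 10 Å sphere).
4. **labeling** — surface residues (total RASA ≥ 16 % unbound), interface
   residues (surface and |MASA − CASA| ≥ 1 Å²), and chain-level curation
   (length ≥ 100; ≥ 20/30 interface residues for hetero/homo complexes).
5. **profiles** — 25 sequence-profile values per residue (20 substitution
   probabilities + entropy, relative entropy, conservation weight,
   variability, aligned-sequence count) from HSSP files or a simplified TSV
   dialect, plus 13 vendored physicochemical values per amino acid; all
   parts are assembled into a fixed-order 50-dimensional residue vector.
6. **encoding** — a sliding window of 11 sequence neighbours, each
   neighbour's 50-vector divided by its Cα–Cα distance to the query (self
   distance ≡ 1), blocks sorted by ascending distance, zero padding at the
   termini: a 550-dimensional descriptor per surface residue.
7. **ensemble** — bagging over CART decision trees (bootstrap samples,
   majority vote, vote-fraction scores) with stratified cross-validation.
8. **evaluation** — recall, precision, accuracy, F-measure, MCC, ROC and
   trapezoidal AUC; zero-denominator metrics are reported as undefined.
9. **synthetic** — toy two-chain complexes with a known contact patch,
   synthetic profiles, and labeled Gaussian datasets, so the whole pipeline
   is testable without any downloads.

## CLI

```sh
# write a synthetic fixture complex + profiles
ppisite simulate --n-res 30 --patch 10 --gap 4.0 --seed 1 --outdir fix/

# extract the 550-column feature matrix
ppisite extract --pdb fix/complex.pdb \
    --profile A=fix/profile_A.tsv --profile B=fix/profile_B.tsv \
    --out features.csv

# cross-validate + train, then predict and evaluate
ppisite train --features features.csv --model-out model.joblib \
    --report-out report.json
ppisite predict --model model.joblib --features features.csv --out pred.csv
ppisite evaluate --predictions pred.csv --out metrics.json
```

A YAML config (`--config`) can set any pipeline option (window size,
surface threshold, interface delta, SASA quadrature points, bagging size,
folds, seed).  Train/test splitting is by chain, never by residue.

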