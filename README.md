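# abtriage

Two-layer triage of paired antibody variable domains for developability-style
candidate selection:

1. **Physicochemical pre-filter (PCF)** — sequence-only calculators (CDR-H3
   loop length on the H95–H102 window, additive per-residue unfolding ΔG,
   Henderson–Hasselbalch isoelectric point with the EMBOSS pKa set, a
   more-than-two-cysteines hard rule) gated by Z-scores against a reference
   antibody set (default Z = 2).
2. **Fixed-grid encoding** — chains are Chothia-numbered by a deterministic
   template-alignment backend and padded onto canonical grids (heavy = 132
   slots, light = 122), then encoded per residue. A seeded mock encoder is
   always available, so nothing requires language-model weights; adapter
   hooks declare the published layout contracts (e.g. 254 × 512 = 130,048
   features for the 512-dim encoder).
3. **Layer 1** — rbf kernel PCA (γ = 500 default) to two components, fit on
   library + clinical (+ query) encodings; a rotated ellipse is built from
   the clinical projections at a chosen Z stringency (or `"all"`) and only
   queries inside the ellipse survive.
4. **Layer 2** — univariate F-regression feature ranking, top-k selection
   (default k = 2500), a linear-margin classifier (ridge / logistic also
   wired) with Platt-calibrated probabilities and a tunable decision
   threshold (0.5 default, 0.8 high stringency), evaluated by stratified
   10-fold CV with MCC / sensitivity / specificity.

Stage order is fixed (PCF → encode → Layer 1 → Layer 2), encoding happens
once per record, and every stage can be disabled or tightened independently.

## CLI

```bash
# full pipeline
abtriage run --input query.fasta --clinical clinical.csv \
    --approved approved.csv --discontinued discontinued.csv \
    --pcf-z 2 --layer1-z all --layer2-threshold 0.5 --seed 1 \
    --out report.tsv        # + report.tsv.json run header

# per-record physicochemical features
abtriage physchem --input query.fasta --out features.tsv

# seeded synthetic fixtures (repertoires, embedding clouds, labeled features)
abtriage synth repertoire --n 100 --seed 1 --out rep.csv
abtriage synth clouds --n-reference 50 --n-background 500 --out clouds.tsv
abtriage synth features --n 200 --d 100 --k-informative 5 --out feats.tsv

# supervised stage on its own
abtriage layer2 train --approved a.csv --discontinued d.csv --k 2500 --out model.json
abtriage layer2 predict --model model.json --input query.csv
```

Paired FASTA uses `/H`,`/L` (or `_VH`,`_VL`) suffixes on a shared id stem;
CSV/XLSX tables use columns `id, sequence_heavy, sequence_light[, status]`.

## Data

`src/abtriage/data/` packages the canonical grid slot lists, germline-like
template/reference chains, the per-residue unfolding ΔH/ΔS table and the
EMBOSS pKa set (all overridable).

To reproduce the published therapeutic-set statistics, place CSV exports of
the per-antibody sequence tables under `data/supplementary/` as
`table_s1.csv` (therapeutic set) and `table_s5.csv` (approved/discontinued
set, extra `status` column with values `approved`/`discontinued`), both with
columns `id, sequence_heavy, sequence_light`.
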