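# messar

Substructure recommendation for tandem mass spectra (MS/MS) by association
rule mining.

Identifying unknown metabolites from MS/MS data is limited by the size of
spectral libraries and molecular databases. Instead of attempting a full
identification, `messar` generates *structural hypotheses*: it learns
recurring links between spectral features and molecular substructures from a
structure-annotated spectral library, and uses them to recommend ranked
substructures for any unknown spectrum — no candidate database required.
It is aimed at metabolomics researchers doing de novo annotation, and at
developers who want a transparent, fully scriptable rule-mining pipeline.

## Method

A labeled library (MGF with `SMILES=`/`INCHIKEY=` headers, plus optional
fragmentation-tree edges) is converted into transactions joining

* **spectral features** — neutral fragment masses (*Mass*) and mass
  differences (*MDiff*, neutral losses along fragmentation-tree edges),
  discretized at 4 decimals; and
* **substructures** — predefined functional-group patterns found in the
  molecule, plus fragments obtained by cleaving one or two acyclic bonds
  (C/H/O/N fragments with fewer than 5 C+O atoms are discarded as trivial).

Association rules *X ⇒ Y* (a body of 1–3 co-occurring features, one
substructure head) are mined and scored as binary classifiers:

```
Supp(X) = TP + FP   spectra containing the feature set X
Supp(Y) = TP + FN   compounds containing the substructure Y
precision = TP / Supp(X)        recall = TP / Supp(Y)
```

Rules are filtered with a **target–decoy** scheme: a decoy library keeps
every structure label but randomizes the spectra, decoupling features from
structures; the simple FDR at a recall threshold *t* is
`#{decoy rules ≥ t} / #{target rules ≥ t}`, and the smallest threshold
achieving the requested FDR (default 1%) defines the final database.

To annotate an unknown spectrum, its features are matched against rule
bodies within a 20 ppm window (all body features must match). Matched rules
are ranked by recall and aggregated: rules with analogous heads (Tanimoto
similarity > 0.5 on hashed path fingerprints) are merged into their maximum
common substructure (MCS), scored by the summed recall of all contributing
rules. Three aggregation modes exist: `exhaustive` (all pairs), `fast`
(top-20 rules by recall) and `naive` (identical heads only).

## Worked example

The classic chloride worked example: in a library where the HCl-loss mass
difference (35.9767 Da, the monoisotopic mass of HCl) appears in every
chlorinated compound's spectrum, mining recovers a perfect-precision rule
`MDiff 35.9767 ⇒ CCl`. With the bundled synthetic fixture:

```sh
python - <<'EOF'
from messar import build_transactions, chloride_loss_spec, generate_library, mine_rules
from messar.feature_extraction import extract_target_features

spec = chloride_loss_spec(seed=1)          # 100 compounds, 30 chlorinated
lib = generate_library(spec)
feats = [extract_target_features(r) for r in lib.records]
txns = build_transactions(lib, feats, ["CCl"], max_cuts=1)
for r in mine_rules(txns)[:1]:
    print(r.body_token(), "=>", r.head.smiles,
          f"Supp(X)={r.supp_x} Supp(Y)={r.supp_y} TP={r.tp}",
          f"precision={r.precision:.2f} recall={r.recall:.2f}")
EOF
```

prints

```
MDiff:35.9767 => CCl Supp(X)=30 Supp(Y)=30 TP=30 precision=1.00 recall=1.00
```

i.e. all 30 spectra showing the HCl loss belong to the 30 chlorinated
compounds (precision 1.0) and every chlorinated compound shows it
(recall 1.0).

The same pipeline is available from the shell:

```sh
messar simulate --spec fixture.json --out fixtures/
messar train    --library fixtures/library.mgf --tree-edges fixtures/tree_edges.tsv --out target.tsv
messar make-decoy --library fixtures/library.mgf --seed 7 --out decoy.mgf
messar train    --library decoy.mgf --kind decoy --seed 7 --out decoy.tsv
messar filter   --target-db target.tsv --decoy-db decoy.tsv --alpha 0.01 --out rules.tsv
messar annotate --spectrum query.mgf --rules rules.tsv --mode exhaustive --out recommendations.tsv
```

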