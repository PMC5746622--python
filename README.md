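# sanops-alert

Tooling for prior-CT alerting over major body regions, and for grading how
well an anatomic terminology supports that use case.

The package has three layers:

1. **Region model** (`sanops_model`) — 17 major body regions (head, neck,
   chest, abdomen, pelvis, and proximal/mid/distal thirds of each
   extremity) with a symmetric adjacency table, plus the alert rules:
   *same* (identical exam code), *similar* (different codes sharing an
   assigned region), *proximate* (disjoint but adjacent regions).
2. **Terminology grading** (`terminology_graph`, `utility_classifier`) — a
   typed ontology-graph model (`is_a`, `part_of`, `has_part`,
   `regional_part_of`, `constitutional_part_of`) and an ordinal 1–5
   classifier measuring how much graph machinery a terminology needs to
   recover an exam's body region: 1 = region attributed directly, 2 =
   uniform-relation walk with no bypass, 3 = uniform walk in a
   polyhierarchy with bypassing routes, 4 = only mixed-relation walks,
   5 = no route at all.
3. **Alert engine and analysis** (`alert_engine`, `fixtures`,
   `stats_compare`) — order-time alert decisions per terminology backend
   at a chosen utility threshold (`max_class`, where 1 models the
   terminology "as is"), built-in mini-terminology fixtures encoding the
   structural behaviour of five real terminologies for a 7-scenario
   firing matrix, random graph/sample generators for property testing,
   and nonparametric group comparison (Kruskal–Wallis, pairwise rank-sum,
   uncorrected, α = .05 by default).

## CLI

The console script is `sanops-alert`:

```sh
# 7-scenario x 5-terminology firing matrix (cells: similar/proximate/-)
sanops-alert scenarios --out matrix.csv

# grade one exam mapping, with the witness walk when one exists
sanops-alert classify --backend fma --exam "Esophagus CT"

# ranked alert decisions for a current order against a prior history CSV
sanops-alert alert --backend radlex --max-class 1 \
    --current CTX-002 --priors priors.csv

# compare utility-class samples across terminologies
sanops-alert compare --in classes.csv --alpha 0.05 --out report.csv

# export a built-in fixture terminology as ontology JSON
sanops-alert fixtures --name fma --out fma_mini.json
```

Every flag can instead be given in a YAML file via `--config`; explicit
flags win. Exam history CSVs have columns
`patient_id,site_id,exam_code,timestamp` (ISO-8601 timestamps); class
sample CSVs have `terminology,exam_code,class`.

## Ontology JSON dialect

A terminology is a single JSON object
`{"name", "concepts": [{"id","label"}...], "edges": [{"source","target","relation"}...]}`
with relations from the five types above. Edges are stored in their
asserted direction (child/part → parent/whole; `has_part` runs
whole → part), the rootward subgraph must be acyclic, and files are
saved with stable ordering so serialization round-trips byte-identically.

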