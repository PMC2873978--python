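# Codebook file format

A codebook is a YAML (or JSON) document with a single top-level key,
`factors`, holding a list of factor descriptors. It round-trips losslessly
through `Codebook.from_yaml` / `Codebook.to_yaml`.

```yaml
factors:
  - symbol: LBXATC            # harmonized identifier, unique in the codebook
    display_name: a-tocopherol
    env_class: nutrients      # environmental class used for grouping/plots
    scale: continuous         # continuous | categorical
    aliases: [LBXVIE]         # cohort-specific raw column names
    units: ug/dL
    lod: 0.1                  # detection limit, measurement units, > 0
    referent_level: null      # categorical factors only
    subset_targeted: false    # assay applied only to a population subset
  - symbol: URXUTRI
    display_name: trichomonas test
    env_class: bacteria
    scale: categorical
    referent_level: negative  # the "negative" assay result is the referent
    subset_targeted: true
```

Rules enforced at load time:

- `symbol` must be unique; an alias may belong to only one factor.
- `scale: continuous` factors must not declare a `referent_level`;
  `scale: categorical` factors must declare one before they can be
  screened.
- `lod`, when present, must be positive. Factors without an `lod` skip the
  below-detection-limit filter and substitution.
- Within one cohort, two raw columns mapping onto the same symbol is a hard
  harmonization error.

Cohort tables are delimited text (CSV, header row) or SAS transport (XPT)
files. Expected non-exposure columns: the phenotype column (default
`fbg`), `age`, `sex` (`male`/`female`), `bmi`, `ethnicity`,
`poverty_index`, and the design columns `stratum`, `psu`, `weight`.
Optional sensitivity columns: `diagnosed`, `triglycerides`, `cholesterol`,
`supplement_count`, and `diet_*` dietary-recall amounts.
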