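# XML report schema

The XML writer emits one `report` document per profiled structure. All
distances are Å, all angles degrees, all numbers fixed to two decimals.
Atom references are PDB serial numbers. The document round-trips through
`nciprofiler.report.parse_xml` byte-identically.

```
report                      @structure_id  @created (ISO-8601, injectable)
├── config
│   └── threshold*          @name @value        (every ThresholdConfig key,
│                                                sorted by name)
└── bindingsite*            @id  ("CODE:chain:number")
    ├── summary
    │   └── count{7}        @type  text=integer (one per interaction type,
    │                                            equals the record count)
    └── interactions
        ├── hydrophobic     ┐
        ├── hbond           │
        ├── waterbridge     │  one container element per type, in this
        ├── saltbridge      │  fixed order; empty when no records
        ├── pistack         │
        ├── pication        │
        └── halogen         ┘
            └── record*     @id (1-based) @residue ("RESN-chain-num")
                            @donor_side (protein|ligand|n/a) @subtype
                ├── protein_atoms   text = comma-separated serials
                ├── ligand_atoms    text = comma-separated serials
                ├── water_atom?     text = serial (water bridges only)
                └── measure*        @name @value @unit
```

Measurement names per type:

| type        | measures                         |
|-------------|----------------------------------|
| hydrophobic | `dist`                           |
| hbond       | `dist_d-a`, `don_angle`          |
| waterbridge | `dist_l-w`, `dist_p-w`, `omega`  |
| saltbridge  | `dist`                           |
| pistack     | `centdist`, `angle`, `offset`    |
| pication    | `dist`, `offset`                 |
| halogen     | `dist`, `don_angle`, `acc_angle` |

`subtype` carries `P`/`T` for stacking, the charge-group pairing for salt
bridges, the cation group for π-cation and the halogen element for
halogen bonds.
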