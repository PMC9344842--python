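{
  "template_id": "fiber-manufacture",
  "version": 1,
  "base": "dublin-core",
  "fields": [
    {"name": "cell_type", "required": true, "kind": "controlled-vocabulary",
     "vocabulary": ["HEK293", "HeLa", "CHO-K1", "primary-fibroblast"]},
    {"name": "collagen_concentration_mg_per_ml", "required": true, "kind": "decimal", "units": "mg/ml"},
    {"name": "cell_density_cells_per_ml", "required": true, "kind": "decimal", "units": "cells/ml"},
    {"name": "alginate_flow_ul_per_min", "required": true, "kind": "decimal", "units": "ul/min"},
    {"name": "cacl2_concentration_mM", "required": true, "kind": "decimal", "units": "mM"},
    {"name": "incubation_temp_C", "required": true, "kind": "decimal", "units": "degC"}
  ]
}
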