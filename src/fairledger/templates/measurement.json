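{
  "template_id": "fiber-measurement",
  "version": 1,
  "base": "dublin-core",
  "fields": [
    {"name": "inner_diameter_um_point1", "required": true, "kind": "decimal", "units": "um"},
    {"name": "inner_diameter_um_point2", "required": true, "kind": "decimal", "units": "um"},
    {"name": "inner_diameter_um_point3", "required": true, "kind": "decimal", "units": "um"},
    {"name": "outer_diameter_um_point1", "required": true, "kind": "decimal", "units": "um"},
    {"name": "outer_diameter_um_point2", "required": true, "kind": "decimal", "units": "um"},
    {"name": "outer_diameter_um_point3", "required": true, "kind": "decimal", "units": "um"},
    {"name": "n_images", "required": true, "kind": "integer", "units": "count"},
    {"name": "microscope_id", "required": true, "kind": "identifier"}
  ]
}
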