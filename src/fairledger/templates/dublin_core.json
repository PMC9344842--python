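{
  "template_id": "dublin-core",
  "version": 1,
  "base": null,
  "fields": [
    {"name": "Creator", "required": true, "kind": "free-text"},
    {"name": "Contributor", "required": true, "kind": "free-text"},
    {"name": "Publisher", "required": true, "kind": "free-text"},
    {"name": "Title", "required": true, "kind": "free-text"},
    {"name": "Date", "required": true, "kind": "date"},
    {"name": "Language", "required": true, "kind": "language-code"},
    {"name": "Format", "required": true, "kind": "free-text"},
    {"name": "Subject", "required": true, "kind": "free-text"},
    {"name": "Description", "required": true, "kind": "free-text"},
    {"name": "Identifier", "required": true, "kind": "identifier"},
    {"name": "Relation", "required": true, "kind": "free-text"},
    {"name": "Source", "required": true, "kind": "free-text"},
    {"name": "Type", "required": true, "kind": "free-text"},
    {"name": "Coverage", "required": true, "kind": "free-text"},
    {"name": "Rights", "required": true, "kind": "free-text"}
  ]
}
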