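{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/ccnkit/dendrogram.schema.json",
  "title": "CCN dendrogram node",
  "description": "Canonical JSON serialization of a cell type taxonomy tree. Leaves omit 'children' or carry an empty array and must have an 'original_label' (the publication's cluster name) or an annotated cell set label; internal nodes have at least two children. Annotation fields are present only after the CCN has been applied.",
  "type": "object",
  "required": ["node_id"],
  "properties": {
    "node_id": {"type": "string", "minLength": 1},
    "original_label": {"type": "string"},
    "cell_set_accession": {"type": "string", "pattern": "^CS[0-9]{8}[0-9]+_[0-9]+$"},
    "cell_set_label": {"type": "string"},
    "cell_set_preferred_alias": {"type": "string"},
    "cell_set_aligned_alias": {"type": "string"},
    "children": {
      "type": "array",
      "items": {"$ref": "#"}
    }
  },
  "additionalProperties": false
}
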