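{
  "name": "igg-pathway-extension-rules",
  "version": "1.0",
  "comment": "Six rules grouping candidate reactions (single-sugar additions absent from the known pathway) by enzyme and substrate features. Predicates are feature bounds on the substrate structure; the three FUT8 predicates are mutually exclusive so the rules partition the candidate set.",
  "rules": [
    {
      "id": "F1",
      "enzyme": "FUT8",
      "description": "core fucosylation of galactosylated, non-bisected, non-sialylated glycans",
      "predicate": {"gal_min": 1, "bis": false, "sia_max": 0}
    },
    {
      "id": "F2",
      "enzyme": "FUT8",
      "description": "core fucosylation of bisected glycans (includes G0N, inhibited in vitro)",
      "predicate": {"bis": true}
    },
    {
      "id": "F3",
      "enzyme": "FUT8",
      "description": "core fucosylation of sialylated, non-bisected glycans",
      "predicate": {"bis": false, "sia_min": 1}
    },
    {
      "id": "G1",
      "enzyme": "B4GalT1",
      "description": "galactosylation of sialylated glycans",
      "predicate": {"sia_min": 1}
    },
    {
      "id": "N1",
      "enzyme": "MGAT3",
      "description": "bisection of galactosylated, non-fucosylated glycans",
      "predicate": {"gal_min": 1, "fuc": false}
    },
    {
      "id": "N2",
      "enzyme": "MGAT3",
      "description": "bisection of galactosylated, fucosylated glycans",
      "predicate": {"gal_min": 1, "fuc": true}
    }
  ]
}
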