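{
  "name": "igg-fc-known-glycosylation-pathway",
  "version": "1.0",
  "comment": "Known IgG Fc N-glycosylation pathway on the biantennary complex-type panel. Boxes = glycan structures, arrows = single-sugar-unit enzymatic additions. Unmeasured structures are listed in the panel but absent from every subclass's measured list.",
  "panel": [
    "G0", "G0F", "G0N", "G0FN",
    "G1", "G1F", "G1N", "G1FN", "G1S1", "G1FS1", "G1FNS1",
    "G2", "G2F", "G2N", "G2FN", "G2S1", "G2FS1", "G2FNS1",
    "G2S2", "G2FS2", "G2FNS2"
  ],
  "measured": {
    "IgG1": [
      "G0", "G0F", "G0N", "G0FN",
      "G1", "G1F", "G1N", "G1FN", "G1S1", "G1FS1",
      "G2", "G2F", "G2N", "G2FN", "G2S1", "G2FS1", "G2FNS1",
      "G2S2", "G2FS2", "G2FNS2"
    ],
    "IgG2": [
      "G0", "G0F", "G0N", "G0FN",
      "G1", "G1F", "G1N", "G1FN", "G1S1", "G1FS1",
      "G2", "G2F", "G2N", "G2FN", "G2S1", "G2FS1", "G2FNS1",
      "G2S2", "G2FS2", "G2FNS2"
    ],
    "IgG4": [
      "G0F", "G0FN",
      "G1F", "G1FN", "G1FS1",
      "G2F", "G2FN", "G2FS1", "G2FNS1", "G2FS2"
    ]
  },
  "reactions": [
    ["G0", "G0F", "FUT8"],
    ["G0", "G0N", "MGAT3"],
    ["G0F", "G0FN", "MGAT3"],
    ["G0", "G1", "B4GalT1"],
    ["G1", "G2", "B4GalT1"],
    ["G0F", "G1F", "B4GalT1"],
    ["G1F", "G2F", "B4GalT1"],
    ["G0N", "G1N", "B4GalT1"],
    ["G1N", "G2N", "B4GalT1"],
    ["G0FN", "G1FN", "B4GalT1"],
    ["G1FN", "G2FN", "B4GalT1"],
    ["G1", "G1S1", "ST6Gal1"],
    ["G2", "G2S1", "ST6Gal1"],
    ["G2S1", "G2S2", "ST6Gal1"],
    ["G1F", "G1FS1", "ST6Gal1"],
    ["G2F", "G2FS1", "ST6Gal1"],
    ["G2FS1", "G2FS2", "ST6Gal1"],
    ["G1FN", "G1FNS1", "ST6Gal1"],
    ["G2FN", "G2FNS1", "ST6Gal1"],
    ["G2FNS1", "G2FNS2", "ST6Gal1"]
  ]
}
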