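{
  "group": "all",
  "n_group": 9,
  "threshold": 0.02,
  "nodes": [
    {
      "pattern": "L-dopa",
      "n_patients": 8
    },
    {
      "pattern": "L-dopa+MAOBI",
      "n_patients": 1
    },
    {
      "pattern": "NE-DA",
      "n_patients": 1
    }
  ],
  "edges": [
    {
      "from": "L-dopa",
      "to": "L-dopa+MAOBI",
      "n_patients": 1
    }
  ]
}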