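[
  {
    "consequent": "P",
    "conditions": [
      {"channel": "MQ3", "lower": 259, "upper": 642},
      {"channel": "MS1100", "lower": 61, "upper": 449},
      {"channel": "NEM1", "lower": 19, "upper": 36}
    ]
  },
  {
    "consequent": "P",
    "conditions": [
      {"channel": "MS1100", "lower": 61, "upper": 404},
      {"channel": "MQ6", "lower": 183, "upper": 387},
      {"channel": "TEMP1", "lower": 24, "upper": 41},
      {"channel": "NEM1", "lower": 19, "upper": 36}
    ]
  },
  {
    "consequent": "P",
    "conditions": [
      {"channel": "T2620", "lower": 739, "upper": 963}
    ]
  },
  {
    "consequent": "P",
    "conditions": [
      {"channel": "MQ8", "lower": 111, "upper": 320},
      {"channel": "MQ3", "lower": 259, "upper": 642},
      {"channel": "NEM1", "lower": 19, "upper": 36}
    ]
  },
  {
    "consequent": "A",
    "conditions": [
      {"channel": "NH3", "lower": 663, "upper": 748},
      {"channel": "NO2", "lower": 105, "upper": 248},
      {"channel": "T2620", "lower": 784, "upper": 937},
      {"channel": "MQ7", "lower": 170, "upper": 183},
      {"channel": "MQ6", "lower": 279, "upper": 323},
      {"channel": "MQ4", "lower": 82, "upper": 284},
      {"channel": "TEMP1", "lower": 29, "upper": 36}
    ]
  },
  {
    "consequent": "A",
    "conditions": [
      {"channel": "MQ8", "lower": 254, "upper": 273},
      {"channel": "NO2", "lower": 119, "upper": 238},
      {"channel": "T2620", "lower": 751, "upper": 932},
      {"channel": "MQ6", "lower": 251, "upper": 332},
      {"channel": "MQ4", "lower": 141, "upper": 277},
      {"channel": "TEMP1", "lower": 27, "upper": 36}
    ]
  },
  {
    "consequent": "A",
    "conditions": [
      {"channel": "T2602", "lower": 923, "upper": 955},
      {"channel": "T822", "lower": 498, "upper": 796},
      {"channel": "HCHO", "lower": 166, "upper": 270},
      {"channel": "MQ7", "lower": 134, "upper": 250}
    ]
  },
  {
    "consequent": "A",
    "conditions": [
      {"channel": "MQ3", "lower": 385, "upper": 549},
      {"channel": "NH3", "lower": 735, "upper": 792},
      {"channel": "T2602", "lower": 910, "upper": 972},
      {"channel": "MQ6", "lower": 263, "upper": 359},
      {"channel": "MQ4", "lower": 118, "upper": 288},
      {"channel": "NEM1", "lower": 21, "upper": 33}
    ]
  }
]
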