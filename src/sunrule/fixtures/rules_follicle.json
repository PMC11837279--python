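[
  {
    "consequent": "L",
    "conditions": [
      {"channel": "MQ3", "lower": 266, "upper": 637},
      {"channel": "NH3", "lower": 516, "upper": 847}
    ]
  },
  {
    "consequent": "L",
    "conditions": [
      {"channel": "MQ3", "lower": 265, "upper": 637},
      {"channel": "NH3", "lower": 515, "upper": 848}
    ]
  },
  {
    "consequent": "L",
    "conditions": [
      {"channel": "MQ3", "lower": 266, "upper": 637},
      {"channel": "NH3", "lower": 516, "upper": 847}
    ]
  },
  {
    "consequent": "L",
    "conditions": [
      {"channel": "MQ3", "lower": 265, "upper": 637},
      {"channel": "NH3", "lower": 515, "upper": 847}
    ]
  },
  {
    "consequent": "O",
    "conditions": [
      {"channel": "MQ8", "lower": 246, "upper": 318},
      {"channel": "NH3", "lower": 559, "upper": 747},
      {"channel": "T2602", "lower": 905, "upper": 972},
      {"channel": "NO2", "lower": 57, "upper": 172},
      {"channel": "T822", "lower": 527, "upper": 836},
      {"channel": "T2620", "lower": 840, "upper": 920},
      {"channel": "MS1100", "lower": 302, "upper": 394},
      {"channel": "MQ6", "lower": 200, "upper": 344},
      {"channel": "TEMP1", "lower": 31, "upper": 32}
    ]
  },
  {
    "consequent": "O",
    "conditions": [
      {"channel": "MQ8", "lower": 263, "upper": 299},
      {"channel": "NH3", "lower": 529, "upper": 781},
      {"channel": "T2602", "lower": 902, "upper": 970},
      {"channel": "NO2", "lower": 58, "upper": 98},
      {"channel": "T822", "lower": 543, "upper": 744},
      {"channel": "HCHO", "lower": 213, "upper": 244},
      {"channel": "T2620", "lower": 856, "upper": 907},
      {"channel": "MS1100", "lower": 331, "upper": 333},
      {"channel": "MQ7", "lower": 225, "upper": 225},
      {"channel": "MQ135", "lower": 770, "upper": 901}
    ]
  },
  {
    "consequent": "O",
    "conditions": [
      {"channel": "NO2", "lower": 57, "upper": 219},
      {"channel": "HCHO", "lower": 128, "upper": 222},
      {"channel": "T2620", "lower": 736, "upper": 860},
      {"channel": "MS1100", "lower": 149, "upper": 254},
      {"channel": "MQ7", "lower": 199, "upper": 206},
      {"channel": "MQ6", "lower": 206, "upper": 251},
      {"channel": "MQ135", "lower": 804, "upper": 854},
      {"channel": "TEMP1", "lower": 31, "upper": 39}
    ]
  },
  {
    "consequent": "O",
    "conditions": [
      {"channel": "MQ8", "lower": 183, "upper": 206},
      {"channel": "T2620", "lower": 875, "upper": 948},
      {"channel": "MQ7", "lower": 127, "upper": 217}
    ]
  }
]
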