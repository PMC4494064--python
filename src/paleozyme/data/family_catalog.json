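{
  "description": "The 20 surveyed carbohydrate-active enzyme families involved in pectin degradation. Classes: GH = glycoside hydrolase, PL = polysaccharide lyase, CE = carbohydrate esterase. Nine families are pectin-specific.",
  "families": {
    "GH28": {"class": "GH", "pectin_specific": true},
    "GH53": {"class": "GH", "pectin_specific": true},
    "GH93": {"class": "GH", "pectin_specific": true},
    "PL1": {"class": "PL", "pectin_specific": true},
    "PL3": {"class": "PL", "pectin_specific": true},
    "PL4": {"class": "PL", "pectin_specific": true},
    "PL11": {"class": "PL", "pectin_specific": true},
    "CE8": {"class": "CE", "pectin_specific": true},
    "CE13": {"class": "CE", "pectin_specific": true},
    "GH2": {"class": "GH", "pectin_specific": false},
    "GH35": {"class": "GH", "pectin_specific": false},
    "GH43": {"class": "GH", "pectin_specific": false},
    "GH51": {"class": "GH", "pectin_specific": false},
    "GH54": {"class": "GH", "pectin_specific": false},
    "GH78": {"class": "GH", "pectin_specific": false},
    "GH88": {"class": "GH", "pectin_specific": false},
    "GH105": {"class": "GH", "pectin_specific": false},
    "PL9": {"class": "PL", "pectin_specific": false},
    "CE12": {"class": "CE", "pectin_specific": false},
    "CE1": {"class": "CE", "pectin_specific": false}
  }
}
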