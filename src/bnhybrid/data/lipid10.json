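{
 "variables": [
  {
   "name": "Gender",
   "levels": [
    "male",
    "female"
   ]
  },
  {
   "name": "Smoking",
   "levels": [
    "no",
    "yes"
   ]
  },
  {
   "name": "PhysicalActivity",
   "levels": [
    "Insufficient",
    "Normal",
    "Sufficient"
   ]
  },
  {
   "name": "SaltIntake",
   "levels": [
    "<6g",
    "≥6g"
   ]
  },
  {
   "name": "OilIntake",
   "levels": [
    "<25g",
    "≥25g"
   ]
  },
  {
   "name": "BMI",
   "levels": [
    "<18.5",
    "18.5~",
    "24.0~",
    "28.0~"
   ]
  },
  {
   "name": "CentralObesity",
   "levels": [
    "no",
    "yes"
   ]
  },
  {
   "name": "Hyperlipidemia",
   "levels": [
    "no",
    "yes"
   ]
  },
  {
   "name": "Hypertension",
   "levels": [
    "no",
    "yes"
   ]
  },
  {
   "name": "Diabetes",
   "levels": [
    "no",
    "yes"
   ]
  }
 ],
 "edges": [
  [
   "BMI",
   "CentralObesity"
  ],
  [
   "BMI",
   "Hyperlipidemia"
  ],
  [
   "CentralObesity",
   "Diabetes"
  ],
  [
   "CentralObesity",
   "Hypertension"
  ],
  [
   "Gender",
   "Hyperlipidemia"
  ],
  [
   "Gender",
   "PhysicalActivity"
  ],
  [
   "Gender",
   "Smoking"
  ],
  [
   "Hyperlipidemia",
   "Diabetes"
  ],
  [
   "Hyperlipidemia",
   "Hypertension"
  ],
  [
   "OilIntake",
   "Hypertension"
  ],
  [
   "PhysicalActivity",
   "BMI"
  ],
  [
   "PhysicalActivity",
   "Hyperlipidemia"
  ],
  [
   "SaltIntake",
   "Hypertension"
  ],
  [
   "Smoking",
   "Hypertension"
  ]
 ],
 "cpts": {
  "Gender": {
   "parents": [],
   "table": [
    [
     0.48959929932121743,
     0.5104007006787825
    ]
   ]
  },
  "Smoking": {
   "parents": [
    "Gender"
   ],
   "table": [
    [
     0.48,
     0.52
    ],
    [
     0.97,
     0.030000000000000027
    ]
   ]
  },
  "PhysicalActivity": {
   "parents": [
    "Gender"
   ],
   "table": [
    [
     0.32,
     0.4,
     0.28
    ],
    [
     0.38,
     0.4,
     0.22
    ]
   ]
  },
  "SaltIntake": {
   "parents": [],
   "table": [
    [
     0.4,
     0.6
    ]
   ]
  },
  "OilIntake": {
   "parents": [],
   "table": [
    [
     0.44999999999999996,
     0.55
    ]
   ]
  },
  "BMI": {
   "parents": [
    "PhysicalActivity"
   ],
   "table": [
    [
     0.04,
     0.42,
     0.36,
     0.18
    ],
    [
     0.05,
     0.47,
     0.33,
     0.15
    ],
    [
     0.06,
     0.52,
     0.32,
     0.1
    ]
   ]
  },
  "CentralObesity": {
   "parents": [
    "BMI"
   ],
   "table": [
    [
     0.98,
     0.020000000000000018
    ],
    [
     0.8,
     0.19999999999999996
    ],
    [
     0.44999999999999996,
     0.55
    ],
    [
     0.030000000000000027,
     0.97
    ]
   ]
  },
  "Hyperlipidemia": {
   "parents": [
    "PhysicalActivity",
    "Gender",
    "BMI"
   ],
   "table": [
    [
     0.6485099999999999,
     0.35149
    ],
    [
     0.57515,
     0.42485
    ],
    [
     0.37926000000000004,
     0.62074
    ],
    [
     0.24727,
     0.75273
    ],
    [
     0.69397,
     0.30603
    ],
    [
     0.57664,
     0.42335999999999996
    ],
    [
     0.5828,
     0.4172
    ],
    [
     0.37888,
     0.62112
    ],
    [
     0.94811,
     0.05189
    ],
    [
     0.61095,
     0.38905
    ],
    [
     0.43688000000000005,
     0.56312
    ],
    [
     0.29294,
     0.70706
    ],
    [
     0.82164,
     0.17836
    ],
    [
     0.70408,
     0.29591999999999996
    ],
    [
     0.52875,
     0.47125
    ],
    [
     0.4345300000000001,
     0.5654699999999999
    ],
    [
     0.5235799999999999,
     0.47642
    ],
    [
     0.66463,
     0.33537
    ],
    [
     0.43642000000000003,
     0.56358
    ],
    [
     0.25059,
     0.74941
    ],
    [
     0.62195,
     0.37805
    ],
    [
     0.64173,
     0.35827
    ],
    [
     0.55612,
     0.44388
    ],
    [
     0.48239,
     0.51761
    ]
   ]
  },
  "Hypertension": {
   "parents": [
    "Hyperlipidemia",
    "Smoking",
    "SaltIntake",
    "OilIntake",
    "CentralObesity"
   ],
   "table": [
    [
     0.95,
     0.050000000000000044
    ],
    [
     0.35,
     0.65
    ],
    [
     0.35,
     0.65
    ],
    [
     0.05,
     0.95
    ],
    [
     0.35,
     0.65
    ],
    [
     0.05,
     0.95
    ],
    [
     0.05,
     0.95
    ],
    [
     0.05,
     0.95
    ],
    [
     0.35,
     0.65
    ],
    [
     0.05,
     0.95
    ],
    [
     0.05,
     0.95
    ],
    [
     0.05,
     0.95
    ],
    [
     0.05,
     0.95
    ],
    [
     0.05,
     0.95
    ],
    [
     0.05,
     0.95
    ],
    [
     0.05,
     0.95
    ],
    [
     0.35,
     0.65
    ],
    [
     0.05,
     0.95
    ],
    [
     0.05,
     0.95
    ],
    [
     0.05,
     0.95
    ],
    [
     0.05,
     0.95
    ],
    [
     0.05,
     0.95
    ],
    [
     0.05,
     0.95
    ],
    [
     0.05,
     0.95
    ],
    [
     0.05,
     0.95
    ],
    [
     0.05,
     0.95
    ],
    [
     0.05,
     0.95
    ],
    [
     0.05,
     0.95
    ],
    [
     0.05,
     0.95
    ],
    [
     0.05,
     0.95
    ],
    [
     0.05,
     0.95
    ],
    [
     0.05,
     0.95
    ]
   ]
  },
  "Diabetes": {
   "parents": [
    "Hyperlipidemia",
    "CentralObesity"
   ],
   "table": [
    [
     0.95,
     0.050000000000000044
    ],
    [
     0.35,
     0.65
    ],
    [
     0.35,
     0.65
    ],
    [
     0.05,
     0.95
    ]
   ]
  }
 }
}
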