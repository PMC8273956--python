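{
 "variables": [
  {
   "name": "Cloudy",
   "levels": [
    "T",
    "F"
   ]
  },
  {
   "name": "Sprinkler",
   "levels": [
    "T",
    "F"
   ]
  },
  {
   "name": "Rain",
   "levels": [
    "T",
    "F"
   ]
  },
  {
   "name": "WetGrass",
   "levels": [
    "T",
    "F"
   ]
  }
 ],
 "edges": [
  [
   "Cloudy",
   "Rain"
  ],
  [
   "Cloudy",
   "Sprinkler"
  ],
  [
   "Rain",
   "WetGrass"
  ],
  [
   "Sprinkler",
   "WetGrass"
  ]
 ],
 "cpts": {
  "Cloudy": {
   "parents": [],
   "table": [
    [
     0.5,
     0.5
    ]
   ]
  },
  "Sprinkler": {
   "parents": [
    "Cloudy"
   ],
   "table": [
    [
     0.1,
     0.9
    ],
    [
     0.5,
     0.5
    ]
   ]
  },
  "Rain": {
   "parents": [
    "Cloudy"
   ],
   "table": [
    [
     0.8,
     0.19999999999999996
    ],
    [
     0.2,
     0.8
    ]
   ]
  },
  "WetGrass": {
   "parents": [
    "Sprinkler",
    "Rain"
   ],
   "table": [
    [
     0.99,
     0.010000000000000009
    ],
    [
     0.9,
     0.09999999999999998
    ],
    [
     0.9,
     0.09999999999999998
    ],
    [
     0.0,
     1.0
    ]
   ]
  }
 }
}
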