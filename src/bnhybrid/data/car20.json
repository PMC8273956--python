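{
 "variables": [
  {
   "name": "BatteryAge",
   "levels": [
    "ok",
    "bad"
   ]
  },
  {
   "name": "Alternator",
   "levels": [
    "ok",
    "bad"
   ]
  },
  {
   "name": "ChargingSystem",
   "levels": [
    "ok",
    "bad"
   ]
  },
  {
   "name": "BatteryState",
   "levels": [
    "ok",
    "bad"
   ]
  },
  {
   "name": "BatteryVoltage",
   "levels": [
    "ok",
    "bad"
   ]
  },
  {
   "name": "MainFuse",
   "levels": [
    "ok",
    "bad"
   ]
  },
  {
   "name": "Distributor",
   "levels": [
    "ok",
    "bad"
   ]
  },
  {
   "name": "VoltageAtPlug",
   "levels": [
    "ok",
    "bad"
   ]
  },
  {
   "name": "SparkPlugs",
   "levels": [
    "ok",
    "bad"
   ]
  },
  {
   "name": "SparkTiming",
   "levels": [
    "ok",
    "bad"
   ]
  },
  {
   "name": "SparkQuality",
   "levels": [
    "ok",
    "bad"
   ]
  },
  {
   "name": "StarterMotor",
   "levels": [
    "ok",
    "bad"
   ]
  },
  {
   "name": "Starter",
   "levels": [
    "ok",
    "bad"
   ]
  },
  {
   "name": "CarCranks",
   "levels": [
    "ok",
    "bad"
   ]
  },
  {
   "name": "FuelPump",
   "levels": [
    "ok",
    "bad"
   ]
  },
  {
   "name": "FuelSystem",
   "levels": [
    "ok",
    "bad"
   ]
  },
  {
   "name": "AirFilter",
   "levels": [
    "ok",
    "bad"
   ]
  },
  {
   "name": "AirSystem",
   "levels": [
    "ok",
    "bad"
   ]
  },
  {
   "name": "CarStarts",
   "levels": [
    "ok",
    "bad"
   ]
  },
  {
   "name": "Headlights",
   "levels": [
    "ok",
    "bad"
   ]
  }
 ],
 "edges": [
  [
   "AirFilter",
   "AirSystem"
  ],
  [
   "AirSystem",
   "CarStarts"
  ],
  [
   "Alternator",
   "ChargingSystem"
  ],
  [
   "BatteryAge",
   "BatteryState"
  ],
  [
   "BatteryState",
   "BatteryVoltage"
  ],
  [
   "BatteryVoltage",
   "CarCranks"
  ],
  [
   "BatteryVoltage",
   "Headlights"
  ],
  [
   "BatteryVoltage",
   "Starter"
  ],
  [
   "BatteryVoltage",
   "VoltageAtPlug"
  ],
  [
   "CarCranks",
   "CarStarts"
  ],
  [
   "ChargingSystem",
   "BatteryState"
  ],
  [
   "Distributor",
   "SparkTiming"
  ],
  [
   "Distributor",
   "VoltageAtPlug"
  ],
  [
   "FuelPump",
   "FuelSystem"
  ],
  [
   "FuelSystem",
   "CarStarts"
  ],
  [
   "MainFuse",
   "VoltageAtPlug"
  ],
  [
   "SparkPlugs",
   "SparkQuality"
  ],
  [
   "SparkQuality",
   "CarStarts"
  ],
  [
   "SparkTiming",
   "SparkQuality"
  ],
  [
   "Starter",
   "CarCranks"
  ],
  [
   "StarterMotor",
   "Starter"
  ],
  [
   "VoltageAtPlug",
   "SparkQuality"
  ]
 ],
 "cpts": {
  "BatteryAge": {
   "parents": [],
   "table": [
    [
     0.8,
     0.19999999999999996
    ]
   ]
  },
  "Alternator": {
   "parents": [],
   "table": [
    [
     0.8,
     0.19999999999999996
    ]
   ]
  },
  "ChargingSystem": {
   "parents": [
    "Alternator"
   ],
   "table": [
    [
     0.95,
     0.050000000000000044
    ],
    [
     0.35,
     0.65
    ]
   ]
  },
  "BatteryState": {
   "parents": [
    "BatteryAge",
    "ChargingSystem"
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
  },
  "BatteryVoltage": {
   "parents": [
    "BatteryState"
   ],
   "table": [
    [
     0.95,
     0.050000000000000044
    ],
    [
     0.35,
     0.65
    ]
   ]
  },
  "MainFuse": {
   "parents": [],
   "table": [
    [
     0.8,
     0.19999999999999996
    ]
   ]
  },
  "Distributor": {
   "parents": [],
   "table": [
    [
     0.8,
     0.19999999999999996
    ]
   ]
  },
  "VoltageAtPlug": {
   "parents": [
    "BatteryVoltage",
    "Distributor",
    "MainFuse"
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
    ]
   ]
  },
  "SparkPlugs": {
   "parents": [],
   "table": [
    [
     0.8,
     0.19999999999999996
    ]
   ]
  },
  "SparkTiming": {
   "parents": [
    "Distributor"
   ],
   "table": [
    [
     0.95,
     0.050000000000000044
    ],
    [
     0.35,
     0.65
    ]
   ]
  },
  "SparkQuality": {
   "parents": [
    "SparkPlugs",
    "SparkTiming",
    "VoltageAtPlug"
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
    ]
   ]
  },
  "StarterMotor": {
   "parents": [],
   "table": [
    [
     0.8,
     0.19999999999999996
    ]
   ]
  },
  "Starter": {
   "parents": [
    "BatteryVoltage",
    "StarterMotor"
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
  },
  "CarCranks": {
   "parents": [
    "BatteryVoltage",
    "Starter"
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
  },
  "FuelPump": {
   "parents": [],
   "table": [
    [
     0.8,
     0.19999999999999996
    ]
   ]
  },
  "FuelSystem": {
   "parents": [
    "FuelPump"
   ],
   "table": [
    [
     0.95,
     0.050000000000000044
    ],
    [
     0.35,
     0.65
    ]
   ]
  },
  "AirFilter": {
   "parents": [],
   "table": [
    [
     0.8,
     0.19999999999999996
    ]
   ]
  },
  "AirSystem": {
   "parents": [
    "AirFilter"
   ],
   "table": [
    [
     0.95,
     0.050000000000000044
    ],
    [
     0.35,
     0.65
    ]
   ]
  },
  "CarStarts": {
   "parents": [
    "AirSystem",
    "CarCranks",
    "FuelSystem",
    "SparkQuality"
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
    ]
   ]
  },
  "Headlights": {
   "parents": [
    "BatteryVoltage"
   ],
   "table": [
    [
     0.95,
     0.050000000000000044
    ],
    [
     0.35,
     0.65
    ]
   ]
  }
 }
}
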