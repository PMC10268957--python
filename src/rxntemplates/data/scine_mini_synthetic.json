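{
 "compounds": {
  "c-acetaldehyde": {
   "structures": [
    "s-acetaldehyde"
   ]
  },
  "c-eo": {
   "structures": [
    "s-eo"
   ]
  },
  "c-ethoxide": {
   "structures": [
    "s-ethoxide"
   ]
  },
  "c-hydride": {
   "structures": [
    "s-hydride"
   ]
  },
  "c-n1": {
   "structures": [
    "s-n1"
   ]
  },
  "c-n2": {
   "structures": [
    "s-n2"
   ]
  }
 },
 "elementary_steps": {
  "es-1": {
   "atom_map": [
    [
     0,
     0
    ],
    [
     1,
     1
    ],
    [
     2,
     2
    ],
    [
     3,
     3
    ],
    [
     4,
     4
    ],
    [
     5,
     5
    ],
    [
     6,
     6
    ],
    [
     7,
     7
    ],
    [
     8,
     8
    ],
    [
     9,
     9
    ],
    [
     10,
     10
    ],
    [
     11,
     11
    ],
    [
     12,
     12
    ],
    [
     13,
     13
    ],
    [
     14,
     14
    ]
   ],
   "energies": {
    "product": -0.011426396543488536,
    "reactant": 0.0,
    "ts": 0.027423351704372486
   },
   "products": [
    "s-n1"
   ],
   "reactants": [
    "s-ethoxide",
    "s-eo"
   ]
  },
  "es-2": {
   "atom_map": [
    [
     0,
     0
    ],
    [
     1,
     1
    ],
    [
     2,
     2
    ],
    [
     3,
     3
    ],
    [
     4,
     4
    ],
    [
     5,
     5
    ],
    [
     6,
     6
    ],
    [
     7,
     7
    ],
    [
     8,
     8
    ],
    [
     9,
     9
    ],
    [
     10,
     10
    ],
    [
     11,
     11
    ],
    [
     12,
     12
    ],
    [
     13,
     13
    ],
    [
     14,
     14
    ],
    [
     15,
     15
    ],
    [
     16,
     16
    ],
    [
     17,
     17
    ],
    [
     18,
     18
    ],
    [
     19,
     19
    ],
    [
     20,
     20
    ],
    [
     21,
     21
    ]
   ],
   "energies": {
    "product": -0.011426396543488536,
    "reactant": 0.0,
    "ts": 0.030470390782636095
   },
   "products": [
    "s-n2"
   ],
   "reactants": [
    "s-n1",
    "s-eo"
   ]
  },
  "es-3": {
   "atom_map": [
    [
     0,
     0
    ],
    [
     1,
     1
    ],
    [
     2,
     2
    ],
    [
     3,
     7
    ],
    [
     4,
     3
    ],
    [
     5,
     4
    ],
    [
     6,
     5
    ],
    [
     7,
     6
    ]
   ],
   "energies": {
    "product": -0.07617597695659024,
    "reactant": 0.0,
    "ts": 0.001904399423914756
   },
   "products": [
    "s-acetaldehyde",
    "s-hydride"
   ],
   "reactants": [
    "s-ethoxide"
   ]
  },
  "es-broken": {
   "energies": {
    "product": -0.01,
    "reactant": 0.0,
    "ts": 0.02
   },
   "products": [
    "s-n1"
   ],
   "reactants": [
    "s-ethoxide",
    "s-eo"
   ]
  }
 },
 "format": "scine-db-export/1.1.0",
 "reactions": {
  "r-1": {
   "lhs_compounds": [
    "c-ethoxide",
    "c-eo"
   ],
   "rhs_compounds": [
    "c-n1"
   ],
   "steps": [
    "es-1"
   ]
  },
  "r-2": {
   "lhs_compounds": [
    "c-n1",
    "c-eo"
   ],
   "rhs_compounds": [
    "c-n2"
   ],
   "steps": [
    "es-2"
   ]
  },
  "r-3": {
   "lhs_compounds": [
    "c-ethoxide"
   ],
   "rhs_compounds": [
    "c-acetaldehyde",
    "c-hydride"
   ],
   "steps": [
    "es-3",
    "es-broken"
   ]
  }
 },
 "structures": {
  "s-acetaldehyde": {
   "bonds": [
    [
     0,
     1,
     1.0
    ],
    [
     1,
     2,
     1.0
    ],
    [
     1,
     3,
     1.0
    ],
    [
     2,
     4,
     1.0
    ],
    [
     2,
     5,
     1.0
    ],
    [
     2,
     6,
     1.0
    ]
   ],
   "charge": 0,
   "elements": [
    "O",
    "C",
    "C",
    "H",
    "H",
    "H",
    "H"
   ],
   "formal_charges": [
    0,
    0,
    0,
    0,
    0,
    0,
    0
   ]
  },
  "s-eo": {
   "bonds": [
    [
     0,
     1,
     1.0
    ],
    [
     0,
     2,
     1.0
    ],
    [
     1,
     2,
     1.0
    ],
    [
     1,
     3,
     1.0
    ],
    [
     1,
     4,
     1.0
    ],
    [
     2,
     5,
     1.0
    ],
    [
     2,
     6,
     1.0
    ]
   ],
   "charge": 0,
   "elements": [
    "O",
    "C",
    "C",
    "H",
    "H",
    "H",
    "H"
   ],
   "formal_charges": [
    0,
    0,
    0,
    0,
    0,
    0,
    0
   ]
  },
  "s-ethoxide": {
   "bonds": [
    [
     0,
     1,
     1.0
    ],
    [
     1,
     2,
     1.0
    ],
    [
     1,
     3,
     1.0
    ],
    [
     1,
     4,
     1.0
    ],
    [
     2,
     5,
     1.0
    ],
    [
     2,
     6,
     1.0
    ],
    [
     2,
     7,
     1.0
    ]
   ],
   "charge": -1,
   "elements": [
    "O",
    "C",
    "C",
    "H",
    "H",
    "H",
    "H",
    "H"
   ],
   "formal_charges": [
    -1,
    0,
    0,
    0,
    0,
    0,
    0,
    0
   ]
  },
  "s-hydride": {
   "bonds": [],
   "charge": -1,
   "elements": [
    "H"
   ],
   "formal_charges": [
    -1
   ]
  },
  "s-n1": {
   "bonds": [
    [
     0,
     1,
     1.0
    ],
    [
     0,
     9,
     1.0
    ],
    [
     1,
     2,
     1.0
    ],
    [
     1,
     3,
     1.0
    ],
    [
     1,
     4,
     1.0
    ],
    [
     2,
     5,
     1.0
    ],
    [
     2,
     6,
     1.0
    ],
    [
     2,
     7,
     1.0
    ],
    [
     8,
     10,
     1.0
    ],
    [
     9,
     10,
     1.0
    ],
    [
     9,
     11,
     1.0
    ],
    [
     9,
     12,
     1.0
    ],
    [
     10,
     13,
     1.0
    ],
    [
     10,
     14,
     1.0
    ]
   ],
   "charge": -1,
   "elements": [
    "O",
    "C",
    "C",
    "H",
    "H",
    "H",
    "H",
    "H",
    "O",
    "C",
    "C",
    "H",
    "H",
    "H",
    "H"
   ],
   "formal_charges": [
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    -1,
    0,
    0,
    0,
    0,
    0,
    0
   ]
  },
  "s-n2": {
   "bonds": [
    [
     0,
     1,
     1.0
    ],
    [
     0,
     9,
     1.0
    ],
    [
     1,
     2,
     1.0
    ],
    [
     1,
     3,
     1.0
    ],
    [
     1,
     4,
     1.0
    ],
    [
     2,
     5,
     1.0
    ],
    [
     2,
     6,
     1.0
    ],
    [
     2,
     7,
     1.0
    ],
    [
     8,
     10,
     1.0
    ],
    [
     8,
     16,
     1.0
    ],
    [
     9,
     10,
     1.0
    ],
    [
     9,
     11,
     1.0
    ],
    [
     9,
     12,
     1.0
    ],
    [
     10,
     13,
     1.0
    ],
    [
     10,
     14,
     1.0
    ],
    [
     15,
     17,
     1.0
    ],
    [
     16,
     17,
     1.0
    ],
    [
     16,
     18,
     1.0
    ],
    [
     16,
     19,
     1.0
    ],
    [
     17,
     20,
     1.0
    ],
    [
     17,
     21,
     1.0
    ]
   ],
   "charge": -1,
   "elements": [
    "O",
    "C",
    "C",
    "H",
    "H",
    "H",
    "H",
    "H",
    "O",
    "C",
    "C",
    "H",
    "H",
    "H",
    "H",
    "O",
    "C",
    "C",
    "H",
    "H",
    "H",
    "H"
   ],
   "formal_charges": [
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    -1,
    0,
    0,
    0,
    0,
    0,
    0
   ]
  }
 }
}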