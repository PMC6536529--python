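{
 "variant": "wooden",
 "footprint": {
  "width_x": 10.0,
  "length_y": 15.0
 },
 "wall_height": 2.5,
 "aperture_material": "glass",
 "aperture_thickness_cm": 0.8,
 "materials": {
  "air": {
   "composition": [
    [
     "C",
     0.0002
    ],
    [
     "N",
     0.7844
    ],
    [
     "O",
     0.2107
    ],
    [
     "Ar",
     0.0047
    ]
   ],
   "density": 0.001205
  },
  "brick": {
   "composition": [
    [
     "O",
     0.6634
    ],
    [
     "Al",
     0.0037
    ],
    [
     "Si",
     0.3232
    ],
    [
     "Ca",
     0.0071
    ],
    [
     "Fe",
     0.0025
    ]
   ],
   "density": 1.8
  },
  "concrete": {
   "composition": [
    [
     "H",
     0.0847
    ],
    [
     "O",
     0.6041
    ],
    [
     "Na",
     0.0125
    ],
    [
     "Al",
     0.0248
    ],
    [
     "Si",
     0.2419
    ],
    [
     "Ca",
     0.0272
    ],
    [
     "Fe",
     0.0047
    ]
   ],
   "density": 2.25
  },
  "glass": {
   "composition": [
    [
     "O",
     0.6039
    ],
    [
     "Na",
     0.0881
    ],
    [
     "Si",
     0.2518
    ],
    [
     "Ca",
     0.0562
    ]
   ],
   "density": 2.4
  },
  "gypsum": {
   "composition": [
    [
     "H",
     0.3333
    ],
    [
     "O",
     0.5
    ],
    [
     "S",
     0.0833
    ],
    [
     "Ca",
     0.0833
    ]
   ],
   "density": 2.32
  },
  "mineral_wool": {
   "composition": [
    [
     "O",
     0.425
    ],
    [
     "Na",
     0.017
    ],
    [
     "Mg",
     0.054
    ],
    [
     "Al",
     0.106
    ],
    [
     "Si",
     0.182
    ],
    [
     "K",
     0.019
    ],
    [
     "Ca",
     0.143
    ],
    [
     "Mn",
     0.005
    ],
    [
     "Fe",
     0.049
    ]
   ],
   "density": 0.1666667
  },
  "soil": {
   "composition": [
    [
     "H",
     0.3169
    ],
    [
     "O",
     0.5016
    ],
    [
     "Al",
     0.04
    ],
    [
     "Si",
     0.1416
    ]
   ],
   "density": 1.52
  },
  "wood": {
   "composition": [
    [
     "H",
     0.4624
    ],
    [
     "C",
     0.3234
    ],
    [
     "N",
     0.0028
    ],
    [
     "O",
     0.2088
    ],
    [
     "Mg",
     0.0006
    ],
    [
     "S",
     0.0012
    ],
    [
     "K",
     0.0004
    ],
    [
     "Ca",
     0.0004
    ]
   ],
   "density": 0.64
  }
 },
 "wall_stacks": {
  "exterior": [
   [
    "wood",
    2.2
   ],
   [
    "air",
    4.0
   ],
   [
    "gypsum",
    0.9
   ],
   [
    "mineral_wool",
    26.0
   ],
   [
    "air",
    2.8
   ],
   [
    "wood",
    1.1
   ],
   [
    "gypsum",
    1.3
   ]
  ],
  "roof": [
   [
    "concrete",
    5.4
   ],
   [
    "wood",
    2.7
   ]
  ],
  "ceiling": [
   [
    "gypsum",
    1.3
   ],
   [
    "air",
    2.8
   ],
   [
    "mineral_wool",
    40.0
   ]
  ]
 },
 "apertures": [
  {
   "wall": "S",
   "name": "living_picture",
   "offset": 1.5,
   "width": 2.0,
   "z0": 0.6,
   "height": 1.6
  },
  {
   "wall": "S",
   "name": "living_small",
   "offset": 4.4,
   "width": 1.2,
   "z0": 0.9,
   "height": 1.3
  },
  {
   "wall": "S",
   "name": "dining_window",
   "offset": 7.0,
   "width": 1.8,
   "z0": 0.9,
   "height": 1.3
  },
  {
   "wall": "N",
   "name": "bedroom_window",
   "offset": 1.5,
   "width": 1.9,
   "z0": 0.9,
   "height": 1.3
  },
  {
   "wall": "N",
   "name": "bedroom2_window",
   "offset": 6.5,
   "width": 1.9,
   "z0": 0.9,
   "height": 1.3
  },
  {
   "wall": "W",
   "name": "living_west",
   "offset": 2.0,
   "width": 1.2,
   "z0": 0.9,
   "height": 1.3
  },
  {
   "wall": "W",
   "name": "entrance_door",
   "offset": 6.0,
   "width": 1.0,
   "z0": 0.0,
   "height": 2.1
  },
  {
   "wall": "W",
   "name": "bathroom_window",
   "offset": 9.2,
   "width": 0.6,
   "z0": 1.4,
   "height": 0.6
  },
  {
   "wall": "W",
   "name": "bedroom_west",
   "offset": 12.4,
   "width": 1.2,
   "z0": 0.9,
   "height": 1.3
  },
  {
   "wall": "E",
   "name": "patio_door",
   "offset": 1.8,
   "width": 1.6,
   "z0": 0.0,
   "height": 2.1
  },
  {
   "wall": "E",
   "name": "kitchen_window",
   "offset": 6.0,
   "width": 1.4,
   "z0": 0.9,
   "height": 1.3
  },
  {
   "wall": "E",
   "name": "study_window",
   "offset": 9.0,
   "width": 1.0,
   "z0": 1.0,
   "height": 1.2
  },
  {
   "wall": "E",
   "name": "bedroom2_east",
   "offset": 12.5,
   "width": 1.0,
   "z0": 0.9,
   "height": 1.3
  }
 ],
 "rooms": [
  {
   "name": "bedroom",
   "bounds": [
    0,
    11,
    5,
    15
   ]
  },
  {
   "name": "bedroom2",
   "bounds": [
    5,
    11,
    10,
    15
   ]
  },
  {
   "name": "bathroom",
   "bounds": [
    0,
    8,
    3,
    11
   ]
  },
  {
   "name": "dressing",
   "bounds": [
    3,
    8,
    6,
    11
   ]
  },
  {
   "name": "restroom",
   "bounds": [
    6,
    8,
    8,
    11
   ]
  },
  {
   "name": "study",
   "bounds": [
    8,
    8,
    10,
    11
   ]
  },
  {
   "name": "corridor",
   "bounds": [
    0,
    5,
    4,
    8
   ]
  },
  {
   "name": "hall",
   "bounds": [
    4,
    5,
    7,
    8
   ]
  },
  {
   "name": "kitchen",
   "bounds": [
    7,
    5,
    10,
    8
   ]
  },
  {
   "name": "living",
   "bounds": [
    0,
    0,
    6,
    5
   ]
  },
  {
   "name": "dining",
   "bounds": [
    6,
    0,
    10,
    5
   ]
  }
 ],
 "interior_walls": [
  {
   "orientation": "y",
   "position": 11.0,
   "lo": 0.0,
   "hi": 10.0,
   "thickness_cm": 12.0
  },
  {
   "orientation": "y",
   "position": 8.0,
   "lo": 0.0,
   "hi": 10.0,
   "thickness_cm": 17.0
  },
  {
   "orientation": "y",
   "position": 5.0,
   "lo": 0.0,
   "hi": 10.0,
   "thickness_cm": 17.0
  },
  {
   "orientation": "x",
   "position": 5.0,
   "lo": 11.0,
   "hi": 15.0,
   "thickness_cm": 12.0
  },
  {
   "orientation": "x",
   "position": 3.0,
   "lo": 8.0,
   "hi": 11.0,
   "thickness_cm": 12.0
  },
  {
   "orientation": "x",
   "position": 6.0,
   "lo": 8.0,
   "hi": 11.0,
   "thickness_cm": 12.0
  },
  {
   "orientation": "x",
   "position": 8.0,
   "lo": 8.0,
   "hi": 11.0,
   "thickness_cm": 12.0
  },
  {
   "orientation": "x",
   "position": 4.0,
   "lo": 5.0,
   "hi": 8.0,
   "thickness_cm": 12.0
  },
  {
   "orientation": "x",
   "position": 7.0,
   "lo": 5.0,
   "hi": 8.0,
   "thickness_cm": 12.0
  },
  {
   "orientation": "x",
   "position": 6.0,
   "lo": 0.0,
   "hi": 5.0,
   "thickness_cm": 12.0
  }
 ],
 "observation_points": [
  {
   "index": 1,
   "room": "bedroom",
   "x": 2.5,
   "y": 13.0,
   "z": 1.0
  },
  {
   "index": 2,
   "room": "bathroom",
   "x": 1.5,
   "y": 9.5,
   "z": 1.0
  },
  {
   "index": 3,
   "room": "bedroom2",
   "x": 7.5,
   "y": 13.0,
   "z": 1.0
  },
  {
   "index": 4,
   "room": "dressing",
   "x": 4.5,
   "y": 9.5,
   "z": 1.0
  },
  {
   "index": 5,
   "room": "corridor",
   "x": 2.0,
   "y": 6.5,
   "z": 1.0
  },
  {
   "index": 6,
   "room": "restroom",
   "x": 7.0,
   "y": 9.5,
   "z": 1.0
  },
  {
   "index": 7,
   "room": "hall",
   "x": 5.5,
   "y": 6.5,
   "z": 1.0
  },
  {
   "index": 8,
   "room": "study",
   "x": 9.0,
   "y": 9.5,
   "z": 1.0
  },
  {
   "index": 9,
   "room": "kitchen",
   "x": 8.5,
   "y": 6.5,
   "z": 1.0
  },
  {
   "index": 10,
   "room": "living",
   "x": 3.0,
   "y": 2.5,
   "z": 1.0
  },
  {
   "index": 11,
   "room": "dining",
   "x": 8.0,
   "y": 2.5,
   "z": 1.0
  }
 ]
}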