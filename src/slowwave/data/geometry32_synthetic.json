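{
 "description": "Synthetic stand-in layout for a 32-electrode micro-ECoG array covering motor (M), somatosensory (S), parietal (P), retrosplenial (R) and visual (V) areas; 0.550 mm array step.",
 "array_step_mm": 0.55,
 "synthetic": true,
 "electrodes": [
  {
   "id": 1,
   "x_mm": 0.0,
   "y_mm": 4.95,
   "area": "M"
  },
  {
   "id": 2,
   "x_mm": 0.55,
   "y_mm": 4.95,
   "area": "M"
  },
  {
   "id": 3,
   "x_mm": 1.1,
   "y_mm": 4.95,
   "area": "M"
  },
  {
   "id": 4,
   "x_mm": 0.0,
   "y_mm": 4.4,
   "area": "M"
  },
  {
   "id": 5,
   "x_mm": 0.55,
   "y_mm": 4.4,
   "area": "M"
  },
  {
   "id": 6,
   "x_mm": 1.1,
   "y_mm": 4.4,
   "area": "M"
  },
  {
   "id": 7,
   "x_mm": 1.65,
   "y_mm": 4.95,
   "area": "S"
  },
  {
   "id": 8,
   "x_mm": 2.2,
   "y_mm": 4.95,
   "area": "S"
  },
  {
   "id": 9,
   "x_mm": 2.75,
   "y_mm": 4.95,
   "area": "S"
  },
  {
   "id": 10,
   "x_mm": 1.65,
   "y_mm": 4.4,
   "area": "S"
  },
  {
   "id": 11,
   "x_mm": 2.2,
   "y_mm": 4.4,
   "area": "S"
  },
  {
   "id": 12,
   "x_mm": 2.75,
   "y_mm": 4.4,
   "area": "S"
  },
  {
   "id": 13,
   "x_mm": 1.65,
   "y_mm": 3.85,
   "area": "S"
  },
  {
   "id": 14,
   "x_mm": 2.2,
   "y_mm": 3.85,
   "area": "S"
  },
  {
   "id": 15,
   "x_mm": 2.75,
   "y_mm": 3.85,
   "area": "S"
  },
  {
   "id": 16,
   "x_mm": 2.2,
   "y_mm": 3.3,
   "area": "S"
  },
  {
   "id": 17,
   "x_mm": 0.0,
   "y_mm": 3.85,
   "area": "P"
  },
  {
   "id": 18,
   "x_mm": 0.55,
   "y_mm": 3.85,
   "area": "P"
  },
  {
   "id": 19,
   "x_mm": 1.1,
   "y_mm": 3.85,
   "area": "P"
  },
  {
   "id": 20,
   "x_mm": 0.55,
   "y_mm": 3.3,
   "area": "P"
  },
  {
   "id": 21,
   "x_mm": 1.1,
   "y_mm": 3.3,
   "area": "P"
  },
  {
   "id": 22,
   "x_mm": 1.65,
   "y_mm": 3.3,
   "area": "P"
  },
  {
   "id": 23,
   "x_mm": 0.0,
   "y_mm": 2.2,
   "area": "R"
  },
  {
   "id": 24,
   "x_mm": 0.55,
   "y_mm": 2.2,
   "area": "R"
  },
  {
   "id": 25,
   "x_mm": 0.0,
   "y_mm": 1.1,
   "area": "R"
  },
  {
   "id": 26,
   "x_mm": 0.0,
   "y_mm": 0.0,
   "area": "R"
  },
  {
   "id": 27,
   "x_mm": 1.1,
   "y_mm": 1.1,
   "area": "V"
  },
  {
   "id": 28,
   "x_mm": 1.65,
   "y_mm": 1.1,
   "area": "V"
  },
  {
   "id": 29,
   "x_mm": 2.2,
   "y_mm": 1.1,
   "area": "V"
  },
  {
   "id": 30,
   "x_mm": 0.55,
   "y_mm": 0.0,
   "area": "V"
  },
  {
   "id": 31,
   "x_mm": 1.65,
   "y_mm": 0.0,
   "area": "V"
  },
  {
   "id": 32,
   "x_mm": 2.75,
   "y_mm": 0.0,
   "area": "V"
  }
 ]
}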