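{
 "provenance": "Controlled vocabulary of surfactant-water phase-state labels. The canonical state list reconciles a lossy rendering of the published state table: 117 states transcribe unambiguously; one garbled run-together cell ('V2iV2p+X1', adjacent to an exact repetition of three earlier cells) is read as the pair 'V2i+W' / 'V2p+X1', of which only 'V2i+W' is new. 'V2i+W' is therefore a reconstructed entry, included to reach the asserted total of 118 distinct states. 'U' (unknown) is reserved and excluded from the canonical list; 'V2m' is a valid single-phase label that appears in no canonical state.",
 "single_phase": [
  {
   "code": "E",
   "description": "Ice",
   "literature_aliases": [
    "Ice"
   ]
  },
  {
   "code": "H1",
   "description": "Hexagonal phase",
   "literature_aliases": [
    "H_1"
   ]
  },
  {
   "code": "H2",
   "description": "Inverse hexagonal phase",
   "literature_aliases": [
    "H_2"
   ]
  },
  {
   "code": "I1",
   "description": "Cubic micellar phase",
   "literature_aliases": [
    "I_1"
   ]
  },
  {
   "code": "I2",
   "description": "Inverse cubic micellar phase",
   "literature_aliases": [
    "I_2"
   ]
  },
  {
   "code": "L1",
   "description": "Isotropic micellar solution",
   "literature_aliases": [
    "L_1"
   ]
  },
  {
   "code": "L2",
   "description": "Isotropic reverse micellar solution",
   "literature_aliases": [
    "L_2"
   ]
  },
  {
   "code": "L3",
   "description": "Sponge phase",
   "literature_aliases": [
    "L_3"
   ]
  },
  {
   "code": "La",
   "description": "Lamellar phase",
   "literature_aliases": [
    "L_α",
    "D",
    "G"
   ]
  },
  {
   "code": "La1",
   "description": "Lamellar phase",
   "literature_aliases": [
    "Soap Boilers Neat Soap"
   ]
  },
  {
   "code": "La2",
   "description": "Lamellar phase",
   "literature_aliases": [
    "Superneat Soap"
   ]
  },
  {
   "code": "Lb",
   "description": "Gel phase",
   "literature_aliases": [
    "L_β"
   ]
  },
  {
   "code": "M1",
   "description": "2D monoclinic phase",
   "literature_aliases": [
    "M_α"
   ]
  },
  {
   "code": "N1",
   "description": "Nematic liquid of rod- or worm-like micelles",
   "literature_aliases": [
    "N_1"
   ]
  },
  {
   "code": "Pb",
   "description": "Hydrated bilayer-based rippled phase",
   "literature_aliases": [
    "P_β'"
   ]
  },
  {
   "code": "R1",
   "description": "Rhombohedral phase",
   "literature_aliases": [
    "R_α"
   ]
  },
  {
   "code": "S",
   "description": "Non-crystalline solid",
   "literature_aliases": [
    "Neat Soap"
   ]
  },
  {
   "code": "Sa",
   "description": "Non-crystalline solid",
   "literature_aliases": [
    "S_α"
   ]
  },
  {
   "code": "Sb",
   "description": "Non-crystalline solid",
   "literature_aliases": [
    "S_β"
   ]
  },
  {
   "code": "T1",
   "description": "Tetragonal phase",
   "literature_aliases": [
    "T_α"
   ]
  },
  {
   "code": "V1",
   "description": "Bicontinuous cubic phase",
   "literature_aliases": [
    "V_1"
   ]
  },
  {
   "code": "V2",
   "description": "Inverse bicontinuous phase",
   "literature_aliases": [
    "V_2"
   ]
  },
  {
   "code": "V2i",
   "description": "Inverse bicontinuous phase with space group Pn3m",
   "literature_aliases": [
    "V2_i"
   ]
  },
  {
   "code": "V2m",
   "description": "Inverse bicontinuous phase with space group Ia3d",
   "literature_aliases": [
    "V2_m"
   ]
  },
  {
   "code": "V2p",
   "description": "Inverse bicontinuous phase with space group Im3m",
   "literature_aliases": [
    "V2_p"
   ]
  },
  {
   "code": "W",
   "description": "Water phase or sub-micellar solution",
   "literature_aliases": [
    "W"
   ]
  },
  {
   "code": "X",
   "description": "Generic crystalline (solid) surfactant phase",
   "literature_aliases": [
    "X"
   ]
  },
  {
   "code": "X1",
   "description": "Solid surfactant phase (hydration state 1)",
   "literature_aliases": [
    "X_1"
   ]
  },
  {
   "code": "X2",
   "description": "Solid surfactant phase (hydration state 2)",
   "literature_aliases": [
    "X_2"
   ]
  },
  {
   "code": "X3",
   "description": "Solid surfactant phase (hydration state 3)",
   "literature_aliases": [
    "X_3"
   ]
  },
  {
   "code": "X4",
   "description": "Solid surfactant phase (hydration state 4)",
   "literature_aliases": [
    "X_4"
   ]
  },
  {
   "code": "X5",
   "description": "Solid surfactant phase (hydration state 5)",
   "literature_aliases": [
    "X_5"
   ]
  },
  {
   "code": "X6",
   "description": "Solid surfactant phase (hydration state 6)",
   "literature_aliases": [
    "X_6"
   ]
  },
  {
   "code": "Xa",
   "description": "Solid surfactant phase (variant a)",
   "literature_aliases": [
    "X_a"
   ]
  },
  {
   "code": "Xb",
   "description": "Solid surfactant phase (variant b)",
   "literature_aliases": [
    "X_b"
   ]
  },
  {
   "code": "U",
   "description": "Unmeasured / unknown / unclear region or phase state",
   "literature_aliases": []
  }
 ],
 "canonical_states": [
  "E+H1",
  "E+I1",
  "E+L1",
  "E+L2",
  "E+La",
  "E+V1",
  "E+X",
  "E+X1",
  "E+X2",
  "E+X3",
  "H1",
  "H1+I1",
  "H1+L1",
  "H1+La",
  "H1+La1",
  "H1+R1",
  "H1+V1",
  "H1+V2",
  "H1+X1",
  "H1+X2",
  "H1+X4",
  "H2",
  "H2+L1",
  "H2+V2p",
  "H2+W",
  "H2+X1",
  "I1",
  "I1+La",
  "I1+T1",
  "I1+X1",
  "I1+X4",
  "I1+X5",
  "I2",
  "L1",
  "L1+L3",
  "L1+La",
  "L1+La1",
  "L1+Lb",
  "L1+Sa",
  "L1+V1",
  "L1+W",
  "L1+X",
  "L1+X1",
  "L1+X2",
  "L1+X3",
  "L1+X4",
  "L1+X6",
  "L2",
  "L2+La",
  "L2+Lb",
  "L2+V2i",
  "L2+W",
  "L2+X1",
  "L2+Xa",
  "L3",
  "L3+La",
  "L3+W",
  "L3+X1",
  "La",
  "La+S",
  "La+Sa",
  "La+Sb",
  "La+T1",
  "La+V2i",
  "La+V2p",
  "La+W",
  "La+X",
  "La+X1",
  "La+X2",
  "La+X3",
  "La+X4",
  "La+Xb",
  "La1",
  "La1+La2",
  "La2",
  "Lb",
  "Lb+Pb",
  "Lb+W",
  "M1",
  "M1+X1",
  "N1",
  "Pb",
  "Pb+W",
  "R1",
  "R1+X1",
  "S",
  "S+X1",
  "Sa",
  "Sa+Sb",
  "Sb",
  "T1",
  "T1+X1",
  "V1",
  "V1+X1",
  "V2",
  "V2+W",
  "V2+X1",
  "V2i",
  "V2i+V2p",
  "V2i+W",
  "V2i+X1",
  "V2p",
  "V2p+W",
  "V2p+X1",
  "W+X1",
  "W+X2",
  "X",
  "X1",
  "X1+X2",
  "X2",
  "X2+X3",
  "X3",
  "X3+X4",
  "X4",
  "X5",
  "X6",
  "Xa",
  "Xb"
 ],
 "reconstructed_states": [
  "V2i+W"
 ]
}
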