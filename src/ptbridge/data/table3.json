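{
 "source": "paper",
 "units": "kcal/mol",
 "description": "Empirical increments for the activation energy and the second minimum of intramolecular O-H...N proton transfer in tri-ring salen-type Schiff bases, fitted on the para and meta parent groups.",
 "e_sub": {
  "Br|1,3": -0.670,
  "Br|2,4": -0.244,
  "NO2|1,3": -0.322,
  "NO2|2,4": -1.56,
  "NH2|1,3": -1.12,
  "NH2|2,4": 0.754
 },
 "s_sub": {
  "Br|1,3": -0.905,
  "Br|2,4": -0.396,
  "NO2|1,3": -1.496,
  "NO2|2,4": 0.297,
  "NH2|1,3": -0.324,
  "NH2|2,4": -1.747
 },
 "e_ster": {
  "Br|1": -1.199,
  "Br|4": -0.902,
  "NO2|1": -2.127,
  "NO2|4": -0.501,
  "NH2|1": -0.060,
  "NH2|4": -1.743
 },
 "s_ster": {
  "Br|1": -0.759,
  "Br|4": -0.750,
  "NO2|1": 0.613,
  "NO2|4": -2.116,
  "NH2|1": -2.016,
  "NH2|4": -0.141
 }
}
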