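{
 "temperature_K": 298.15,
 "metadata": {"chirality": "R", "note": "synthetic two-conformer example illustrating the ensemble schema"},
 "conformers": [
  {
   "id": "conf-00",
   "delta_G_kcal_mol": 0.0,
   "transitions": [
    {"wavelength_nm": 216.0, "rotatory_strength_1e-40cgs": 28.0},
    {"wavelength_nm": 252.0, "rotatory_strength_1e-40cgs": -6.5},
    {"energy_eV": 6.078, "rotatory_strength_1e-40cgs": 9.0}
   ]
  },
  {
   "id": "conf-01",
   "delta_G_kcal_mol": 1.0,
   "transitions": [
    {"wavelength_nm": 222.0, "rotatory_strength_1e-40cgs": 18.0},
    {"wavelength_nm": 258.0, "rotatory_strength_1e-40cgs": -4.0},
    {"energy_eV": 6.078, "rotatory_strength_1e-40cgs": 7.0}
   ]
  }
 ]
}
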