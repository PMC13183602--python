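activities:
  NBCe1: 4.076091315511062e-10
  NHE3: 4.583054073783303e-05
  NKCC2: 0.0
  SGLT2: 4.463157004840981e-10
  pump_Jmax: 0.000153
  pump_K_K: 2.5
  pump_K_Na: 15.0
cell_type: pct
cytosol_H: 6.31e-05
geometry:
  impermeant_amount: 0.03350211846358537
  impermeant_valence: -1
  volume: 0.0003
interstitium:
  H_concentration: 3.98e-05
  concentrations:
    Cl: 113.0
    HCO3: 25.0
    K: 5.0
    Na: 140.0
    glucose: 5.0
  impermeant_anions: 7.0
  impermeant_osmolytes: 3.0
lumen:
  H_concentration: 0.0001
  concentrations:
    Cl: 113.0
    HCO3: 25.0
    K: 5.0
    Na: 140.0
    glucose: 5.0
  impermeant_anions: 7.0
  impermeant_osmolytes: 3.0
membranes:
  apical:
    Pf: 5.0e-05
    permeabilities:
      Cl: 1.0e-07
      HCO3: 2.0e-08
      K: 3.0e-08
      Na: 2.0e-08
      glucose: 1.0e-08
  basolateral:
    Pf: 5.0e-05
    permeabilities:
      Cl: 2.0e-07
      HCO3: 1.0e-07
      K: 1.5548209931079374e-06
      Na: 5.0e-09
      glucose: 1.656666666666667e-06
  paracellular:
    Pf: 0.0
    permeabilities:
      Cl: 1.9070552878680604e-06
      HCO3: 1.0e-07
      K: 1.0e-06
      Na: 1.0e-06
      glucose: 0.0
sex: female
sex_factors:
  NBCe1: 0.85
  NHE3: 0.7
  NaKATPase: 0.85
  P_K_baso: 1.0
solutes:
- name: Na
  z: 1
- name: K
  z: 1
- name: Cl
  z: -1
- name: HCO3
  z: -1
- name: glucose
  z: 0
varied_parameters:
- NHE3
- NaKATPase
- NBCe1
- P_K_baso
water_permeable: true
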