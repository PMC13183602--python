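activities:
  NBCe1: 0.0
  NHE3: 0.0
  NKCC2: 2.2079018225083553e-09
  SGLT2: 0.0
  pump_Jmax: 0.0002023340919435594
  pump_K_K: 2.5
  pump_K_Na: 15.0
cell_type: mtal
cytosol_H: 3.98e-05
geometry:
  impermeant_amount: 0.035399999999999994
  impermeant_valence: -1
  volume: 0.0003
interstitium:
  H_concentration: 3.98e-05
  concentrations:
    Cl: 145.0
    K: 5.0
    Na: 140.0
lumen:
  H_concentration: 3.98e-05
  concentrations:
    Cl: 146.0
    K: 6.0
    Na: 140.0
membranes:
  apical:
    Pf: 0.0
    permeabilities:
      Cl: 0.0
      K: 3.0663353036000805e-06
      Na: 2.0e-08
  basolateral:
    Pf: 0.0
    permeabilities:
      Cl: 6.859529617831376e-07
      K: 1.0001272013980816e-06
      Na: 2.0e-08
  paracellular:
    Pf: 0.0
    permeabilities:
      Cl: 2.0e-07
      K: 3.0e-07
      Na: 5.286309723814641e-07
sex: female
sex_factors:
  NKCC2: 1.15
  NaKATPase: 0.9
  P_K_api: 1.1
  P_K_baso: 0.9
solutes:
- name: Na
  z: 1
- name: K
  z: 1
- name: Cl
  z: -1
varied_parameters:
- NKCC2
- NaKATPase
- P_K_api
- P_K_baso
water_permeable: false
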