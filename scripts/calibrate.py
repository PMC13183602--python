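"""Derive the shipped baseline variant configurations.

The boundary compositions and a physiologically plausible target cytosolic
state are chosen first; transporter activities and the remaining membrane
permeabilities are then solved in closed form so that the target state is an
exact steady state of the male variant.  Female variants apply the
multiplicative sex factors to the four varied transport parameters.  The
resulting YAML files are frozen under src/episurf/config/ and shipped with
the package; rerunning this script regenerates them bit-identically.

Usage:  python scripts/calibrate.py [--check-only]
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

REPO = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(REPO / "src"))

import yaml

from episurf.cellmodel import (CONSTANTS, CompartmentComposition, ghk_flux,
                               solve_steady_state, variant_from_dict)

OUTDIR = REPO / "src" / "episurf" / "config"

RTF = CONSTANTS.RT_over_F
RT = CONSTANTS.RT
F = CONSTANTS.F

# target pump cycle rate at baseline (mM*cm/s)
R0 = 1.0e-5
PUMP_K_NA = 15.0
PUMP_K_K = 2.5

SEX_FACTORS = {
    "pct": {"NHE3": 0.70, "NaKATPase": 0.85, "NBCe1": 0.85, "P_K_baso": 1.0},
    "mtal": {"NKCC2": 1.15, "NaKATPase": 0.90, "P_K_api": 1.10, "P_K_baso": 0.90},
}


def bisect(f, lo, hi, tol=1e-14, it=200):
    flo = f(lo)
    for _ in range(it):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(hi - lo) < tol:
            return mid
        if (flo < 0) == (fm < 0):
            lo, flo = mid, fm
        else:
            hi = mid
    return 0.5 * (lo + hi)


def pump_jmax(r0, c_na, c_k_ext):
    fna = c_na / (c_na + PUMP_K_NA)
    fk = c_k_ext / (c_k_ext + PUMP_K_K)
    return r0 / (fna ** 3 * fk ** 2)


def calibrate_pct():
    lumen = {"Na": 140.0, "K": 5.0, "Cl": 113.0, "HCO3": 25.0, "glucose": 5.0}
    inter = dict(lumen)
    anions = 7.0               # fixed monovalent anions closing electroneutrality
    H_L, H_I, H_C = 1.0e-4, 3.98e-5, 6.31e-5   # pH 7.0 / 7.4 / 7.2

    # target cytosolic state (inside the plausibility window)
    na, k, hco3, glc = 15.0, 130.0, 25.0, 8.0
    v_c, v_l = -70.0, -1.0
    vol = 3.0e-4

    # fixed (chosen) permeabilities
    pa = {"Na": 2e-8, "K": 3e-8, "Cl": 1e-7, "HCO3": 2e-8, "glucose": 1e-8}
    pb = {"Na": 5e-9, "Cl": 2e-7, "HCO3": 1e-7}
    pp = {"Na": 1e-6, "K": 1e-6, "HCO3": 1e-7, "glucose": 0.0}
    pf_a = pf_b = 5e-5

    va_lc = v_l - v_c          # apical potential, lumen minus cell

    # cytosolic Cl- settles where passive apical influx = basolateral efflux
    def cl_balance(c):
        return (ghk_flux(pa["Cl"], -1, va_lc, lumen["Cl"], c)
                - ghk_flux(pb["Cl"], -1, v_c, c, inter["Cl"]))

    lo = inter["Cl"] * 2.718281828459045 ** (-(v_c / RTF)) * 0 + 1e-9
    cl = bisect(cl_balance, 2.0, 100.0)
    c_imp = na + k - cl - hco3           # z_imp = -1
    assert c_imp > 0

    # neutral impermeant osmolytes on the boundary side so that the target
    # cell osmolarity equals lumen/interstitial osmolarity (zero water flux)
    osm_cell = na + k + cl + hco3 + glc + c_imp
    osm_boundary_base = sum(lumen.values()) + anions
    osmolytes = osm_cell - osm_boundary_base
    assert osmolytes >= 0

    # passive fluxes at the target
    j_a = {s: ghk_flux(pa[s], z, va_lc, lumen[s], c)
           for s, z, c in (("Na", 1, na), ("K", 1, k), ("Cl", -1, cl),
                           ("HCO3", -1, hco3), ("glucose", 0, glc))}
    j_b_fixed = {s: ghk_flux(pb[s], z, v_c, c, inter[s])
                 for s, z, c in (("Na", 1, na), ("Cl", -1, cl),
                                 ("HCO3", -1, hco3))}

    # SGLT2 carries a modest share of apical Na+ entry (NHE3 dominates)
    g = 0.5 * R0
    import math
    dmu_sglt = RT * (math.log(lumen["Na"] / na) + math.log(lumen["glucose"] / glc)) + F * va_lc
    x_sglt2 = g / dmu_sglt
    assert x_sglt2 > 0

    # NHE3 flux s and NBCe1 cycle solved from Na+ and HCO3- balances
    s_flux = 1.5 * (3 * R0 + j_b_fixed["Na"] - j_a["Na"] - g
                    + (j_a["HCO3"] - j_b_fixed["HCO3"]) / 3.0)
    assert s_flux > 0
    kin = (lumen["Na"] * H_C - na * H_L) / ((lumen["Na"] + na) * (H_L + H_C))
    x_nhe3 = s_flux / kin
    j_nbc = (j_a["HCO3"] + s_flux - j_b_fixed["HCO3"]) / 3.0
    dmu_nbc = RT * (math.log(na / inter["Na"]) + 3 * math.log(hco3 / inter["HCO3"])) - 2 * F * v_c
    x_nbce1 = j_nbc / dmu_nbc
    assert x_nbce1 > 0

    # basolateral K+ channel carries pump uptake plus apical leak
    j_bk = j_a["K"] + 2 * R0
    p_bk = j_bk / ghk_flux(1.0, 1, v_c, k, inter["K"])
    assert p_bk > 0

    # basolateral glucose carrier (GLUT-like, z = 0)
    p_bglc = (j_a["glucose"] + g) / (glc - inter["glucose"])
    assert p_bglc > 0

    # open circuit: solve the paracellular Cl- permeability
    i_trans = ((3 * R0 + j_b_fixed["Na"] + j_nbc)          # Na+
               + (j_bk - 2 * R0)                           # K+
               - (j_b_fixed["Cl"])                         # Cl-
               - (3 * j_nbc + j_b_fixed["HCO3"]))          # HCO3-
    i_para_fixed = (ghk_flux(pp["Na"], 1, v_l, lumen["Na"], inter["Na"])
                    + ghk_flux(pp["K"], 1, v_l, lumen["K"], inter["K"])
                    - ghk_flux(pp["HCO3"], -1, v_l, lumen["HCO3"], inter["HCO3"]))
    p_pcl = (i_trans + i_para_fixed) / ghk_flux(1.0, -1, v_l, lumen["Cl"], inter["Cl"])
    assert p_pcl > 0, p_pcl

    pb_full = dict(pb, K=p_bk, glucose=p_bglc)
    pp_full = dict(pp, Cl=p_pcl)

    cfg = {
        "cell_type": "pct",
        "sex": "male",
        "water_permeable": True,
        "solutes": [
            {"name": "Na", "z": 1}, {"name": "K", "z": 1},
            {"name": "Cl", "z": -1}, {"name": "HCO3", "z": -1},
            {"name": "glucose", "z": 0},
        ],
        "lumen": {"concentrations": lumen, "H_concentration": H_L,
                  "impermeant_anions": anions,
                  "impermeant_osmolytes": osmolytes},
        "interstitium": {"concentrations": inter, "H_concentration": H_I,
                         "impermeant_anions": anions,
                         "impermeant_osmolytes": osmolytes},
        "cytosol_H": H_C,
        "membranes": {
            "apical": {"permeabilities": pa, "Pf": pf_a},
            "basolateral": {"permeabilities": pb_full, "Pf": pf_b},
            "paracellular": {"permeabilities": pp_full, "Pf": 0.0},
        },
        "activities": {
            "NHE3": x_nhe3, "SGLT2": x_sglt2, "NBCe1": x_nbce1, "NKCC2": 0.0,
            "pump_Jmax": pump_jmax(R0, na, inter["K"]),
            "pump_K_Na": PUMP_K_NA, "pump_K_K": PUMP_K_K,
        },
        "geometry": {"volume": vol, "impermeant_amount": c_imp * vol,
                     "impermeant_valence": -1},
        "varied_parameters": ["NHE3", "NaKATPase", "NBCe1", "P_K_baso"],
        "sex_factors": SEX_FACTORS["pct"],
    }
    return cfg


def calibrate_mtal():
    import math
    lumen = {"Na": 140.0, "K": 6.0, "Cl": 146.0}
    inter = {"Na": 140.0, "K": 5.0, "Cl": 145.0}
    H = 3.98e-5

    na, k, cl = 13.0, 130.0, 25.0
    v_c, v_l = -70.0, 3.0
    vol = 3.0e-4
    c_imp = na + k - cl
    assert c_imp > 0

    pa = {"Na": 2e-8, "Cl": 0.0}
    pb = {"Na": 2e-8}
    pp = {"K": 3e-7, "Cl": 2e-7}

    va_lc = v_l - v_c

    j_a_na = ghk_flux(pa["Na"], 1, va_lc, lumen["Na"], na)
    j_b_na = ghk_flux(pb["Na"], 1, v_c, na, inter["Na"])

    # NKCC2 cycle from the Na+ balance
    j_nk = 3 * R0 + j_b_na - j_a_na
    assert j_nk > 0
    dmu_nk = RT * (math.log(lumen["Na"] / na) + math.log(lumen["K"] / k)
                   + 2 * math.log(lumen["Cl"] / cl))
    x_nkcc2 = j_nk / dmu_nk
    assert x_nkcc2 > 0

    # apical K+ channel recycles two K+ per pump cycle into the lumen
    j_ak = -2 * R0
    p_ak = j_ak / ghk_flux(1.0, 1, va_lc, lumen["K"], k)
    assert p_ak > 0

    # basolateral channels from K+ and Cl- balances
    j_bk = j_nk + 2 * R0 + j_ak
    p_bk = j_bk / ghk_flux(1.0, 1, v_c, k, inter["K"])
    assert p_bk > 0
    p_bcl = 2 * j_nk / ghk_flux(1.0, -1, v_c, cl, inter["Cl"])
    assert p_bcl > 0

    # open circuit: solve the paracellular Na+ permeability
    i_trans = ((3 * R0 + j_b_na) + (j_bk - 2 * R0) - 2 * j_nk)
    i_para_fixed = (ghk_flux(pp["K"], 1, v_l, lumen["K"], inter["K"])
                    - ghk_flux(pp["Cl"], -1, v_l, lumen["Cl"], inter["Cl"]))
    p_pna = -(i_trans + i_para_fixed) / ghk_flux(1.0, 1, v_l, lumen["Na"], inter["Na"])
    assert p_pna > 0, p_pna

    cfg = {
        "cell_type": "mtal",
        "sex": "male",
        "water_permeable": False,
        "solutes": [
            {"name": "Na", "z": 1}, {"name": "K", "z": 1}, {"name": "Cl", "z": -1},
        ],
        "lumen": {"concentrations": lumen, "H_concentration": H},
        "interstitium": {"concentrations": inter, "H_concentration": H},
        "cytosol_H": H,
        "membranes": {
            "apical": {"permeabilities": dict(pa, K=p_ak), "Pf": 0.0},
            "basolateral": {"permeabilities": dict(pb, K=p_bk, Cl=p_bcl), "Pf": 0.0},
            "paracellular": {"permeabilities": dict(pp, Na=p_pna), "Pf": 0.0},
        },
        "activities": {
            "NKCC2": x_nkcc2, "NHE3": 0.0, "SGLT2": 0.0, "NBCe1": 0.0,
            "pump_Jmax": pump_jmax(R0, na, inter["K"]),
            "pump_K_Na": PUMP_K_NA, "pump_K_K": PUMP_K_K,
        },
        "geometry": {"volume": vol, "impermeant_amount": c_imp * vol,
                     "impermeant_valence": -1},
        "varied_parameters": ["NKCC2", "NaKATPase", "P_K_api", "P_K_baso"],
        "sex_factors": SEX_FACTORS["mtal"],
    }
    return cfg


def make_female(cfg):
    out = yaml.safe_load(yaml.safe_dump(cfg))   # deep copy
    out["sex"] = "female"
    factors = SEX_FACTORS[cfg["cell_type"]]
    act_map = {"NHE3": "NHE3", "NBCe1": "NBCe1", "NKCC2": "NKCC2",
               "NaKATPase": "pump_Jmax"}
    for name, f in factors.items():
        if name in act_map:
            out["activities"][act_map[name]] *= f
        elif name == "P_K_api":
            out["membranes"]["apical"]["permeabilities"]["K"] *= f
        elif name == "P_K_baso":
            out["membranes"]["basolateral"]["permeabilities"]["K"] *= f
        else:
            raise ValueError(name)
    return out


def check(cfg):
    variant = variant_from_dict(cfg)
    st = solve_steady_state(variant)
    na = st.cytosol.concentrations["Na"]
    k = st.cytosol.concentrations["K"]
    print(f"{variant.name:12s} iters={st.iterations:2d} "
          f"res={st.residual_norm:.2e} Na={na:6.2f} K={k:6.2f} "
          f"Va={st.Va:7.2f} Vb={st.Vb:7.2f} V_lumen={st.V_lumen:6.2f} "
          f"JNa={st.fluxes.basolateral['Na']:.3e}")
    assert 10 <= na <= 25, na
    assert 100 <= k <= 145, k
    assert -90 <= st.Va <= -40, st.Va
    return st


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--check-only", action="store_true")
    args = ap.parse_args()

    configs = {}
    pct_m = calibrate_pct()
    mtal_m = calibrate_mtal()
    configs["pct_male"] = pct_m
    configs["pct_female"] = make_female(pct_m)
    configs["mtal_male"] = mtal_m
    configs["mtal_female"] = make_female(mtal_m)

    for name, cfg in configs.items():
        check(cfg)
        if not args.check_only:
            path = OUTDIR / f"{name}.yaml"
            path.write_text(yaml.safe_dump(cfg, sort_keys=True))
            print(f"wrote {path}")


if __name__ == "__main__":
    main()
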