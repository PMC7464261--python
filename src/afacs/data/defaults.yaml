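# Bundled default scenario: model inputs for the 30-day AF-ACS trade-off
# analysis. Stroke rates at scores 2 and 3 are the directly supported
# values; the remaining scores come from the Danish nationwide AF cohort
# (Olesen et al., BMJ 2011) and are marked as an extension.
name: bundled-defaults

stroke:
  # annual stroke / systemic embolism rate per 100 patient-years,
  # non-anticoagulated AF patients, by CHA2DS2-VASc score
  annual_rate_per_100:
    2: 3.7
    3: 5.9
  # extension entries (non-core source); includes score 4 = 9.27,
  # consistent with the third reported monthly risk of 0.8/100
  extension_annual_rate_per_100:
    0: 0.78
    1: 2.01
    4: 9.27
    5: 15.26
    6: 19.74
    7: 21.50
    8: 22.38
    9: 23.64
  acs_multiplier: 3.9        # early post-ACS excess, applied uniformly
  oac_rrr: 0.64              # full anticoagulation vs no anticoagulation
  dapt_vs_oac_rr: 1.72       # aspirin+clopidogrel DAPT vs full OAC

coronary:
  # 30-day NNTB anchors (score, p2y12, nntb) used to calibrate the
  # clopidogrel-DAPT reference rate table by inversion
  nntb_anchors:
    - [1, ticagrelor, 179]
    - [3, ticagrelor, 140]
    - [9, ticagrelor, 105]
  # independent anchors kept for the calibration cross-check
  crosscheck_anchors:
    - [1, prasugrel, 97]
    - [9, prasugrel, 57]
  rrr:
    ticagrelor: 0.12
    prasugrel: 0.22
  complex_pci_risk_ratio: 3.4

bleeding:
  edges_csv: bleeding_edges.csv   # relative to the package data directory
  qualitative_nodes:
    - DAT-edoxaban-60

sample_size:
  base_rate: 0.007
  relative_increase: 0.55
  alpha: 0.05
  power: 0.90
  horizon_years: 1.0
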