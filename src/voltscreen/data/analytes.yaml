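# Electrochemical fingerprint library: DPV peak inventories on a boron-doped
# diamond electrode in Britton-Robinson buffer (0.1 mol/L, pH 8.0), potentials
# in V vs Ag/AgCl.  One record per analyte; `anodic` / `cathodic` list the
# peaks observed in each sweep direction.  Peaks omit `rel_amplitude` /
# `width` where the loader defaults apply (R1 1.0, R2 0.6, oxidations 0.8;
# width 0.07 V).  `sign` is inferred from the label prefix (O = oxidation,
# R = reduction) unless given explicitly.
#
# New analytes (e.g. bupropion, benzylone, dipentylone) can be appended with
# the same schema:
#   - analyte_id: <string>
#     category: SC | interferent | silent
#     group: G1..G6        # SCs only
#     anodic:   [{label, potential, sign?, rel_amplitude?, width?}, ...]
#     cathodic: [{label, potential, ...}, ...]

analytes:
  # ---- Group G1: N-alkyl cathinones, disubstituted amine -------------------
  - analyte_id: mephedrone
    category: SC
    group: G1
    anodic:
      - {label: R1, potential: -1.40}
      - {label: O1, potential: +1.19}
    cathodic:
      - {label: R1, potential: -1.40}
      - {label: R2, potential: -1.60}
  - analyte_id: 4-MPD
    category: SC
    group: G1
    anodic:
      - {label: R1, potential: -1.40}
      - {label: O1, potential: +1.10}
    cathodic:
      - {label: R1, potential: -1.40}
      - {label: R2, potential: -1.60}
  - analyte_id: ethcathinone
    # O1 (~+1.27 V) is only resolved in cyclic voltammetry, not DPV, so the
    # DPV library carries the R1 process alone on the anodic sweep.
    category: SC
    group: G1
    anodic:
      - {label: R1, potential: -1.40}
    cathodic:
      - {label: R1, potential: -1.40}
      - {label: R2, potential: -1.60}

  # ---- Group G2: 3,4-methylenedioxy, N-alkyl (disubstituted N) -------------
  - analyte_id: methylone
    category: SC
    group: G2
    anodic: &g2_anodic
      - {label: R1, potential: -1.40}
      - {label: O1, potential: +0.60}
      - {label: O2, potential: +1.00}
      - {label: O3, potential: +1.25}
    cathodic: &g2_cathodic
      - {label: O3, potential: +1.30}
      - {label: R1, potential: -1.40}
      - {label: R2, potential: -1.60}
  - analyte_id: ethylone
    category: SC
    group: G2
    anodic: *g2_anodic
    cathodic: *g2_cathodic
  - analyte_id: eutylone
    category: SC
    group: G2
    anodic: *g2_anodic
    cathodic: *g2_cathodic
  - analyte_id: ephylone
    category: SC
    group: G2
    anodic: *g2_anodic
    cathodic: *g2_cathodic
  - analyte_id: MDPT
    category: SC
    group: G2
    anodic: *g2_anodic
    cathodic: *g2_cathodic

  # ---- Group G3: 3,4-methylenedioxy, trisubstituted N ----------------------
  - analyte_id: dibutylone
    category: SC
    group: G3
    anodic:
      - {label: R1, potential: -1.40}
      - {label: O1, potential: +0.60}
      - {label: O2, potential: +0.83}
      - {label: O3, potential: +1.03}
      - {label: O4, potential: +1.19}
    cathodic:
      - {label: O4, potential: +1.30}
      - {label: O3, potential: +1.00}
      - {label: R1, potential: -1.30}
      - {label: R2, potential: -1.60}

  # ---- Group G4: 3,4-methylenedioxy, N-pyrrolidine -------------------------
  - analyte_id: MDPV
    category: SC
    group: G4
    anodic: &g4_anodic
      - {label: R1, potential: -1.40}
      - {label: O1, potential: +0.60}
      - {label: O2, potential: +0.78}
      - {label: O3, potential: +0.90}
      - {label: O4, potential: +1.01}
      - {label: O5, potential: +1.19}
    cathodic: &g4_cathodic
      - {label: O5, potential: +1.30}
      - {label: O4, potential: +1.00}
      - {label: R1, potential: -1.30}
      - {label: R2, potential: -1.60}
  - analyte_id: MDPHP
    category: SC
    group: G4
    anodic: *g4_anodic
    cathodic: *g4_cathodic

  # ---- Group G5: N-pyrrolidine, no methylenedioxy --------------------------
  - analyte_id: MPHP
    category: SC
    group: G5
    anodic: &g5_anodic
      - {label: R1, potential: -1.30}
      - {label: O1, potential: +0.90}
      - {label: O2, potential: +1.00}
    cathodic: &g5_cathodic
      - {label: O2, potential: +1.00}
      - {label: R1, potential: -1.30}
      - {label: R2, potential: -1.60}
  - analyte_id: alpha-PVP
    category: SC
    group: G5
    anodic: *g5_anodic
    cathodic: *g5_cathodic
  - analyte_id: TH-PVP
    category: SC
    group: G5
    anodic: *g5_anodic
    cathodic: *g5_cathodic

  # ---- Group G6: thiophene ring (alpha-PVT) --------------------------------
  - analyte_id: alpha-PVT
    category: SC
    group: G6
    anodic:
      - {label: R1, potential: -1.30}
      - {label: O1, potential: -0.31}
      - {label: O2, potential: -0.17}
      - {label: O3, potential: +0.82}
      - {label: O4, potential: +0.95}
    cathodic:
      - {label: O3, potential: +1.00}
      - {label: O4, potential: +1.30}
      - {label: R1, potential: -1.22}
      - {label: R2, potential: -1.47}

  # ---- Interferents --------------------------------------------------------
  - analyte_id: caffeine
    category: interferent
    anodic:
      - {label: O1, potential: +1.30}
    cathodic: []
  - analyte_id: paracetamol
    category: interferent
    anodic:
      - {label: O1, potential: +0.21}
    cathodic:
      - {label: R1, potential: -0.24, rel_amplitude: 0.6}
  - analyte_id: benzocaine
    category: interferent
    anodic:
      - {label: O1, potential: +0.77}
    cathodic: []
  - analyte_id: lidocaine
    category: interferent
    anodic:
      - {label: O1, potential: +0.87}
    cathodic: []
  - analyte_id: procaine
    category: interferent
    anodic:
      - {label: O1, potential: +0.77}
    cathodic: []
  - analyte_id: ketamine
    category: interferent
    anodic:
      - {label: O1, potential: +1.09}
    cathodic: []
  - analyte_id: MDMA
    category: interferent
    anodic: &mdx_anodic
      - {label: O1, potential: +1.00}
      - {label: O2, potential: +1.20}
    cathodic: &mdx_cathodic
      - {label: R1, potential: -0.70, rel_amplitude: 0.6}
      - {label: R2, potential: -0.50, rel_amplitude: 0.6}
  - analyte_id: MDEA
    category: interferent
    anodic: *mdx_anodic
    cathodic: *mdx_cathodic
  - analyte_id: mCPP
    category: interferent
    anodic:
      - {label: O1, potential: +0.99}
    cathodic: []
  - analyte_id: BZP
    category: interferent
    anodic:
      - {label: O1, potential: +0.76}
      - {label: O2, potential: +1.00}
    cathodic: []

  # ---- Electrochemically silent on BDDE ------------------------------------
  - analyte_id: cocaine
    category: silent
    anodic: []
    cathodic: []
  - analyte_id: amphetamine
    category: silent
    anodic: []
    cathodic: []
  - analyte_id: methamphetamine
    category: silent
    anodic: []
    cathodic: []

groups:
  - group_id: G1
    n_anodic_expected: 1
    anodic_windows: [[1.00, 1.30]]
    special_markers: {}
  - group_id: G2
    n_anodic_expected: 3
    anodic_windows: [[0.50, 0.70], [0.90, 1.10], [1.15, 1.35]]
    special_markers: {methylenedioxy: true}
  - group_id: G3
    n_anodic_expected: 4
    anodic_windows: [[0.50, 0.70], [0.73, 0.93], [0.93, 1.13], [1.09, 1.29]]
    special_markers: {methylenedioxy: true}
  - group_id: G4
    n_anodic_expected: 5
    anodic_windows: [[0.50, 0.70], [0.68, 0.88], [0.80, 1.00], [0.91, 1.11], [1.09, 1.29]]
    special_markers: {methylenedioxy: true}
  - group_id: G5
    n_anodic_expected: 2
    anodic_windows: [[0.80, 1.00], [0.90, 1.10]]
    special_markers: {}
  - group_id: G6
    n_anodic_expected: 4
    anodic_windows: [[-0.41, -0.21], [-0.27, -0.07], [0.72, 0.92], [0.85, 1.05]]
    special_markers: {thiophene: true}
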