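{
  "alpha_bare": {
    "file": "table1_alpha_bare.csv",
    "table": 1,
    "caption": "Corrected Gibbs free energies of the bare alpha-pinene radicals and hydroxylated products, with printed relative energies (kcal/mol) against the most stable conformation.",
    "molecule": "alpha-pinene"
  },
  "beta_bare": {
    "file": "table2_beta_bare.csv",
    "table": 2,
    "caption": "Corrected Gibbs free energies of the bare beta-pinene radicals and hydroxylated products, with printed relative energies (kcal/mol) against the most stable conformation.",
    "molecule": "beta-pinene"
  },
  "rs_coordinates": {
    "file": "table3_rs_coordinates.csv",
    "table": 3,
    "caption": "Relative Gibbs free-energy coordinates of the R/S cis/trans epsilon abstraction paths of alpha-pinene (kcal/mol, gamma coordinate-1 reference).",
    "molecule": "alpha-pinene"
  },
  "beta_descriptors": {
    "file": "table4_beta_descriptors.csv",
    "table": 4,
    "caption": "Kinetic and thermodynamic descriptors of hydrogen abstraction from beta-pinene by the CYP model (kcal/mol).",
    "molecule": "beta-pinene"
  },
  "beta_coordI": {
    "file": "table5_beta_coordI.csv",
    "table": 5,
    "caption": "Boltzmann distribution over the beta-pinene reactant-complex conformers at reaction coordinate I.",
    "molecule": "beta-pinene",
    "stage": "I"
  },
  "beta_coordIII": {
    "file": "table6_beta_coordIII.csv",
    "table": 6,
    "caption": "Boltzmann distribution over the beta-pinene radical conformers at reaction coordinate III.",
    "molecule": "beta-pinene",
    "stage": "III"
  },
  "alpha_descriptors": {
    "file": "table7_alpha_descriptors.csv",
    "table": 7,
    "caption": "Kinetic and thermodynamic descriptors of hydrogen abstraction from alpha-pinene by the CYP model (kcal/mol).",
    "molecule": "alpha-pinene"
  },
  "alpha_coordI": {
    "file": "table8_alpha_coordI.csv",
    "table": 8,
    "caption": "Boltzmann distribution over the alpha-pinene reactant-complex conformers at reaction coordinate I. The alpha-quartet row is tagged suspect: its printed free energy implies a negligible weight, inconsistent with its printed 20.9% population.",
    "molecule": "alpha-pinene",
    "stage": "I"
  },
  "alpha_coordIII": {
    "file": "table9_alpha_coordIII.csv",
    "table": 9,
    "caption": "Boltzmann distribution over the alpha-pinene radical conformers at reaction coordinate III.",
    "molecule": "alpha-pinene",
    "stage": "III"
  }
}
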