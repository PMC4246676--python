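{
 "flux_ratios": [
  {
   "denominator": "HK_c",
   "numerator": "GPT_cp",
   "ratio": 0.45
  }
 ],
 "id": "toy_central_metabolism_v1",
 "metabolites": [
  {
   "compartment": "c",
   "id": "Suc_c",
   "name": "sucrose"
  },
  {
   "compartment": "c",
   "id": "Hex_c",
   "name": "hexose"
  },
  {
   "compartment": "c",
   "id": "G6P_c",
   "name": "glucose-6-phosphate"
  },
  {
   "compartment": "c",
   "id": "Pyr_c",
   "name": "pyruvate"
  },
  {
   "compartment": "p",
   "id": "G6P_p",
   "name": "glucose-6-phosphate"
  },
  {
   "compartment": "p",
   "id": "Pyr_p",
   "name": "pyruvate"
  },
  {
   "compartment": "p",
   "id": "E4P_p",
   "name": "erythrose-4-phosphate"
  },
  {
   "compartment": "c",
   "id": "E4P_c",
   "name": "erythrose-4-phosphate"
  },
  {
   "compartment": "p",
   "id": "AcCoA_p",
   "name": "acetyl-CoA"
  },
  {
   "compartment": "p",
   "id": "FA_p",
   "name": "fatty acid"
  },
  {
   "compartment": "c",
   "id": "FA_c",
   "name": "fatty acid"
  },
  {
   "compartment": "c",
   "id": "TAG_c",
   "name": "triacylglycerol"
  },
  {
   "compartment": "p",
   "id": "ADPG_p",
   "name": "ADP-glucose"
  },
  {
   "compartment": "p",
   "id": "Starch_p",
   "name": "starch"
  },
  {
   "compartment": "m",
   "id": "Pyr_m",
   "name": "pyruvate"
  },
  {
   "compartment": "m",
   "id": "AcCoA_m",
   "name": "acetyl-CoA"
  },
  {
   "compartment": "m",
   "id": "OAA_m",
   "name": "oxaloacetate"
  },
  {
   "compartment": "c",
   "id": "OAA_c",
   "name": "oxaloacetate"
  },
  {
   "compartment": "c",
   "id": "AA_c",
   "name": "amino acids"
  },
  {
   "compartment": "c",
   "id": "Prot_c",
   "name": "protein"
  }
 ],
 "objective": "biomass",
 "reactions": [
  {
   "compartment": "c",
   "exchange": true,
   "genes": [],
   "id": "Ex_suc",
   "lower_bound": 0,
   "name": "sucrose uptake",
   "pathway": "sugar_uptake",
   "stoichiometry": {
    "Suc_c": 1.0
   },
   "upper_bound": 10
  },
  {
   "compartment": "c",
   "exchange": false,
   "genes": [],
   "id": "INV_c",
   "lower_bound": 0,
   "name": "invertase",
   "pathway": "sugar_uptake",
   "stoichiometry": {
    "Hex_c": 2.0,
    "Suc_c": -1.0
   },
   "upper_bound": 1000
  },
  {
   "compartment": "c",
   "exchange": false,
   "genes": [],
   "id": "HK_c",
   "lower_bound": 0,
   "name": "hexokinase",
   "pathway": "glycolysis",
   "stoichiometry": {
    "G6P_c": 1.0,
    "Hex_c": -1.0
   },
   "upper_bound": 1000
  },
  {
   "compartment": "cp",
   "exchange": false,
   "genes": [],
   "id": "GPT_cp",
   "lower_bound": 0,
   "name": "glucose-6-P/Pi translocator",
   "pathway": "transport",
   "stoichiometry": {
    "G6P_c": -1.0,
    "G6P_p": 1.0
   },
   "upper_bound": 1000
  },
  {
   "compartment": "c",
   "exchange": false,
   "genes": [],
   "id": "GLY_c",
   "lower_bound": 0,
   "name": "cytosolic glycolysis (lumped)",
   "pathway": "glycolysis",
   "stoichiometry": {
    "G6P_c": -1.0,
    "Pyr_c": 2.0
   },
   "upper_bound": 1000
  },
  {
   "compartment": "p",
   "exchange": false,
   "genes": [],
   "id": "GLY_p",
   "lower_bound": 0,
   "name": "plastidic glycolysis (lumped)",
   "pathway": "glycolysis",
   "stoichiometry": {
    "G6P_p": -1.0,
    "Pyr_p": 2.0
   },
   "upper_bound": 1000
  },
  {
   "compartment": "p",
   "exchange": false,
   "genes": [],
   "id": "PPP_p",
   "lower_bound": 0,
   "name": "oxidative pentose-phosphate (lumped)",
   "pathway": "pentose_phosphate",
   "stoichiometry": {
    "E4P_p": 1.0,
    "G6P_p": -1.0
   },
   "upper_bound": 1000
  },
  {
   "compartment": "pc",
   "exchange": false,
   "genes": [],
   "id": "E4PT_pc",
   "lower_bound": 0,
   "name": "erythrose-4-P export",
   "pathway": "transport",
   "stoichiometry": {
    "E4P_c": 1.0,
    "E4P_p": -1.0
   },
   "upper_bound": 1000
  },
  {
   "compartment": "cp",
   "exchange": false,
   "genes": [],
   "id": "PYRT_cp",
   "lower_bound": 0,
   "name": "pyruvate import (plastid)",
   "pathway": "transport",
   "stoichiometry": {
    "Pyr_c": -1.0,
    "Pyr_p": 1.0
   },
   "upper_bound": 1000
  },
  {
   "compartment": "cm",
   "exchange": false,
   "genes": [],
   "id": "PYRT_cm",
   "lower_bound": 0,
   "name": "pyruvate import (mitochondrion)",
   "pathway": "transport",
   "stoichiometry": {
    "Pyr_c": -1.0,
    "Pyr_m": 1.0
   },
   "upper_bound": 1000
  },
  {
   "compartment": "m",
   "exchange": false,
   "genes": [],
   "id": "PDH_m",
   "lower_bound": 0,
   "name": "mitochondrial pyruvate dehydrogenase",
   "pathway": "tca",
   "stoichiometry": {
    "AcCoA_m": 1.0,
    "Pyr_m": -1.0
   },
   "upper_bound": 1000
  },
  {
   "compartment": "m",
   "exchange": false,
   "genes": [],
   "id": "TCA_m",
   "lower_bound": 0,
   "name": "TCA cycle (lumped)",
   "pathway": "tca",
   "stoichiometry": {
    "AcCoA_m": -1.0,
    "OAA_m": 1.0
   },
   "upper_bound": 1000
  },
  {
   "compartment": "mc",
   "exchange": false,
   "genes": [],
   "id": "OAAT_mc",
   "lower_bound": 0,
   "name": "oxaloacetate export",
   "pathway": "transport",
   "stoichiometry": {
    "OAA_c": 1.0,
    "OAA_m": -1.0
   },
   "upper_bound": 1000
  },
  {
   "compartment": "p",
   "exchange": false,
   "genes": [],
   "id": "PDH_p",
   "lower_bound": 0,
   "name": "plastidic pyruvate dehydrogenase",
   "pathway": "fatty_acid",
   "stoichiometry": {
    "AcCoA_p": 1.0,
    "Pyr_p": -1.0
   },
   "upper_bound": 1000
  },
  {
   "compartment": "p",
   "exchange": false,
   "genes": [],
   "id": "FAS_p",
   "lower_bound": 0,
   "name": "fatty-acid synthase (lumped)",
   "pathway": "fatty_acid",
   "stoichiometry": {
    "AcCoA_p": -4.0,
    "FA_p": 1.0
   },
   "upper_bound": 1000
  },
  {
   "compartment": "pc",
   "exchange": false,
   "genes": [],
   "id": "FAT_pc",
   "lower_bound": 0,
   "name": "fatty-acid export",
   "pathway": "transport",
   "stoichiometry": {
    "FA_c": 1.0,
    "FA_p": -1.0
   },
   "upper_bound": 1000
  },
  {
   "compartment": "c",
   "exchange": false,
   "genes": [],
   "id": "TAG_c",
   "lower_bound": 0,
   "name": "TAG assembly",
   "pathway": "fatty_acid",
   "stoichiometry": {
    "FA_c": -3.0,
    "TAG_c": 1.0
   },
   "upper_bound": 1000
  },
  {
   "compartment": "p",
   "exchange": false,
   "genes": [],
   "id": "AGP_p",
   "lower_bound": 0,
   "name": "ADP-glucose pyrophosphorylase",
   "pathway": "starch_synthesis",
   "stoichiometry": {
    "ADPG_p": 1.0,
    "G6P_p": -1.0
   },
   "upper_bound": 1000
  },
  {
   "compartment": "p",
   "exchange": false,
   "genes": [],
   "id": "STS_p",
   "lower_bound": 0,
   "name": "starch synthase",
   "pathway": "starch_synthesis",
   "stoichiometry": {
    "ADPG_p": -1.0,
    "Starch_p": 1.0
   },
   "upper_bound": 1000
  },
  {
   "compartment": "c",
   "exchange": false,
   "genes": [],
   "id": "AAS_c",
   "lower_bound": 0,
   "name": "amino-acid synthesis (lumped)",
   "pathway": "amino_acid",
   "stoichiometry": {
    "AA_c": 2.0,
    "E4P_c": -1.0,
    "OAA_c": -1.0
   },
   "upper_bound": 1000
  },
  {
   "compartment": "c",
   "exchange": false,
   "genes": [],
   "id": "PROT_c",
   "lower_bound": 0,
   "name": "protein synthesis",
   "pathway": "protein_synthesis",
   "stoichiometry": {
    "AA_c": -1.0,
    "Prot_c": 1.0
   },
   "upper_bound": 1000
  },
  {
   "compartment": "c",
   "exchange": false,
   "genes": [],
   "id": "biomass",
   "lower_bound": 0,
   "name": "biomass assembly",
   "pathway": "biomass",
   "stoichiometry": {
    "Prot_c": -0.5,
    "Starch_p": -0.1,
    "TAG_c": -0.4
   },
   "upper_bound": 1000
  },
  {
   "compartment": "m",
   "exchange": true,
   "genes": [],
   "id": "RESP_m",
   "lower_bound": 0.0,
   "name": "respiration (pyruvate oxidation to CO2, lumped)",
   "pathway": "tca",
   "stoichiometry": {
    "Pyr_m": -1.0
   },
   "upper_bound": 1000.0
  }
 ]
}
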