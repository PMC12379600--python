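{
  "_comment": "Lipid definitions. Formulas are element counts per molecule. The tail region holds only the hydrocarbon chains (C13H27 per myristoyl chain); glycerol backbone, carbonyls, phosphate and polar group belong to the headgroup. n_exchangeable_H is the chemical maximum of labile hydrogens in the headgroup; an exchange scenario chooses how many actually exchange. d54 analogues carry fully deuterated chains (27 D per chain).",
  "DMPE": {
    "full_name": "1,2-dimyristoyl-sn-glycero-3-phosphoethanolamine",
    "n_chains": 2,
    "tail_formula": {"C": 26, "H": 54},
    "headgroup_formula": {"C": 7, "H": 12, "N": 1, "O": 8, "P": 1},
    "n_exchangeable_H": 3,
    "tails_deuterated": false
  },
  "DMPG": {
    "full_name": "1,2-dimyristoyl-sn-glycero-3-phospho-(1'-rac-glycerol), sodium salt",
    "n_chains": 2,
    "tail_formula": {"C": 26, "H": 54},
    "headgroup_formula": {"C": 8, "H": 12, "O": 10, "P": 1, "Na": 1},
    "n_exchangeable_H": 2,
    "tails_deuterated": false
  },
  "TMCL": {
    "full_name": "1',3'-bis[1,2-dimyristoyl-sn-glycero-3-phospho]-glycerol, disodium salt",
    "n_chains": 4,
    "tail_formula": {"C": 52, "H": 108},
    "headgroup_formula": {"C": 13, "H": 16, "O": 17, "P": 2, "Na": 2},
    "n_exchangeable_H": 1,
    "tails_deuterated": false
  },
  "d54-DMPE": {
    "full_name": "1,2-dimyristoyl-d54-sn-glycero-3-phosphoethanolamine",
    "n_chains": 2,
    "tail_formula": {"C": 26, "D": 54},
    "headgroup_formula": {"C": 7, "H": 12, "N": 1, "O": 8, "P": 1},
    "n_exchangeable_H": 3,
    "tails_deuterated": true
  },
  "d54-DMPG": {
    "full_name": "1,2-dimyristoyl-d54-sn-glycero-3-phospho-(1'-rac-glycerol), sodium salt",
    "n_chains": 2,
    "tail_formula": {"C": 26, "D": 54},
    "headgroup_formula": {"C": 8, "H": 12, "O": 10, "P": 1, "Na": 1},
    "n_exchangeable_H": 2,
    "tails_deuterated": true
  }
}
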