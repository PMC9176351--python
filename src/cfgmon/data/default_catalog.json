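[
  {
    "name": "ketone",
    "smarts": "[#6][CX3](=O)[#6]",
    "description": "Carbonyl carbon flanked by two carbons; excludes aldehydes, acids and amides."
  },
  {
    "name": "diketone",
    "smarts": "[#6][CX3](=O)[CX3](=O)[#6]",
    "description": "Alpha-diketone: two directly bonded ketone carbonyls (1,2-dione)."
  },
  {
    "name": "aniline",
    "smarts": "[NX3;!$(N=*)]c1ccccc1",
    "description": "Trivalent amine nitrogen bonded to a benzene carbon."
  },
  {
    "name": "azo",
    "smarts": "[#6]N=N[#6]",
    "description": "C-substituted azo bridge; E/Z unconstrained."
  },
  {
    "name": "1,2-quinone",
    "smarts": "O=[#6]1-[#6](=O)-[#6]=,:[#6]-[#6]=,:[#6]-1",
    "description": "Ortho-quinone: six-membered carbocycle with adjacent diones and two ring double (or fused-aromatic) bonds."
  },
  {
    "name": "1,4-quinone",
    "smarts": "O=[#6]1-[#6]=,:[#6]-[#6](=O)-[#6]=,:[#6]-1",
    "description": "Para-quinone: six-membered carbocycle with 1,4-diones and two ring double (or fused-aromatic) bonds."
  },
  {
    "name": "1,2-naphthoquinone",
    "smarts": "O=C1C(=O)c2ccccc2C=C1",
    "description": "Naphthalene-1,2-dione core (benzo-fused ortho-quinone)."
  },
  {
    "name": "1,4-naphthoquinone",
    "smarts": "O=C1c2ccccc2C(=O)C=C1",
    "description": "Naphthalene-1,4-dione core (benzo-fused para-quinone)."
  }
]
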