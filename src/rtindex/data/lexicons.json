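{
  "criteria": {
    "IRB": [
      "institutional review board",
      "\\bIRB\\b",
      "ethic(?:s|al)\\s+(?:committee|review board)",
      "NRES committee",
      "human subjects? protocols?",
      "ethics approval"
    ],
    "CONSENT": [
      "informed consent",
      "written consent",
      "\\bconsent\\s+(?:was|were|had been)\\s+(?:obtained|given|provided|waived)",
      "parental permission",
      "oral assent",
      "\\bassent\\s+was\\s+obtained"
    ],
    "IACUC": [
      "\\bIACUC\\b",
      "animal care and use committee",
      "animal ethics committee",
      "animal welfare (?:committee|act)",
      "animal \\(scientific procedures\\)",
      "project licen[cs]es?",
      "animal (?:experiments?|work|procedures?|studies) were (?:performed|conducted|carried out|approved|done) in accordance"
    ],
    "RANDOMIZATION": [
      "randomi[sz]ation",
      "randomi[sz]ed",
      "randomly\\s+(?:assigned|allocated|divided|distributed|selected|chosen)"
    ],
    "BLINDING": [
      "double[- ]?blind",
      "single[- ]?blind"
    ],
    "POWER": [
      "power analysis",
      "power calculation",
      "sample[- ]size calculations?",
      "sample size was\\s+(?:based|calculated|determined|estimated|computed|chosen)",
      "statistical power",
      "a priori power"
    ],
    "CELL_AUTH": [
      "authenticat",
      "STR profil",
      "short tandem repeat",
      "GenePrint",
      "identity was\\s+(?:verified|confirmed)"
    ],
    "CELL_CONTAM": [
      "mycoplasma"
    ]
  },
  "blinding_terms": [
    "\\bblind(?:ed|ing)?\\b",
    "\\bunaware\\b",
    "\\bmasked\\b"
  ],
  "blinding_context": [
    "experimenter", "investigator", "observer", "person", "personnel",
    "analyst", "assessor", "rater", "curator", "researcher",
    "scored", "scoring", "analysis", "analyses", "assessment",
    "evaluat", "quantif", "group assignment", "group allocation",
    "condition", "treatment", "outcome", "genotype", "diagnosis",
    "experimental question", "cohort"
  ],
  "sex_terms": [
    "\\bmales?\\b",
    "\\bfemales?\\b",
    "\\bsex\\b",
    "\\bsexes\\b",
    "\\bboth sexes\\b",
    "\\bmothers?\\b",
    "\\bmen\\b",
    "\\bwomen\\b",
    "\\bboys?\\b",
    "\\bgirls?\\b"
  ],
  "sex_exclusions": [
    "sex-determining",
    "sex determination",
    "sex chromosome",
    "sex comb",
    "maleless",
    "male-specific lethal",
    "male sterile",
    "female-sterile"
  ],
  "vendors": [
    "Santa Cruz Biotechnology", "Santa Cruz Biotech", "Santa Cruz",
    "Abcam", "Sigma-Aldrich", "Sigma", "Thermo Fisher Scientific",
    "Thermo Fisher", "Thermo Scientific", "Invitrogen",
    "Cell Signaling Technology", "Cell Signaling", "Millipore",
    "EMD Millipore", "BD Biosciences", "Jackson ImmunoResearch",
    "The Jackson Laboratory", "Jackson Laboratory", "Charles River Laboratories",
    "Charles River", "Taconic", "Envigo", "R&D Systems", "BioLegend",
    "ATCC", "American Tissue Culture Collection",
    "American Type Culture Collection", "Addgene", "Promega", "DGRC",
    "Bloomington Drosophila Stock Center", "Rainbow Transgenics",
    "Roche", "Qiagen", "New England Biolabs", "Proteintech",
    "Novus Biologicals", "Dako", "GeneTex", "Synaptic Systems",
    "Bio-Rad", "Merck", "Lonza", "DSMZ", "JCRB", "RIKEN"
  ],
  "cell_lines": [
    "HeLa", "HEK293T", "HEK293", "HEK-293", "H1299", "A549", "MCF-7",
    "MCF7", "U2OS", "Jurkat", "CHO-K1", "CHO", "3T3-L1", "NIH3T3",
    "NIH 3T3", "J774A.1", "MOLM-14", "K562", "HCT116", "PC12",
    "SH-SY5Y", "RAW 264.7", "RAW264.7", "Caco-2", "HepG2", "U937",
    "THP-1", "MDCK", "Vero", "COS-7"
  ],
  "organism_strains": [
    "C57BL/6[JN]?",
    "BALB/cJ?",
    "Sprague[- ]Dawley",
    "Wistar",
    "Long[- ]Evans",
    "w1118",
    "vas-Cas9",
    "Tg\\([^()]{1,60}\\)[A-Za-z0-9]*",
    "[A-Z][A-Za-z0-9]{1,12}-Cre"
  ],
  "organism_species": [
    "\\bmice\\b", "\\bmouse\\b", "\\brats?\\b", "\\bzebrafish\\b",
    "\\bmacaques?\\b", "\\bDrosophila\\b", "\\bC\\. elegans\\b",
    "\\bXenopus\\b", "\\brabbits?\\b", "\\bferrets?\\b",
    "\\bguinea pigs?\\b", "\\brhesus\\b", "\\bmarmosets?\\b",
    "\\bpiglets?\\b"
  ],
  "catalog_cue_patterns": [
    "#\\s?([A-Za-z0-9][A-Za-z0-9\\-]*)",
    "(?i:\\bcat(?:alog(?:ue)?)?\\.?\\s*(?:no\\.?|num(?:ber)?|#|:)\\s*)([A-Za-z0-9][A-Za-z0-9\\-]+)",
    "\\bnumber\\s+([A-Z][A-Za-z0-9\\-]*\\d[A-Za-z0-9\\-]*)\\b",
    "\\b(ab\\d{3,})\\b",
    "\\b(sc-\\d{2,})\\b"
  ],
  "catalog_vendor_code_pattern": "\\b([A-Z]{2,4}-\\d{2,6})\\b"
}
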