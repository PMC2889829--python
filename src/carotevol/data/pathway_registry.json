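{
  "_comment": "Curated registry of known microbial carotenoid biosynthetic reactions used for in-silico pathway reconstruction. Compounds modified at one vs both ends are collapsed to a single node, stoichiometry is ignored (presence/absence logic only), and glycosylations/esterifications are omitted. Multi-round modifications by one enzyme (e.g. the spirilloxanthin branch) are collapsed into sequential single-substrate edges. This is curated data, not code; extend or replace it via a user registry file.",
  "precursors": ["FPP", "GGPP"],
  "compounds": {
    "FPP": "precursor",
    "GGPP": "precursor",
    "4,4'-diapophytoene": "C30",
    "4,4'-diaponeurosporene": "C30",
    "4,4'-diapolycopene": "C30",
    "4,4'-diaponeurosporenal": "C30",
    "4,4'-diapolycopenal": "C30",
    "phytoene": "C40",
    "zeta-carotene": "C40",
    "7,9,7',9'-cis-lycopene": "C40",
    "lycopene": "C40",
    "neurosporene": "C40",
    "gamma-carotene": "C40",
    "beta-carotene": "C40",
    "delta-carotene": "C40",
    "epsilon-carotene": "C40",
    "zeaxanthin": "C40",
    "nostoxanthin": "C40",
    "echinenone": "C40",
    "canthaxanthin": "C40",
    "4-keto-gamma-carotene": "C40",
    "isorenieratene": "C40",
    "chi-carotene": "C40",
    "renierapurpurin": "C40",
    "hydroxyrenierapurpurin": "C40",
    "synechoxanthin": "C40",
    "rhodopin": "C40",
    "3,4-didehydrorhodopin": "C40",
    "anhydrorhodovibrin": "C40",
    "spirilloxanthin": "C40",
    "hydroxyneurosporene": "C40",
    "demethylspheroidene": "C40",
    "spheroidene": "C40",
    "spheroidenone": "C40",
    "flavuxanthin": "C50",
    "decaprenoxanthin": "C50",
    "C.p.450": "C50"
  },
  "intermediates": [
    "4,4'-diapophytoene",
    "phytoene",
    "zeta-carotene",
    "7,9,7',9'-cis-lycopene",
    "hydroxyneurosporene",
    "demethylspheroidene",
    "3,4-didehydrorhodopin",
    "anhydrorhodovibrin",
    "chi-carotene",
    "renierapurpurin",
    "hydroxyrenierapurpurin",
    "flavuxanthin"
  ],
  "default_variants": {
    "CrtN": "4-step",
    "CrtI": "4-step",
    "CrtY": "bi",
    "CrtL": "bi",
    "CruA": "bi",
    "CrtYcd": "bi"
  },
  "reactions": [
    {"family": "CrtM", "variant": "", "substrate": "FPP", "product": "4,4'-diapophytoene"},
    {"family": "CrtN", "variant": "4-step", "substrate": "4,4'-diapophytoene", "product": "4,4'-diapolycopene"},
    {"family": "CrtN", "variant": "3-step", "substrate": "4,4'-diapophytoene", "product": "4,4'-diaponeurosporene"},
    {"family": "CrtNb", "variant": "", "substrate": "4,4'-diaponeurosporene", "product": "4,4'-diaponeurosporenal"},
    {"family": "CrtNb", "variant": "", "substrate": "4,4'-diapolycopene", "product": "4,4'-diapolycopenal"},
    {"family": "CrtB", "variant": "", "substrate": "GGPP", "product": "phytoene"},
    {"family": "CrtI", "variant": "4-step", "substrate": "phytoene", "product": "lycopene"},
    {"family": "CrtI", "variant": "3-step", "substrate": "phytoene", "product": "neurosporene"},
    {"family": "CrtP", "variant": "", "substrate": "phytoene", "product": "zeta-carotene"},
    {"family": "CrtQ", "variant": "", "substrate": "zeta-carotene", "product": "7,9,7',9'-cis-lycopene"},
    {"family": "CrtH", "variant": "", "substrate": "7,9,7',9'-cis-lycopene", "product": "lycopene"},
    {"family": "CrtY", "variant": "bi", "substrate": "lycopene", "product": "gamma-carotene"},
    {"family": "CrtY", "variant": "bi", "substrate": "gamma-carotene", "product": "beta-carotene"},
    {"family": "CrtY", "variant": "mono", "substrate": "lycopene", "product": "gamma-carotene"},
    {"family": "CrtL", "variant": "bi", "substrate": "lycopene", "product": "gamma-carotene"},
    {"family": "CrtL", "variant": "bi", "substrate": "gamma-carotene", "product": "beta-carotene"},
    {"family": "CrtL", "variant": "mono", "substrate": "lycopene", "product": "gamma-carotene"},
    {"family": "CrtLe", "variant": "", "substrate": "lycopene", "product": "delta-carotene"},
    {"family": "CrtLe", "variant": "", "substrate": "delta-carotene", "product": "epsilon-carotene"},
    {"family": "CruA", "variant": "bi", "substrate": "lycopene", "product": "gamma-carotene"},
    {"family": "CruA", "variant": "bi", "substrate": "gamma-carotene", "product": "beta-carotene"},
    {"family": "CruA", "variant": "mono", "substrate": "lycopene", "product": "gamma-carotene"},
    {"family": "CruP", "variant": "", "substrate": "lycopene", "product": "gamma-carotene"},
    {"family": "CruB", "variant": "", "substrate": "lycopene", "product": "gamma-carotene"},
    {"family": "CrtYcd", "variant": "bi", "substrate": "lycopene", "product": "gamma-carotene"},
    {"family": "CrtYcd", "variant": "bi", "substrate": "gamma-carotene", "product": "beta-carotene"},
    {"family": "CrtYcd", "variant": "mono", "substrate": "lycopene", "product": "gamma-carotene"},
    {"family": "CrtEb", "variant": "", "substrate": "lycopene", "product": "flavuxanthin"},
    {"family": "CrtYef", "variant": "", "substrate": "flavuxanthin", "product": "decaprenoxanthin"},
    {"family": "LitAB", "variant": "", "substrate": "flavuxanthin", "product": "C.p.450"},
    {"family": "CrtZ", "variant": "", "substrate": "beta-carotene", "product": "zeaxanthin"},
    {"family": "CrtR", "variant": "", "substrate": "beta-carotene", "product": "zeaxanthin"},
    {"family": "CrtG", "variant": "", "substrate": "zeaxanthin", "product": "nostoxanthin"},
    {"family": "CrtW", "variant": "", "substrate": "beta-carotene", "product": "echinenone"},
    {"family": "CrtW", "variant": "", "substrate": "echinenone", "product": "canthaxanthin"},
    {"family": "CrtO", "variant": "", "substrate": "beta-carotene", "product": "echinenone"},
    {"family": "CrtO", "variant": "", "substrate": "gamma-carotene", "product": "4-keto-gamma-carotene"},
    {"family": "CrtU", "variant": "", "substrate": "beta-carotene", "product": "isorenieratene"},
    {"family": "CruE", "variant": "", "substrate": "beta-carotene", "product": "chi-carotene"},
    {"family": "CruH", "variant": "", "substrate": "chi-carotene", "product": "renierapurpurin"},
    {"family": "CruF", "variant": "", "substrate": "renierapurpurin", "product": "hydroxyrenierapurpurin"},
    {"family": "CruG", "variant": "", "substrate": "hydroxyrenierapurpurin", "product": "synechoxanthin"},
    {"family": "CrtC", "variant": "", "substrate": "lycopene", "product": "rhodopin"},
    {"family": "CrtC", "variant": "", "substrate": "neurosporene", "product": "hydroxyneurosporene"},
    {"family": "CrtD", "variant": "", "substrate": "rhodopin", "product": "3,4-didehydrorhodopin"},
    {"family": "CrtD", "variant": "", "substrate": "hydroxyneurosporene", "product": "demethylspheroidene"},
    {"family": "CrtF", "variant": "", "substrate": "3,4-didehydrorhodopin", "product": "anhydrorhodovibrin"},
    {"family": "CrtF", "variant": "", "substrate": "anhydrorhodovibrin", "product": "spirilloxanthin"},
    {"family": "CrtF", "variant": "", "substrate": "demethylspheroidene", "product": "spheroidene"},
    {"family": "CrtA", "variant": "", "substrate": "spheroidene", "product": "spheroidenone"}
  ]
}
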