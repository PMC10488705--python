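{
  "version": "1.0",
  "assembly": "NC_000010.11",
  "chromosome": "10",
  "loci": [
    {"rsid": "rs1799853", "position": 94942290, "ref": "C", "alt": "T", "tags_star": "*2"},
    {"rsid": "rs7900194", "position": 94942309, "ref": "G", "alt": "A", "tags_star": "*8"},
    {"rsid": "rs28371685", "position": 94981224, "ref": "C", "alt": "T", "tags_star": "*11"},
    {"rsid": "rs1057910", "position": 94981296, "ref": "A", "alt": "C", "tags_star": "*3"},
    {"rsid": "rs28371686", "position": 94981301, "ref": "C", "alt": "G", "tags_star": "*5"}
  ],
  "star_alleles": [
    {"name": "*1", "activity": 1.0, "function": "normal"},
    {"name": "*2", "activity": 0.5, "function": "decreased"},
    {"name": "*3", "activity": 0.0, "function": "no-function"},
    {"name": "*5", "activity": 0.5, "function": "decreased"},
    {"name": "*8", "activity": 0.5, "function": "decreased"},
    {"name": "*11", "activity": 0.5, "function": "decreased"}
  ],
  "pooled_allele": {"name": "var", "members": ["*5", "*8", "*11"], "activity": 0.5, "function": "decreased"}
}
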