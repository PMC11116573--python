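{
  "_comment": "SYNTHETIC illustration of an AOPWiki-style reference (peroxisomal fatty-acid beta-oxidation inhibition leading to steatosis). Hand-built example of the documented JSON schema, not a transcription of the live AOPWiki entry.",
  "aop_id": "36-synthetic",
  "title": "Peroxisomal Fatty Acid Beta-Oxidation Inhibition Leading to Steatosis (synthetic)",
  "events": [
    {"event_id": "E1", "title": "Activation, PPAR-alpha", "type": "MIE"},
    {"event_id": "E2", "title": "Decreased, fatty acid beta-oxidation", "type": "KE"},
    {"event_id": "E3", "title": "Increased, lipid accumulation", "type": "KE"},
    {"event_id": "E4", "title": "Increased, steatosis", "type": "AO"}
  ],
  "kers": [
    {"upstream": "E1", "downstream": "E2"},
    {"upstream": "E2", "downstream": "E3"},
    {"upstream": "E3", "downstream": "E4"}
  ]
}
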