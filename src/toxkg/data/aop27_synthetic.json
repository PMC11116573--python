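{
  "_comment": "SYNTHETIC illustration of an AOPWiki-style reference (bile salt export pump inhibition leading to cholestatic injury). Event list and wiring are hand-built examples of the documented JSON schema, not a transcription of the live AOPWiki entry.",
  "aop_id": "27-synthetic",
  "title": "Cholestatic Liver Injury induced by Inhibition of the Bile Salt Export Pump (synthetic)",
  "events": [
    {"event_id": "E1", "title": "Inhibition, Bile Salt Export Pump", "type": "MIE"},
    {"event_id": "E2", "title": "Increased, bile accumulation", "type": "KE"},
    {"event_id": "E3", "title": "Increased, oxidative stress", "type": "KE"},
    {"event_id": "E4", "title": "Occurrence, cholestasis", "type": "AO"}
  ],
  "kers": [
    {"upstream": "E1", "downstream": "E2"},
    {"upstream": "E2", "downstream": "E3"},
    {"upstream": "E3", "downstream": "E4"}
  ]
}
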