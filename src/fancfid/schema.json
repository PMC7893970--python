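{
  "women": {
    "woman_id": {"type": "identifier", "required": true},
    "cluster_id": {"type": "identifier", "required": true},
    "age_years": {"type": "real", "min": 12, "required": false},
    "n_visits": {"type": "integer", "min": 0, "required": true},
    "provider": {"type": "enum", "values": ["HEW", "SKILLED", "NONE"], "required": true},
    "tt_doses": {"type": "integer", "min": 0, "required": true},
    "prior_pregnancy_problems": {"type": "boolean", "required": false},
    "partner_education": {"type": "enum", "values": ["NO_FORMAL", "FORMAL_1_8"], "required": false},
    "maternal_education": {"type": "enum", "values": ["NO_FORMAL", "FORMAL"], "required": false},
    "n_abortions": {"type": "integer", "min": 0, "required": false},
    "walk_minutes_to_health_post": {"type": "real", "min": 0, "required": false},
    "first_visit_month": {"type": "integer", "min": 1, "max": 10, "required": false},
    "weight_measured": {"type": "boolean", "required": true},
    "height_measured": {"type": "boolean", "required": true},
    "bp_measured": {"type": "boolean", "required": true},
    "advised_institutional_birth": {"type": "boolean", "required": true},
    "advised_bpcr": {"type": "boolean", "required": true},
    "advised_danger_signs": {"type": "boolean", "required": true},
    "advised_hygiene": {"type": "boolean", "required": true},
    "advised_pmtct": {"type": "boolean", "required": true},
    "advised_sti": {"type": "boolean", "required": true},
    "advised_bed_net": {"type": "boolean", "required": true},
    "hiv_tested": {"type": "boolean", "required": true},
    "advised_nutrition": {"type": "boolean", "required": true},
    "told_seek_care": {"type": "boolean", "required": true},
    "iron_folate": {"type": "boolean", "required": true},
    "referred_institutional_birth": {"type": "boolean", "required": true},
    "edd_told": {"type": "boolean", "required": true},
    "tt_adequate": {"type": "boolean", "required": false, "derived_from": "tt_doses"}
  },
  "clusters": {
    "cluster_id": {"type": "identifier", "required": true},
    "n_hews": {"type": "integer", "min": 0, "required": true},
    "farthest_household_minutes": {"type": "real", "min": 0, "required": true},
    "weekly_hc_supervision": {"type": "boolean", "required": true},
    "monthly_woreda_supervision": {"type": "boolean", "required": true},
    "community_support": {"type": "boolean", "required": true},
    "hda_support": {"type": "boolean", "required": true},
    "onsite_assistance": {"type": "boolean", "required": true},
    "fanc_training": {"type": "boolean", "required": true},
    "recent_refresher": {"type": "boolean", "required": true},
    "supply_*": {"type": "boolean", "required": false, "note": "one column per audited supply item, supply_ prefix"}
  },
  "booleans": ["0", "1", "yes", "no", "true", "false"],
  "missing_marker": ""
}
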