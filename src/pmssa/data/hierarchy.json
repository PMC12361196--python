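{
  "name": "pmssa-published-weights",
  "description": "The published 5-domain / 18-characteristic / 84-item weighting table of the primary-care medication safety self-assessment instrument. Combination weights are transcribed as printed (two decimals of a percent; they sum to 99.95%), so the loader applies a 0.1% slack. lambda_max and cr are the published consistency diagnostics of each domain-level comparison matrix.",
  "weight_sum_tolerance": 0.001,
  "domains": [
    {
      "id": "1", "name": "Human factor", "lambda_max": 4.123, "cr": 0.045,
      "characteristics": [
        {"id": "1.1", "name": "Patient information", "n_items": 3, "combination_weight_pct": 7.75},
        {"id": "1.2", "name": "Patient education", "n_items": 5, "combination_weight_pct": 3.12},
        {"id": "1.3", "name": "Staff competency and education", "n_items": 7, "combination_weight_pct": 11.73},
        {"id": "1.4", "name": "Staffing patterns", "n_items": 4, "combination_weight_pct": 11.73}
      ]
    },
    {
      "id": "2", "name": "Technology applications", "lambda_max": 2.000, "cr": 0.000,
      "characteristics": [
        {"id": "2.1", "name": "Information technology applications", "n_items": 8, "combination_weight_pct": 8.87},
        {"id": "2.2", "name": "Automation equipment", "n_items": 3, "combination_weight_pct": 4.43}
      ]
    },
    {
      "id": "3", "name": "Drug management", "lambda_max": 6.282, "cr": 0.045,
      "characteristics": [
        {"id": "3.1", "name": "Product selection and pharmacy inventory", "n_items": 6, "combination_weight_pct": 8.80},
        {"id": "3.2", "name": "Drug storage", "n_items": 5, "combination_weight_pct": 4.88},
        {"id": "3.4", "name": "High-alert medications", "n_items": 3, "combination_weight_pct": 3.35},
        {"id": "3.5", "name": "Product with similar/confusing packaging and look/sound alike name", "n_items": 4, "combination_weight_pct": 3.01},
        {"id": "3.6", "name": "Emergency supplies", "n_items": 3, "combination_weight_pct": 2.63},
        {"id": "3.7", "name": "Product out of pharmacy medication list", "n_items": 3, "combination_weight_pct": 1.22}
      ]
    },
    {
      "id": "4", "name": "Workflow and environment", "lambda_max": 4.061, "cr": 0.022,
      "characteristics": [
        {"id": "4.1", "name": "Order entry", "n_items": 6, "combination_weight_pct": 5.23},
        {"id": "4.2", "name": "Pharmacists review", "n_items": 4, "combination_weight_pct": 3.08},
        {"id": "4.3", "name": "Drug preparing, dispensing and administering", "n_items": 5, "combination_weight_pct": 3.08},
        {"id": "4.4", "name": "Environment factors", "n_items": 3, "combination_weight_pct": 0.93}
      ]
    },
    {
      "id": "5", "name": "Risk management and safety culture", "lambda_max": 2.000, "cr": 0.000,
      "characteristics": [
        {"id": "5.1", "name": "Risk management", "n_items": 6, "combination_weight_pct": 12.08},
        {"id": "5.2", "name": "Safety culture", "n_items": 6, "combination_weight_pct": 4.03}
      ]
    }
  ]
}
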