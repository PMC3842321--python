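{
  "description": "Published per-class classification counts for the 28-sample cohort, with the performance percentages reported alongside them. Used to recompute every reported metric from the raw counts.",
  "three_class": {
    "classes": ["SDHx", "VHL", "sporadic"],
    "totals": {"SDHx": 12, "VHL": 6, "sporadic": 10},
    "correct": {"SDHx": 12, "VHL": 5, "sporadic": 8},
    "carrier_classes": ["SDHx", "VHL"],
    "reported_percent": {
      "carrier_sensitivity": 94,
      "carrier_specificity": 80,
      "carrier_ppv": 89,
      "carrier_npv": 89,
      "carrier_accuracy": 89
    }
  },
  "sporadic_vs_sdhx": {
    "classes": ["SDHx", "sporadic"],
    "totals": {"SDHx": 12, "sporadic": 10},
    "correct": {"SDHx": 11, "sporadic": 9},
    "positive": "SDHx",
    "reported_percent": {
      "sensitivity": 92,
      "specificity": 90,
      "ppv": 92,
      "npv": 90,
      "accuracy": 91
    }
  },
  "sporadic_vs_vhl": {
    "classes": ["VHL", "sporadic"],
    "totals": {"VHL": 6, "sporadic": 10},
    "correct": {"VHL": 6, "sporadic": 10},
    "positive": "VHL",
    "reported_percent": {"accuracy": 100}
  },
  "sdhx_vs_vhl": {
    "classes": ["SDHx", "VHL"],
    "totals": {"SDHx": 12, "VHL": 6},
    "correct": {"SDHx": 12, "VHL": 6},
    "positive": "SDHx",
    "reported_percent": {"accuracy": 100}
  }
}
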