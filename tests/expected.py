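"""Reference values the analysis must reproduce from the deterministic
reference cohort (group × finding contingency structure of the published
1,473-patient suspected-PE study)."""

#: (LR+ printed, LR− printed) per finding and population.
TABLE3_PRINTED = {
    "all": {
        "normal": ("0.86 (0.78–0.96)", "1.4 (1.1–1.7)"),
        "pleural_effusion": ("1.1 (0.66–2.0)", "0.99 (0.95–1.0)"),
        "consolidation": ("1.8 (1.4–2.4)", "0.88 (0.82–0.95)"),
        "malignancy_mass": ("0.93 (0.40–2.2)", "1.0 (0.98–1.0)"),
        "congestive_heart_failure": ("0.98 (0.45–2.2)", "1.0 (0.97–1.0)"),
        "pneumothorax": ("0.00", "1.0 (0.99–1.0)"),
        "rib_fracture": ("0.00", "1.0 (0.99–1.0)"),
        "atelectasis": ("0.49 (0.06–3.8)", "1.0 (0.99–1.0)"),
    },
    "ctpa_indicated": {
        "normal": ("1.1 (0.95–1.2)", "0.89 (0.73–1.1)"),
        "pleural_effusion": ("0.58 (0.33–1.0)", "1.1 (1.0–1.1)"),
        "consolidation": ("1.4 (0.99–1.8)", "0.93 (0.86–1.0)"),
        "malignancy_mass": ("0.51 (0.22–1.2)", "1.0 (1.0–1.1)"),
        "congestive_heart_failure": ("0.67 (0.29–1.5)", "1.0 (0.99–1.0)"),
        "pneumothorax": ("n.a.", "n.a."),
        "rib_fracture": ("0.00", "1.0 (0.99–1.0)"),
        "atelectasis": ("0.37 (0.05–3.0)", "1.0 (0.99–1.0)"),
    },
}

#: Headline odds ratios at two-decimal precision.
HEADLINE_ORS_PRINTED = {
    "abnormal_cxr_pe": "1.60 (1.18–2.18)",
    "consolidation_pe": "2.08 (1.45–2.99)",
    "normal_cxr_no_ctpa": "3.65 (2.84–4.70)",
}

#: All-patients column of the finding-count table: (count, percent).
TABLE2_ALL_PRINTED = {
    "normal": (1069, 72.6),
    "pleural_effusion": (86, 5.8),
    "consolidation": (206, 14.0),
    "malignancy_mass": (44, 3.0),
    "congestive_heart_failure": (49, 3.3),
    "pneumothorax": (2, 0.1),
    "rib_fracture": (4, 0.3),
    "atelectasis": (13, 0.9),
}
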