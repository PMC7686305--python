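"""Published in vivo prostate relaxometry summary values bundled as data.

These constants come from a 3 T clinical prostate cohort (14 patients,
19 biopsy-proven lesions: 10 peripheral-zone, 9 transition-zone) and drive
two things: the default truth distributions of the virtual-pelvis generator
and the "table replay" mode that recomputes the coefficient-of-variation
table directly from the summary means and SDs.

Layout: ``SUMMARY_TABLE[tissue][column] = (mean, sd)`` with columns
MRF_T1_pre, MRF_T1_post, MRF_T2_pre, MRF_T2_post, VFA_T1_pre, MSE_T2_pre,
ADC_pre.  T1/T2 in ms, ADC in 10^-3 mm^2/s.
"""

from __future__ import annotations

__all__ = [
    "TISSUES",
    "LESION_TISSUES",
    "SUMMARY_COLUMNS",
    "SUMMARY_TABLE",
    "PUBLISHED_CV_TABLE",
    "CV_REPLAY_EXCLUSIONS",
    "MATCHED_SUBSETS",
]

TISSUES = (
    "All lesions",
    "PZ lesions",
    "TZ lesions",
    "Normal PZ",
    "Normal TZ",
    "Muscle",
    "Fat",
)

LESION_TISSUES = ("PZ lesions", "TZ lesions")

SUMMARY_COLUMNS = (
    "MRF_T1_pre",
    "MRF_T1_post",
    "MRF_T2_pre",
    "MRF_T2_post",
    "VFA_T1_pre",
    "MSE_T2_pre",
    "ADC_pre",
)

SUMMARY_TABLE: dict[str, dict[str, tuple[float, float]]] = {
    "All lesions": {
        "MRF_T1_pre": (1666.0, 294.0),
        "MRF_T1_post": (717.8, 346.0),
        "MRF_T2_pre": (443.6, 259.0),
        "MRF_T2_post": (252.9, 167.5),
        "VFA_T1_pre": (1990.0, 522.7),
        "MSE_T2_pre": (76.6, 27.8),
        "ADC_pre": (0.94, 0.17),
    },
    "PZ lesions": {
        "MRF_T1_pre": (1640.0, 368.1),
        "MRF_T1_post": (678.4, 287.9),
        "MRF_T2_pre": (507.8, 292.7),
        "MRF_T2_post": (273.4, 160.7),
        "VFA_T1_pre": (1986.0, 629.5),
        "MSE_T2_pre": (89.2, 21.8),
        "ADC_pre": (0.93, 0.16),
    },
    "TZ lesions": {
        "MRF_T1_pre": (1696.0, 200.5),
        "MRF_T1_post": (761.5, 414.8),
        "MRF_T2_pre": (372.2, 209.0),
        "MRF_T2_post": (230.1, 181.5),
        "VFA_T1_pre": (2002.0, 413.7),
        "MSE_T2_pre": (69.3, 9.8),
        "ADC_pre": (0.90, 0.14),
    },
    "Normal PZ": {
        "MRF_T1_pre": (2521.0, 405.9),
        "MRF_T1_post": (1270.0, 224.6),
        "MRF_T2_pre": (546.7, 294.0),
        "MRF_T2_post": (326.5, 255.3),
        "VFA_T1_pre": (2188.0, 813.9),
        "MSE_T2_pre": (139.4, 79.12),
        "ADC_pre": (1.61, 0.22),
    },
    "Normal TZ": {
        "MRF_T1_pre": (1753.0, 444.7),
        "MRF_T1_post": (723.8, 407.3),
        "MRF_T2_pre": (451.0, 228.0),
        "MRF_T2_post": (237.9, 270.5),
        "VFA_T1_pre": (2118.0, 732.1),
        "MSE_T2_pre": (88.56, 11.67),
        "ADC_pre": (1.27, 0.14),
    },
    "Muscle": {
        "MRF_T1_pre": (1542.0, 211.4),
        "MRF_T1_post": (1214.0, 149.4),
        "MRF_T2_pre": (232.2, 156.3),
        "MRF_T2_post": (180.6, 142.4),
        "VFA_T1_pre": (1813.0, 334.9),
        "MSE_T2_pre": (41.6, 2.7),
        "ADC_pre": (1.17, 0.04),
    },
    "Fat": {
        "MRF_T1_pre": (414.3, 67.1),
        "MRF_T1_post": (327.4, 65.4),
        "MRF_T2_pre": (240.4, 41.1),
        "MRF_T2_post": (213.7, 41.5),
        "VFA_T1_pre": (1682.0, 491.3),
        "MSE_T2_pre": (115.7, 6.6),
        "ADC_pre": (0.08, 0.07),
    },
}

# Published coefficient-of-variation table (percent), same layout.
PUBLISHED_CV_TABLE: dict[str, dict[str, float]] = {
    "All lesions": {
        "MRF_T1_pre": 17.6, "MRF_T1_post": 48.2, "MRF_T2_pre": 58.4,
        "MRF_T2_post": 66.2, "VFA_T1_pre": 26.3, "MSE_T2_pre": 24.0,
        "ADC_pre": 17.6,
    },
    "PZ lesions": {
        "MRF_T1_pre": 22.5, "MRF_T1_post": 42.4, "MRF_T2_pre": 57.6,
        "MRF_T2_post": 58.8, "VFA_T1_pre": 31.7, "MSE_T2_pre": 24.5,
        "ADC_pre": 17.5,
    },
    "TZ lesions": {
        "MRF_T1_pre": 11.8, "MRF_T1_post": 54.5, "MRF_T2_pre": 56.2,
        "MRF_T2_post": 78.9, "VFA_T1_pre": 20.7, "MSE_T2_pre": 14.2,
        "ADC_pre": 15.6,
    },
    "Normal PZ": {
        "MRF_T1_pre": 16.1, "MRF_T1_post": 17.7, "MRF_T2_pre": 53.8,
        "MRF_T2_post": 78.2, "VFA_T1_pre": 37.2, "MSE_T2_pre": 56.7,
        "ADC_pre": 13.9,
    },
    "Normal TZ": {
        "MRF_T1_pre": 25.4, "MRF_T1_post": 56.3, "MRF_T2_pre": 50.6,
        "MRF_T2_post": 113.7, "VFA_T1_pre": 34.6, "MSE_T2_pre": 13.2,
        "ADC_pre": 10.9,
    },
    "Muscle": {
        "MRF_T1_pre": 13.7, "MRF_T1_post": 12.3, "MRF_T2_pre": 67.3,
        "MRF_T2_post": 78.9, "VFA_T1_pre": 18.5, "MSE_T2_pre": 6.6,
        "ADC_pre": 3.7,
    },
    "Fat": {
        "MRF_T1_pre": 16.2, "MRF_T1_post": 20.0, "MRF_T2_pre": 17.1,
        "MRF_T2_post": 19.4, "VFA_T1_pre": 29.2, "MSE_T2_pre": 5.7,
        "ADC_pre": 8.0,
    },
}

# Two published CV cells are arithmetically inconsistent with the summary
# table (27.8/76.6 = 36.3 != 24.0; 0.07/0.08 = 87.5 != 8.0) and are excluded
# from the replay comparison.
CV_REPLAY_EXCLUSIONS = (
    ("All lesions", "MSE_T2_pre"),
    ("Fat", "ADC_pre"),
)

# Patient-matched (lesion-host) normal-tissue subsets, reported alongside the
# pooled values above; they differ because lesion-bearing patients are a
# non-random subset of the cohort.
MATCHED_SUBSETS: dict[str, dict[str, tuple[float, float]]] = {
    "Normal PZ (matched)": {
        "MRF_T1_pre": (2200.0, 776.5),
        "MRF_T1_post": (1317.0, 219.6),
    },
    "Normal TZ (matched)": {
        "MRF_T1_pre": (1966.0, 315.1),
        "MRF_T1_post": (966.4, 635.5),
    },
}
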