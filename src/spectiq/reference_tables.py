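"""Published reference measurements from a physical CZT SPECT/CT acquisition.

Recovery coefficients (%) measured on a CZT SPECT/CT system imaging the
NEMA IEC phantom at four T/B fills, reported per sphere diameter for the
correction-combination, energy-window and acquisition-time comparisons.
They serve two roles here: input rows for recomputing the study's paired
t-tests exactly, and the qualitative baseline the synthetic pipeline is
expected to mirror (ordering and trend properties, not absolute values —
absolute RCs are scanner-specific).

Sphere order in every row: 37, 28, 22, 17, 13, 10 mm.
"""

SPHERE_DIAMETERS_MM = (37, 28, 22, 17, 13, 10)

TB_RATIOS = (32, 16, 8, 4)

#: RC (%) per correction combination; 35 iterations, 20 subsets, no filter,
#: 120 s/frame, 15% window.
RC_BY_CORRECTIONS = {
    32: {
        "AC+SC+RR": (106.70, 94.94, 73.44, 71.06, 74.39, 67.80),
        "AC+RR": (120.23, 107.38, 82.77, 78.93, 80.52, 75.68),
        "AC+SC": (67.96, 53.86, 41.65, 34.67, 29.91, 31.02),
    },
    16: {
        "AC+SC+RR": (106.57, 97.53, 75.37, 76.64, 63.44, 75.91),
        "AC+RR": (122.00, 109.81, 84.78, 87.25, 72.80, 81.33),
        "AC+SC": (71.98, 59.22, 43.23, 41.91, 30.89, 32.54),
    },
    8: {
        "AC+SC+RR": (103.58, 96.65, 73.31, 70.98, 73.14, 54.67),
        "AC+RR": (120.84, 112.18, 88.17, 84.09, 81.65, 62.93),
        "AC+SC": (71.91, 60.81, 45.30, 41.41, 38.88, 28.21),
    },
    4: {
        "AC+SC+RR": (102.89, 96.64, 75.93, 74.79, 53.82, 67.59),
        "AC+RR": (123.41, 115.88, 92.70, 88.94, 66.64, 75.21),
        "AC+SC": (73.86, 62.46, 51.10, 44.19, 34.34, 39.69),
    },
}

#: Percent contrast (%) per correction combination (same protocol).
CONTRAST_BY_CORRECTIONS = {
    32: {
        "AC+SC+RR": (88.95, 80.36, 77.35, 71.82, 59.65, 54.13),
        "AC+RR": (73.37, 65.86, 64.64, 56.71, 46.45, 43.12),
        "AC+SC": (58.30, 42.81, 32.41, 15.69, 8.91, 7.41),
    },
    16: {
        "AC+SC+RR": (92.82, 79.25, 85.58, 62.21, 59.91, 48.74),
        "AC+RR": (76.85, 64.98, 71.41, 51.78, 51.15, 37.85),
        "AC+SC": (80.79, 66.69, 60.76, 43.97, 28.20, 23.83),
    },
    8: {
        "AC+SC+RR": (78.65, 71.05, 64.37, 57.63, 43.49, 39.34),
        "AC+RR": (69.73, 65.77, 50.55, 52.58, 37.50, 32.00),
        "AC+SC": (77.93, 63.92, 38.94, 38.93, 28.40, 22.11),
    },
    4: {
        "AC+SC+RR": (99.94, 76.67, 72.83, 66.09, 45.03, 65.30),
        "AC+RR": (80.81, 62.67, 64.85, 51.79, 39.67, 45.96),
        "AC+SC": (77.03, 63.33, 41.89, 38.29, 9.28, 40.53),
    },
}

#: RC (%) per photopeak window halfwidth (15% vs 20% total width labels);
#: 35 it, 20 subsets, no filter, AC+SC+RR, 120 s/frame.
RC_BY_WINDOW = {
    32: {
        15: (106.70, 94.94, 73.44, 71.06, 74.39, 67.80),
        20: (105.50, 94.23, 72.93, 70.83, 72.89, 65.26),
    },
    16: {
        15: (106.57, 97.53, 75.37, 76.64, 63.44, 75.91),
        20: (104.94, 96.93, 75.36, 77.38, 63.79, 74.35),
    },
    8: {
        15: (103.58, 96.65, 73.31, 70.98, 73.14, 54.67),
        20: (102.46, 96.73, 74.10, 74.64, 72.02, 51.80),
    },
    4: {
        15: (102.89, 96.64, 75.93, 74.79, 53.82, 67.59),
        20: (104.26, 96.31, 79.16, 77.13, 57.10, 58.69),
    },
}

#: RC (%) per acquisition time (s/frame); 35 it, 20 subsets, no filter,
#: AC+SC+RR, 15% window.
RC_BY_TIME = {
    32: {
        5: (106.95, 88.73, 62.68, 63.13, 60.54, 65.16),
        10: (107.95, 91.69, 65.81, 65.90, 79.24, 56.79),
        20: (108.60, 91.89, 71.77, 70.44, 72.52, 65.60),
        40: (107.65, 93.33, 72.92, 71.78, 76.66, 79.02),
        60: (107.80, 94.66, 73.57, 70.86, 76.84, 71.53),
        80: (107.03, 94.16, 72.40, 70.76, 77.06, 71.47),
        100: (106.92, 94.40, 72.97, 70.94, 75.35, 68.91),
        120: (106.70, 94.94, 73.44, 71.06, 74.39, 67.80),
    },
    16: {
        5: (110.31, 103.77, 75.90, 81.12, 59.25, 43.66),
        10: (110.49, 100.87, 77.71, 80.73, 67.05, 35.59),
        20: (108.68, 95.65, 77.63, 79.50, 60.86, 66.15),
        40: (104.55, 97.85, 75.80, 75.59, 58.92, 65.15),
        60: (103.98, 96.69, 74.82, 74.33, 60.26, 65.82),
        80: (105.21, 97.14, 74.00, 75.02, 62.69, 70.83),
        100: (105.83, 96.80, 73.98, 76.75, 65.52, 74.21),
        120: (106.57, 97.53, 75.37, 76.64, 63.44, 75.91),
    },
    8: {
        5: (89.75, 89.79, 74.99, 71.09, 48.65, 98.87),
        10: (94.57, 96.78, 72.29, 68.26, 62.37, 65.46),
        20: (101.43, 92.18, 78.06, 72.69, 84.84, 92.74),
        40: (104.44, 94.10, 77.68, 70.95, 81.08, 56.57),
        60: (105.14, 94.96, 74.50, 71.64, 70.88, 53.06),
        80: (104.39, 94.64, 73.74, 67.25, 78.64, 57.59),
        100: (103.85, 96.58, 72.37, 72.04, 78.16, 54.77),
        120: (103.58, 96.65, 73.31, 70.98, 73.14, 54.67),
    },
    4: {
        5: (75.02, 65.68, 60.85, 54.83, 3.72, 20.36),
        10: (91.33, 76.63, 72.05, 44.15, 26.79, 18.01),
        20: (97.88, 91.30, 69.08, 65.61, 49.50, 93.46),
        40: (102.02, 92.37, 74.92, 65.15, 29.80, 55.07),
        60: (102.09, 96.05, 71.97, 74.78, 40.34, 78.31),
        80: (103.36, 97.70, 71.71, 79.94, 46.03, 77.28),
        100: (103.17, 95.81, 74.64, 77.40, 43.13, 73.95),
        120: (102.89, 96.64, 75.93, 74.79, 53.82, 67.59),
    },
}
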