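"""Bundled scale definition for the 23-item Burnout Assessment Tool (BAT).

The BAT is a self-report burnout questionnaire with four subscales —
exhaustion (EX, 8 items), mental distance (MD, 5 items), cognitive
impairment (CI, 5 items) and emotional impairment (EI, 5 items) — each item
scored on five ordered frequency categories (1 = never .. 5 = always).

``BAT_THRESHOLDS`` holds a published partial-credit calibration of the
Swedish BAT on a large occupational cohort with rather low burnout levels;
it drives the default synthetic-data generator so that simulated response
distributions (strong floor, rarely used top categories, huge threshold
standard errors for the top EI categories) resemble real survey data.
"""

from __future__ import annotations

BAT_MIN_CODE = 1
BAT_MAX_CODE = 5

BAT_SUBSCALES: dict[str, list[str]] = {
    "EX": [f"EX{i}" for i in range(1, 9)],
    "MD": [f"MD{i}" for i in range(1, 6)],
    "CI": [f"CI{i}" for i in range(1, 6)],
    "EI": [f"EI{i}" for i in range(1, 6)],
}

BAT_ITEMS: list[str] = [i for items in BAT_SUBSCALES.values() for i in items]

# Four threshold locations (logits) per item, categories 1..5.
# CI5 has reversed thresholds 3 and 4 in this calibration.
BAT_THRESHOLDS: dict[str, tuple[float, float, float, float]] = {
    "EX1": (-4.61, -2.21, -0.59, 2.20),
    "EX2": (-5.32, -3.05, -1.36, 0.75),
    "EX3": (-5.00, -2.69, -0.53, 1.00),
    "EX4": (-3.63, -1.62, 0.21, 2.67),
    "EX5": (-4.59, -2.25, -0.34, 1.18),
    "EX6": (-2.89, -0.84, 0.69, 3.24),
    "EX7": (-3.34, -1.59, -0.14, 1.62),
    "EX8": (-5.22, -2.83, -1.13, 0.95),
    "MD1": (-3.77, -1.24, 0.24, 1.91),
    "MD2": (-2.51, -0.75, 0.56, 2.35),
    "MD3": (-1.28, 0.23, 1.07, 3.76),
    "MD4": (-1.12, 0.04, 1.04, 1.86),
    "MD5": (-0.84, -0.02, 1.04, 3.00),
    "CI1": (-3.91, -0.89, 1.62, 3.08),
    "CI2": (-3.61, -0.92, 1.77, 4.23),
    "CI3": (-3.79, -1.07, 0.92, 3.39),
    "CI4": (-3.81, -0.75, 1.41, 4.43),
    "CI5": (-2.65, 0.95, 3.71, 1.99),
    "EI1": (-2.22, 0.58, 3.46, 5.85),
    "EI2": (-1.57, 0.10, 1.79, 2.82),
    "EI3": (-3.02, -0.78, 1.03, 7.68),
    "EI4": (-1.34, 0.37, 1.42, 6.96),
    "EI5": (-1.86, 0.24, 1.92, 6.19),
}

# Person distribution of the same calibration (logits).
BAT_PERSON_MEAN = -0.95
BAT_PERSON_SD = 0.63

# Average latent correlation between the four subscales in that cohort.
BAT_LATENT_CORRELATION = 0.61
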