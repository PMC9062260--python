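"""Published validation values for the four-ring DMI scanner model.

Scatter fractions and prompt-coincidence counts from the original
validation study of this scanner model (full-statistics Monte Carlo
simulations of 10-minute acquisitions compared with measurements on the
clinical system), used for regression comparison of desk-scale runs.
Set-ups: NEMA-B / NEMA = NEMA IQ phantom with / without background
activity; CYL-B / CYL = Data Spectrum phantom with / without background.
"""

PUBLISHED_SCATTER_FRACTION_PCT = {
    # setup: (simulated, measured)
    "NEMA-B": (37.3, 38.5),
    "NEMA": (27.5, 27.6),
    "CYL-B": (33.6, 35.0),
    "CYL": (29.7, 31.2),
}

PUBLISHED_PROMPTS = {
    "NEMA-B": (2.6e8, 2.4e8),
    "NEMA": (1.6e7, 1.6e7),
    "CYL-B": (1.3e8, 1.2e8),
    "CYL": (2.2e6, 2.3e6),
}

#: headline image-quality values for the simulated NEMA-B reconstruction
PUBLISHED_CRC_PCT = {"37": 81.0, "10": 40.0}
PUBLISHED_LUNG_ERROR_PCT = 4.0


def max_sf_gap_pp():
    """Largest |measured - simulated| scatter-fraction gap (percentage
    points) across the four set-ups."""
    return max(abs(m - s) for s, m in PUBLISHED_SCATTER_FRACTION_PCT.values())
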