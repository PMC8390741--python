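"""Unit conventions and conversion constants.

Canonical internal units throughout the package: activity in MBq, volume in
cc, time in hours post-injection, absorbed dose in mGy.  The regression
models are trained on concentrations in mCi/cc (the unit the packaged
coefficient sets were fitted in); the MBq→mCi conversion happens exactly
once, at the regression boundary, to rule out silent double conversion.
"""

MBQ_PER_MCI = 37.0
SECONDS_PER_HOUR = 3600.0
MGY_PER_GY = 1000.0

#: grams per cc assumed when converting a VOI volume to a mass (soft tissue).
DEFAULT_TISSUE_DENSITY_G_PER_CC = 1.0


def mbq_per_cc_to_mci_per_cc(conc):
    """Convert an activity concentration from MBq/cc to mCi/cc."""
    return conc / MBQ_PER_MCI


def volume_cc_to_mass_kg(volume_cc, density_g_per_cc=DEFAULT_TISSUE_DENSITY_G_PER_CC):
    """VOI volume (cc) to mass (kg) at the given tissue density (g/cc)."""
    return volume_cc * density_g_per_cc / 1000.0
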