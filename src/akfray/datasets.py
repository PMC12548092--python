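"""Published catalytic parameters of E. coli adenylate kinase variants.

Steady-state parameters (coupled ATPase assay, technical triplicates) for
wild-type AKeco and the helix-terminus variants, as reported: kcat (s^-1),
K_M (uM) and the specificity constant kcat/K_M (uM^-1 s^-1), each with the
fitted standard error. These are inputs to the ratio analysis, not values
this package fits.
"""

from __future__ import annotations

from .kinetics import MMFit

AKECO_CATALYTIC_TABLE: dict[str, MMFit] = {
    "wild_type": MMFit(kcat=360.0, kcat_err=11.0, km=110.0, km_err=9.0),
    "K47A": MMFit(kcat=464.0, kcat_err=3.0, km=116.0, km_err=8.0),
    "E114A": MMFit(kcat=254.0, kcat_err=4.0, km=36.0, km_err=7.0),
}

# specificity constants as printed alongside the table (uM^-1 s^-1)
AKECO_PRINTED_SPECIFICITY = {
    "wild_type": (3.3, 0.3),
    "K47A": (4.0, 0.3),
    "E114A": (7.1, 1.3),
}
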