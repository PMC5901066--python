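"""Reference parameter sets for the three Mn(II)-loaded SOD proteins.

Literature zero-field parameters from 94 GHz field-swept echo EPR of
S. aureus Mn(Mn)SOD and Mn(cam)SOD and E. coli Mn(Fe)SOD, and the fitted
single-quantum 1H ELDOR-NMR Gaussian components at the D_zz,-5/2 field
position.  These serve as simulation inputs and as round-trip ground truth
for the extraction pipeline.
"""

from .endor_eldor import SpectralComponent
from .spin_core import SpectrometerSettings, ZFSParameters

W_BAND = SpectrometerSettings(nu_obs_ghz=94.0, g=2.0023, temperature_k=6.0)

ZFS_PRESETS = {
    "Mn(Mn)SOD": ZFSParameters(-10.60, 0.63),
    "Mn(cam)SOD": ZFSParameters(-10.66, 0.43),
    "Mn(Fe)SOD": ZFSParameters(-10.46, 0.33),
}

#: The |D| + E threshold separating active Mn-loaded SODs (above ~11.5 GHz)
#: from catalytically inactive Mn(Fe)SOD (below this bound).
INACTIVE_D_PLUS_E_BOUND_GHZ = 10.9

#: SQ 1H components at the D_zz,-5/2 edge: A_eff (FWHM) = 5.3 (2.2) and
#: 6.4 (2.2) MHz, contributing through the M_s = -5/2 and -3/2 manifolds.
SQ_PROTON_COMPONENTS = [
    SpectralComponent(5.3, 2.2, manifolds=(-2.5, -1.5)),
    SpectralComponent(6.4, 2.2, manifolds=(-2.5, -1.5)),
]

#: The third, weaker component required only for Mn(Fe)SOD.
MNFE_EXTRA_COMPONENT = SpectralComponent(2.6, 2.2, manifolds=(-2.5, -1.5))

#: His171 ring-proton effective couplings (MHz) along D_zz in the two
#: structural models: ring dihedral -60 deg (global-optimum-like, Fe-specific
#: behaviour) vs +30 deg (crystal-dihedral-constrained, Mn-specific).
RING_AEFF_MODELS = {
    "GO": {"H2_His171": -1.8, "H5_His171": -0.5},
    "CD_NH": {"H2_His171": -0.9, "H5_His171": 1.6},
}
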