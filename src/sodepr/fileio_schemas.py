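"""Documented key sets for the package's YAML file formats.

Spin-system file (YAML mapping)::

    nu_obs_GHz: 94.0        # microwave observation frequency
    g: 2.0023               # isotropic electronic g-value
    temperature_K: 6.0
    D_GHz: -10.60           # axial zero-field parameter (signed)
    E_GHz: 0.63             # rhombic zero-field parameter (0 <= E <= |D|/3)
    nuclei: []              # optional inline tensor records (see below)

Tensor-set file (YAML mapping)::

    source: dft_GO | dft_CD_NH | dft_CD_OH | synthetic | file
    nuclei:
      - id: H_w             # unique identity
        isotope: 1H         # registry name (1H, 14N)
        a_iso_MHz: -0.45
        t_principal_MHz: [-3.3, -3.3, 6.6]   # traceless dipolar values
        euler_deg: [0, 17, 0]                # ZYZ intrinsic, principal->molecular
        quadrupole_MHz: [-0.4, -0.4, 0.8]    # optional, I >= 1 only
        quad_euler_deg: [0, 0, 0]            # optional

Unknown keys are ignored with a warning so files stay forward compatible.
"""

SPIN_SYSTEM_KEYS = {
    "nu_obs_GHz",
    "g",
    "temperature_K",
    "D_GHz",
    "E_GHz",
    "nuclei",
}

TENSOR_KEYS = {
    "id",
    "isotope",
    "a_iso_MHz",
    "t_principal_MHz",
    "euler_deg",
    "quadrupole_MHz",
    "quad_euler_deg",
}
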