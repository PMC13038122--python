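"""Physical defaults for the L2/3 -> L5 motor-cortex example circuit.

Relative subtype frequencies, synapse constants, presynaptic/postsynaptic
cell-count ratios and cortical-column geometry are shipped here so that the
published circuit configuration is one import away.  All depths are in
micrometres; cortical depth z runs from 0 at the CSF boundary to
-COLUMN_DEPTH_UM at the white-matter boundary, soma-relative depth z' is
positive from the soma toward the dendrites (toward the pia).
"""

from __future__ import annotations

#: Relative frequency of inhibitory basket-cell subtypes (morphological type x
#: electrical type) within their layer, from a morphology/e-type resolved
#: survey of cortical microcircuitry.  Normalized before averaging.
BASKET_SUBTYPE_WEIGHTS: dict[str, float] = {
    "LBC_dNAC": 0.245,
    "LBC_cSTUT": 0.165,
    "LBC_cACint": 0.117,
    "NBC_dNAC": 0.191,
    "NBC_cACint": 0.053,
    "SBC_bNAC": 0.112,
    "SBC_cACint": 0.117,
}

#: Presynaptic-to-postsynaptic cell-count ratios used to scale population
#: delay kernels: L2/3 pyramidal cells per L5 pyramidal cell, and L2/3 basket
#: cells per L5 pyramidal cell.
COUNT_RATIO_EXCITATORY = 5.04
COUNT_RATIO_INHIBITORY = 0.40

#: Total cortical column depth (um) after rescaling to human M1.
COLUMN_DEPTH_UM = 2700.0

#: L2/3 band in cortical depth coordinates (um), normalized depths 0.1-0.29.
L23_BAND_UM = (-783.0, -270.0)

#: Synapse double-exponential constants per receptor:
#: (tau_rise ms, tau_fall ms, E_reversal mV, g_peak uS).
SYNAPSE_TABLE: dict[str, tuple[float, float, float, float]] = {
    "AMPA": (0.05, 5.3, 0.0, 0.1),
    "NMDA": (15.0, 150.0, 0.0, 0.03),
    "GABAa": (0.07, 18.2, -80.0, 0.5),
    "GABAb": (3.5, 260.9, -93.0, 0.5),
}

#: Extracellular magnesium concentration (mmol) for the NMDA gate.
MG_MMOL = 1.0

#: Uniform parameter bounds of the six-dimensional surrogate input
#: xi = (theta, rel_gradient, intensity, f_NMDA, f_GABAa, f_ex).
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "theta": (0.0, 180.0),          # deg, polar angle vs somatodendritic axis
    "rel_gradient": (-20.0, 20.0),  # %/mm along z'
    "intensity": (100.0, 400.0),    # V/m
    "f_nmda": (0.25, 0.75),         # NMDA fraction of excitatory synapses
    "f_gabaa": (0.9, 1.0),          # GABAa fraction of inhibitory synapses
    "f_ex": (0.2, 0.8),             # excitatory fraction of all synapses
}

PARAM_NAMES = tuple(PARAM_BOUNDS)

#: Index of the field-gradient parameter within PARAM_NAMES; its univariate
#: polynomial order in the surrogate basis is capped lower than the others.
GRADIENT_PARAM_INDEX = 1

#: Azimuthal rotations averaged per morphology (6 degree steps, 0..354).
N_PHI_ROTATIONS = 60

#: Histogram bin sizes for the axonal stage.
AXONAL_DZ_UM = 100.0
AXONAL_DT_MS = 0.1

#: Depth bin size for the dendritic (synapto-dendritic) stage.
DENDRITIC_DZ_UM = 50.0

#: Soma-relative depth range covered by cell delay kernels (um).
ZPRIME_RANGE_UM = (-2000.0, 500.0)

#: Averaging sample counts for the mean dendritic current.
N_DEPTH_SAMPLES = 25
N_POSTSYNAPTIC_MORPHOLOGIES = 30
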