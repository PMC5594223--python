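"""Canonical label vocabularies shared across the package.

The electrode montage, the frequency bands, the connectivity-measure names
and the perfusion-region list are closed vocabularies: every module that
builds or consumes feature vectors refers to these, never to ad-hoc strings.
"""

from __future__ import annotations

# 10-20 electrodes retained for analysis, in fixed order.
EEG_CHANNELS: tuple[str, ...] = (
    "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
)

DEFAULT_SFREQ = 200.0     # Hz
DEFAULT_DURATION = 180.0  # seconds of artifact-free wakefulness per subject

# Analysis grid: 1-Hz steps from 2 to 80 Hz inclusive.
FREQ_GRID_HZ: tuple[int, ...] = tuple(range(2, 81))

# Classical frequency bands (inclusive integer ranges on the grid).
BANDS: dict[str, tuple[int, int]] = {
    "delta": (2, 4),
    "theta": (5, 7),
    "alpha": (8, 13),
    "beta": (14, 30),
    "gamma": (31, 80),
}
BAND_ORDER: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")

# The 14 frequency-domain interaction measures, in report order.
MEASURES: tuple[str, ...] = (
    "S", "DC", "h", "Af", "COH", "iCOH", "pCOH",
    "PDC", "PDCF", "GPDC", "DTF", "dDTF", "ffDTF", "GGC",
)

GRAPH_METRICS: tuple[str, ...] = (
    "assortativity", "efficiency", "clustering", "modularity", "transitivity",
)

# Bilateral perfusion regions; the stored vector interleaves left/right per
# region, followed by the two midline/subcortical entries (46 values total).
_BILATERAL_REGIONS: tuple[str, ...] = (
    "cerebellar_cortex",
    "cerebellar_white_matter",
    "nucleus_lentiformis",
    "nucleus_caudatus",
    "thalamus",
    "sensorimotor_cortex",
    "occipital_cortex",
    "superior_parietal_lobule",
    "anterior_dorsal_frontal",
    "posterior_dorsal_frontal",
    "anterior_orbital_frontal",
    "posterior_orbital_cortex",
    "parietotemporal_cortex",
    "medial_temporal_lobe",
    "lateral_temporal_lobe",
    "posterior_temporal_lobe",
    "temporal_pole",
    "insular_cortex",
    "anterior_cingulate",
    "posterior_cingulate",
    "anterior_subcortical",
    "posterior_subcortical",
)

SPECT_REGIONS: tuple[str, ...] = tuple(
    f"{region}_{side}" for region in _BILATERAL_REGIONS for side in ("L", "R")
) + ("pons_midbrain", "other_subcortical")

N_SPECT_REGIONS = len(SPECT_REGIONS)
assert N_SPECT_REGIONS == 46

# Diagnostic group labels.
GROUPS: tuple[str, ...] = ("aSCC", "aMCI", "AD", "DCI")
GROUP_SIZES: dict[str, int] = {"aSCC": 41, "aMCI": 71, "AD": 39, "DCI": 69}

# Feature-vector scenarios.
SCENARIOS: tuple[str, ...] = (
    "eeg_single",
    "spect",
    "eeg_single+spect",
    "eeg_merged",
    "eeg_merged+spect",
    "eeg_graph",
    "eeg_graph+spect",
)
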