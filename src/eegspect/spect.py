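"""SPECT regional perfusion profiles (cerebellar count ratios).

A profile is a vector of 46 named region-to-cerebellum perfusion ratios:
22 bilateral regions stored left/right interleaved, then the
pons+midbrain region and the remaining-subcortical region.  Region names
are a closed vocabulary; unknown names are rejected at parse time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .constants import N_SPECT_REGIONS, SPECT_REGIONS

__all__ = ["SPECTProfile", "normalize_counts", "read_spect_csv", "write_spect_csv"]

# ratios stored to 6 decimal places in CSV round-trips
CSV_FLOAT_FORMAT = "%.6f"


@dataclass
class SPECTProfile:
    """Named 46-region perfusion ratio vector."""

    values: NDArray[np.float64]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_SPECT_REGIONS,):
            raise ValueError(
                f"SPECT profile must have exactly {N_SPECT_REGIONS} values, "
                f"got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SPECT profile contains non-finite values")
        if np.any(self.values <= 0):
            raise ValueError("SPECT ratios must be positive")

    @property
    def regions(self) -> tuple[str, ...]:
        return SPECT_REGIONS

    def __getitem__(self, region: str) -> float:
        try:
            return float(self.values[SPECT_REGIONS.index(region)])
        except ValueError as exc:
            raise KeyError(f"unknown SPECT region {region!r}") from exc

    @classmethod
    def from_mapping(cls, mapping: dict[str, float]) -> "SPECTProfile":
        unknown = set(mapping) - set(SPECT_REGIONS)
        if unknown:
            raise ValueError(f"unknown SPECT regions: {sorted(unknown)}")
        missing = set(SPECT_REGIONS) - set(mapping)
        if missing:
            raise ValueError(f"missing SPECT regions: {sorted(missing)}")
        return cls(np.array([mapping[r] for r in SPECT_REGIONS], dtype=float))


def normalize_counts(
    region_counts: NDArray[np.float64], cerebellar_count: float
) -> SPECTProfile:
    """Count-normalize regional count rates by the cerebellar count rate.

    ratio_i = count_i / cerebellar_count.  Provided for real-data
    ingestion; the synthetic cohort generates directly in ratio space.
    """
    if cerebellar_count <= 0:
        raise ValueError("cerebellar reference count must be positive")
    counts = np.asarray(region_counts, dtype=float)
    if counts.shape != (N_SPECT_REGIONS,):
        raise ValueError(f"expected {N_SPECT_REGIONS} region counts")
    return SPECTProfile(counts / cerebellar_count)


def write_spect_csv(path, profiles: dict[str, tuple[str, SPECTProfile]]) -> None:
    """Write profiles as CSV: subject_id, group, then the 46 region columns.

    ``profiles`` maps subject_id -> (group_label, profile).
    """
    rows = []
    for sid, (group, prof) in profiles.items():
        row = {"subject_id": sid, "group": group}
        row.update(dict(zip(SPECT_REGIONS, prof.values)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def read_spect_csv(path) -> dict[str, tuple[str, SPECTProfile]]:
    """Read a profile CSV written by :func:`write_spect_csv`; strict header."""
    df = pd.read_csv(path)
    expected = ["subject_id", "group", *SPECT_REGIONS]
    if list(df.columns) != expected:
        unknown = [c for c in df.columns if c not in expected]
        missing = [c for c in expected if c not in df.columns]
        raise ValueError(
            f"SPECT CSV header mismatch (unknown={unknown}, missing={missing}, "
            "or wrong order)"
        )
    out = {}
    for _, row in df.iterrows():
        prof = SPECTProfile(row[list(SPECT_REGIONS)].to_numpy(dtype=float))
        out[str(row["subject_id"])] = (str(row["group"]), prof)
    return out
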