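"""Feature vectors with per-feature provenance, and the seven scenarios.

Every feature carries a :class:`FeatureDescriptor` naming its origin —
EEG (measure, band, source electrode, sink electrode), GRAPH (measure,
band, metric) or SPECT (region) — so that selected feature subsets stay
interpretable.

Scenarios
---------
eeg_single           all band-averaged values of one EEG measure
                     (17 x 17 x 5 = 1445 features for 17 channels)
spect                the 46 perfusion ratios
eeg_single+spect     concatenation of the two above
eeg_merged           concatenation of the *optimized* (post-selection)
                     per-measure EEG vectors
eeg_merged+spect     eeg_merged plus the optimized SPECT vector
eeg_graph            5 global graph metrics per measure and band (350)
eeg_graph+spect      eeg_graph plus the 46 perfusion ratios
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

from .connectivity import BandedConnectivity, compute_all
from .constants import (
    BAND_ORDER,
    GRAPH_METRICS,
    MEASURES,
    SCENARIOS,
    SPECT_REGIONS,
)
from .graphs import GraphSummary, connectivity_to_graph, graph_summary
from .mvar import MVARModel
from .spect import SPECTProfile

__all__ = [
    "FeatureDescriptor",
    "FeatureVector",
    "SubjectFeatures",
    "build_initial_vector",
    "merge_optimized",
    "spect_vector",
    "stack_vectors",
]


@dataclass(frozen=True)
class FeatureDescriptor:
    """Provenance of one scalar feature; uniquely identifies it."""

    modality: str  # EEG | GRAPH | SPECT
    measure: str | None = None
    band: str | None = None
    source: str | None = None
    sink: str | None = None
    metric: str | None = None
    region: str | None = None

    def __post_init__(self) -> None:
        if self.modality == "EEG":
            ok = (self.measure and self.band and self.source and self.sink
                  and not self.metric and not self.region)
        elif self.modality == "GRAPH":
            ok = (self.measure and self.band and self.metric
                  and not self.source and not self.sink and not self.region)
        elif self.modality == "SPECT":
            ok = (self.region and not self.measure and not self.band
                  and not self.source and not self.sink and not self.metric)
        else:
            ok = False
        if not ok:
            raise ValueError(f"inconsistent descriptor fields: {self}")

    def name(self) -> str:
        if self.modality == "EEG":
            return f"EEG:{self.measure}:{self.band}:{self.source}->{self.sink}"
        if self.modality == "GRAPH":
            return f"GRAPH:{self.measure}:{self.band}:{self.metric}"
        return f"SPECT:{self.region}"


@dataclass
class FeatureVector:
    """A flat numeric vector with parallel descriptors for one subject."""

    values: NDArray[np.float64]
    descriptors: list[FeatureDescriptor]
    scenario: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.descriptors):
            raise ValueError("values and descriptors must have equal length")
        if len(set(self.descriptors)) != len(self.descriptors):
            raise ValueError("duplicate feature descriptors")

    def __len__(self) -> int:
        return len(self.values)

    def subset(self, indices) -> "FeatureVector":
        return FeatureVector(
            self.values[list(indices)],
            [self.descriptors[i] for i in indices],
            self.scenario,
        )


def eeg_descriptors(measure: str, channels: list[str]) -> list[FeatureDescriptor]:
    return [
        FeatureDescriptor("EEG", measure=measure, band=band, source=src, sink=snk)
        for band in BAND_ORDER
        for snk in channels
        for src in channels
    ]


def graph_descriptors() -> list[FeatureDescriptor]:
    return [
        FeatureDescriptor("GRAPH", measure=m, band=b, metric=metric)
        for m in MEASURES
        for b in BAND_ORDER
        for metric in GRAPH_METRICS
    ]


def spect_descriptors() -> list[FeatureDescriptor]:
    return [FeatureDescriptor("SPECT", region=r) for r in SPECT_REGIONS]


def spect_vector(profile: SPECTProfile) -> FeatureVector:
    """The 46-region perfusion profile as a provenance-tagged fragment."""
    return FeatureVector(profile.values.copy(), spect_descriptors(), "spect")


@dataclass
class SubjectFeatures:
    """All computed per-subject features downstream of the raw data.

    ``eeg`` maps measure name to its band-averaged connectivity; ``graph``
    maps (measure, band) to the graph summary; ``spect`` is the perfusion
    profile.  Channels must be consistent across measures.
    """

    channels: list[str]
    eeg: dict[str, BandedConnectivity] = field(default_factory=dict)
    graph: dict[tuple[str, str], GraphSummary] = field(default_factory=dict)
    spect: SPECTProfile | None = None

    @classmethod
    def from_model(
        cls,
        model: MVARModel,
        spect: SPECTProfile | None = None,
        with_graph: bool = True,
    ) -> "SubjectFeatures":
        """Derive all features from a fitted MVAR model (+ optional SPECT)."""
        channels = list(
            model.channel_labels
            or [f"ch{i}" for i in range(model.n_channels)]
        )
        banded = compute_all(model)
        graph: dict[tuple[str, str], GraphSummary] = {}
        if with_graph:
            for m, bc in banded.items():
                for band, mat in bc.bands.items():
                    W = connectivity_to_graph(mat)
                    graph[(m, band)] = graph_summary(W, measure=m, band=band)
        return cls(channels=channels, eeg=banded, graph=graph, spect=spect)

    # ---- per-modality fragments ------------------------------------------

    def eeg_fragment(self, measure: str) -> FeatureVector:
        if measure not in self.eeg:
            raise ValueError(f"EEG measure {measure!r} not available")
        bc = self.eeg[measure]
        vals = np.concatenate([bc.bands[b].ravel() for b in BAND_ORDER])
        return FeatureVector(
            vals, eeg_descriptors(measure, self.channels), "eeg_single"
        )

    def graph_fragment(self) -> FeatureVector:
        if not self.graph:
            raise ValueError("graph features not computed")
        vals = []
        for m in MEASURES:
            for b in BAND_ORDER:
                gs = self.graph[(m, b)]
                fv = gs.feature_values()
                vals.extend(fv[metric] for metric in GRAPH_METRICS)
        return FeatureVector(np.asarray(vals), graph_descriptors(), "eeg_graph")

    def spect_fragment(self) -> FeatureVector:
        if self.spect is None:
            raise ValueError("SPECT profile not available")
        return spect_vector(self.spect)


def _concat(parts: list[FeatureVector], scenario: str) -> FeatureVector:
    values = np.concatenate([p.values for p in parts]) if parts else np.empty(0)
    descs = [d for p in parts for d in p.descriptors]
    return FeatureVector(values, descs, scenario)


def build_initial_vector(
    scenario: str,
    subject: SubjectFeatures,
    measure: str | None = None,
) -> FeatureVector:
    """Assemble the initial (pre-selection) feature vector of a scenario.

    ``measure`` is required for the per-measure scenarios (eeg_single and
    eeg_single+spect).  The merged scenarios are built from optimized
    per-measure vectors via :func:`merge_optimized`, not here.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if scenario in ("eeg_merged", "eeg_merged+spect"):
        raise ValueError(f"{scenario} is assembled via merge_optimized")
    if scenario == "eeg_single":
        if measure is None:
            raise ValueError("eeg_single requires a measure")
        return subject.eeg_fragment(measure)
    if scenario == "spect":
        return subject.spect_fragment()
    if scenario == "eeg_single+spect":
        if measure is None:
            raise ValueError("eeg_single+spect requires a measure")
        return _concat(
            [subject.eeg_fragment(measure), subject.spect_fragment()], scenario
        )
    if scenario == "eeg_graph":
        fv = subject.graph_fragment()
        fv.scenario = scenario
        return fv
    # eeg_graph+spect
    return _concat([subject.graph_fragment(), subject.spect_fragment()], scenario)


def merge_optimized(
    selected: list[FeatureVector], scenario: str = "eeg_merged"
) -> FeatureVector:
    """Deduplicated concatenation of optimized (post-selection) vectors.

    The merged vector becomes the initial vector for a fresh selection
    run.  A descriptor appearing in several inputs is kept once (first
    occurrence).
    """
    seen: set[FeatureDescriptor] = set()
    values: list[float] = []
    descs: list[FeatureDescriptor] = []
    for fv in selected:
        for v, d in zip(fv.values, fv.descriptors):
            if d not in seen:
                seen.add(d)
                values.append(float(v))
                descs.append(d)
    return FeatureVector(np.asarray(values), descs, scenario)


def stack_vectors(vectors: list[FeatureVector]):
    """Stack per-subject vectors of one scenario into an (n, k) matrix.

    All vectors must share identical descriptor lists; returns
    ``(X, descriptors)``.
    """
    if not vectors:
        raise ValueError("no feature vectors to stack")
    ref = vectors[0].descriptors
    for fv in vectors[1:]:
        if fv.descriptors != ref:
            raise ValueError("feature vectors have inconsistent descriptors")
    X = np.vstack([fv.values for fv in vectors])
    return X, list(ref)
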