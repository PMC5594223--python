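"""Synthetic cohort generation with the study's data structure.

Each diagnostic group is defined by a stable MVAR template (the EEG
generator) and per-region perfusion means (the SPECT generator).  A
subject is a jittered realization of the group template plus an
independent Gaussian perfusion draw, so every downstream stage — MVAR
fitting, connectivity, graph reduction, feature assembly, nested
classification — can be exercised and validated without patient data.

The EEG generative model is deliberately an MVAR process (the same family
the analysis fits), which makes parameter recovery an exact oracle.
Per-subject variability is additive Gaussian jitter on the template
coefficients with standard deviation proportional to each entry's
magnitude (zero entries stay zero, preserving the directed coupling
structure); jittered models are rejection-sampled for stability with at
most 100 retries.  SPECT draws are truncated at zero by redraw, keeping
small-sd means unbiased.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.typing import NDArray

from .constants import (
    DEFAULT_DURATION,
    DEFAULT_SFREQ,
    EEG_CHANNELS,
    GROUP_SIZES,
    N_SPECT_REGIONS,
    SPECT_REGIONS,
)
from .edf import write_edf
from .mvar import MVARModel
from .spect import SPECTProfile, write_spect_csv

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "Subject",
    "generate_subject_eeg",
    "generate_subject_spect",
    "generate_cohort",
    "make_template",
    "study_cohort_spec",
    "reduced_cohort_spec",
    "write_cohort",
]

MAX_STABILITY_RETRIES = 100


@dataclass
class GroupSpec:
    """One diagnostic group: size, EEG template, perfusion distribution."""

    name: str
    n_subjects: int
    mvar_template: MVARModel
    spect_means: NDArray[np.float64]
    spect_sd: NDArray[np.float64]
    subject_jitter: float = 0.05

    def __post_init__(self) -> None:
        self.spect_means = np.asarray(self.spect_means, dtype=float)
        self.spect_sd = np.asarray(self.spect_sd, dtype=float)
        if self.n_subjects < 2:
            raise ValueError(f"group {self.name}: need at least 2 subjects")
        if not self.mvar_template.is_stable():
            raise ValueError(
                f"group {self.name}: MVAR template unstable (spectral radius "
                f"{self.mvar_template.spectral_radius():.4f})"
            )
        if self.spect_means.shape != (N_SPECT_REGIONS,):
            raise ValueError(f"group {self.name}: spect_means must have 46 entries")
        if self.spect_sd.shape != (N_SPECT_REGIONS,) or np.any(self.spect_sd < 0):
            raise ValueError(f"group {self.name}: spect_sd must be 46 non-negatives")
        if self.subject_jitter < 0:
            raise ValueError("subject_jitter must be non-negative")


@dataclass
class CohortSpec:
    """A full synthetic cohort: groups sharing acquisition parameters."""

    groups: list[GroupSpec]
    sampling_rate: float = DEFAULT_SFREQ
    duration: float = DEFAULT_DURATION
    n_channels: int = 17
    seed: int = 0

    def __post_init__(self) -> None:
        for g in self.groups:
            if g.mvar_template.n_channels != self.n_channels:
                raise ValueError(
                    f"group {g.name}: template has {g.mvar_template.n_channels} "
                    f"channels, cohort expects {self.n_channels}"
                )
            if g.mvar_template.sfreq != self.sampling_rate:
                raise ValueError(f"group {g.name}: sampling rate mismatch")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.duration))

    def to_json(self) -> str:
        return json.dumps(
            {
                "sampling_rate": self.sampling_rate,
                "duration": self.duration,
                "n_channels": self.n_channels,
                "seed": self.seed,
                "groups": [
                    {
                        "name": g.name,
                        "n_subjects": g.n_subjects,
                        "mvar_template": json.loads(g.mvar_template.to_json()),
                        "spect_means": g.spect_means.tolist(),
                        "spect_sd": g.spect_sd.tolist(),
                        "subject_jitter": g.subject_jitter,
                    }
                    for g in self.groups
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        d = json.loads(text)
        groups = [
            GroupSpec(
                name=g["name"],
                n_subjects=g["n_subjects"],
                mvar_template=MVARModel.from_json(json.dumps(g["mvar_template"])),
                spect_means=np.asarray(g["spect_means"]),
                spect_sd=np.asarray(g["spect_sd"]),
                subject_jitter=g["subject_jitter"],
            )
            for g in d["groups"]
        ]
        return cls(
            groups=groups,
            sampling_rate=d["sampling_rate"],
            duration=d["duration"],
            n_channels=d["n_channels"],
            seed=d["seed"],
        )


@dataclass
class Subject:
    id: str
    group: str
    eeg: NDArray[np.float64]
    spect: SPECTProfile


def _jittered_template(
    template: MVARModel, jitter: float, rng: np.random.Generator
) -> MVARModel:
    if jitter == 0:
        return template
    for _ in range(MAX_STABILITY_RETRIES):
        noise = rng.standard_normal(template.coefficients.shape)
        coeffs = template.coefficients * (1.0 + jitter * noise)
        cand = MVARModel(
            coeffs,
            template.resid_cov,
            sfreq=template.sfreq,
            channel_labels=template.channel_labels,
        )
        if cand.is_stable():
            return cand
    raise RuntimeError(
        f"no stable jittered model within {MAX_STABILITY_RETRIES} retries "
        f"(jitter={jitter})"
    )


def generate_subject_eeg(
    template: MVARModel,
    jitter: float,
    n_samples: int,
    seed: int | np.random.Generator,
) -> NDArray[np.float64]:
    """Simulate one subject's EEG from a (jittered) group template.

    A burn-in of max(1000, 10*order) samples is discarded.  Identical
    seeds give bit-identical output.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if not template.is_stable():
        raise ValueError("unstable MVAR template rejected")
    if n_samples <= 10 * template.order:
        raise ValueError("n_samples must exceed 10x the template order")
    model = _jittered_template(template, jitter, rng)
    return model.simulate(n_samples, rng)


def generate_subject_spect(
    means: NDArray[np.float64],
    sd: NDArray[np.float64],
    seed: int | np.random.Generator,
) -> SPECTProfile:
    """Independent Gaussian perfusion draws, truncated at 0 by redraw."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    means = np.asarray(means, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if means.shape != (N_SPECT_REGIONS,) or sd.shape != (N_SPECT_REGIONS,):
        raise ValueError(f"means and sd must have length {N_SPECT_REGIONS}")
    if np.any(sd < 0):
        raise ValueError("sd must be non-negative")
    values = means + sd * rng.standard_normal(N_SPECT_REGIONS)
    for _ in range(1000):
        bad = values <= 0
        if not np.any(bad):
            break
        values[bad] = means[bad] + sd[bad] * rng.standard_normal(int(bad.sum()))
    else:
        raise RuntimeError("could not draw positive perfusion ratios")
    return SPECTProfile(values)


def generate_cohort(spec: CohortSpec) -> list[Subject]:
    """Generate all subjects of a cohort, deterministically from spec.seed."""
    subjects: list[Subject] = []
    ss = np.random.SeedSequence(spec.seed)
    total = sum(g.n_subjects for g in spec.groups)
    child_seeds = ss.spawn(total)
    k = 0
    for g in spec.groups:
        for i in range(g.n_subjects):
            rng = np.random.default_rng(child_seeds[k])
            k += 1
            try:
                eeg = generate_subject_eeg(
                    g.mvar_template, g.subject_jitter, spec.n_samples, rng
                )
            except RuntimeError as exc:
                raise RuntimeError(f"group {g.name}: {exc}") from exc
            spect = generate_subject_spect(g.spect_means, g.spect_sd, rng)
            subjects.append(
                Subject(id=f"{g.name}_{i:03d}", group=g.name, eeg=eeg, spect=spect)
            )
    return subjects


# ---------------------------------------------------------------------------
# template and cohort-spec builders


def make_template(
    n_channels: int,
    sfreq: float = DEFAULT_SFREQ,
    osc_freq_hz: float = 10.0,
    damping: float = 0.92,
    couplings: dict[tuple[int, int], float] | None = None,
    coupling_lag: int = 1,
    order: int = 5,
    noise_scale: float = 1.0,
    channel_labels: list[str] | None = None,
) -> MVARModel:
    """Build a stable oscillatory MVAR template.

    Each channel carries a damped oscillation at ``osc_freq_hz`` (an AR(2)
    resonance with pole radius ``damping``); ``couplings`` adds directed
    influence entries ``{(sink, source): strength}`` at ``coupling_lag``.
    Raises if the result is unstable.
    """
    A = np.zeros((order, n_channels, n_channels))
    theta = 2 * np.pi * osc_freq_hz / sfreq
    a1 = 2 * damping * np.cos(theta)
    a2 = -(damping**2)
    A[0] += a1 * np.eye(n_channels)
    if order >= 2:
        A[1] += a2 * np.eye(n_channels)
    for (sink, source), w in (couplings or {}).items():
        if sink == source:
            raise ValueError("couplings must be off-diagonal")
        A[coupling_lag - 1][sink, source] += w
    model = MVARModel(
        A,
        (noise_scale**2) * np.eye(n_channels),
        sfreq=sfreq,
        channel_labels=channel_labels,
    )
    if not model.is_stable():
        raise ValueError(
            f"template unstable (spectral radius {model.spectral_radius():.4f}); "
            "reduce damping or coupling strengths"
        )
    return model


def _spect_means(offsets: dict[str, float] | None = None) -> NDArray[np.float64]:
    """Baseline perfusion ratios ~1.0 with named regional offsets."""
    means = np.ones(N_SPECT_REGIONS)
    for region, off in (offsets or {}).items():
        hits = [i for i, r in enumerate(SPECT_REGIONS) if r.startswith(region)]
        if not hits:
            raise ValueError(f"unknown SPECT region prefix {region!r}")
        for i in hits:
            means[i] += off
    return means


# regional hypoperfusion patterns: temporo-parietal + posterior cingulate
# deficit for the dementia-spectrum groups, mild frontal reduction for the
# depressive group.  Effect sizes are package choices (no published
# calibration exists); see docs/methods.md.
_GROUP_SPECT_OFFSETS = {
    "aSCC": {},
    "aMCI": {
        "parietotemporal_cortex": -0.06,
        "medial_temporal_lobe": -0.06,
        "posterior_cingulate": -0.04,
    },
    "AD": {
        "parietotemporal_cortex": -0.15,
        "medial_temporal_lobe": -0.12,
        "posterior_temporal_lobe": -0.10,
        "posterior_cingulate": -0.10,
    },
    "DCI": {
        "anterior_dorsal_frontal": -0.05,
        "anterior_cingulate": -0.04,
    },
}

# directed low-frequency coupling (sink, source) entries per group, added
# on top of the shared oscillatory backbone at lag 1
_GROUP_COUPLINGS = {
    "aSCC": {(1, 0): 0.10},
    "aMCI": {(1, 0): 0.10, (2, 0): 0.08},
    "AD": {(1, 0): 0.04, (3, 2): 0.10},
    "DCI": {(1, 0): 0.10, (3, 0): 0.08},
}


def study_cohort_spec(
    seed: int = 0,
    sizes: dict[str, int] | None = None,
    spect_sd: float = 0.05,
    jitter: float = 0.05,
) -> CohortSpec:
    """Cohort spec with the study's structure: 41/71/39/69 subjects,
    17 channels at 200 Hz, 3-minute segments, group-dependent coupling
    and perfusion means."""
    sizes = dict(GROUP_SIZES if sizes is None else sizes)
    groups = []
    for name, n in sizes.items():
        template = make_template(
            n_channels=len(EEG_CHANNELS),
            couplings=_GROUP_COUPLINGS.get(name, {}),
            channel_labels=list(EEG_CHANNELS),
        )
        groups.append(
            GroupSpec(
                name=name,
                n_subjects=n,
                mvar_template=template,
                spect_means=_spect_means(_GROUP_SPECT_OFFSETS.get(name, {})),
                spect_sd=np.full(N_SPECT_REGIONS, spect_sd),
                subject_jitter=jitter,
            )
        )
    return CohortSpec(groups=groups, seed=seed)


def reduced_cohort_spec(
    seed: int = 0,
    n_per_group: int = 24,
    n_channels: int = 4,
    duration: float = 15.0,
    groups: tuple[str, ...] = ("aSCC", "AD"),
    identical: bool = False,
    spect_sd: float = 0.05,
    jitter: float = 0.05,
) -> CohortSpec:
    """Small cohort for fast end-to-end runs (test profile).

    ``identical=True`` gives every group the same generating distribution
    (a null cohort); otherwise group-dependent couplings and perfusion
    offsets are injected as in the study-scale spec.
    """
    labels = [f"ch{i}" for i in range(n_channels)]
    out = []
    for name in groups:
        couplings = {} if identical else {
            (s, src): w
            for (s, src), w in _GROUP_COUPLINGS.get(name, {}).items()
            if s < n_channels and src < n_channels
        }
        offsets = {} if identical else _GROUP_SPECT_OFFSETS.get(name, {})
        template = make_template(
            n_channels=n_channels, couplings=couplings, channel_labels=labels
        )
        out.append(
            GroupSpec(
                name=name,
                n_subjects=n_per_group,
                mvar_template=template,
                spect_means=_spect_means(offsets),
                spect_sd=np.full(N_SPECT_REGIONS, spect_sd),
                subject_jitter=jitter,
            )
        )
    return CohortSpec(
        groups=out,
        sampling_rate=DEFAULT_SFREQ,
        duration=duration,
        n_channels=n_channels,
        seed=seed,
    )


def write_cohort(subjects: list[Subject], spec: CohortSpec, outdir) -> None:
    """Write a cohort as one EDF per subject + SPECT CSV + JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = spec.groups[0].mvar_template.channel_labels or [
        f"ch{i}" for i in range(spec.n_channels)
    ]
    for s in subjects:
        write_edf(
            outdir / f"{s.id}.edf",
            s.eeg,
            spec.sampling_rate,
            labels,
            patient_id=s.id,
            recording_id=f"group {s.group}",
        )
    write_spect_csv(
        outdir / "spect.csv", {s.id: (s.group, s.spect) for s in subjects}
    )
    (outdir / "manifest.json").write_text(spec.to_json())
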