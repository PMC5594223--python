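"""End-to-end orchestration: cohort -> features -> pairwise comparisons.

``run_all`` executes, for each pair of available diagnostic groups and
each requested scenario, the full nested classification, honoring the
scenario dependency graph: the merged scenarios consume the *optimized*
(post-selection) per-measure feature sets of the eeg_single runs (and the
optimized SPECT set for eeg_merged+spect), so those runs are executed
first.

The report is machine-readable: a table shaped like the published
accuracy table (rows = scenarios/measures, columns = group pairs, cells =
"overall (acc1/acc2)"), plus a JSON log with the selected features and
fold compositions of every run.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ComparisonResult, PairwiseComparison, SelectionConfig
from .cohort import CohortSpec, Subject, generate_cohort
from .constants import EEG_CHANNELS, MEASURES, SCENARIOS
from .edf import read_edf
from .features import (
    FeatureDescriptor,
    SubjectFeatures,
    build_initial_vector,
    merge_optimized,
    stack_vectors,
)
from .mvar import fit_mvar
from .spect import read_spect_csv

__all__ = ["RunManifest", "PipelineReport", "read_eeg_edf", "run_all",
           "compute_subject_features"]

logger = logging.getLogger(__name__)


def read_eeg_edf(path, expected_sfreq: float = 200.0,
                 channels=EEG_CHANNELS, allow_sfreq_mismatch: bool = False):
    """Read an EDF file and return (data, labels, sfreq) in canonical order.

    Channels are reordered to the canonical montage; extra channels are
    dropped (logged); a missing canonical channel or an unexpected
    sampling rate is an error (the latter can be overridden).
    """
    data, labels, fs = read_edf(path)
    missing = [c for c in channels if c not in labels]
    if missing:
        raise ValueError(f"{path}: missing canonical channels {missing}")
    extra = [c for c in labels if c not in channels]
    if extra:
        logger.info("%s: dropping non-canonical channels %s", path, extra)
    if fs != expected_sfreq and not allow_sfreq_mismatch:
        raise ValueError(
            f"{path}: sampling rate {fs} Hz != expected {expected_sfreq} Hz"
        )
    idx = [labels.index(c) for c in channels]
    return data[idx], list(channels), fs


@dataclass
class RunManifest:
    """Everything needed to reproduce one pipeline run."""

    cohort_spec: CohortSpec | None = None      # synthetic mode
    edf_dir: str | None = None                 # real-data mode
    spect_csv: str | None = None
    scenarios: tuple[str, ...] = SCENARIOS
    config: SelectionConfig = dc_field(default_factory=SelectionConfig)
    mvar_order: int = 100
    seed: int = 0
    group_pairs: tuple[tuple[str, str], ...] | None = None  # None = all pairs
    measures: tuple[str, ...] = MEASURES

    def __post_init__(self) -> None:
        unknown = set(self.scenarios) - set(SCENARIOS)
        if unknown:
            raise ValueError(f"unknown scenarios: {sorted(unknown)}")
        if (self.cohort_spec is None) == (self.edf_dir is None):
            raise ValueError("exactly one of cohort_spec or edf_dir is required")


def _load_subjects(manifest: RunManifest) -> list[Subject]:
    if manifest.cohort_spec is not None:
        return generate_cohort(manifest.cohort_spec)
    spect = read_spect_csv(manifest.spect_csv)
    subjects = []
    for path in sorted(Path(manifest.edf_dir).glob("*.edf")):
        sid = path.stem
        if sid not in spect:
            raise ValueError(f"subject {sid} has EEG but no SPECT row")
        group, profile = spect[sid]
        data, _, _ = read_eeg_edf(path)
        subjects.append(Subject(id=sid, group=group, eeg=data, spect=profile))
    if not subjects:
        raise ValueError(f"no EDF files found in {manifest.edf_dir}")
    return subjects


def compute_subject_features(
    subjects: list[Subject],
    mvar_order: int,
    sfreq: float,
    channel_labels: list[str],
    with_graph: bool = True,
) -> dict[str, SubjectFeatures]:
    """Fit the MVAR model of every subject and derive all features."""
    out = {}
    for s in subjects:
        model = fit_mvar(s.eeg, mvar_order, sfreq=sfreq,
                         channel_labels=channel_labels)
        out[s.id] = SubjectFeatures.from_model(model, spect=s.spect,
                                               with_graph=with_graph)
    return out


@dataclass
class PipelineReport:
    """All comparison results of one run plus provenance."""

    results: dict[tuple, ComparisonResult]
    manifest_json: str
    seed: int

    def table(self) -> pd.DataFrame:
        """Accuracy table: rows = scenario (and measure), cols = pairs."""
        rows = {}
        for (pair, scenario, measure), res in self.results.items():
            row_key = f"{scenario}:{measure}" if measure else scenario
            col = f"{pair[0]}-{pair[1]}"
            rows.setdefault(row_key, {})[col] = res.table_cell()
        chance = {}
        for (pair, _sc, _m), res in self.results.items():
            chance[f"{pair[0]}-{pair[1]}"] = f"{res.chance_level:.2f}"
        df = pd.DataFrame(rows).T
        df.loc["chance_level"] = pd.Series(chance)
        return df

    def feature_log(self) -> dict:
        log = {}
        for (pair, scenario, measure), res in self.results.items():
            key = f"{pair[0]}-{pair[1]}|{scenario}" + (
                f"|{measure}" if measure else ""
            )
            log[key] = {
                "overall_accuracy": res.overall_accuracy,
                "per_group_accuracy": list(res.per_group_accuracy),
                "chance_level": res.chance_level,
                "n_train": res.n_train,
                "n_test": res.n_test,
                "final_features": [
                    d.name() for d in (res.final_descriptors or [])
                ],
                "per_fold_n_selected": [
                    len(s) for s in res.per_fold_selections
                ],
            }
        return log

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table().to_csv(outdir / "accuracy_table.csv")
        (outdir / "feature_log.json").write_text(
            json.dumps(self.feature_log(), indent=1)
        )
        (outdir / "manifest.json").write_text(self.manifest_json)


def _comparison_seed(base_seed: int, pair, scenario: str, measure) -> int:
    # deterministic per-run seed independent of execution order
    text = f"{pair[0]}|{pair[1]}|{scenario}|{measure or ''}"
    h = 2166136261
    for ch in text.encode():
        h = ((h ^ ch) * 16777619) % (2**32)
    return int((base_seed * 1000003 + h) % (2**31 - 1))


def run_all(manifest: RunManifest) -> PipelineReport:
    """Run every configured (pair, scenario) comparison on the cohort."""
    subjects = _load_subjects(manifest)
    if manifest.cohort_spec is not None:
        sfreq = manifest.cohort_spec.sampling_rate
        labels = (
            manifest.cohort_spec.groups[0].mvar_template.channel_labels
            or [f"ch{i}" for i in range(manifest.cohort_spec.n_channels)]
        )
    else:
        sfreq, labels = 200.0, list(EEG_CHANNELS)

    need_graph = any(s.startswith("eeg_graph") for s in manifest.scenarios)
    feats = compute_subject_features(
        subjects, manifest.mvar_order, sfreq, labels, with_graph=need_graph
    )
    y = np.array([s.group for s in subjects])
    sids = [s.id for s in subjects]
    group_names = list(dict.fromkeys(y.tolist()))  # first-appearance order
    pairs = manifest.group_pairs or tuple(
        itertools.combinations(group_names, 2)
    )

    results: dict[tuple, ComparisonResult] = {}

    def _run(pair, scenario, measure, X, descriptors) -> ComparisonResult:
        seed = _comparison_seed(manifest.seed, pair, scenario, measure)
        res = PairwiseComparison(
            X, y, pair, descriptors=descriptors, config=manifest.config,
            scenario=scenario if not measure else f"{scenario}:{measure}",
        ).fit(seed=seed)
        results[(tuple(pair), scenario, measure)] = res
        return res

    def _matrix(scenario, measure=None):
        vecs = [
            build_initial_vector(scenario, feats[sid], measure=measure)
            for sid in sids
        ]
        return stack_vectors(vecs)

    scen = set(manifest.scenarios)
    for pair in pairs:
        pair = tuple(pair)
        # per-measure scenarios; eeg_single selections feed the merged runs
        single_selected: dict[str, list[FeatureDescriptor]] = {}
        need_single = "eeg_single" in scen or bool(
            {"eeg_merged", "eeg_merged+spect"} & scen
        )
        if need_single:
            for measure in manifest.measures:
                X, descs = _matrix("eeg_single", measure)
                res = _run(pair, "eeg_single", measure, X, descs)
                single_selected[measure] = res.final_descriptors
        if "eeg_single+spect" in scen:
            for measure in manifest.measures:
                X, descs = _matrix("eeg_single+spect", measure)
                _run(pair, "eeg_single+spect", measure, X, descs)

        spect_selected: list[FeatureDescriptor] = []
        if "spect" in scen or "eeg_merged+spect" in scen:
            X, descs = _matrix("spect")
            res = _run(pair, "spect", None, X, descs)
            spect_selected = res.final_descriptors

        # merged scenarios reuse the optimized per-measure selections
        if {"eeg_merged", "eeg_merged+spect"} & scen:
            any_sid = sids[0]
            idx_of = {
                m: {
                    d: i
                    for i, d in enumerate(
                        feats[any_sid].eeg_fragment(m).descriptors
                    )
                }
                for m in manifest.measures
            }
            frags = {
                sid: merge_optimized(
                    [
                        feats[sid].eeg_fragment(m).subset(
                            [idx_of[m][d] for d in single_selected[m]]
                        )
                        for m in manifest.measures
                    ]
                )
                for sid in sids
            }
            if "eeg_merged" in scen:
                X, descs = stack_vectors([frags[sid] for sid in sids])
                _run(pair, "eeg_merged", None, X, descs)
            if "eeg_merged+spect" in scen:
                spect_idx = {
                    d: i
                    for i, d in enumerate(
                        feats[any_sid].spect_fragment().descriptors
                    )
                }
                merged_plus = {
                    sid: merge_optimized(
                        [
                            frags[sid],
                            feats[sid].spect_fragment().subset(
                                [spect_idx[d] for d in spect_selected]
                            ),
                        ],
                        scenario="eeg_merged+spect",
                    )
                    for sid in sids
                }
                X, descs = stack_vectors([merged_plus[sid] for sid in sids])
                _run(pair, "eeg_merged+spect", None, X, descs)

        for scenario in ("eeg_graph", "eeg_graph+spect"):
            if scenario in manifest.scenarios:
                X, descs = _matrix(scenario)
                _run(pair, scenario, None, X, descs)

    manifest_json = json.dumps(
        {
            "seed": manifest.seed,
            "scenarios": list(manifest.scenarios),
            "mvar_order": manifest.mvar_order,
            "mode": "synthetic" if manifest.cohort_spec else "edf",
            "cohort_spec": (
                json.loads(manifest.cohort_spec.to_json())
                if manifest.cohort_spec else None
            ),
        },
        indent=1,
    )
    return PipelineReport(results=results, manifest_json=manifest_json,
                          seed=manifest.seed)
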