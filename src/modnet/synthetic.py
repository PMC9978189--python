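"""Synthetic modular cohorts with known ground truth.

The generator emulates the second-order structure that the network
estimators consume: each scan is drawn from a zero-mean Gaussian whose
correlation matrix has a planted block-modular pattern — ``within_corr``
inside each of ``k_true`` modules, ``between_corr`` elsewhere, unit
variances.  Two classes differ on a small set of *discriminative* edges:
for the patient class (label 1) the correlation of each chosen
within-module edge is reduced by ``effect_size`` (weakened connectivity).
A per-subject covariance jitter makes scans of the same subject more alike
than scans of different subjects, so subject-level CV is meaningfully
different from scan-level CV.

Everything is reproducible from ``(spec, seed)``; cohorts can be kept in
memory or written to disk as one TSV per scan plus a manifest CSV and a
ground-truth JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import TimeSeries
from .graph import ModulePartition

__all__ = ["ModularCohortSpec", "Cohort", "generate_scan", "generate_cohort"]

_PD_FLOOR = 1e-6  # smallest admissible covariance eigenvalue after projection
_PD_LIMIT = -0.1  # below this, projection would distort the planted structure


@dataclass(frozen=True)
class ModularCohortSpec:
    """Parameters of the synthetic cohort.

    Defaults mirror the study conditions this package targets: 116 ROIs,
    137 retained time points per scan, 8 planted modules, within-module
    correlation 0.7 against 0 between modules, 48 control and 95 patient
    subjects with 2 scans each, and 12 within-module edges weakened by 0.3
    in the patient class.
    """

    n_rois: int = 116
    n_timepoints: int = 137
    k_true: int = 8
    module_sizes: tuple[int, ...] | None = None
    within_corr: float = 0.7
    between_corr: float = 0.0
    noise_sd: float = 0.0
    n_subjects_per_class: tuple[int, int] = (48, 95)  # (controls, patients)
    scans_per_subject: int = 2
    n_discriminative_edges: int = 12
    effect_size: float = 0.3
    subject_jitter_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = self.module_sizes
        if sizes is None:
            base, extra = divmod(self.n_rois, self.k_true)
            sizes = tuple(base + (1 if i < extra else 0) for i in range(self.k_true))
            object.__setattr__(self, "module_sizes", sizes)
        else:
            object.__setattr__(self, "module_sizes", tuple(int(s) for s in sizes))
            sizes = self.module_sizes
        if sum(sizes) != self.n_rois:
            raise ValueError(f"module_sizes {sizes} do not sum to n_rois = {self.n_rois}")
        if len(sizes) != self.k_true:
            raise ValueError("module_sizes length must equal k_true")
        if not (0.0 <= self.between_corr < self.within_corr < 1.0):
            raise ValueError("require 0 <= between_corr < within_corr < 1")
        if min(sizes) < 1:
            raise ValueError("every module needs at least one ROI")
        # equicorrelated blocks: smallest eigenvalue is 1 - within_corr > 0,
        # so the base matrix is positive definite by construction
        if self.effect_size < 0 or self.effect_size >= self.within_corr:
            raise ValueError("effect_size must be in [0, within_corr)")

    @property
    def partition(self) -> ModulePartition:
        labels = np.repeat(np.arange(self.k_true), self.module_sizes)
        return ModulePartition(labels=labels)


def _ensure_pd(sigma: np.ndarray, context: str) -> np.ndarray:
    """Project a symmetric matrix to the nearest PD matrix by eigenvalue
    clipping; raise if the smallest eigenvalue is so negative that the
    projection would distort the planted structure."""
    vals, vecs = np.linalg.eigh(sigma)
    if vals[0] >= _PD_FLOOR:
        return sigma
    if vals[0] < _PD_LIMIT:
        raise ValueError(
            f"{context}: covariance far from positive definite "
            f"(min eigenvalue {vals[0]:.3g}); reduce the effect size or jitter"
        )
    clipped = np.maximum(vals, _PD_FLOOR)
    out = (vecs * clipped) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)  # restore unit variances
    return (out + out.T) / 2.0


def _base_correlation(spec: ModularCohortSpec) -> np.ndarray:
    labels = spec.partition.labels
    same = labels[:, None] == labels[None, :]
    sigma = np.where(same, spec.within_corr, spec.between_corr)
    np.fill_diagonal(sigma, 1.0)
    return sigma


def _discriminative_edges(spec: ModularCohortSpec) -> list[tuple[int, int]]:
    """Within-module edges carrying the class difference, drawn from the
    spec's own seed so the ground truth is a function of the spec alone."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x0D15C]))
    labels = spec.partition.labels
    candidates = [
        (i, j)
        for i in range(spec.n_rois)
        for j in range(i + 1, spec.n_rois)
        if labels[i] == labels[j]
    ]
    if spec.n_discriminative_edges > len(candidates):
        raise ValueError("more discriminative edges requested than within-module pairs")
    idx = rng.choice(len(candidates), size=spec.n_discriminative_edges, replace=False)
    return [candidates[i] for i in np.sort(idx)]


def class_correlation(spec: ModularCohortSpec, class_label: int) -> np.ndarray:
    """Population correlation matrix of one class (PD-checked)."""
    sigma = _base_correlation(spec)
    if class_label == 1:
        for i, j in _discriminative_edges(spec):
            sigma[i, j] -= spec.effect_size
            sigma[j, i] = sigma[i, j]
    return _ensure_pd(sigma, "class covariance after discriminative-edge shift")


def _subject_correlation(
    spec: ModularCohortSpec, class_label: int, rng: np.random.Generator
) -> np.ndarray:
    sigma = class_correlation(spec, class_label)
    if spec.subject_jitter_sd > 0:
        jit = rng.normal(0.0, spec.subject_jitter_sd, size=sigma.shape)
        jit = (jit + jit.T) / 2.0
        np.fill_diagonal(jit, 0.0)
        sigma = _ensure_pd(sigma + jit, "subject covariance after jitter")
    return sigma


def generate_scan(
    spec: ModularCohortSpec,
    class_label: int,
    rng: np.random.Generator,
    subject_sigma: np.ndarray | None = None,
) -> tuple[TimeSeries, ModulePartition]:
    """Draw one scan's time series and return it with the planted partition.

    ``subject_sigma`` carries the subject-level covariance so repeated
    scans of one subject share it; when omitted a fresh subject draw is
    made from ``rng``.
    """
    if subject_sigma is None:
        subject_sigma = _subject_correlation(spec, class_label, rng)
    chol = np.linalg.cholesky(subject_sigma)
    raw = rng.standard_normal((spec.n_timepoints, spec.n_rois)) @ chol.T
    if spec.noise_sd > 0:
        raw = raw + spec.noise_sd * rng.standard_normal(raw.shape)
    ts = TimeSeries.from_raw(raw)
    return ts, spec.partition


@dataclass
class Cohort:
    """In-memory synthetic cohort with its ground truth."""

    spec: ModularCohortSpec
    scans: list[TimeSeries]
    manifest: pd.DataFrame  # columns: scan_id, subject_id, label, path
    partition: ModulePartition
    discriminative_edges: list[tuple[int, int]]

    @property
    def labels(self) -> np.ndarray:
        return self.manifest["label"].to_numpy()

    @property
    def subjects(self) -> np.ndarray:
        return self.manifest["subject_id"].to_numpy()


def generate_cohort(
    spec: ModularCohortSpec, out_dir: str | Path | None = None
) -> Cohort:
    """Generate the full two-class cohort; optionally write it to disk.

    With ``out_dir`` given, writes one TSV per scan (header row of ROI
    names), ``manifest.csv`` and ``ground_truth.json``; byte-identical
    output is guaranteed for identical ``(spec, seed)``.
    """
    from .io import write_timeseries  # local import to avoid a cycle

    edges = _discriminative_edges(spec)
    records = []
    scans: list[TimeSeries] = []
    root = np.random.SeedSequence(spec.seed)
    class_names = {0: "NC", 1: "PT"}
    subject_seeds = root.spawn(sum(spec.n_subjects_per_class))
    s_idx = 0
    for label, n_subj in zip((0, 1), spec.n_subjects_per_class):
        for i in range(n_subj):
            rng = np.random.default_rng(subject_seeds[s_idx])
            s_idx += 1
            subject_id = f"{class_names[label]}{i + 1:03d}"
            sigma = _subject_correlation(spec, label, rng)
            for s in range(spec.scans_per_subject):
                ts, _ = generate_scan(spec, label, rng, subject_sigma=sigma)
                scan_id = f"{subject_id}_s{s + 1}"
                path = f"{scan_id}.tsv" if out_dir is not None else ""
                records.append(
                    {
                        "scan_id": scan_id,
                        "subject_id": subject_id,
                        "label": label,
                        "path": path,
                    }
                )
                scans.append(ts)
    manifest = pd.DataFrame.from_records(records)
    cohort = Cohort(
        spec=spec,
        scans=scans,
        manifest=manifest,
        partition=spec.partition,
        discriminative_edges=edges,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec, ts in zip(records, scans):
            write_timeseries(ts, out / rec["path"])
        manifest.to_csv(out / "manifest.csv", index=False)
        truth = {
            "spec": dataclasses.asdict(spec),
            "partition": cohort.partition.labels.tolist(),
            "discriminative_edges": [list(e) for e in edges],
        }
        (out / "ground_truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return cohort
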