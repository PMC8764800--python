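"""Two-class synthetic connectome datasets with planted discriminative edges.

A shared base correlation matrix is drawn from a low-rank factor model and
projected to a valid correlation matrix; SSD subjects additionally receive a
symmetric offset ``effect_delta`` on a fixed set of planted edges.  Every
subject then gets independent symmetric Gaussian noise, clipping to
[-0.999, 0.999], and the configured diagonal.  The planted edge set is the
ground truth that saliency analysis should recover.

Noise is added to the correlations directly (fast and directly controllable);
an optional time-series mode instead simulates latent factor signals with
planted cross-loadings and runs them through the package's own correlation
step, exercising the full input path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (Atlas, ConnectomeDataset, NEGATIVE_LABEL, POSITIVE_LABEL,
                 SubjectRecord, correlation_matrix, write_matrix)

CLIP = 0.999


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset."""

    n_nodes: int = 30
    n_per_class: int = 100
    n_planted: int = 10
    effect_delta: float = 0.4
    subject_noise_sd: float = 0.1
    base_rank: int = 3
    seed: int = 0
    diag: float = 0.0
    planted_edges: list[tuple[int, int]] | None = None  # overrides n_planted

    def validate(self) -> None:
        if self.n_nodes < 2 or self.n_per_class < 1:
            raise ValueError("need n_nodes >= 2 and n_per_class >= 1")
        if self.subject_noise_sd <= 0:
            raise ValueError("subject_noise_sd must be positive")
        if self.planted_edges is not None:
            canon = {(min(i, j), max(i, j)) for i, j in self.planted_edges}
            if len(canon) != len(self.planted_edges) or any(
                    i == j or not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes)
                    for i, j in self.planted_edges):
                raise ValueError("planted edges must be distinct off-diagonal pairs")


def _base_correlation(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Low-rank-plus-diagonal covariance projected to a correlation matrix."""
    L = rng.normal(size=(cfg.n_nodes, cfg.base_rank)) / np.sqrt(cfg.base_rank)
    cov = L @ L.T + np.eye(cfg.n_nodes)  # PSD by construction
    d = 1.0 / np.sqrt(np.diag(cov))
    return d[:, None] * cov * d[None, :]


def _choose_planted(cfg: SimConfig, base: np.ndarray,
                    rng: np.random.Generator) -> list[tuple[int, int]]:
    if cfg.planted_edges is not None:
        edges = [(min(i, j), max(i, j)) for i, j in cfg.planted_edges]
    else:
        iu = np.triu_indices(cfg.n_nodes, k=1)
        # only plant where the offset cannot saturate the correlation scale
        ok = np.flatnonzero(np.abs(base[iu] + cfg.effect_delta) < 0.9)
        if len(ok) < cfg.n_planted:
            raise ValueError(
                f"effect_delta={cfg.effect_delta} leaves only {len(ok)} feasible "
                f"edges; {cfg.n_planted} requested")
        pick = rng.choice(ok, size=cfg.n_planted, replace=False)
        edges = [(int(iu[0][p]), int(iu[1][p])) for p in pick]
    for i, j in edges:
        if abs(base[i, j] + cfg.effect_delta) >= 1.0:
            raise ValueError(f"planted edge ({i},{j}) saturates: base "
                             f"{base[i, j]:.3f} + delta {cfg.effect_delta}")
    return sorted(edges)


def generate_dataset(cfg: SimConfig) -> tuple[ConnectomeDataset, list[tuple[int, int]]]:
    """Generate a labelled dataset; returns (dataset, planted ground truth)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    base = _base_correlation(cfg, rng)
    edges = _choose_planted(cfg, base, rng)
    shifted = base.copy()
    for i, j in edges:
        shifted[i, j] += cfg.effect_delta
        shifted[j, i] += cfg.effect_delta
    atlas = Atlas(tuple(f"R{i:03d}" for i in range(cfg.n_nodes)))
    subjects: list[SubjectRecord] = []
    for label, mean in ((POSITIVE_LABEL, shifted), (NEGATIVE_LABEL, base)):
        for s in range(cfg.n_per_class):
            noise = rng.normal(scale=cfg.subject_noise_sd,
                               size=(cfg.n_nodes, cfg.n_nodes))
            noise = (noise + noise.T) / np.sqrt(2.0)  # symmetric, same marginal sd
            m = np.clip(mean + noise, -CLIP, CLIP)
            np.fill_diagonal(m, cfg.diag)
            subjects.append(SubjectRecord(f"{label}{s:04d}", label, m))
    return ConnectomeDataset(subjects, atlas), edges


def generate_timeseries_dataset(cfg: SimConfig, n_timepoints: int = 200
                                ) -> tuple[ConnectomeDataset, list[tuple[int, int]]]:
    """Latent-factor time-series mode exercising :func:`correlation_matrix`.

    Each region mixes shared factor signals plus unit noise; planted edges get
    an extra shared latent source for SSD subjects only, raising their pairwise
    correlation by an amount that grows with ``effect_delta``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    L = rng.normal(size=(cfg.n_nodes, cfg.base_rank)) * 0.4
    iu = np.triu_indices(cfg.n_nodes, k=1)
    if cfg.planted_edges is not None:
        edges = sorted((min(i, j), max(i, j)) for i, j in cfg.planted_edges)
    else:
        pick = rng.choice(len(iu[0]), size=cfg.n_planted, replace=False)
        edges = sorted((int(iu[0][p]), int(iu[1][p])) for p in pick)
    load = np.sqrt(cfg.effect_delta)
    atlas = Atlas(tuple(f"R{i:03d}" for i in range(cfg.n_nodes)))
    subjects: list[SubjectRecord] = []
    for label in (POSITIVE_LABEL, NEGATIVE_LABEL):
        for s in range(cfg.n_per_class):
            factors = rng.normal(size=(n_timepoints, cfg.base_rank))
            ts = factors @ L.T + rng.normal(size=(n_timepoints, cfg.n_nodes))
            if label == POSITIVE_LABEL:
                for e, (i, j) in enumerate(edges):
                    shared = rng.normal(size=n_timepoints)
                    ts[:, i] += load * shared
                    ts[:, j] += load * shared
            m = correlation_matrix(ts, diag=cfg.diag)
            subjects.append(SubjectRecord(f"{label}{s:04d}", label, m))
    return ConnectomeDataset(subjects, atlas), edges


def write_fixture(dataset: ConnectomeDataset, out_dir: str | Path) -> Path:
    """Write a dataset in exactly the manifest/matrix format the loader reads.

    Returns the manifest path; region names go to ``atlas.txt`` alongside.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "atlas.txt").write_text("\n".join(dataset.atlas.names) + "\n")
    rows = ["subject_id\tlabel\tmatrix_path"]
    for rec in dataset.subjects:
        fname = f"{rec.subject_id}.txt"
        write_matrix(rec.matrix, out_dir / fname)
        rows.append(f"{rec.subject_id}\t{rec.label}\t{fname}")
    manifest = out_dir / "manifest.tsv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest
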