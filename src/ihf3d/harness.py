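"""Benchmark orchestration: fit once, score every challenge, tabulate.

A run fits the chosen detector on the ID training cohort exactly once,
scores the ID test cohort once, and evaluates every OOD challenge against
that single set of ID test scores — so one acceptance threshold governs all
challenges, as a shared ID test set implies.  Outputs are per-challenge
FPR@TPR95 / AUROC rows plus their arithmetic mean, a severity sweep over
synthetic corruptions, and a pairwise Fechner-correlation audit between
methods' per-challenge FPR vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ihf
from .anomalies import CORRUPTION_KINDS, CorruptionSpec, corrupt
from .metrics import ScoreSet, accept_threshold, auroc, fechner_correlation, fpr_at_tpr
from .preprocess import PreprocessConfig
from .volume_io import Volume, read_volume

logger = logging.getLogger(__name__)

__all__ = ["ChallengeConfig", "ReportTable", "score_volumes", "run_benchmark", "run_benchmark_volumes", "severity_sweep", "fechner_audit"]


@dataclass
class ChallengeConfig:
    """Directory-based benchmark description (one detector, many challenges)."""

    id_train: Path
    id_test: Path
    ood_challenges: dict[str, Path]
    method: ihf.IHFConfig = field(default_factory=ihf.IHFConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    output: Path | None = None


@dataclass
class ReportTable:
    """Per-challenge metric rows plus their arithmetic means."""

    rows: pd.DataFrame  # index: challenge name; columns: fpr_at_95tpr, auroc

    @property
    def averages(self) -> pd.Series:
        return self.rows.mean(axis=0)

    def to_markdown(self) -> str:
        full = pd.concat([self.rows, self.averages.to_frame("average").T])
        return full.to_markdown(floatfmt=".3f")

    def to_csv(self, path: str | Path) -> None:
        full = pd.concat([self.rows, self.averages.to_frame("average").T])
        full.to_csv(path, index_label="challenge")


def score_volumes(
    ref: ihf.IHFReference, volumes: list[Volume], pre: PreprocessConfig
) -> np.ndarray:
    return np.array([ihf.score(ref, v, ref.config, pre) for v in volumes])


def run_benchmark_volumes(
    train: list[Volume],
    id_test: list[Volume],
    challenges: dict[str, list[Volume]],
    method: ihf.IHFConfig | None = None,
    pre: PreprocessConfig | None = None,
) -> tuple[ReportTable, ihf.IHFReference, np.ndarray]:
    """In-memory benchmark core; returns the table, the fitted reference and
    the (reused) ID test scores."""
    method = method or ihf.IHFConfig()
    pre = pre or PreprocessConfig()
    ref = ihf.fit_reference(train, method, pre)
    id_scores = score_volumes(ref, id_test, pre)
    tau = accept_threshold(id_scores)
    rows = {}
    for name, vols in challenges.items():
        ood_scores = score_volumes(ref, vols, pre)
        s = ScoreSet(id_scores=id_scores, ood_scores=ood_scores)
        rows[name] = {"fpr_at_95tpr": fpr_at_tpr(s), "auroc": auroc(s)}
        logger.info("challenge=%s tau=%.6g n_id=%d n_ood=%d fpr=%.3f", name, tau, len(id_scores), len(ood_scores), rows[name]["fpr_at_95tpr"])
    table = ReportTable(rows=pd.DataFrame.from_dict(rows, orient="index"))
    return table, ref, id_scores


def _load_dir(path: Path) -> list[Volume]:
    files = sorted(Path(path).glob("*.nii*"))
    if not files:
        raise ValueError(f"no NIfTI volumes found in {path}")
    vols = []
    for f in files:
        try:
            vols.append(read_volume(f))
        except Exception as exc:  # name the offending file
            raise ValueError(f"failed to read {f}: {exc}") from exc
    return vols


def run_benchmark(config: ChallengeConfig) -> ReportTable:
    """Directory-driven benchmark: fit on id_train, score id_test once, then
    every challenge directory; optionally write the table as CSV."""
    if len(set(config.ood_challenges)) != len(config.ood_challenges):
        raise ValueError("challenge names must be unique")
    train = _load_dir(config.id_train)
    id_test = _load_dir(config.id_test)
    challenges = {name: _load_dir(p) for name, p in config.ood_challenges.items()}
    table, _, _ = run_benchmark_volumes(train, id_test, challenges, config.method, config.preprocess)
    if config.output is not None:
        table.to_csv(config.output)
    return table


def severity_sweep(
    ref: ihf.IHFReference,
    id_test: list[Volume],
    id_scores: np.ndarray,
    kinds: tuple[str, ...] = CORRUPTION_KINDS,
    levels: tuple[int, ...] = (1, 2, 3, 4, 5),
    seeds: tuple[int, ...] = (0,),
    pre: PreprocessConfig | None = None,
) -> pd.DataFrame:
    """FPR by (corruption kind, severity level) on corrupted copies of id_test.

    Each repetition seed corrupts every test volume with a per-volume derived
    seed; the OOD score pool for a cell aggregates all repetitions.
    """
    pre = pre or PreprocessConfig()
    out = pd.DataFrame(index=list(kinds), columns=list(levels), dtype=float)
    for kind in kinds:
        for level in levels:
            scores = []
            for rep in seeds:
                for i, v in enumerate(id_test):
                    spec = CorruptionSpec(kind=kind, severity=level, seed=int(rep) * 100003 + i)
                    scores.append(ihf.score(ref, corrupt(v, spec), ref.config, pre))
            s = ScoreSet(id_scores=id_scores, ood_scores=np.array(scores))
            out.loc[kind, level] = fpr_at_tpr(s)
    return out


def fechner_audit(results: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Fechner correlations between methods' per-challenge FPR vectors.

    Returns a symmetric matrix with unit diagonal, methods as both index and
    columns."""
    names = list(results)
    lengths = {len(np.asarray(results[n])) for n in names}
    if len(lengths) != 1:
        raise ValueError("all result vectors must have equal length")
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            r = fechner_correlation(np.asarray(results[a]), np.asarray(results[b]))
            mat.loc[a, b] = mat.loc[b, a] = r
    return mat
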