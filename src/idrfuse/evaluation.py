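"""Metrics and stability experiment harnesses.

Per-residue disorder prediction is scored with sensitivity, specificity,
balanced accuracy, Matthews correlation and ROC AUC, with the disordered
residue as the positive class and residues pooled across the proteins of
a dataset. Two experiment designs probe stability under changing
short/long-disorder composition:

* ``ratio_sweep`` — removes SDR proteins in seeded random increments,
  producing nested datasets from the full mixture down to LDR-only, and
  re-scores every method on each;
* ``resample_compare`` — repeatedly scores methods on random protein
  subsets and tallies pairwise wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .errors import ContractError, DataError, ParameterError
from .features import SDR_PROTEIN, classify_protein
from .types import PredictionTrack


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ContractError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    """Sn, Sp, BACC and MCC from confusion counts; metrics whose
    denominator is zero are reported as ``nan`` and flagged."""

    sn: float
    sp: float
    bacc: float
    mcc: float
    auc: float | None = None
    undefined: tuple = ()


def confusion_counts(track, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Tally per-residue confusion counts at the given call threshold."""
    probs = track.probabilities if isinstance(track, PredictionTrack) else np.asarray(track, float)
    labels = np.asarray(labels)
    if probs.shape != labels.shape:
        raise ContractError(
            f"track length {probs.size} does not match {labels.size} labels"
        )
    if not np.isin(labels, (0, 1)).all():
        raise ContractError("labels must be binary 0/1")
    calls = probs >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(calls & pos)),
        fp=int(np.sum(calls & ~pos)),
        tn=int(np.sum(~calls & ~pos)),
        fn=int(np.sum(~calls & pos)),
    )


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    """Sn = TP/(TP+FN), Sp = TN/(TN+FP), BACC = (Sn+Sp)/2 and
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))."""
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    sn = ratio(counts.tp, counts.tp + counts.fn, "Sn")
    sp = ratio(counts.tn, counts.tn + counts.fp, "Sp")
    bacc = (sn + sp) / 2.0
    if np.isnan(bacc):
        undefined.append("BACC")
    denom = (
        (counts.tp + counts.fp) * (counts.tp + counts.fn)
        * (counts.tn + counts.fp) * (counts.tn + counts.fn)
    )
    if denom == 0:
        undefined.append("MCC")
        mcc = float("nan")
    else:
        mcc = (counts.tp * counts.tn - counts.fp * counts.fn) / np.sqrt(denom)
    return MetricReport(sn=sn, sp=sp, bacc=bacc, mcc=mcc, undefined=tuple(undefined))


def auc(scores, labels) -> float:
    """ROC AUC, equal to the Mann-Whitney pair-ranking probability
    (ties between a positive and a negative score count one half)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise DataError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(labels, scores))


def evaluate_tracks(tracks, labels, threshold: float = 0.5) -> MetricReport:
    """Pool residues of many proteins and compute the full metric report."""
    probs = np.concatenate([
        t.probabilities if isinstance(t, PredictionTrack) else np.asarray(t, float)
        for t in tracks
    ])
    y = np.concatenate([np.asarray(v) for v in labels])
    report = compute_metrics(confusion_counts(probs, y, threshold))
    report.auc = auc(probs, y)
    return report


# ---------------------------------------------------------------------------
# Stability experiments
# ---------------------------------------------------------------------------


def ratio_sweep(labels: list, method_tracks: dict, steps: int = 11,
                seed: int = 0, threshold: float = 0.5) -> pd.DataFrame:
    """Score each method on nested datasets with progressively fewer SDR
    proteins.

    ``labels`` is one 0/1 track per protein; ``method_tracks`` maps a
    method name to its per-protein probability tracks. SDR proteins are
    removed in ``steps - 1`` seeded-random increments, so step 0 is the
    full mixture and the last step keeps no SDR protein. Returns a tidy
    frame with one row per (step, method).
    """
    if steps < 1:
        raise ParameterError("steps must be >= 1")
    n = len(labels)
    classes = [classify_protein(y) for y in labels]
    sdr_idx = [i for i in range(n) if classes[i] == SDR_PROTEIN]
    if not sdr_idx and steps > 1:
        warnings.warn("no SDR proteins; ratio sweep degenerates to a single step")
        steps = 1
    rng = np.random.default_rng(seed)
    removal_order = rng.permutation(sdr_idx)

    rows = []
    for step in range(steps):
        n_removed = int(round(step * len(sdr_idx) / max(steps - 1, 1)))
        removed = set(removal_order[:n_removed].tolist())
        keep = [i for i in range(n) if i not in removed]
        kept_classes = [classes[i] for i in keep]
        sdr_fraction = kept_classes.count(SDR_PROTEIN) / len(keep)
        for method, tracks in method_tracks.items():
            report = evaluate_tracks(
                [tracks[i] for i in keep], [labels[i] for i in keep], threshold
            )
            rows.append({
                "step": step,
                "n_proteins": len(keep),
                "sdr_fraction": sdr_fraction,
                "method": method,
                "sn": report.sn, "sp": report.sp, "bacc": report.bacc,
                "mcc": report.mcc, "auc": report.auc,
            })
    return pd.DataFrame(rows)


def resample_compare(labels: list, method_tracks: dict, n_proteins: int,
                     repeats: int = 50, seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeatedly score methods on random protein subsets.

    Each repeat samples ``n_proteins`` proteins without replacement and
    records every method's pooled-residue AUC. Returns the per-repeat
    table and a pairwise win-count matrix (ties excluded from wins).
    """
    n = len(labels)
    if n_proteins > n:
        raise ParameterError(f"cannot sample {n_proteins} proteins from {n}")
    rng = np.random.default_rng(seed)
    methods = list(method_tracks)
    rows = []
    for rep in range(repeats):
        idx = rng.choice(n, size=n_proteins, replace=False)
        for method in methods:
            tracks = method_tracks[method]
            report_auc = auc(
                np.concatenate([np.asarray(tracks[i].probabilities
                                           if isinstance(tracks[i], PredictionTrack)
                                           else tracks[i], dtype=float) for i in idx]),
                np.concatenate([np.asarray(labels[i]) for i in idx]),
            )
            rows.append({"repeat": rep, "method": method, "auc": report_auc})
    table = pd.DataFrame(rows)
    wide = table.pivot(index="repeat", columns="method", values="auc")
    wins = pd.DataFrame(0, index=methods, columns=methods)
    for a in methods:
        for b in methods:
            if a != b:
                wins.loc[a, b] = int((wide[a] > wide[b]).sum())
    return table, wins
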