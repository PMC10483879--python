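"""Synthetic data generation.

Everything the framework consumes can be generated here with no
external tools or downloads: label tracks with an exact LDR/SDR/ordered
protein composition, evolutionary profiles and contact matrices whose
statistics are correlated with the disorder labels to a tunable degree,
structural feature tables, and base-predictor probability streams whose
AUC is calibrated through the binormal model.

What is emulated and what is not: run-length structure (geometric run
lengths split at the 30-residue LDR boundary), compositional bias of
disordered segments (enrichment of disorder-promoting residues),
profile noise (Dirichlet rows around the class composition) and
short-range contact decay are reproduced; true evolutionary covariation,
alignment-depth effects and annotator noise are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .errors import ContractError, DataError, ParameterError
from .features import FULLY_ORDERED, LDR_PROTEIN, SDR_PROTEIN, classify_protein
from .types import (
    CCMMatrix,
    PSIBLAST_ALPHABET,
    PredictionTrack,
    ProfileSet,
    ProteinRecord,
    StructuralTracks,
)

#: Background amino-acid frequencies (PSI-BLAST column order), roughly the
#: Robinson-Robinson composition.
BACKGROUND_FREQS = np.array([
    0.079, 0.051, 0.045, 0.054, 0.019, 0.043, 0.063, 0.074, 0.022, 0.051,
    0.091, 0.057, 0.022, 0.039, 0.052, 0.071, 0.058, 0.013, 0.032, 0.064,
])
BACKGROUND_FREQS = BACKGROUND_FREQS / BACKGROUND_FREQS.sum()

#: Composition inside disordered runs: disorder-promoting residues
#: (P, E, S, Q, K, G, A) enriched, order-promoting aromatics/hydrophobics
#: depleted.
_DIS_BOOST = {"P": 2.5, "E": 2.2, "S": 2.0, "Q": 1.8, "K": 1.8, "G": 1.6, "A": 1.4,
              "W": 0.3, "C": 0.3, "F": 0.4, "Y": 0.5, "I": 0.5, "L": 0.6, "V": 0.6}
DISORDER_FREQS = BACKGROUND_FREQS * np.array(
    [_DIS_BOOST.get(a, 1.0) for a in PSIBLAST_ALPHABET]
)
DISORDER_FREQS = DISORDER_FREQS / DISORDER_FREQS.sum()


@dataclass
class DisorderCompositionSpec:
    """Exact protein-class composition of a generated dataset.

    Lengths are drawn uniformly in ``length_range``; SDR run lengths are
    truncated-geometric on 1..30 and LDR run lengths shifted-geometric
    starting at 31 (the class boundary is the only length constant the
    taxonomy fixes; geometric tails are the conventional null for run
    lengths).
    """

    n_ldr: int = 0
    n_sdr: int = 0
    n_ordered: int = 0
    length_range: tuple = (60, 120)
    sdr_run_p: float = 0.15
    ldr_run_p: float = 0.08
    composition_divergence: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_ldr, self.n_sdr, self.n_ordered) < 0:
            raise ParameterError("class counts must be nonnegative")
        if self.n_ldr + self.n_sdr + self.n_ordered == 0:
            raise ParameterError("at least one protein must be requested")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ParameterError(f"bad length range {self.length_range}")
        if self.n_ldr and hi < 33:
            raise DataError("proteins too short to host an LDR run plus ordered background")


def _sample_sdr_run(rng, p: float = 0.15) -> int:
    # truncated geometric with support 1..30
    while True:
        r = int(rng.geometric(p))
        if r <= 30:
            return r


def _sample_ldr_run(rng, max_len: int, p: float) -> int:
    return min(31 + int(rng.geometric(p)) - 1, max_len)


def _place_runs(rng, L: int, runs: list[int]) -> np.ndarray | None:
    """Place disordered runs into an ordered background with at least one
    ordered residue between runs; None if they do not fit."""
    labels = np.zeros(L, dtype=np.int8)
    if sum(runs) + len(runs) > L:  # runs plus at least one ordered residue
        return None
    for run in sorted(runs, reverse=True):
        placed = False
        for _attempt in range(20):
            start = int(rng.integers(0, L - run + 1))
            lo, hi = max(start - 1, 0), min(start + run + 1, L)
            if labels[lo:hi].any():
                continue
            labels[start : start + run] = 1
            placed = True
            break
        if not placed:
            return None
    if labels.all():
        return None
    return labels


def _sequence_for_labels(rng, labels: np.ndarray, divergence: float) -> str:
    mix = min(max(divergence, 0.0), 1.0)
    dis = (1 - mix) * BACKGROUND_FREQS + mix * DISORDER_FREQS
    letters = []
    aa = np.array(list(PSIBLAST_ALPHABET))
    for y in labels:
        freqs = dis if y else BACKGROUND_FREQS
        letters.append(str(rng.choice(aa, p=freqs)))
    return "".join(letters)


def simulate_proteins(spec: DisorderCompositionSpec) -> list[ProteinRecord]:
    """Generate proteins whose label tracks realize the requested class
    composition exactly; every record is verified with
    :func:`classify_protein` (rejection sampling on construction)."""
    rng = np.random.default_rng(spec.seed)
    records = []
    plan = (
        [LDR_PROTEIN] * spec.n_ldr + [SDR_PROTEIN] * spec.n_sdr
        + [FULLY_ORDERED] * spec.n_ordered
    )
    for idx, wanted in enumerate(plan):
        for _attempt in range(200):
            L = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
            if wanted == FULLY_ORDERED:
                labels = np.zeros(L, dtype=np.int8)
            elif wanted == SDR_PROTEIN:
                n_runs = int(rng.integers(1, 4))
                labels = _place_runs(
                    rng, L, [_sample_sdr_run(rng, spec.sdr_run_p) for _ in range(n_runs)]
                )
            else:
                runs = [_sample_ldr_run(rng, L - 2, spec.ldr_run_p)]
                if rng.random() < 0.5:
                    runs.append(_sample_sdr_run(rng, spec.sdr_run_p))
                labels = _place_runs(rng, L, runs)
            if labels is None or classify_protein(labels) != wanted:
                continue
            sequence = _sequence_for_labels(rng, labels, spec.composition_divergence)
            records.append(ProteinRecord(id=f"syn{idx:04d}", sequence=sequence, labels=labels))
            break
        else:
            raise DataError(f"could not realize class {wanted} within the length range")
    return records


def simulate_profiles(record: ProteinRecord, signal_strength: float = 1.0,
                      seed: int = 0, concentration: float = 50.0
                      ) -> tuple[ProfileSet, CCMMatrix, StructuralTracks]:
    """Generate label-correlated profiles, a contact matrix and structural
    tracks for one protein.

    PSFM and HMM rows are Dirichlet draws around the residue's class
    composition (background for ordered residues, a background/disorder
    mixture controlled by ``signal_strength`` for disordered ones; 0
    makes the profiles label-independent). The PSSM is the log2 ratio of
    the PSFM against the background. The contact matrix is symmetric with
    short-range decay plus noise. Structural tracks have the fixed block
    widths; the seven physico-chemical columns carry a mild label shift
    scaled by ``signal_strength``.
    """
    if signal_strength < 0:
        raise ParameterError("signal_strength must be >= 0")
    rng = np.random.default_rng(seed)
    labels = record.labels if record.labels is not None else np.zeros(record.length, np.int8)
    s = min(signal_strength, 1.0)
    dis_mean = (1 - s) * BACKGROUND_FREQS + s * DISORDER_FREQS

    L = record.length
    psfm = np.empty((L, 20))
    hmm = np.empty((L, 20))
    for i in range(L):
        mean = dis_mean if labels[i] else BACKGROUND_FREQS
        psfm[i] = rng.dirichlet(concentration * mean)
        hmm[i] = rng.dirichlet(concentration * mean)
    pssm = np.log2((psfm + 1e-4) / (BACKGROUND_FREQS + 1e-4))
    profiles = ProfileSet(pssm=pssm, psfm=psfm, hmm=hmm)

    ij = np.abs(np.subtract.outer(np.arange(L), np.arange(L)))
    base = np.exp(-ij / 6.0)
    noise = rng.normal(0.0, 0.05, size=(L, L))
    values = np.clip(base + (noise + noise.T) / 2.0, 0.0, 1.0)
    ccm = CCMMatrix((values + values.T) / 2.0)

    shift = 0.5 * signal_strength * labels[:, None]
    tracks = StructuralTracks(
        ss=rng.dirichlet(np.ones(8), size=L),
        cn=rng.normal(0.0, 1.0, size=(L, 2)),
        hse=rng.normal(0.0, 1.0, size=(L, 4)),
        seven=rng.normal(0.0, 1.0, size=(L, 7)) + shift,
        sa=rng.normal(0.0, 1.0, size=(L, 1)),
    )
    return profiles, ccm, tracks


# ---------------------------------------------------------------------------
# Calibrated predictor streams
# ---------------------------------------------------------------------------

_MAX_D = 10.0


@dataclass(frozen=True)
class PredictorSpec:
    """A simulated base predictor with a target ranking quality.

    Scores follow the binormal model: negatives ~ N(0,1), positives
    ~ N(d,1) with d = sqrt(2) * Phi^-1(AUC), squashed to [0,1] by the
    (monotone, hence AUC-preserving) normal CDF. ``auc_by_class``
    overrides the target per protein class to plant length specialists.
    """

    auc: float = 0.75
    tie_fraction: float = 0.0
    auc_by_class: dict | None = None

    def __post_init__(self):
        targets = [self.auc] + list((self.auc_by_class or {}).values())
        for t in targets:
            if not 0.5 < t <= 1.0:
                raise ParameterError(f"target AUC must lie in (0.5, 1], got {t}")
        if not 0.0 <= self.tie_fraction < 1.0:
            raise ParameterError("tie_fraction must lie in [0, 1)")

    def target_for(self, protein_class: str) -> float:
        if self.auc_by_class and protein_class in self.auc_by_class:
            return self.auc_by_class[protein_class]
        return self.auc


def binormal_d(target_auc: float) -> float:
    """Effect size d with theoretical AUC Phi(d / sqrt(2)); capped for the
    separation limit at AUC = 1."""
    if target_auc >= 1.0:
        return _MAX_D
    return min(float(np.sqrt(2.0) * norm.ppf(target_auc)), _MAX_D)


def simulate_predictor(labels, spec: PredictorSpec, seed: int = 0,
                       record_id: str = "simulated") -> PredictionTrack:
    """Draw a calibrated probability track for one label vector."""
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ContractError("labels must be binary 0/1")
    if len(np.unique(labels)) < 2:
        raise DataError("both label classes must be present")
    rng = np.random.default_rng(seed)
    d = binormal_d(spec.auc)
    raw = rng.normal(0.0, 1.0, size=labels.size) + d * labels
    probs = norm.cdf(raw - d / 2.0)
    if spec.tie_fraction > 0:
        mask = rng.random(labels.size) < spec.tie_fraction
        probs[mask] = 0.5
    return PredictionTrack(id=record_id, probabilities=probs)


def _scores_for_protein(rng, labels: np.ndarray, d: float) -> np.ndarray:
    raw = rng.normal(0.0, 1.0, size=labels.size) + d * labels
    return norm.cdf(raw - d / 2.0)


def build_validation_suite(ratios: list, method_specs: list, size: int = 20,
                           seed: int = 0, length_range: tuple = (60, 120)):
    """Build ratio-stratified validation datasets with six simulated
    predictor tracks per protein.

    ``ratios`` are (SDR parts, LDR parts) tuples, one dataset per ratio;
    ``method_specs`` are six :class:`PredictorSpec` in the fixed fusion
    method order. Per-class AUC targets plant length specialists.
    """
    from .fusion import N_METHODS, ValidationDataset, ValidationSuite

    if not ratios:
        raise ParameterError("at least one SDR:LDR ratio is required")
    if len(method_specs) != N_METHODS:
        raise ParameterError(f"exactly {N_METHODS} predictor specs are required")
    datasets = []
    for di, ratio in enumerate(ratios):
        sdr_part, ldr_part = ratio
        if sdr_part < 0 or ldr_part < 0 or sdr_part + ldr_part == 0:
            raise ParameterError(f"invalid SDR:LDR ratio {ratio}")
        n_sdr = int(round(size * sdr_part / (sdr_part + ldr_part)))
        n_ldr = size - n_sdr
        comp = DisorderCompositionSpec(
            n_ldr=n_ldr, n_sdr=n_sdr, length_range=length_range,
            seed=seed + 1000 * di,
        )
        records = simulate_proteins(comp)
        rng = np.random.default_rng(seed + 1000 * di + 17)
        labels, tracks = [], []
        for rec in records:
            cls = classify_protein(rec.labels)
            rows = np.stack([
                _scores_for_protein(rng, rec.labels, binormal_d(ms.target_for(cls)))
                for ms in method_specs
            ])
            labels.append(rec.labels)
            tracks.append(rows)
        datasets.append(ValidationDataset(
            name=f"ratio_{sdr_part}:{ldr_part}", labels=labels, tracks=tracks,
            ratio=(sdr_part, ldr_part),
        ))
    return ValidationSuite(datasets)


# ---------------------------------------------------------------------------
# Planted-signal toy tasks (learnability checks for the neural predictors)
# ---------------------------------------------------------------------------


def planted_feature_dataset(spec: DisorderCompositionSpec, width: int,
                            signal: float = 2.0, n_signal_cols: int = 3,
                            seed: int = 0):
    """(features, labels) pairs where the first feature columns carry a
    label-dependent shift of size ``signal`` on top of unit noise."""
    records = simulate_proteins(spec)
    rng = np.random.default_rng(seed)
    out = []
    for rec in records:
        X = rng.normal(0.0, 1.0, size=(rec.length, width))
        X[:, :n_signal_cols] += signal * (2.0 * rec.labels[:, None] - 1.0) / 2.0
        out.append((X, rec.labels.astype(float)))
    return out


def planted_tensor_dataset(n: int, delta: float = 2.0, seed: int = 0):
    """Windowed-tensor toy task: unit-noise 20 x 20 x 3 tensors whose
    center window row (row 10) of the first channel is shifted by
    ``delta`` for positive residues."""
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.5).astype(float)
    X = rng.normal(0.0, 1.0, size=(n, 20, 20, 3))
    X[:, 9, :, 0] += delta * (2.0 * y[:, None] - 1.0) / 2.0
    return X, y


# ---------------------------------------------------------------------------
# Fixture bundles
# ---------------------------------------------------------------------------


def write_fixture_bundle(directory, spec: DisorderCompositionSpec,
                         signal_strength: float = 1.0) -> list[ProteinRecord]:
    """Write a complete input bundle (FASTA, labels, per-protein profile /
    contact / structural files in their real formats) for integration
    tests and the ``simulate`` CLI subcommand."""
    from . import io_formats

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = simulate_proteins(spec)
    io_formats.write_fasta(records, directory / "proteins.fasta")
    io_formats.write_labels(records, directory / "labels.txt")
    for k, rec in enumerate(records):
        profiles, ccm, tracks = simulate_profiles(
            rec, signal_strength=signal_strength, seed=spec.seed + 7919 * (k + 1)
        )
        io_formats.write_pssm_ascii(rec, profiles.pssm, profiles.psfm,
                                    directory / f"{rec.id}.pssm")
        io_formats.write_hhm(rec, profiles.hmm, directory / f"{rec.id}.hhm")
        io_formats.write_ccmpred(ccm, directory / f"{rec.id}.ccm")
        io_formats.write_structural_tracks(tracks, directory / f"{rec.id}.struct.tsv")
    return records
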