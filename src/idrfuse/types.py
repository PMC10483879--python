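"""Core domain containers.

Per-residue disorder prediction treats a protein as a plain sequence of
residues; every container here is keyed by the protein length ``L``.
Indexing is 0-based everywhere in memory; 1-based indices appear only in
file formats and error messages (converted at the I/O boundary).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError

#: The 20 standard amino acids in PSI-BLAST profile column order.
PSIBLAST_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

#: Match-emission column order used by HH-suite ``.hhm`` profiles.
HHSUITE_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Residue letters accepted in input sequences (standard 20 plus X).
SEQUENCE_ALPHABET = set(PSIBLAST_ALPHABET) | {"X"}

#: Disordered runs strictly longer than this many residues count as long
#: disordered regions (LDRs); runs of up to 30 residues are short (SDRs).
LDR_MIN_RUN = 30

#: Feature blocks in their fixed concatenation order, with per-residue widths.
BLOCK_WIDTHS = {
    "PSSM": 20,
    "PSFM": 20,
    "HHM": 20,
    "SS": 8,
    "CN": 2,
    "HSE": 4,
    "SEVEN": 7,
    "SA": 1,
    "CCM": 21,
}

BLOCK_ORDER = tuple(BLOCK_WIDTHS)


@dataclass
class ProteinRecord:
    """A protein sequence with optional per-residue disorder labels.

    ``labels[i] == 1`` marks residue ``i`` as disordered.
    """

    id: str
    sequence: str
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ContractError(f"record {self.id!r}: empty sequence")
        if any(c.isspace() for c in self.sequence):
            raise ContractError(f"record {self.id!r}: sequence contains whitespace")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
            if self.labels.shape != (len(self.sequence),):
                raise ContractError(
                    f"record {self.id!r}: {self.labels.size} labels for "
                    f"{len(self.sequence)} residues"
                )
            if not np.isin(self.labels, (0, 1)).all():
                raise ContractError(f"record {self.id!r}: labels must be 0/1")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class PredictionTrack:
    """Per-residue disorder probabilities for one protein, plus binary calls.

    Calls are derived by thresholding (``p >= threshold`` is a disorder
    call); the default operating point is 0.5.
    """

    id: str
    probabilities: np.ndarray
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.ndim != 1 or self.probabilities.size < 1:
            raise ContractError(f"track {self.id!r}: probabilities must be a 1-D vector")
        if ((self.probabilities < 0) | (self.probabilities > 1)).any():
            raise ContractError(f"track {self.id!r}: probabilities outside [0,1]")

    @property
    def calls(self) -> np.ndarray:
        return (self.probabilities >= self.threshold).astype(np.int8)

    def __len__(self) -> int:
        return self.probabilities.size


@dataclass
class ProfileSet:
    """The three L x 20 evolutionary profiles of one protein.

    ``pssm`` holds log-odds scores (unbounded reals), ``psfm`` observed
    amino-acid frequencies and ``hmm`` profile-HMM match emissions, the
    latter two in [0, 1].
    """

    pssm: np.ndarray
    psfm: np.ndarray
    hmm: np.ndarray

    def __post_init__(self) -> None:
        self.pssm = np.asarray(self.pssm, dtype=float)
        self.psfm = np.asarray(self.psfm, dtype=float)
        self.hmm = np.asarray(self.hmm, dtype=float)
        L = self.pssm.shape[0]
        for name in ("pssm", "psfm", "hmm"):
            m = getattr(self, name)
            if m.ndim != 2 or m.shape != (L, 20):
                raise ContractError(f"{name} must be L x 20, got {m.shape}")
        for name in ("psfm", "hmm"):
            m = getattr(self, name)
            if ((m < 0) | (m > 1)).any():
                raise ContractError(f"{name} entries must lie in [0,1]")

    @property
    def length(self) -> int:
        return self.pssm.shape[0]


@dataclass
class CCMMatrix:
    """L x L residue-residue contact/coevolution probabilities."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ContractError(f"CCM must be square, got {self.values.shape}")

    @property
    def length(self) -> int:
        return self.values.shape[0]


@dataclass
class StructuralTracks:
    """Precomputed per-residue structural feature blocks.

    Block widths are fixed: 8-state secondary structure (SS), contact
    number (CN, 2), half-sphere exposure (HSE, 4), seven physico-chemical
    property scales (SEVEN) and solvent accessibility (SA, 1).
    """

    ss: np.ndarray
    cn: np.ndarray
    hse: np.ndarray
    seven: np.ndarray
    sa: np.ndarray

    _WIDTHS = {"ss": 8, "cn": 2, "hse": 4, "seven": 7, "sa": 1}

    def __post_init__(self) -> None:
        L = None
        for name, width in self._WIDTHS.items():
            m = np.asarray(getattr(self, name), dtype=float)
            if m.ndim == 1:
                m = m[:, None]
            setattr(self, name, m)
            if m.ndim != 2 or m.shape[1] != width:
                raise ContractError(
                    f"{name} block must have {width} columns, got {m.shape}"
                )
            if L is None:
                L = m.shape[0]
            elif m.shape[0] != L:
                raise ContractError(f"{name} block has {m.shape[0]} rows, expected {L}")

    @property
    def length(self) -> int:
        return self.ss.shape[0]


@dataclass(frozen=True)
class FeatureConfig:
    """Which feature blocks a base predictor consumes.

    The block concatenation order is fixed (:data:`BLOCK_ORDER`), so a
    config is just the enabled subset. ``width`` is the per-residue
    dimensionality of the assembled feature vector.
    """

    blocks: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        unknown = set(self.blocks) - set(BLOCK_WIDTHS)
        if unknown:
            raise ContractError(f"unknown feature blocks: {sorted(unknown)}")
        object.__setattr__(self, "blocks", frozenset(self.blocks))

    @classmethod
    def of(cls, *blocks: str) -> "FeatureConfig":
        return cls(frozenset(blocks))

    @property
    def width(self) -> int:
        return sum(BLOCK_WIDTHS[b] for b in self.blocks)

    @property
    def ordered_blocks(self) -> tuple:
        return tuple(b for b in BLOCK_ORDER if b in self.blocks)


#: Full nine-block configuration used by four of the five sequence models
#: (width 103).
FULL_CONFIG = FeatureConfig.of("PSSM", "PSFM", "HHM", "SS", "CN", "HSE", "SEVEN", "SA", "CCM")

#: The hierarchical-attention model drops CN and HSE (width 97).
HAN_CONFIG = FeatureConfig.of("PSSM", "PSFM", "HHM", "SS", "SEVEN", "SA", "CCM")
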