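"""Readers and writers for every external format the framework touches.

Supported formats: FASTA sequences, PSI-BLAST ASCII profile matrices
(PSSM + percentage frequencies), HH-suite ``.hhm`` profiles, CCMpred
plain-text contact matrices, tab-separated structural-feature tables,
per-residue label tables, and the tab-separated prediction output.

Every parser has a matching writer so that synthetic fixtures round-trip;
file indices are 1-based, in-memory arrays 0-based.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import ContractError, FormatError
from .types import (
    CCMMatrix,
    HHSUITE_ALPHABET,
    PSIBLAST_ALPHABET,
    PredictionTrack,
    ProteinRecord,
    StructuralTracks,
)

# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Record ids are taken from the header up to the first whitespace and
    sequences are uppercased. An empty file yields an empty list; sequence
    data before any ``>`` header is a format error.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}: line {lineno}: sequence data before any '>' header"
                    )
                break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for start in range(0, rec.length, width):
                fh.write(rec.sequence[start : start + width] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

_PSSM_HEADER = (
    "Last position-specific scoring matrix computed, weighted observed "
    "percentages rounded down, information per position, and relative "
    "weight of gapless real matches to pseudocounts"
)


def parse_pssm_ascii(path) -> tuple[np.ndarray, np.ndarray]:
    """Parse a PSI-BLAST ASCII matrix into (pssm, psfm).

    Each residue row carries the 1-based index, the residue letter, 20
    integer log-odds and 20 observed percentages. The log-odds become the
    PSSM; the percentages are rescaled to [0, 1] to form the PSFM. Column
    order is the fixed PSI-BLAST amino-acid order.
    """
    pssm_rows, psfm_rows = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens or not tokens[0].isdigit():
                continue
            if len(tokens) < 42:
                raise FormatError(
                    f"{path}: row at line {lineno} has {len(tokens)} columns, "
                    "expected index + residue + 40 numeric columns"
                )
            try:
                scores = [float(t) for t in tokens[2:22]]
                freqs = [float(t) for t in tokens[22:42]]
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric cell at line {lineno}: {exc}")
            pssm_rows.append(scores)
            psfm_rows.append([f / 100.0 for f in freqs])
    pssm = np.array(pssm_rows, dtype=float).reshape(len(pssm_rows), 20)
    psfm = np.array(psfm_rows, dtype=float).reshape(len(psfm_rows), 20)
    return pssm, psfm


def write_pssm_ascii(record: ProteinRecord, pssm: np.ndarray, psfm: np.ndarray, path) -> None:
    """Serialize profiles in the PSI-BLAST ASCII layout (percentages rounded)."""
    pssm = np.asarray(pssm, dtype=float)
    psfm = np.asarray(psfm, dtype=float)
    if pssm.shape != (record.length, 20) or psfm.shape != (record.length, 20):
        raise ContractError(
            f"record {record.id!r}: profile shapes {pssm.shape}/{psfm.shape} "
            f"do not match L={record.length}"
        )
    header_cols = "  ".join(PSIBLAST_ALPHABET) + "   " + "   ".join(PSIBLAST_ALPHABET)
    with open(path, "w") as fh:
        fh.write("\n" + _PSSM_HEADER + "\n")
        fh.write("            " + header_cols + "\n")
        for i in range(record.length):
            scores = " ".join(f"{v:6.0f}" if float(v).is_integer() else f"{v:6.2f}" for v in pssm[i])
            freqs = " ".join(f"{100 * v:4.1f}" for v in psfm[i])
            fh.write(f"{i + 1:5d} {record.sequence[i]} {scores}  {freqs}  0.00 0.00\n")
        fh.write("\n")


# ---------------------------------------------------------------------------
# HH-suite .hhm
# ---------------------------------------------------------------------------


def _decode_hhm(token: str, path, lineno: int) -> float:
    if token == "*":
        return 0.0
    try:
        v = int(token)
    except ValueError:
        raise FormatError(f"{path}: line {lineno}: bad emission value {token!r}")
    p = 2.0 ** (-v / 1000.0)
    if p > 1.0:
        raise FormatError(
            f"{path}: line {lineno}: stored value {v} decodes to probability {p} > 1"
        )
    return p


def parse_hhm(path) -> np.ndarray:
    """Parse an HH-suite ``.hhm`` profile into an L x 20 emission matrix.

    Stored integers ``v`` decode to probabilities ``2**(-v/1000)``; the
    ``*`` sentinel decodes to 0. Columns follow the HH-suite amino-acid
    order; one row per match state.
    """
    rows: list[list[float]] = []
    declared_length = None
    with open(path) as fh:
        lines = fh.readlines()
    it = iter(enumerate(lines, start=1))
    for lineno, line in it:
        if line.startswith("LENG"):
            declared_length = int(line.split()[1])
        if line.startswith("HMM"):
            next(it, None)  # transition-name header
            next(it, None)  # begin-state transition line
            break
    else:
        raise FormatError(f"{path}: no HMM block found")
    for lineno, line in it:
        if line.startswith("//"):
            break
        tokens = line.split()
        if not tokens:
            continue
        if len(tokens) < 22:
            raise FormatError(
                f"{path}: line {lineno}: truncated match-emission line "
                f"({len(tokens)} fields, expected >= 22)"
            )
        rows.append([_decode_hhm(t, path, lineno) for t in tokens[2:22]])
        next(it, None)  # per-state transition line
    if declared_length is not None and len(rows) != declared_length:
        raise FormatError(
            f"{path}: {len(rows)} match states parsed but LENG declares {declared_length}"
        )
    return np.array(rows, dtype=float).reshape(len(rows), 20)


def write_hhm(record: ProteinRecord, hmm: np.ndarray, path) -> None:
    """Serialize an emission matrix in the HH-suite ``.hhm`` layout."""
    hmm = np.asarray(hmm, dtype=float)
    if hmm.shape != (record.length, 20):
        raise ContractError(
            f"record {record.id!r}: emission shape {hmm.shape} does not match L={record.length}"
        )

    def encode(p: float) -> str:
        if p <= 0.0:
            return "*"
        return str(int(round(-1000.0 * np.log2(p))))

    with open(path, "w") as fh:
        fh.write("HHsearch 1.5\n")
        fh.write(f"NAME  {record.id}\n")
        fh.write(f"LENG  {record.length} match states\n")
        fh.write("#\n")
        fh.write("NULL   " + " ".join(["3000"] * 20) + "\n")
        fh.write("HMM    " + "\t".join(HHSUITE_ALPHABET) + "\n")
        fh.write("       M->M\tM->I\tM->D\tI->M\tI->I\tD->M\tD->D\tNeff\tNeff_I\tNeff_D\n")
        fh.write("       0\t*\t*\t0\t*\t0\t*\t*\t*\t*\n")
        for i in range(record.length):
            values = "\t".join(encode(p) for p in hmm[i])
            fh.write(f"{record.sequence[i]} {i + 1}\t{values}\t{i + 1}\n")
            fh.write("       0\t*\t*\t*\t*\t*\t*\t0\t0\t0\n")
        fh.write("//\n")


# ---------------------------------------------------------------------------
# CCMpred
# ---------------------------------------------------------------------------


def parse_ccmpred(path) -> CCMMatrix:
    """Parse a CCMpred plain-text L x L contact matrix.

    Values are clipped to [0, 1] with a warning; symmetry is recorded
    as-is, not enforced.
    """
    try:
        values = np.loadtxt(path, dtype=float, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric matrix cell: {exc}")
    if values.shape[0] != values.shape[1]:
        raise FormatError(
            f"{path}: matrix is {values.shape[0]} x {values.shape[1]}, expected square"
        )
    if (values < 0).any() or (values > 1).any():
        warnings.warn(f"{path}: contact values outside [0,1] were clipped")
        values = np.clip(values, 0.0, 1.0)
    return CCMMatrix(values)


def write_ccmpred(ccm: CCMMatrix, path) -> None:
    np.savetxt(path, ccm.values, fmt="%.6f", delimiter="\t")


# ---------------------------------------------------------------------------
# Structural feature tables
# ---------------------------------------------------------------------------

_STRUCT_COLUMNS = (
    [f"SS{i}" for i in range(1, 9)]
    + [f"CN{i}" for i in range(1, 3)]
    + [f"HSE{i}" for i in range(1, 5)]
    + [f"SEVEN{i}" for i in range(1, 8)]
    + ["SA1"]
)


def read_structural_tracks(path) -> StructuralTracks:
    """Read a tab-separated structural-feature table (header names blocks)."""
    with open(path) as fh:
        header = fh.readline().split()
        if header != _STRUCT_COLUMNS:
            raise FormatError(
                f"{path}: header does not name the SS/CN/HSE/SEVEN/SA blocks"
            )
        try:
            data = np.loadtxt(fh, dtype=float, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric cell: {exc}")
    if data.shape[1] != len(_STRUCT_COLUMNS):
        raise FormatError(
            f"{path}: {data.shape[1]} columns, expected {len(_STRUCT_COLUMNS)}"
        )
    return StructuralTracks(
        ss=data[:, 0:8], cn=data[:, 8:10], hse=data[:, 10:14],
        seven=data[:, 14:21], sa=data[:, 21:22],
    )


def write_structural_tracks(tracks: StructuralTracks, path) -> None:
    data = np.hstack([tracks.ss, tracks.cn, tracks.hse, tracks.seven, tracks.sa])
    with open(path, "w") as fh:
        fh.write("\t".join(_STRUCT_COLUMNS) + "\n")
        np.savetxt(fh, data, fmt="%.6f", delimiter="\t")


# ---------------------------------------------------------------------------
# Label tables
# ---------------------------------------------------------------------------


def read_labels(path) -> dict[str, np.ndarray]:
    """Read per-residue 0/1 label tracks grouped under '>' headers."""
    labels: dict[str, np.ndarray] = {}
    current: str | None = None
    values: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current is not None:
                    labels[current] = np.array(values, dtype=np.int8)
                current = line[1:].split()[0]
                values = []
            else:
                if current is None:
                    raise FormatError(f"{path}: line {lineno}: labels before any header")
                for c in line:
                    if c not in "01":
                        raise FormatError(f"{path}: line {lineno}: label {c!r} not in 0/1")
                    values.append(int(c))
    if current is not None:
        labels[current] = np.array(values, dtype=np.int8)
    return labels


def write_labels(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.labels is None:
                raise ContractError(f"record {rec.id!r} carries no labels")
            fh.write(f">{rec.id}\n")
            track = "".join(str(int(v)) for v in rec.labels)
            for start in range(0, len(track), width):
                fh.write(track[start : start + width] + "\n")


# ---------------------------------------------------------------------------
# Prediction output
# ---------------------------------------------------------------------------


def write_predictions(
    records: Sequence[ProteinRecord], tracks: Sequence[PredictionTrack], path
) -> None:
    """Write per-residue predictions as tab-separated ``index residue prob call``
    lines grouped under ``>`` headers. Probabilities are printed with 3
    decimals; output is byte-deterministic for identical inputs.
    """
    if len(records) != len(tracks):
        raise ContractError(
            f"{len(records)} records but {len(tracks)} prediction tracks"
        )
    with open(path, "w") as fh:
        for rec, track in zip(records, tracks):
            if len(track) != rec.length:
                raise ContractError(
                    f"record {rec.id!r}: track length {len(track)} != L={rec.length}"
                )
            fh.write(f">{rec.id}\n")
            calls = track.calls
            for i in range(rec.length):
                fh.write(
                    f"{i + 1}\t{rec.sequence[i]}\t{track.probabilities[i]:.3f}\t{calls[i]}\n"
                )


def read_predictions(path) -> list[PredictionTrack]:
    tracks: list[PredictionTrack] = []
    current: str | None = None
    probs: list[float] = []

    def flush():
        if current is not None:
            tracks.append(PredictionTrack(id=current, probabilities=np.array(probs)))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                current = line[1:].split()[0]
                probs = []
            else:
                fields = line.split("\t")
                if len(fields) != 4:
                    raise FormatError(
                        f"{path}: line {lineno}: expected 4 tab-separated fields"
                    )
                probs.append(float(fields[2]))
    flush()
    return tracks
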