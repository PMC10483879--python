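"""Per-residue feature encoding.

Two representations are produced from the evolutionary profiles:

* a windowed 20 x 20 x 3 tensor per residue (PSSM', PSFM', HMM' channels,
  the residue sitting in row 10 of a 20-residue window) consumed by the
  architecture-search predictor, and
* a flat per-residue vector concatenating the enabled feature blocks in
  fixed order (PSSM, PSFM, HHM, SS, CN, HSE, SEVEN, SA, CCM-window)
  consumed by the five sequence models.

Window positions falling outside the protein are zero-padded, matching
the "missing values are set to 0" rule of the CCM window.
"""

from __future__ import annotations

import numpy as np

from .errors import ContractError, ParameterError
from .types import (
    BLOCK_WIDTHS,
    CCMMatrix,
    FeatureConfig,
    LDR_MIN_RUN,
    ProfileSet,
    StructuralTracks,
)

#: Residues spanned by the profile window; the center residue is the 10th.
WINDOW_SIZE = 20
_CENTER_OFFSET = 9  # rows i-9 .. i+10 (0-based: i-9 .. i+10 inclusive)

#: Width of the per-residue CCM window vector.
CCM_WINDOW = 21


def window_profile(profile: np.ndarray, i: int) -> np.ndarray:
    """Extract the 20-row window of ``profile`` centred so that residue
    ``i`` (0-based) is the 10th row; out-of-range rows are zero.
    """
    profile = np.asarray(profile, dtype=float)
    L = profile.shape[0]
    if not 0 <= i < L:
        raise IndexError(f"residue index {i} out of range for L={L}")
    out = np.zeros((WINDOW_SIZE, profile.shape[1]), dtype=float)
    lo = i - _CENTER_OFFSET
    hi = lo + WINDOW_SIZE
    src_lo, src_hi = max(lo, 0), min(hi, L)
    out[src_lo - lo : src_hi - lo] = profile[src_lo:src_hi]
    return out


def stack_channels(pssm_w: np.ndarray, psfm_w: np.ndarray, hmm_w: np.ndarray) -> np.ndarray:
    """Stack the three windowed profiles into a 20 x 20 x 3 tensor
    (channel order PSSM', PSFM', HMM'; values untouched)."""
    channels = {"PSSM": pssm_w, "PSFM": psfm_w, "HMM": hmm_w}
    for name, ch in channels.items():
        ch = np.asarray(ch, dtype=float)
        if ch.shape != (WINDOW_SIZE, 20):
            raise ContractError(f"{name} channel has shape {ch.shape}, expected (20, 20)")
        channels[name] = ch
    return np.stack([channels["PSSM"], channels["PSFM"], channels["HMM"]], axis=-1)


def residue_tensor(profiles: ProfileSet, i: int) -> np.ndarray:
    """The 20 x 20 x 3 windowed tensor for residue ``i``."""
    return stack_channels(
        window_profile(profiles.pssm, i),
        window_profile(profiles.psfm, i),
        window_profile(profiles.hmm, i),
    )


def residue_tensors(profiles: ProfileSet) -> np.ndarray:
    """All L windowed tensors of a protein as an (L, 20, 20, 3) array."""
    return np.stack([residue_tensor(profiles, i) for i in range(profiles.length)])


def ccm_window(ccm: CCMMatrix, i: int, k: int = CCM_WINDOW) -> np.ndarray:
    """Row-``i`` contact probabilities in a window of odd width ``k``
    centred on the diagonal entry C[i, i]; out-of-range entries are 0."""
    if k % 2 == 0 or k < 1:
        raise ParameterError(f"CCM window width must be odd and positive, got {k}")
    L = ccm.length
    if not 0 <= i < L:
        raise IndexError(f"residue index {i} out of range for L={L}")
    half = (k - 1) // 2
    out = np.zeros(k, dtype=float)
    lo = i - half
    src_lo, src_hi = max(lo, 0), min(i + half + 1, L)
    out[src_lo - lo : src_hi - lo] = ccm.values[i, src_lo:src_hi]
    return out


def assemble_features(
    profiles: ProfileSet | None,
    tracks: StructuralTracks | None,
    ccm: CCMMatrix | None,
    config: FeatureConfig,
) -> np.ndarray:
    """Concatenate the enabled feature blocks into an L x D matrix.

    Blocks appear in the fixed order PSSM, PSFM, HHM, SS, CN, HSE, SEVEN,
    SA, CCM; D is the sum of enabled block widths. Inputs are only
    required for the blocks they feed.
    """
    blocks = config.ordered_blocks
    length = None
    columns: list[np.ndarray] = []

    def require(obj, block):
        if obj is None:
            raise ContractError(f"feature block {block} is enabled but its input is missing")
        return obj

    for block in blocks:
        if block in ("PSSM", "PSFM", "HHM"):
            p = require(profiles, block)
            col = {"PSSM": p.pssm, "PSFM": p.psfm, "HHM": p.hmm}[block]
        elif block in ("SS", "CN", "HSE", "SEVEN", "SA"):
            t = require(tracks, block)
            col = getattr(t, block.lower())
        else:  # CCM
            c = require(ccm, block)
            col = np.stack([ccm_window(c, i) for i in range(c.length)])
        if length is None:
            length = col.shape[0]
        elif col.shape[0] != length:
            raise ContractError(
                f"feature block {block} has {col.shape[0]} rows, expected {length}"
            )
        columns.append(col)
    if not columns:
        raise ContractError("no feature blocks enabled")
    out = np.hstack(columns)
    assert out.shape[1] == config.width
    return out


# ---------------------------------------------------------------------------
# Protein-class taxonomy
# ---------------------------------------------------------------------------

LDR_PROTEIN = "LDR_protein"
SDR_PROTEIN = "SDR_protein"
FULLY_ORDERED = "fully_ordered"


def disorder_runs(labels: np.ndarray) -> list[int]:
    """Lengths of the maximal runs of 1s in a binary label track."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ContractError("empty label track")
    if not np.isin(labels, (0, 1)).all():
        raise ContractError("label track must be binary 0/1")
    padded = np.concatenate([[0], labels.astype(int), [0]])
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list((ends - starts))


def classify_protein(labels: np.ndarray) -> str:
    """Classify a label track as LDR protein, SDR protein or fully ordered.

    A disordered run of more than 30 residues makes the protein an LDR
    protein; otherwise any disordered residue makes it an SDR protein
    (a run of exactly 30 counts as short); no disordered residues means
    fully ordered.
    """
    runs = disorder_runs(labels)
    if any(r > LDR_MIN_RUN for r in runs):
        return LDR_PROTEIN
    if runs:
        return SDR_PROTEIN
    return FULLY_ORDERED
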