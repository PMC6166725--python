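"""Sliding-window hydrophobicity profiling and proline-aromatic motif scan.

Chaperone substrate-binding domains and PPIase domains select hydrophobic
stretches of unfolded client proteins; within those stretches a proline
immediately adjacent to an aromatic residue (the proline-aromatic motif) is
the recognition element for prolyl isomerization. This module computes the
windowed hydrophobicity profile of a substrate sequence, extracts contiguous
hydrophobic stretches, and reports prolines with aromatic neighbours.

Positions are 0-based within this module; the table writers in
:mod:`ppiscan.io` convert to the 1-based residue numbering used in reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Roseman (1988) side-chain transfer free energies, positive = hydrophobic.
# The scale is a named, swappable asset: pass any {letter: value} mapping.
ROSEMAN_1988 = {
    "A": 0.39, "R": -3.95, "N": -1.91, "D": -3.81, "C": 0.25,
    "Q": -1.30, "E": -2.91, "G": 0.00, "H": -0.64, "I": 1.82,
    "L": 1.82, "K": -2.77, "M": 0.96, "F": 2.27, "P": 0.99,
    "S": -1.24, "T": -1.00, "W": 2.25, "Y": 1.47, "V": 1.30,
}

SCALES = {"roseman1988": ROSEMAN_1988}

#: Residues counted as aromatic in the motif scan. Tryptophan, tyrosine and
#: histidine are directly supported by observed contacts; phenylalanine is
#: included by conservative generalization and can be excluded.
AROMATIC_DEFAULT = frozenset("WFYH")


@dataclass
class SequenceProfile:
    """Windowed hydrophobicity profile of a sequence.

    ``scores`` has one entry per residue; positions where the centered
    window does not fit (the (window−1)/2 residues at each terminus) are
    NaN — undefined, never zero-filled.
    """

    sequence: str
    scores: np.ndarray
    window: int

    def defined(self) -> np.ndarray:
        """Boolean mask of positions with a defined score."""
        return ~np.isnan(self.scores)


@dataclass
class MotifHit:
    """A proline with an immediately adjacent aromatic residue (0-based)."""

    proline_position: int
    aromatic_position: int
    aromatic_residue: str
    in_hydrophobic_stretch: bool

    def __post_init__(self):
        if abs(self.proline_position - self.aromatic_position) != 1:
            raise ValueError("motif residues must be sequence neighbours")


def hydrophobicity_profile(
    sequence: str,
    window: int = 9,
    scale: dict[str, float] | str = "roseman1988",
    on_unknown: str = "error",
) -> SequenceProfile:
    """Mean hydrophobicity over a centered sliding window.

    Parameters
    ----------
    sequence : amino-acid string (standard one-letter codes).
    window : odd window width ≥ 1; 9 reproduces the profiling convention
        used for unfolded substrate mapping.
    scale : per-residue scale mapping or the name of a built-in scale.
    on_unknown : ``"error"`` raises on a letter absent from the scale;
        ``"skip"`` marks every window containing it undefined.

    Returns
    -------
    SequenceProfile with NaN at terminal positions where the window does
    not fit and at windows poisoned by unknown letters under ``skip``.
    """
    if isinstance(scale, str):
        scale = SCALES[scale]
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 1, got {window}")
    if on_unknown not in ("error", "skip"):
        raise ValueError("on_unknown must be 'error' or 'skip'")

    seq = sequence.upper()
    values = np.empty(len(seq))
    for i, aa in enumerate(seq):
        if aa in scale:
            values[i] = scale[aa]
        elif on_unknown == "error":
            raise ValueError(f"unknown residue letter {aa!r} at position {i}")
        else:
            values[i] = np.nan

    half = window // 2
    scores = np.full(len(seq), np.nan)
    for i in range(half, len(seq) - half):
        scores[i] = np.mean(values[i - half : i + half + 1])  # NaN-poisoning intended
    return SequenceProfile(sequence=seq, scores=scores, window=window)


def hydrophobic_stretches(
    profile: SequenceProfile, threshold: float = 0.0
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive defined positions scoring above threshold.

    Returns disjoint, sorted, inclusive 0-based ``(start, end)`` pairs
    covering exactly the positions with score > threshold.
    """
    above = np.where(np.nan_to_num(profile.scores, nan=-np.inf) > threshold)[0]
    runs: list[tuple[int, int]] = []
    for pos in above:
        if runs and pos == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], int(pos))
        else:
            runs.append((int(pos), int(pos)))
    return runs


def scan_proline_aromatic(
    sequence: str,
    stretches: list[tuple[int, int]] | None = None,
    aromatics: frozenset[str] | set[str] | str = AROMATIC_DEFAULT,
) -> list[MotifHit]:
    """Report every proline flanked by an aromatic residue.

    Both neighbours are examined independently, so a proline between two
    aromatics yields two hits. ``in_hydrophobic_stretch`` is True iff the
    proline position falls inside one of ``stretches`` (empty/None means
    no stretch information, flag False).
    """
    seq = sequence.upper()
    aromatics = frozenset(aromatics)
    stretches = stretches or []
    hits: list[MotifHit] = []
    for i, aa in enumerate(seq):
        if aa != "P":
            continue
        in_stretch = any(s <= i <= e for s, e in stretches)
        for j in (i - 1, i + 1):
            if 0 <= j < len(seq) and seq[j] in aromatics:
                hits.append(
                    MotifHit(
                        proline_position=i,
                        aromatic_position=j,
                        aromatic_residue=seq[j],
                        in_hydrophobic_stretch=in_stretch,
                    )
                )
    return hits
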