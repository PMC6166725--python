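#!/usr/bin/env python
"""Hydrophobicity profile and proline-aromatic motif scan of the substrate.

Slides a 9-residue window of Roseman hydrophobicity over the demo substrate,
extracts the contiguous stretches scoring above zero, and reports every
proline flanked by an aromatic residue — the recognition element a PPIase
chaperone domain selects. Writes results/profile/{profile,motifs}.tsv.
"""

import numpy as np
import pandas as pd

from ppiscan import sequence_profile as sp
from ppiscan.io import _write_tsv
from ppiscan.pipeline import DEMO_SEQUENCE

OUT = "results/profile"


def main():
    seq = DEMO_SEQUENCE
    profile = sp.hydrophobicity_profile(seq, window=9)
    stretches = sp.hydrophobic_stretches(profile, threshold=0.0)
    hits = sp.scan_proline_aromatic(seq, stretches)

    in_stretch = np.zeros(len(seq), dtype=bool)
    for s, e in stretches:
        in_stretch[s:e + 1] = True
    _write_tsv(pd.DataFrame({
        "position": np.arange(1, len(seq) + 1), "aa": list(seq),
        "score": profile.scores, "in_stretch": in_stretch,
    }), f"{OUT}/profile.tsv", {"window": 9, "threshold": 0.0,
                               "scale": "roseman1988"})
    _write_tsv(pd.DataFrame(
        [{"proline": h.proline_position + 1,
          "aromatic": h.aromatic_position + 1,
          "aromatic_residue": h.aromatic_residue,
          "in_hydrophobic_stretch": h.in_hydrophobic_stretch} for h in hits],
        columns=["proline", "aromatic", "aromatic_residue",
                 "in_hydrophobic_stretch"]), f"{OUT}/motifs.tsv")

    print(f"{len(stretches)} hydrophobic stretch(es) above 0:")
    for s, e in stretches:
        print(f"  residues {s + 1}-{e + 1}")
    print(f"{len(hits)} proline-aromatic motif hit(s):")
    for h in hits:
        print(f"  P{h.proline_position + 1}-{h.aromatic_residue}"
              f"{h.aromatic_position + 1}"
              f" (in hydrophobic stretch: {h.in_hydrophobic_stretch})")


if __name__ == "__main__":
    main()
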