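"""Independent brute-force oracles shared by the test modules.

These deliberately avoid the package's own code paths: the alignment oracle
is a full sliding-window scan with no seeding, and the complement table is
written out by hand.
"""

from __future__ import annotations

import numpy as np

from retroquant.align import ReferenceGenome

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def oracle_align(seq: str, ref: ReferenceGenome, max_mm: int):
    """O(L*G) scan of every placement on both strands; unique-minimum rule."""
    placements = []
    for chrom, g in ref.sequences.items():
        garr = np.frombuffer(g.encode(), dtype=np.uint8)
        for strand, q in (("+", seq), ("-", rc(seq))):
            if len(g) < len(q):
                continue
            qarr = np.frombuffer(q.encode(), dtype=np.uint8)
            windows = np.lib.stride_tricks.sliding_window_view(garr, len(q))
            diff = windows != qarr
            diff |= qarr == ord("N")
            diff |= windows == ord("N")
            mms = diff.sum(axis=1)
            for pos in np.nonzero(mms <= max_mm)[0]:
                placements.append((int(mms[pos]), chrom, int(pos), strand))
    if not placements:
        return None
    best = min(p[0] for p in placements)
    hits = [p for p in placements if p[0] == best]
    if len(hits) != 1:
        return None
    mm, chrom, pos, strand = hits[0]
    return chrom, pos, strand, mm
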