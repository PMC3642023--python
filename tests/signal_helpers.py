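"""Shared helper: build a SignalTrack for a region of given copy number."""

import numpy as np

from famprior.cnv import compute_baf, compute_sequence_count
from famprior.simulate import simulate_pileup


def signal_track(copy, rng, depth=50.0, chrom="chr1", start=10_000, end=70_000):
    positions = np.arange(start, end + 1, 500)
    het = positions[::10].tolist()
    piles = {p.pos: p for p in simulate_pileup(copy, het, depth, rng, chrom=chrom)}
    depths = []
    for p in positions:
        if int(p) in piles:
            depths.append(piles[int(p)].ref_count + piles[int(p)].alt_count)
        else:
            depths.append(float(rng.poisson(depth * copy / 2.0)))
    bafs = {pos: compute_baf(sp) for pos, sp in piles.items() if compute_baf(sp) is not None}
    return compute_sequence_count(
        chrom, positions.tolist(), depths, baseline=depth, snv_positions=set(piles), bafs=bafs
    )
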