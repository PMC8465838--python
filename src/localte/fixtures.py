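"""Analytically characterized synthetic rasters for testing and demos.

Each fixture has a known TE signature: a lagged copier carries a purely
excitatory local TE signature (te_I = 0), a lagged inverter a purely
inhibitory one (te_E = 0), an independent pair is a null, and the tiny net
is a 5-cell network with a known signed adjacency.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .calcium import BinaryRaster

__all__ = ["make_fixtures"]

KINDS = ("copier", "inverter", "independent", "tiny-net")


def make_fixtures(kind: str, t_bins: int = 1000, seed: int = 0, lag: int = 1):
    """Build one synthetic raster with known ground truth.

    Returns ``(BinaryRaster, truth)`` where ``truth`` is the signed adjacency
    (+1 excitatory, -1 inhibitory, 0 none), rows targets / columns sources.
    """
    if t_bins < 10:
        raise ValueError("t_bins must be >= 10")
    rng = np.random.default_rng(seed)
    if kind == "copier":
        src = rng.integers(0, 2, size=t_bins)
        tgt = np.roll(src, lag)
        tgt[:lag] = 0
        states = np.stack([src, tgt])
        truth = np.array([[0, 0], [1, 0]])  # 0 -> 1 excitatory
    elif kind == "inverter":
        src = rng.integers(0, 2, size=t_bins)
        tgt = 1 - np.roll(src, lag)
        tgt[:lag] = 0
        states = np.stack([src, tgt])
        truth = np.array([[0, 0], [-1, 0]])  # 0 -> 1 inhibitory
    elif kind == "independent":
        states = rng.integers(0, 2, size=(2, t_bins))
        truth = np.zeros((2, 2), dtype=int)
    elif kind == "tiny-net":
        # 5 cells: 0 drives 1 and 2 (excitatory), 3 inhibits 4; sources are
        # sparse random, targets follow with a 1-bin lag
        truth = np.zeros((5, 5), dtype=int)
        truth[1, 0] = truth[2, 0] = 1
        truth[4, 3] = -1
        src0 = (rng.random(t_bins) < 0.25).astype(np.int8)
        src3 = (rng.random(t_bins) < 0.25).astype(np.int8)
        follow = lambda s: np.concatenate([[0], s[:-1]])
        states = np.stack([src0, follow(src0), follow(src0), src3, 1 - follow(src3)])
    else:
        raise ValueError(f"unknown fixture kind {kind!r}, choose from {KINDS}")
    raster = BinaryRaster(states.astype(np.int8), bin_size=10.0, provenance=f"fixture_{kind}")
    return raster, truth


def write_fixtures(kind: str, outdir: str | Path, t_bins: int = 1000, seed: int = 0):
    """Emit the raster and truth of one fixture as delimited text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    raster, truth = make_fixtures(kind, t_bins=t_bins, seed=seed)
    raster.save(outdir / f"{kind}_raster.txt")
    np.savetxt(outdir / f"{kind}_truth.txt", truth, fmt="%d")
    return outdir
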