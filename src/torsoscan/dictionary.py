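"""Square fiducial marker dictionary (4x4 code grid, 50 ids).

Markers are the classic black-bordered square fiducials: a 1-cell black
border around a 4x4 grid of black/white cells encoding a 16-bit code.  The
dictionary is generated deterministically at import time with two
guarantees that make decoding at Hamming tolerance 0 unambiguous:

* the four in-plane rotations of every code are pairwise distinct (at
  Hamming distance >= 2), so the decoded rotation fixes the corner order;
* any rotation of one code differs from any rotation of another by
  Hamming distance >= 4.

The code-grid convention: ``grid[r, c]`` is the cell in row ``r`` (from the
top) and column ``c`` (from the left) of the *upright* marker; value 1 is a
white cell.  Corner order everywhere is top-left, top-right, bottom-right,
bottom-left (clockwise when viewed upright).
"""

from __future__ import annotations

import numpy as np

__all__ = ["MarkerDictionary", "DICT_4X4_50"]

_GRID = 4
_GENERATION_SEED = 40504  # fixed: the dictionary is part of the package


def _rotations(grid: np.ndarray) -> list[np.ndarray]:
    return [np.rot90(grid, k) for k in range(4)]


def _min_distance(grid: np.ndarray, others: list[np.ndarray]) -> int:
    return min(int(np.sum(grid != o)) for o in others)


class MarkerDictionary:
    """A fixed set of 4x4 binary codes with rotation-aware separation."""

    def __init__(self, n_codes: int = 50, name: str = "4x4_50",
                 min_inter_distance: int = 4, min_self_distance: int = 2,
                 seed: int = _GENERATION_SEED):
        self.name = name
        self.n_codes = n_codes
        rng = np.random.default_rng(seed)
        codes: list[np.ndarray] = []
        pool: list[np.ndarray] = []  # all rotations of accepted codes
        while len(codes) < n_codes:
            bits = rng.integers(0, 2, size=(_GRID, _GRID), dtype=np.uint8)
            ones = int(bits.sum())
            if not 5 <= ones <= 11:
                continue
            rots = _rotations(bits)
            if min(int(np.sum(rots[0] != r)) for r in rots[1:]) < min_self_distance:
                continue
            if pool and min(_min_distance(r, pool) for r in rots) < min_inter_distance:
                continue
            codes.append(bits)
            pool.extend(rots)
        self.codes = np.stack(codes)  # (n, 4, 4) uint8
        # decode lookup: 16-bit int of each rotation -> (id, rotation)
        self._lookup: dict[int, tuple[int, int]] = {}
        for mid, grid in enumerate(self.codes):
            for rot in range(4):
                key = self._pack(np.rot90(grid, -rot))
                self._lookup[key] = (mid, rot)

    @staticmethod
    def _pack(grid: np.ndarray) -> int:
        bits = np.asarray(grid, dtype=np.uint8).ravel()
        return int(bits @ (1 << np.arange(bits.size - 1, -1, -1, dtype=np.int64)))

    def grid(self, marker_id: int) -> np.ndarray:
        """The upright 4x4 code grid of ``marker_id`` (1 = white cell)."""
        return self.codes[marker_id].copy()

    def pattern(self, marker_id: int) -> np.ndarray:
        """The 6x6 cell pattern including the black border (float 0/1)."""
        pat = np.zeros((_GRID + 2, _GRID + 2), dtype=float)
        pat[1:-1, 1:-1] = self.codes[marker_id]
        return pat

    def decode(self, grid: np.ndarray) -> tuple[int, int] | None:
        """Decode an observed 4x4 binary grid.

        Returns ``(marker_id, rotation)`` or None.  ``rotation`` is the
        number of quarter turns clockwise by which the observed grid is
        rotated relative to the upright marker: the observed corner that is
        really the marker's top-left corner has index ``(-rotation) % 4``
        ... concretely, rolling the observed corner list left by
        ``rotation`` yields canonical (TL, TR, BR, BL) order.
        """
        key = self._pack(np.asarray(grid, dtype=np.uint8))
        return self._lookup.get(key)

    def __len__(self) -> int:
        return self.n_codes


DICT_4X4_50 = MarkerDictionary()
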