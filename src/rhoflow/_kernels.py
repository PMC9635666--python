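"""Inner loops of the forward simulator.

The only hot loop is the gamete-assembly kernel: given the parent haplotype
matrix and, per gamete, the two parental haplotype rows plus the crossover
breakpoints (already mapped to column indices), copy alternating segments
into the offspring matrix.  All randomness is generated by the caller with
numpy Generators, so the kernel itself is deterministic and the jitted and
pure-Python variants produce identical output.
"""

from __future__ import annotations

import numpy as np


def _copy_gametes_py(parents, row_a, row_b, bp_cols, bp_off, out):
    n_g, n_sites = out.shape
    for g in range(n_g):
        a = row_a[g]
        b = row_b[g]
        prev = 0
        use_a = True
        for j in range(bp_off[g], bp_off[g + 1]):
            cut = bp_cols[j]
            if use_a:
                out[g, prev:cut] = parents[a, prev:cut]
            else:
                out[g, prev:cut] = parents[b, prev:cut]
            use_a = not use_a
            prev = cut
        if use_a:
            out[g, prev:n_sites] = parents[a, prev:n_sites]
        else:
            out[g, prev:n_sites] = parents[b, prev:n_sites]


def _copy_gametes_elem(parents, row_a, row_b, bp_cols, bp_off, out):
    # elementwise variant: faster than slice copies once jitted
    n_g, n_sites = out.shape
    for g in range(n_g):
        a = row_a[g]
        b = row_b[g]
        prev = 0
        use_a = True
        for j in range(bp_off[g], bp_off[g + 1]):
            cut = bp_cols[j]
            src = a if use_a else b
            for s in range(prev, cut):
                out[g, s] = parents[src, s]
            use_a = not use_a
            prev = cut
        src = a if use_a else b
        for s in range(prev, n_sites):
            out[g, s] = parents[src, s]


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    copy_gametes = njit(cache=False)(_copy_gametes_elem)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    copy_gametes = _copy_gametes_py
    HAVE_NUMBA = False


def assemble_gametes(parents: np.ndarray, row_a, row_b, bp_cols, bp_off) -> np.ndarray:
    """Assemble offspring haplotypes from parental rows and breakpoint columns."""
    n_g = len(row_a)
    out = np.empty((n_g, parents.shape[1]), dtype=np.uint8)
    copy_gametes(
        np.ascontiguousarray(parents),
        np.asarray(row_a, dtype=np.int64),
        np.asarray(row_b, dtype=np.int64),
        np.asarray(bp_cols, dtype=np.int64),
        np.asarray(bp_off, dtype=np.int64),
        out,
    )
    return out
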