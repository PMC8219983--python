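"""Minimum-free-energy model for single RNA hairpins.

The internal backend scores single-hairpin structures (one helix, interrupted
by bulges or interior loops, closing one hairpin loop) with the Turner 2004
nearest-neighbor parameters: stacking energies for Watson-Crick and GU pairs,
hairpin-loop initiation by size, hairpin terminal-mismatch terms, and
size-dependent bulge/interior-loop penalties. Multibranch structures,
pseudoknots, dangles and special tetraloop bonuses are outside the model.
The optimum is found by dynamic programming over all nested pairings whose
interior loops hold at most ``max_unpaired`` unpaired bases.

The external backend delegates to the Vienna RNA package's full MFE folder
when its Python bindings are importable.
"""

from __future__ import annotations

import math

import numpy as np

from . import _turner2004 as T
from .errors import ConfigurationError

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit as _njit

    def _jit(fn):
        return _njit(cache=True)(fn)

except ImportError:  # pragma: no cover

    def _jit(fn):
        return fn


INF = 1e9
DEFAULT_MIN_LOOP = 3
DEFAULT_MAX_UNPAIRED = 10  # total unpaired nt allowed in one interior loop

BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3, "N": 4}
_TABLE_SIZE = 4096

_PAIR_IDX = np.full((5, 5), -1, dtype=np.int8)
for _i, (_x, _y) in enumerate([("C", "G"), ("G", "C"), ("G", "U"), ("U", "G"), ("A", "U"), ("U", "A")]):
    _PAIR_IDX[BASE_CODE[_x], BASE_CODE[_y]] = _i

_STACK = np.array(T.STACK, dtype=np.float64)

_HINIT = np.empty(_TABLE_SIZE, dtype=np.float64)
_HINIT[:3] = INF
for _n in range(3, _TABLE_SIZE):
    if _n in T.HAIRPIN_INIT:
        _HINIT[_n] = T.HAIRPIN_INIT[_n]
    else:
        _HINIT[_n] = T.HAIRPIN_INIT[30] + T.LXC * math.log(_n / 30.0)

_MMH = np.zeros((6, 4, 4), dtype=np.float64)
for _i, _name in enumerate(T.PAIR_NAMES):
    _MMH[_i] = np.array(T.MISMATCH_HAIRPIN[_name])

_TRI = np.array([T.TRILOOP_CLOSE[n] for n in T.PAIR_NAMES], dtype=np.float64)

_BULGE = np.empty(_TABLE_SIZE, dtype=np.float64)
_BULGE[0] = INF
for _n in range(1, _TABLE_SIZE):
    if _n in T.BULGE_INIT:
        _BULGE[_n] = T.BULGE_INIT[_n]
    else:
        _BULGE[_n] = T.BULGE_INIT[6] + T.LXC * math.log(_n / 6.0)

_INTERIOR = np.empty(_TABLE_SIZE, dtype=np.float64)
_INTERIOR[:2] = INF
for _n in range(2, _TABLE_SIZE):
    if _n in T.INTERIOR_INIT:
        _INTERIOR[_n] = T.INTERIOR_INIT[_n]
    else:
        _INTERIOR[_n] = T.INTERIOR_INIT[6] + T.LXC * math.log(_n / 6.0)


def encode(seq: str) -> np.ndarray:
    """Encode DNA/RNA to the internal integer alphabet (A0 C1 G2 U/T3 N4)."""
    try:
        return np.array([BASE_CODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as e:  # pragma: no cover - guarded upstream
        raise ValueError(f"illegal base {e.args[0]!r}") from None


def pairable(x: str, y: str, allow_GU: bool = True) -> bool:
    """Can bases x (5') and y (3') pair (Watson-Crick, optionally GU)?"""
    idx = _PAIR_IDX[BASE_CODE[x], BASE_CODE[y]]
    if idx < 0:
        return False
    if not allow_GU and idx in (2, 3):
        return False
    return True


@_jit
def _fold_dp(s, min_loop, max_unpaired, stack, hinit, mmh, tri, bulge, interior,
             asym, asym_max, pair_idx):
    n = s.size
    V = np.full((n, n), INF)
    TBI = np.full((n, n), -1, dtype=np.int32)
    TBJ = np.full((n, n), -1, dtype=np.int32)
    for i in range(n - min_loop - 2, -1, -1):
        for j in range(i + min_loop + 1, n):
            pt = pair_idx[s[i], s[j]]
            if pt < 0:
                continue
            lsize = j - i - 1
            li = lsize if lsize < hinit.size else hinit.size - 1
            e = hinit[li]
            if lsize == 3:
                e += tri[pt]
            elif s[i + 1] < 4 and s[j - 1] < 4:
                e += mmh[pt, s[i + 1], s[j - 1]]
            best = e
            bi = -1
            bj = -1
            for d1 in range(0, max_unpaired + 1):
                ip = i + 1 + d1
                if ip >= j:
                    break
                for d2 in range(0, max_unpaired + 1 - d1):
                    jp = j - 1 - d2
                    if jp - ip <= min_loop:
                        break
                    if V[ip, jp] >= INF / 2:
                        continue
                    if d1 == 0 and d2 == 0:
                        le = stack[pt, pair_idx[s[ip], s[jp]]]
                    elif d1 == 0 or d2 == 0:
                        k = d1 + d2
                        le = bulge[k]
                        if k == 1:  # single-nt bulge keeps coaxial stacking
                            le += stack[pt, pair_idx[s[ip], s[jp]]]
                    else:
                        a = asym * abs(d1 - d2)
                        if a > asym_max:
                            a = asym_max
                        le = interior[d1 + d2] + a
                    if V[ip, jp] + le < best:
                        best = V[ip, jp] + le
                        bi = ip
                        bj = jp
            V[i, j] = best
            TBI[i, j] = bi
            TBJ[i, j] = bj
    bi = -1
    bj = -1
    be = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if V[i, j] < be:
                be = V[i, j]
                bi = i
                bj = j
    return V, TBI, TBJ, bi, bj, be


def fold_hairpin(
    seq: str,
    backend: str = "internal",
    min_loop: int = DEFAULT_MIN_LOOP,
    max_unpaired: int = DEFAULT_MAX_UNPAIRED,
) -> tuple[str, float]:
    """Fold one sequence into its best single hairpin.

    Returns ``(structure, dG)`` with the structure in dot-bracket notation and
    dG in kcal/mol. A sequence with no favorable pairing returns all dots and
    dG = 0.0.
    """
    if backend == "external":
        return _fold_external(seq)
    if backend != "internal":
        raise ConfigurationError(f"unknown folding backend {backend!r}")
    n = len(seq)
    if n == 0:
        return "", 0.0
    s = encode(seq)
    _, TBI, TBJ, bi, bj, be = _fold_dp(
        s, min_loop, max_unpaired, _STACK, _HINIT, _MMH, _TRI, _BULGE,
        _INTERIOR, T.INTERIOR_ASYM, T.INTERIOR_ASYM_MAX, _PAIR_IDX,
    )
    if bi < 0 or be >= 0.0:
        return "." * n, 0.0
    structure = ["."] * n
    i, j = bi, bj
    while i >= 0:
        structure[i] = "("
        structure[j] = ")"
        i, j = TBI[i, j], TBJ[i, j]
    return "".join(structure), round(float(be), 2)


def _fold_external(seq: str) -> tuple[str, float]:
    try:
        import RNA
    except ImportError:
        raise ConfigurationError(
            "the external backend needs the Vienna RNA Python bindings "
            "(import RNA); install the viennarna package or fall back to "
            "backend='internal'"
        ) from None
    structure, dg = RNA.fold(seq.upper().replace("T", "U"))
    return structure, round(float(dg), 2)


# --- direct scoring of explicit pairings (shared with the test oracles) ----


def score_hairpin(seq: str, pairs: list[tuple[int, int]]) -> float:
    """Energy of an explicit single-hairpin pairing under the same tables.

    ``pairs`` is the nested pair list ``[(i0,j0), (i1,j1), ...]`` ordered from
    outermost to innermost (0-based). Raises ValueError for invalid nesting or
    unpairable bases.
    """
    if not pairs:
        return 0.0
    s = encode(seq)
    for k in range(1, len(pairs)):
        (pi, pj), (ci, cj) = pairs[k - 1], pairs[k]
        if not (pi < ci <= cj < pj):
            raise ValueError("pairs are not properly nested")
    e = 0.0
    for (i, j) in pairs:
        if _PAIR_IDX[s[i], s[j]] < 0:
            raise ValueError(f"bases {i},{j} cannot pair")
    for k in range(1, len(pairs)):
        (i, j), (ip, jp) = pairs[k - 1], pairs[k]
        pt = _PAIR_IDX[s[i], s[j]]
        d1, d2 = ip - i - 1, j - jp - 1
        if d1 == 0 and d2 == 0:
            e += _STACK[pt, _PAIR_IDX[s[ip], s[jp]]]
        elif d1 == 0 or d2 == 0:
            k2 = d1 + d2
            e += _BULGE[min(k2, _TABLE_SIZE - 1)]
            if k2 == 1:
                e += _STACK[pt, _PAIR_IDX[s[ip], s[jp]]]
        else:
            e += _INTERIOR[min(d1 + d2, _TABLE_SIZE - 1)] + min(
                T.INTERIOR_ASYM * abs(d1 - d2), T.INTERIOR_ASYM_MAX
            )
    ci, cj = pairs[-1]
    lsize = cj - ci - 1
    if lsize < 3:
        raise ValueError("hairpin loop shorter than 3 nt")
    pt = _PAIR_IDX[s[ci], s[cj]]
    e += _HINIT[min(lsize, _TABLE_SIZE - 1)]
    if lsize == 3:
        e += _TRI[pt]
    elif s[ci + 1] < 4 and s[cj - 1] < 4:
        e += _MMH[pt, s[ci + 1], s[cj - 1]]
    return round(float(e), 2)


def structure_from_pairs(n: int, pairs: list[tuple[int, int]]) -> str:
    out = ["."] * n
    for i, j in pairs:
        out[i] = "("
        out[j] = ")"
    return "".join(out)
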