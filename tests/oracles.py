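"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: plain-string scanning, exhaustive
recursion over pairings (sharing only the published energy tables with the
implementation), and O(genes x positions) interval classification.
"""

from __future__ import annotations

from slofe.energy import score_hairpin

_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_GU = {("G", "T"), ("T", "G")}


def _pairs(x: str, y: str, allow_gu: bool = True) -> bool:
    return (x, y) in _PAIRS or (allow_gu and (x, y) in _GU)


def enumerate_candidates(seq: str, stem_min=6, stem_max=40, loop_min=3,
                         loop_max=30, allow_gu=True, max_mismatch=2):
    """All maximal hairpin candidate spans on one strand (0-based inclusive).

    Re-derives the scan semantics by explicit simulation over every possible
    loop window, without the implementation's data structures.
    """
    seq = seq.upper().replace("U", "T")
    found = set()
    n = len(seq)
    for loop in range(loop_min, loop_max + 1):
        for lstart in range(1, n - loop):
            i, j = lstart - 1, lstart + loop
            if j >= n or not _pairs(seq[i], seq[j], allow_gu):
                continue
            pairs, mismatches = 1, 0
            oi, oj = i, j
            while pairs < stem_max and i - 1 >= 0 and j + 1 < n:
                i, j = i - 1, j + 1
                if _pairs(seq[i], seq[j], allow_gu):
                    pairs += 1
                    oi, oj = i, j
                elif mismatches < max_mismatch:
                    mismatches += 1
                else:
                    break
            if pairs >= stem_min and "N" not in seq[oi : oj + 1]:
                found.add((oi, oj))
    return found


def enumerate_hairpins(seq: str, min_loop=3, max_unpaired=10):
    """Exhaustively score every nested single-hairpin pairing.

    Returns (best_energy, best_pairs); (0.0, []) when nothing beats the open
    chain. Exponential - keep sequences short.
    """
    n = len(seq)
    pseq = seq.upper().replace("U", "T")  # pairing checks are alphabet-blind
    best = [0.0, []]

    def extend(chain):
        e = score_hairpin(seq, chain)
        if e < best[0]:
            best[0], best[1] = e, list(chain)
        i, j = chain[-1]
        for d1 in range(0, max_unpaired + 1):
            ip = i + 1 + d1
            if ip >= j:
                break
            for d2 in range(0, max_unpaired + 1 - d1):
                jp = j - 1 - d2
                if jp - ip <= min_loop:
                    break
                if _pairs(pseq[ip], pseq[jp]):
                    chain.append((ip, jp))
                    extend(chain)
                    chain.pop()

    for i in range(n):
        for j in range(i + min_loop + 1, n):
            if _pairs(pseq[i], pseq[j]):
                extend([(i, j)])
    return best[0], best[1]


def classify_interval(sl_start, sl_end, genes):
    """Positional category by explicit case analysis over gene intervals.

    ``genes`` is a list of (start, end, strand) tuples, 1-based inclusive.
    """
    over = [g for g in genes if not (sl_end < g[0] or sl_start > g[1])]
    if not over:
        return "intergenic"
    if len(over) > 1:
        return "overlapped_with_two_genes"
    gs, ge, strand = over[0]
    if sl_start >= gs and sl_end <= ge:
        return "intragenic"
    crosses_right = sl_end > ge
    crosses_left = sl_start < gs
    if strand == "+":
        return "overlapped_on_3" if crosses_right else "overlapped_on_5"
    return "overlapped_on_3" if crosses_left else "overlapped_on_5"
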