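"""Post-processing of raw stem-loops: flank trimming, redundancy removal,
the free-energy floor, downstream-U features and stability scoring.

The stability factors rank a stem-loop by free-energy density:

    S1 = dG            S2 = dG / L        S3 = dG * sl       S4 = dG * sl / L

with L the stem-loop length and sl the stem length (paired positions on one
side). Scores are normalized against the cohort minimum (the most stable SL
scores 1) and the stable set is the fraction above a normalized threshold.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discovery import StemLoop
from .errors import EmptyStemLoopError
from .io import GenomeRecord

DG_FLOOR = -5.0  # retain only dG strictly below this (kcal/mol)
STABLE_THRESHOLD = 0.60
U_WINDOW = 10  # nt immediately 3' of the stem-loop

#: tail-position taxonomy; "downstream" = a poly(U) run of >=4 starting within
#: the first DOWNSTREAM_RUN_START window positions; "upstream" = >=4 U paired
#: within the lower UPSTREAM_STEM_FRACTION of the 3' stem side; "discontinuous"
#: = >=4 U in the window scattered in runs of 2-3.
DOWNSTREAM_RUN_START = 3
DOWNSTREAM_MIN_RUN = 4
UPSTREAM_STEM_FRACTION = 0.40
UPSTREAM_MIN_U = 4
DISCONTINUOUS_MIN_U = 4
DISCONTINUOUS_MIN_RUN = 2


@dataclass(frozen=True)
class UFeatures:
    polyU_len: int
    U_content: int
    window: str  # RNA, 5'->3' on the SL's strand; may be shorter at contig end
    tail_position: str  # downstream | upstream | discontinuous | none

    def __post_init__(self):
        if not (0 <= self.polyU_len <= self.U_content <= U_WINDOW):
            raise ValueError("need 0 <= polyU_len <= U_content <= window size")


@dataclass(frozen=True)
class StabilityScores:
    S1: float
    S2: float
    S3: float
    S4: float


def trim_flanks(sl: StemLoop) -> StemLoop:
    """Remove unpaired positions outside the outermost pair.

    Idempotent; coordinates are updated strand-aware so the trimmed SL still
    maps to the same genomic bases.
    """
    st = sl.structure
    lead = st.find("(")
    if lead < 0:
        raise EmptyStemLoopError(f"{sl.id}: structure has no pairs")
    trail = len(st) - 1 - st.rfind(")")
    if lead == 0 and trail == 0:
        return sl
    if sl.strand == "+":
        start, end = sl.start + lead, sl.end - trail
    else:
        start, end = sl.start + trail, sl.end - lead
    return dataclasses.replace(
        sl,
        id=f"SL_{sl.contig}_{start}_{end}_{sl.strand}",
        start=start,
        end=end,
        sequence=sl.sequence[lead : len(st) - trail],
        structure=st[lead : len(st) - trail],
    )


def _overlap(a: StemLoop, b: StemLoop) -> int:
    return min(a.end, b.end) - max(a.start, b.start) + 1


def _is_redundant_pair(a: StemLoop, b: StemLoop, overlap_frac: float, mismatch_nt: int) -> bool:
    if a.contig != b.contig or a.strand != b.strand:
        return False
    ov = _overlap(a, b)
    if ov <= 0:
        return False
    if ov / min(a.total_len, b.total_len) > overlap_frac:
        return True
    # aligned-overlap Hamming distance; same-genome same-strand overlaps are
    # identical sequence, so any overlap is a near-duplicate under the <3 rule
    return 0 < mismatch_nt
    # (kept explicit: a nonzero mismatch_nt merges, mismatch_nt=0 disables)


def deduplicate(
    sls: list[StemLoop],
    dg_max: float = DG_FLOOR,
    overlap_frac: float = 0.75,
    mismatch_nt: int = 3,
) -> list[StemLoop]:
    """Apply the four redundancy/quality rules.

    (i) drop SLs whose span is contained in another same-strand SL,
    (ii) drop duplicates of identical (sequence, structure),
    (iii) among partially overlapping same-strand SLs (overlap fraction of the
    shorter > ``overlap_frac``, or aligned-overlap Hamming distance <
    ``mismatch_nt``) keep the lower-dG member, and (iv) keep only SLs with
    dG strictly below ``dg_max``. Conflicts are resolved most-stable-first
    (ties: 5'-most), which makes the operation idempotent and order-free.
    """
    kept_sig: set[tuple] = set()
    pool = []
    for sl in sls:
        if sl.dG >= dg_max:
            continue
        sig = (sl.contig, sl.strand, sl.sequence, sl.structure)
        pool.append((sig, sl))
    # identical (sequence, structure): keep the 5'-most
    best_by_sig: dict[tuple, StemLoop] = {}
    for sig, sl in pool:
        cur = best_by_sig.get(sig)
        if cur is None or (sl.start, sl.end) < (cur.start, cur.end):
            best_by_sig[sig] = sl
    unique = sorted(best_by_sig.values(), key=lambda s: (s.dG, s.start, s.end, s.strand))
    accepted: dict[tuple[str, str], list[StemLoop]] = {}
    out = []
    for sl in unique:
        key = (sl.contig, sl.strand)
        conflict = any(
            _is_redundant_pair(sl, other, overlap_frac, mismatch_nt)
            for other in accepted.get(key, ())
        )
        if not conflict:
            accepted.setdefault(key, []).append(sl)
            out.append(sl)
    out.sort(key=lambda s: (s.contig, s.start, s.end, s.strand))
    return out


def _longest_u_run(window: str) -> tuple[int, int]:
    """(length, 1-based start) of the first longest U run; (0, 0) if none."""
    best_len, best_start = 0, 0
    i = 0
    while i < len(window):
        if window[i] == "U":
            j = i
            while j < len(window) and window[j] == "U":
                j += 1
            if j - i > best_len:
                best_len, best_start = j - i, i + 1
            i = j
        else:
            i += 1
    return best_len, best_start


def _stem_3prime_positions(sl: StemLoop) -> list[int]:
    """Indices (into sl.sequence) of ')' positions, outermost (3'-most) first."""
    return [i for i in range(len(sl.structure) - 1, -1, -1) if sl.structure[i] == ")"]


def u_features(sl: StemLoop, genome: GenomeRecord) -> UFeatures:
    """U features in the 10-nt window immediately 3' of the (trimmed) SL."""
    if sl.strand == "+":
        lo, hi = sl.end + 1, min(sl.end + U_WINDOW, genome.length)
    else:
        lo, hi = max(sl.start - U_WINDOW, 1), sl.start - 1
    window = genome.subseq(lo, hi, sl.strand).replace("T", "U") if lo <= hi else ""
    run_len, run_start = _longest_u_run(window)
    u_content = window.count("U")
    if run_len >= DOWNSTREAM_MIN_RUN and 1 <= run_start <= DOWNSTREAM_RUN_START:
        tail = "downstream"
    elif _upstream_stem_u(sl) >= UPSTREAM_MIN_U:
        tail = "upstream"
    elif u_content >= DISCONTINUOUS_MIN_U and DISCONTINUOUS_MIN_RUN <= run_len < DOWNSTREAM_MIN_RUN:
        tail = "discontinuous"
    else:
        tail = "none"
    return UFeatures(run_len, u_content, window, tail)


def _upstream_stem_u(sl: StemLoop, fraction: float = UPSTREAM_STEM_FRACTION) -> int:
    """U count among the lower (tail-proximal) fraction of the 3' stem side."""
    pos3 = _stem_3prime_positions(sl)
    if not pos3:
        return 0
    k = max(1, int(np.ceil(fraction * len(pos3))))
    return sum(1 for i in pos3[:k] if sl.sequence[i] in "UT")


def stability_scores(sl: StemLoop) -> StabilityScores:
    L = sl.total_len
    stem = sl.stem_len
    if L <= 0 or stem <= 0:
        raise ValueError(f"{sl.id}: stem and total length must be positive")
    dg = sl.dG
    return StabilityScores(S1=dg, S2=dg / L, S3=dg * stem, S4=dg * stem / L)


def attach_scores(sls: list[StemLoop]) -> list[StemLoop]:
    """Compute S1..S4 and the cohort-normalized S4 for every SL."""
    scored = []
    for sl in sls:
        s = stability_scores(sl)
        scored.append(dataclasses.replace(sl, S1=s.S1, S2=s.S2, S3=s.S3, S4=s.S4))
    s4min = min((sl.S4 for sl in scored), default=0.0)
    for i, sl in enumerate(scored):
        scored[i] = dataclasses.replace(
            sl, S4_norm=1.0 if s4min == 0 else sl.S4 / s4min
        )
    return scored


def normalized_score(sls: list[StemLoop], score: str = "S4") -> list[float]:
    """score / cohort minimum, so the most stable SL scores 1.0."""
    vals = [getattr(sl, score) for sl in sls]
    if any(v is None for v in vals):
        raise ValueError("stability scores not attached; call attach_scores first")
    vmin = min(vals, default=0.0)
    if vmin == 0:
        return [1.0 for _ in vals]
    return [v / vmin for v in vals]


def select_stable(
    sls: list[StemLoop],
    score: str = "S4",
    threshold: float = STABLE_THRESHOLD,
) -> list[StemLoop]:
    """Retain SLs whose normalized stability score is >= threshold."""
    if not sls:
        return []
    norm = normalized_score(sls, score)
    return [sl for sl, v in zip(sls, norm) if v >= threshold]


def enrichment_per_100(sls: list[StemLoop], score: str = "S4") -> pd.DataFrame:
    """Intergenic fraction among top-ranked SLs, in rank windows of 100.

    Diagnostic table behind the stable-SL threshold choice: SLs are ranked by
    normalized score and the share of intergenic SLs is reported per window.
    Requires positional categories to be attached.
    """
    if any(sl.category is None for sl in sls):
        raise ValueError("positional categories not attached")
    norm = normalized_score(sls, score)
    order = np.argsort(norm)[::-1]
    rows = []
    for w0 in range(0, len(sls), 100):
        idx = order[w0 : w0 + 100]
        inter = sum(1 for i in idx if sls[i].category == "intergenic")
        rows.append(
            {
                "rank_from": w0 + 1,
                "rank_to": w0 + len(idx),
                "n_intergenic": inter,
                "fraction_intergenic": inter / len(idx),
                "min_normalized_score": float(min(norm[i] for i in idx)),
            }
        )
    return pd.DataFrame(rows)
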