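"""Local nucleotide alignment engine for reference-gene and spacer searches.

The presence/absence semantics of the pipeline rest on finding, for a short
query (a reference gene, a CRISPR spacer, a cas gene), its best local
alignment within one or more strain contigs, and summarising it as

* ``identity``  -- matching columns / alignment columns of the best local
  alignment, in [0, 1];
* ``coverage``  -- fraction of query bases included in that alignment.

Two routes produce the same summary:

* **direct route** (targets up to ``direct_limit`` bp): an exact affine-gap
  Smith-Waterman over the full query x target matrix, with a fixed,
  documented tie-break so results are bit-reproducible;
* **anchored route** (long targets): candidate loci are found by sampled
  k-mer anchoring (falling back to a bit-vector edit-distance scan of the
  whole contig), and the best-scoring local segment is extracted from the
  alignment path within a window around each locus.

Scoring is BLAST-like: match +2, mismatch -3, gap open -5 (charged on the
first gap base), gap extend -2.  ``N`` never matches anything, including
another ``N``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple, Sequence

import edlib
import numpy as np
from numba import njit


class Scoring(NamedTuple):
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5      # score of the first base of a gap
    gap_extend: int = -2    # score of each further gap base


DEFAULT_SCORING = Scoring()

#: targets at or below this length take the exact full-matrix route
DIRECT_LIMIT = 4000

#: anchor k-mer size and sampling stride for the long-target route
ANCHOR_K = 12
ANCHOR_STRIDE = 4
#: minimum anchors on one diagonal band to accept a candidate window
MIN_ANCHOR_CLUSTER = 2
#: queries shorter than this skip k-mer anchoring (edlib scan is cheap there)
MIN_ANCHOR_QUERY = 100

_NEG = np.int32(-(10 ** 8))

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class LocalHit:
    """Summary of the best local alignment of a query against a contig set."""

    identity: float
    coverage: float
    score: int
    contig_index: int = -1
    strand: str = "+"
    t_start: int = -1          # 0-based, inclusive
    t_end: int = -1            # 0-based, exclusive
    q_start: int = 0
    q_end: int = 0
    substitution_only: bool = False

    @property
    def empty(self) -> bool:
        return self.score <= 0


_NO_HIT = LocalHit(identity=0.0, coverage=0.0, score=0)


# ---------------------------------------------------------------------------
# exact affine Smith-Waterman (direct route)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sw_fill(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n = q.shape[0]
    m = t.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e = E[i, j - 1] + gap_extend
            eh = H[i, j - 1] + gap_open
            if eh > e:
                e = eh
            E[i, j] = e
            f = F[i - 1, j] + gap_extend
            fh = H[i - 1, j] + gap_open
            if fh > f:
                f = fh
            F[i, j] = f
            if qi == t[j - 1] and qi < 4:
                s = match
            else:
                s = mismatch
            h = H[i - 1, j - 1] + s
            if h < e:
                h = e
            if h < f:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


def sw_align(q: np.ndarray, t: np.ndarray,
             scoring: Scoring = DEFAULT_SCORING) -> LocalHit:
    """Exact local alignment of encoded query vs encoded target.

    Ties are broken deterministically: the end cell is the first maximum in
    row-major order, and the traceback prefers diagonal moves, then gaps in
    the target (query-consuming), then gaps in the query.
    """
    if len(q) == 0 or len(t) == 0:
        return _NO_HIT
    H, E, F, best, bi, bj = _sw_fill(
        q, t, scoring.match, scoring.mismatch,
        scoring.gap_open, scoring.gap_extend)
    if best <= 0:
        return _NO_HIT
    i, j = bi, bj
    state = 0  # 0=H 1=F 2=E
    matches = 0
    columns = 0
    while True:
        if state == 0:
            h = H[i, j]
            if h == 0:
                break
            eq = q[i - 1] == t[j - 1] and q[i - 1] < 4
            s = scoring.match if eq else scoring.mismatch
            if h == H[i - 1, j - 1] + s:
                columns += 1
                if eq:
                    matches += 1
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = 1
            elif h == E[i, j]:
                state = 2
            else:  # pragma: no cover - defensive
                raise RuntimeError("inconsistent traceback")
        elif state == 1:  # gap in target, consume query
            columns += 1
            if F[i, j] == H[i - 1, j] + scoring.gap_open:
                state = 0
            i -= 1
        else:  # gap in query, consume target
            columns += 1
            if E[i, j] == H[i, j - 1] + scoring.gap_open:
                state = 0
            j -= 1
    q_start, t_start = i, j
    identity = matches / columns if columns else 0.0
    coverage = (bi - q_start) / len(q)
    return LocalHit(identity=identity, coverage=coverage, score=int(best),
                    t_start=t_start, t_end=bj, q_start=q_start, q_end=bi,
                    substitution_only=(columns == bi - q_start == bj - t_start))


# ---------------------------------------------------------------------------
# long-target route: locate, then extract the best local segment of the path
# ---------------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _parse_cigar(cigar: str) -> list[tuple[str, int]]:
    return [(op, int(num)) for num, op in _CIGAR_RE.findall(cigar)]


def _best_path_segment(runs: Sequence[tuple[str, int]], q_len: int,
                       t_offset: int, scoring: Scoring) -> LocalHit | None:
    """Best-scoring contiguous sub-alignment of an edlib path.

    Boundaries are constrained to lie on ``=`` runs (a local optimum never
    starts or ends on a mismatch or gap), which makes a run-level Kadane
    scan exact for this path.
    """
    # per-run score and query/target consumption
    scores = []
    for op, ln in runs:
        if op == "=":
            scores.append(scoring.match * ln)
        elif op == "X":
            scores.append(scoring.mismatch * ln)
        else:  # I (query only) or D (target only)
            scores.append(scoring.gap_open + scoring.gap_extend * (ln - 1))
    best_sum = 0
    best_span = None
    cur = 0
    cur_start = -1
    for idx, (op, ln) in enumerate(runs):
        if op == "=":
            if cur_start < 0 or cur < 0:
                cur = 0
                cur_start = idx
            cur += scores[idx]
            if cur > best_sum:
                best_sum = cur
                best_span = (cur_start, idx)
        elif cur_start >= 0:
            cur += scores[idx]
    if best_span is None:
        return None
    first, last = best_span
    q_pos = 0
    t_pos = 0
    q_start = t_start = 0
    matches = columns = 0
    q_end = t_end = 0
    for idx, (op, ln) in enumerate(runs):
        if idx == first:
            q_start, t_start = q_pos, t_pos
        if first <= idx <= last:
            columns += ln
            if op == "=":
                matches += ln
        if op in "=XI":
            q_pos += ln
        if op in "=XD":
            t_pos += ln
        if idx == last:
            q_end, t_end = q_pos, t_pos
            break
    sub_only = all(op in "=X" for op, _ in runs[first:last + 1])
    return LocalHit(identity=matches / columns, coverage=(q_end - q_start) / q_len,
                    score=int(best_sum), t_start=t_offset + t_start,
                    t_end=t_offset + t_end, q_start=q_start, q_end=q_end,
                    substitution_only=sub_only)


def _align_window(q_str: str, window: str, w_offset: int,
                  scoring: Scoring) -> LocalHit | None:
    k = max(20, int(0.45 * len(q_str)))
    res = edlib.align(q_str, window, mode="HW", task="path", k=k)
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    cigar = res["cigar"]
    if "I" in cigar or "D" in cigar:
        # the unit-cost edit path can tie-break through indels where the
        # affine-gap optimum keeps substitutions; refine gapped windows
        # with the exact kernel
        hit = sw_align(encode(q_str), encode(window), scoring)
        if hit.empty:
            return None
        return LocalHit(identity=hit.identity, coverage=hit.coverage,
                        score=hit.score, t_start=w_offset + hit.t_start,
                        t_end=w_offset + hit.t_end, q_start=hit.q_start,
                        q_end=hit.q_end,
                        substitution_only=hit.substitution_only)
    loc = res["locations"][0]
    runs = _parse_cigar(cigar)
    return _best_path_segment(runs, len(q_str), w_offset + loc[0], scoring)


def semiglobal_identity(query: str, contigs: Sequence[str],
                        max_divergence: float = 0.25) -> float:
    """Identity of the best end-to-end (infix) placement of ``query``.

    The whole query is aligned inside each contig (both strands); the
    returned identity is matches / alignment columns of the best
    placement.  Unlike the local route nothing is trimmed, so edge
    mismatches lower identity instead of coverage.  Placements needing
    more than ``max_divergence`` x query-length edits return 0.0.
    """
    best = 0.0
    k = max(6, int(max_divergence * len(query)))
    for q_str in (query.upper(), revcomp(query.upper())):
        for contig in contigs:
            res = edlib.align(q_str, contig.upper(), mode="HW", task="path", k=k)
            if res["editDistance"] < 0 or not res.get("cigar"):
                continue
            runs = _parse_cigar(res["cigar"])
            columns = sum(ln for _, ln in runs)
            matches = sum(ln for op, ln in runs if op == "=")
            if columns:
                best = max(best, matches / columns)
    return best


class _ContigIndex:
    """Sorted sampled k-mer index over one (forward-strand) contig."""

    def __init__(self, codes: np.ndarray, valid: np.ndarray, k: int):
        self.k = k
        pos = np.nonzero(valid)[0].astype(np.int64)
        kept = codes[pos]
        order = np.argsort(kept, kind="stable")
        self.sorted_codes = kept[order]
        self.positions = pos[order]

    def anchor_offsets(self, q_codes: np.ndarray, q_pos: np.ndarray,
                       max_hits_per_kmer: int = 64) -> np.ndarray:
        left = np.searchsorted(self.sorted_codes, q_codes, side="left")
        right = np.searchsorted(self.sorted_codes, q_codes, side="right")
        counts = right - left
        single = counts == 1
        parts = [self.positions[left[single]] - q_pos[single]]
        multi = np.nonzero((counts > 1) & (counts <= max_hits_per_kmer))[0]
        for i in multi:
            parts.append(self.positions[left[i]:right[i]] - q_pos[i])
        return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)


def _kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling 2-bit codes of all k-mers; ``valid`` is False where any N."""
    n = len(enc)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    base = np.minimum(enc, 3).astype(np.int64)
    codes = np.zeros(n - k + 1, dtype=np.int64)
    for off in range(k):
        codes = (codes << 2) | base[off:off + n - k + 1]
    ok = (enc < 4)
    valid = np.ones(n - k + 1, dtype=bool)
    for off in range(k):
        valid &= ok[off:off + n - k + 1]
    return codes, valid


def _cluster_windows(offsets: np.ndarray, q_len: int, t_len: int,
                     max_windows: int = 2,
                     min_cluster: int = MIN_ANCHOR_CLUSTER) -> list[tuple[int, int]]:
    """Group anchor offsets into diagonal bands; return candidate windows.

    Bands carried by fewer than ``min_cluster`` anchors are discarded:
    isolated k-mer hits on a 2-bit alphabet arise by chance even against
    unrelated sequence.
    """
    if len(offsets) == 0:
        return []
    offsets = np.sort(offsets)
    tol = max(32, q_len // 5)
    breaks = np.nonzero(np.diff(offsets) > tol)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(offsets) - 1]))
    sizes = ends - starts + 1
    order = np.argsort(sizes, kind="stable")[::-1][:max_windows]
    margin = q_len // 6 + 48
    windows = []
    for ci in order:
        if sizes[ci] < min_cluster:
            continue
        lo = int(offsets[starts[ci]])
        hi = int(offsets[ends[ci]])
        w_lo = max(0, lo - margin)
        w_hi = min(t_len, hi + q_len + margin)
        if w_hi > w_lo:
            windows.append((w_lo, w_hi))
    return windows


@lru_cache(maxsize=4096)
def _revcomp_cached(seq: str) -> str:
    return revcomp(seq)


@lru_cache(maxsize=4096)
def _sampled_query_kmers(q_str: str, stride: int) -> tuple[np.ndarray, np.ndarray]:
    """Sampled (codes, query positions) of a query's anchor k-mers, memoised
    so repeated searches of the same gene across strains reuse them."""
    q_codes, q_valid = _kmer_codes(encode(q_str), ANCHOR_K)
    sel = np.arange(0, len(q_codes), stride)
    sel = sel[q_valid[sel]]
    return q_codes[sel], sel


class SequenceSearcher:
    """Reusable searcher for short queries against a strain's contigs.

    Builds per-contig k-mer indexes lazily; small contigs take the exact
    Smith-Waterman route, long contigs the anchored route.  Both query
    orientations are always searched; on ties the forward strand and the
    earlier contig win.
    """

    def __init__(self, contigs: Sequence[str],
                 scoring: Scoring = DEFAULT_SCORING,
                 direct_limit: int = DIRECT_LIMIT):
        if not contigs or any(len(c) == 0 for c in contigs):
            raise ValueError("strain must supply at least one non-empty contig")
        self.contigs = [c.upper() for c in contigs]
        self.scoring = scoring
        self.direct_limit = direct_limit
        self._encoded = [encode(c) for c in self.contigs]
        self._indexes: dict[int, _ContigIndex] = {}

    def _index(self, ci: int) -> _ContigIndex:
        if ci not in self._indexes:
            codes, valid = _kmer_codes(self._encoded[ci], ANCHOR_K)
            self._indexes[ci] = _ContigIndex(codes, valid, ANCHOR_K)
        return self._indexes[ci]

    def _anchor_windows(self, q_str: str, ci: int,
                        stride: int = ANCHOR_STRIDE) -> list[tuple[int, int]]:
        codes, positions = _sampled_query_kmers(q_str, stride)
        if not len(codes):
            return []
        offs = self._index(ci).anchor_offsets(codes, positions)
        return _cluster_windows(offs, len(q_str), len(self.contigs[ci]))

    #: the whole-contig scan abandons beyond this query-length fraction of
    #: edits; a more diverged copy on a long contig is reported as absent
    SCAN_MAX_DIVERGENCE = 0.35

    def _scan_window(self, q_str: str, ci: int) -> list[tuple[int, int]]:
        contig = self.contigs[ci]
        k = max(12, int(self.SCAN_MAX_DIVERGENCE * len(q_str)))
        res = edlib.align(q_str, contig, mode="HW", task="locations", k=k)
        if res["editDistance"] < 0:
            return []
        loc = res["locations"][0]
        margin = len(q_str) // 2 + 48
        return [(max(0, loc[0] - margin), min(len(contig), loc[1] + 1 + margin))]

    def _eval_windows(self, q_str: str, ci: int,
                      windows: Sequence[tuple[int, int]]) -> LocalHit | None:
        best: LocalHit | None = None
        for w_lo, w_hi in windows:
            hit = _align_window(q_str, self.contigs[ci][w_lo:w_hi], w_lo,
                                self.scoring)
            if hit is not None and (best is None or hit.score > best.score):
                best = hit
            # a near-full-length, high-identity hit cannot be improved by
            # a smaller anchor cluster
            if best is not None and best.coverage >= 0.99 and best.identity >= 0.9:
                break
        return best

    def best_local(self, query: str) -> LocalHit:
        """Best local alignment of ``query`` over all contigs and strands.

        Long contigs are searched by k-mer anchoring: a query that leaves
        no anchor cluster on either strand (no locus at roughly 70%
        identity or better) is reported as having no hit.  Queries too
        short to anchor fall back to a banded whole-contig scan instead.
        Small contigs always take the exact full-matrix route.
        """
        if not query:
            raise ValueError("empty query sequence")
        query = query.upper()
        orientations = (("+", query), ("-", _revcomp_cached(query)))
        best = _NO_HIT

        def consider(hit: LocalHit | None, ci: int, strand: str) -> None:
            nonlocal best
            if hit is not None and hit.score > best.score:
                best = LocalHit(
                    identity=hit.identity, coverage=hit.coverage,
                    score=hit.score, contig_index=ci, strand=strand,
                    t_start=hit.t_start, t_end=hit.t_end,
                    q_start=hit.q_start, q_end=hit.q_end,
                    substitution_only=hit.substitution_only)

        long_targets: list[int] = []
        for ci, contig in enumerate(self.contigs):
            if len(contig) <= self.direct_limit:
                for strand, q_str in orientations:
                    consider(sw_align(encode(q_str), self._encoded[ci],
                                      self.scoring), ci, strand)
            else:
                long_targets.append(ci)
        if not long_targets:
            return best
        if len(query) < MIN_ANCHOR_QUERY:
            for ci in long_targets:
                for strand, q_str in orientations:
                    windows = self._scan_window(q_str, ci)
                    consider(self._eval_windows(q_str, ci, windows), ci, strand)
            return best
        # sparse anchoring first; densify only when nothing anchored anywhere
        for stride in (ANCHOR_STRIDE, 1):
            anchored = False
            for ci in long_targets:
                for strand, q_str in orientations:
                    windows = self._anchor_windows(q_str, ci, stride)
                    if windows:
                        anchored = True
                        consider(self._eval_windows(q_str, ci, windows),
                                 ci, strand)
            if anchored:
                break
        return best
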