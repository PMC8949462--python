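"""Local alignment kernel: affine-gap Smith-Waterman, k-mer seeding, E-values.

The dynamic program is jit-compiled with numba.  Gap convention follows the
usual pairwise-aligner one: a gap of length L costs ``gap_open`` for its first
column and ``gap_extend`` for each of the L-1 further columns (both scores are
non-positive).

Statistical significance uses the Karlin-Altschul formula
``E = K * m * n * exp(-lambda * S)`` with (lambda, K) fixed per scoring scheme
from published tables; the bit score is ``(lambda*S - ln K) / ln 2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

NT_ALPHABET = "ACGTN#"  # '#' is the masking sentinel
_PROT_BASE = "ARNDCQEGHILKMFPSTWYVBZX*"
PROT_ALPHABET = _PROT_BASE + "#"
MASK_SCORE = -(10 ** 6)

_NT_INDEX = {c: i for i, c in enumerate(NT_ALPHABET)}
_PROT_INDEX = {c: i for i, c in enumerate(PROT_ALPHABET)}


def _nt_matrix(match: int, mismatch: int) -> np.ndarray:
    n = len(NT_ALPHABET)
    m = np.full((n, n), mismatch, dtype=np.int32)
    for i in range(4):
        m[i, i] = match
    m[4, :] = m[:, 4] = mismatch  # N never counts as a match
    m[5, :] = m[:, 5] = MASK_SCORE
    return m


def _protein_matrix(name: str = "BLOSUM62") -> np.ndarray:
    blosum = substitution_matrices.load(name)
    n = len(PROT_ALPHABET)
    m = np.full((n, n), MASK_SCORE, dtype=np.int32)
    for i, a in enumerate(_PROT_BASE):
        for j, b in enumerate(_PROT_BASE):
            m[i, j] = int(blosum[a][b])
    return m


@dataclass
class ScoringScheme:
    """Scoring parameters plus Karlin-Altschul statistics for one search mode.

    Defaults mirror the customary parameters of the corresponding BLAST
    programs: nucleotide match +2 / mismatch -3 with gaps -5/-2, protein
    BLOSUM62 with gaps -11/-1.
    """

    mode: str  # 'nucleotide' | 'protein'
    gap_open: int
    gap_extend: int
    lam: float
    K: float
    word_size: int
    matrix: np.ndarray = field(repr=False)
    # bit score an ungapped seed extension must reach before the seed's
    # window is handed to the gapped DP (the usual one-hit trigger)
    one_hit_trigger_bits: float = 25.0

    def __post_init__(self):
        if self.mode not in ("nucleotide", "protein"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")

    @classmethod
    def nucleotide(cls, match: int = 2, mismatch: int = -3,
                   gap_open: int = -5, gap_extend: int = -2,
                   lam: float = 0.610, K: float = 0.35,
                   word_size: int = 11) -> "ScoringScheme":
        return cls("nucleotide", gap_open, gap_extend, lam, K, word_size,
                   _nt_matrix(match, mismatch))

    @classmethod
    def protein(cls, gap_open: int = -11, gap_extend: int = -1,
                lam: float = 0.267, K: float = 0.041,
                word_size: int = 5,
                one_hit_trigger_bits: float = 22.0) -> "ScoringScheme":
        return cls("protein", gap_open, gap_extend, lam, K, word_size,
                   _protein_matrix(), one_hit_trigger_bits)

    @property
    def alphabet(self) -> str:
        return NT_ALPHABET if self.mode == "nucleotide" else PROT_ALPHABET

    def encode(self, seq: str) -> np.ndarray:
        index = _NT_INDEX if self.mode == "nucleotide" else _PROT_INDEX
        try:
            return np.fromiter((index[c] for c in seq.upper()),
                               dtype=np.int8, count=len(seq))
        except KeyError as exc:
            raise ValueError(
                f"character {exc.args[0]!r} not in {self.mode} alphabet") from exc


def evalue(raw_score: float, m: int, n: int, s: ScoringScheme) -> float:
    """Karlin-Altschul expectation for a raw score in an m x n search space."""
    if m < 1 or n < 1:
        raise ValueError("search-space dimensions must be >= 1")
    # floor keeps E positive when exp() underflows for very strong scores
    return max(s.K * m * n * math.exp(-s.lam * raw_score), 1e-300)


def bit_score(raw_score: float, s: ScoringScheme) -> float:
    return (s.lam * raw_score - math.log(s.K)) / math.log(2.0)


def raw_for_bits(bits: float, s: ScoringScheme) -> int:
    """Smallest raw score whose bit score reaches ``bits``."""
    return math.ceil((bits * math.log(2.0) + math.log(s.K)) / s.lam)


@njit(cache=False)
def _sw_kernel(q, t, mat, go, ge, dlo, dhi):  # pragma: no cover - via wrapper
    """Affine-gap Smith-Waterman with full traceback, banded on diagonals.

    Only cells with diagonal ``t_index - q_index`` (0-based) in
    ``[dlo, dhi]`` are evaluated; paths cannot leave the band.  Passing
    ``dlo = -len(q), dhi = len(t)`` evaluates the full matrix.
    Returns (score, q_start, q_end, t_start, t_end, n_identical, n_columns),
    spans 0-based half-open.  Pointer bits: 0-1 H-source (0 stop, 1 diag,
    2 left/E, 3 up/F); bit 2: E extends; bit 3: F extends.
    """
    m = q.shape[0]
    n = t.shape[0]
    NEG = -(10 ** 9)
    H_prev = np.full(n + 1, NEG, dtype=np.int64)
    H_cur = np.full(n + 1, NEG, dtype=np.int64)
    F = np.full(n + 1, NEG, dtype=np.int64)
    ptr = np.zeros((m + 1) * (n + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        E = NEG
        qi = q[i - 1]
        row = i * (n + 1)
        jlo = i + dlo if i + dlo > 1 else 1
        jhi = i + dhi if i + dhi < n else n
        if jlo > jhi:
            continue
        H_cur[jlo - 1] = NEG
        for j in range(jlo, jhi + 1):
            p = 0
            # E: gap in target direction? (gap in query string = consume t)
            e_open = H_cur[j - 1] + go
            e_ext = E + ge
            if e_ext > e_open:
                E = e_ext
                p |= 4
            else:
                E = e_open
            # F: consume q
            f_open = H_prev[j] + go
            f_ext = F[j] + ge
            if f_ext > f_open:
                F[j] = f_ext
                p |= 8
            else:
                F[j] = f_open
            dpred = H_prev[j - 1]
            if dpred < 0:  # out-of-band / boundary: start a fresh alignment
                dpred = 0
            diag = dpred + mat[qi, t[j - 1]]
            h = 0
            src = 0
            if diag > h:
                h = diag
                src = 1
            if E > h:
                h = E
                src = 2
            if F[j] > h:
                h = F[j]
                src = 3
            H_cur[j] = h
            ptr[row + j] = p | src
            if h > best:
                best = h
                bi = i
                bj = j
        if jhi < n:
            H_cur[jhi + 1] = NEG
        tmp = H_prev
        H_prev = H_cur
        H_cur = tmp
    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0
    # traceback
    i = bi
    j = bj
    ident = 0
    cols = 0
    state = 0  # 0=H, 1=E, 2=F
    while True:
        p = ptr[i * (n + 1) + j]
        if state == 0:
            src = p & 3
            if src == 0:
                break
            if src == 1:
                cols += 1
                if q[i - 1] == t[j - 1]:
                    ident += 1
                i -= 1
                j -= 1
            elif src == 2:
                state = 1
            else:
                state = 2
        elif state == 1:  # E: consumed t[j-1]
            cols += 1
            ext = p & 4
            j -= 1
            if not ext:
                state = 0
        else:  # F: consumed q[i-1]
            cols += 1
            ext = p & 8
            i -= 1
            if not ext:
                state = 0
    return best, i, bi, j, bj, ident, cols


@njit(cache=False)
def _sw_score_only(q, t, mat, go, ge, dlo, dhi):  # pragma: no cover
    """Optimal local-alignment score without traceback, banded on diagonals.

    Same band convention as :func:`_sw_kernel`; linear memory.
    """
    m = q.shape[0]
    n = t.shape[0]
    NEG = -(10 ** 9)
    H_prev = np.full(n + 1, NEG, dtype=np.int64)
    H_cur = np.full(n + 1, NEG, dtype=np.int64)
    F = np.full(n + 1, NEG, dtype=np.int64)
    best = 0
    for i in range(1, m + 1):
        E = NEG
        qi = q[i - 1]
        jlo = i + dlo if i + dlo > 1 else 1
        jhi = i + dhi if i + dhi < n else n
        if jlo > jhi:
            continue
        H_cur[jlo - 1] = NEG
        for j in range(jlo, jhi + 1):
            e_open = H_cur[j - 1] + go
            e_ext = E + ge
            E = e_ext if e_ext > e_open else e_open
            f_open = H_prev[j] + go
            f_ext = F[j] + ge
            F[j] = f_ext if f_ext > f_open else f_open
            dpred = H_prev[j - 1]
            if dpred < 0:
                dpred = 0
            h = dpred + mat[qi, t[j - 1]]
            if E > h:
                h = E
            if F[j] > h:
                h = F[j]
            if h < 0:
                h = 0
            H_cur[j] = h
            if h > best:
                best = h
        if jhi < n:
            H_cur[jhi + 1] = NEG
        tmp = H_prev
        H_prev = H_cur
        H_cur = tmp
    return best


@dataclass
class LocalAlignment:
    score: int
    query_span: tuple  # 0-based half-open on the query
    target_span: tuple
    n_identical: int
    n_columns: int

    @property
    def pct_identity(self) -> float:
        return 100.0 * self.n_identical / self.n_columns if self.n_columns else 0.0


def smith_waterman(a: str, b: str, s: ScoringScheme) -> LocalAlignment:
    """Optimal local alignment of two sequences under the scheme's scoring.

    Score is 0 (empty alignment) when no positive-scoring alignment exists.
    """
    qa = s.encode(a)
    tb = s.encode(b)
    if len(qa) == 0 or len(tb) == 0:
        return LocalAlignment(0, (0, 0), (0, 0), 0, 0)
    aln = _align_encoded(qa, tb, s)
    if aln.score == 0:
        return LocalAlignment(0, (0, 0), (0, 0), 0, 0)
    return aln


def _align_encoded(q: np.ndarray, t: np.ndarray, s: ScoringScheme,
                   dlo: int | None = None,
                   dhi: int | None = None) -> LocalAlignment:
    if dlo is None:
        dlo = -len(q)
    if dhi is None:
        dhi = len(t)
    sc, qs, qe, ts, te, ident, cols = _sw_kernel(q, t, s.matrix,
                                                 s.gap_open, s.gap_extend,
                                                 dlo, dhi)
    return LocalAlignment(int(sc), (int(qs), int(qe)), (int(ts), int(te)),
                          int(ident), int(cols))


_KMER_BASE = 32  # > both alphabet sizes; 32**11 fits comfortably in int64


def _kmer_keys(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer key of every k-word of an encoded sequence (vectorized)."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64)
    arr = codes.astype(np.int64)
    keys = np.zeros(n - k + 1, dtype=np.int64)
    for x in range(k):
        keys = keys * _KMER_BASE + arr[x:n - k + 1 + x]
    return keys


def _kmer_index(codes: np.ndarray, k: int) -> dict:
    """Map k-word integer key -> sorted array of start positions."""
    keys = _kmer_keys(codes, k)
    if keys.size == 0:
        return {}
    order = np.argsort(keys, kind="stable")
    sk = keys[order]
    starts = np.flatnonzero(np.r_[True, sk[1:] != sk[:-1]])
    bounds = np.r_[starts, sk.size]
    return {int(sk[starts[i]]): order[bounds[i]:bounds[i + 1]]
            for i in range(starts.size)}


@njit(cache=False)
def _ungapped_extend(q, t, qpos, tpos, k, mat):  # pragma: no cover
    """Best gapless extension score through an exact k-word seed."""
    score = 0
    for x in range(k):
        score += mat[q[qpos + x], t[tpos + x]]
    best = score
    run = 0
    i, j = qpos - 1, tpos - 1
    while i >= 0 and j >= 0:
        run += mat[q[i], t[j]]
        if run > 0:
            best += run
            run = 0
        elif run < -30:
            break
        i -= 1
        j -= 1
    run = 0
    i, j = qpos + k, tpos + k
    while i < q.shape[0] and j < t.shape[0]:
        run += mat[q[i], t[j]]
        if run > 0:
            best += run
            run = 0
        elif run < -30:
            break
        i += 1
        j += 1
    return best


def _seed_windows(q: np.ndarray, t: np.ndarray, index: dict,
                  s: ScoringScheme, min_score: int,
                  band: int = 48, pad: int = 48) -> list:
    """Candidate target windows from diagonal-clustered exact-word seeds.

    Clusters with >= 2 seeds are promoted directly; a singleton cluster is
    promoted only when a gapless extension through its seed reaches the
    one-hit trigger score (capped at the reporting score), the usual cheap
    chance-hit filter.  Windows are padded by the unaligned query flanks plus
    ``pad`` and merged when overlapping.

    Returns (t_lo, t_hi, dlo, dhi) tuples: target span plus the allowed
    diagonal band (target index minus query index, both 0-based, relative to
    the whole target) widened by ``band`` around the cluster's seed diagonals.
    """
    k = s.word_size
    trigger = min(min_score, raw_for_bits(s.one_hit_trigger_bits, s))
    qlen = len(q)
    n_target = len(t)
    seeds = []  # (diag, tpos, qpos)
    for i, key in enumerate(_kmer_keys(q, k)):
        hits = index.get(int(key))
        if hits is not None:
            for tpos in hits:
                tpos = int(tpos)
                seeds.append((tpos - i, tpos, i))
    if not seeds:
        return []
    seeds.sort()
    clusters = []
    cur = [seeds[0]]
    for seed in seeds[1:]:
        if seed[0] - cur[-1][0] <= band:
            cur.append(seed)
        else:
            clusters.append(cur)
            cur = [seed]
    clusters.append(cur)
    windows = []
    for cl in clusters:
        if len(cl) == 1:
            _, tpos, qpos = cl[0]
            ung = _ungapped_extend(q, t, qpos, tpos, k, s.matrix)
            if ung < trigger:
                continue
        t_lo = min(c[1] for c in cl)
        t_hi = max(c[1] for c in cl) + k
        q_lo = min(c[2] for c in cl)
        q_hi = max(c[2] for c in cl) + k
        lo = max(0, t_lo - q_lo - pad)
        hi = min(n_target, t_hi + (qlen - q_hi) + pad)
        dlo = min(c[0] for c in cl) - band
        dhi = max(c[0] for c in cl) + band
        windows.append((lo, hi, dlo, dhi))
    if not windows:
        return []
    windows.sort()
    merged = [list(windows[0])]
    for lo, hi, dlo, dhi in windows[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
            merged[-1][2] = min(merged[-1][2], dlo)
            merged[-1][3] = max(merged[-1][3], dhi)
        else:
            merged.append([lo, hi, dlo, dhi])
    return [tuple(w) for w in merged]


def iter_local_hits(q: np.ndarray, t: np.ndarray, s: ScoringScheme,
                    min_score: int, dlo: int | None = None,
                    dhi: int | None = None) -> list:
    """All disjoint local alignments scoring >= min_score.

    The optimal alignment is reported, then the target is split at its span
    and each remainder searched recursively (equivalent to masking, without
    re-scanning the matched region).  ``dlo``/``dhi`` restrict the search to
    a diagonal band over the whole of ``t`` (default: unbanded).
    Deterministic.
    """
    if min_score <= 0:
        raise ValueError("min_score must be positive")
    if dlo is None:
        dlo = -len(q)
    if dhi is None:
        dhi = len(t)
    max_match = int(s.matrix[:4, :4].max()) if s.mode == "nucleotide" else \
        int(s.matrix.max())
    min_len = max(1, -(-min_score // max_match))
    out = []
    stack = [(0, len(t))]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < min_len:
            continue
        seg = t[lo:hi]
        # cheap score-only screen before the full-traceback DP
        if _sw_score_only(q, seg, s.matrix, s.gap_open, s.gap_extend,
                          dlo - lo, dhi - lo) < min_score:
            continue
        aln = _align_encoded(q, seg, s, dlo - lo, dhi - lo)
        if aln.score < min_score:
            continue
        ts, te = aln.target_span
        out.append(LocalAlignment(aln.score, aln.query_span,
                                  (ts + lo, te + lo), aln.n_identical,
                                  aln.n_columns))
        stack.append((lo, lo + ts))
        stack.append((lo + te, hi))
    out.sort(key=lambda a: (-a.score, a.target_span))
    return out
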