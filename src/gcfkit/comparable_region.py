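"""Selection of the comparable region between two domain strings.

A pair of gene cluster records is compared only over a "comparable region":
the slice pair anchored on their longest common run of domain tokens
(computed forward and with one record reversed, preferring runs that touch
core-biosynthetic domains), grown by a match/mismatch extension strategy,
and finally adjusted by the alignment mode (local, glocal or global).

All indices are 0-based half-open into the two domain strings; when
``reverse`` is true the B indices refer to the reversed orientation of B.
"""

from __future__ import annotations

from collections import defaultdict, deque
from dataclasses import dataclass, replace

from gcfkit.domain_annotation import DomainString

#: (match, mismatch, gap) scores of the extension walks.
DEFAULT_EXTEND_SCORES = (5, -3, -2)

EXTEND_STRATEGIES = ("legacy", "simple_match", "greedy")
ALIGNMENT_MODES = ("global", "glocal", "local")


@dataclass(frozen=True)
class ComparableRegion:
    """The aligned slice pair of two domain strings."""

    a_start: int
    a_stop: int
    b_start: int
    b_stop: int
    reverse: bool

    def __post_init__(self) -> None:
        if not (0 <= self.a_start <= self.a_stop and 0 <= self.b_start <= self.b_stop):
            raise ValueError("malformed comparable region")
        if (self.a_stop == self.a_start) != (self.b_stop == self.b_start):
            raise ValueError("empty on one side only")

    @property
    def is_empty(self) -> bool:
        return self.a_stop == self.a_start


@dataclass(frozen=True)
class LcsCandidate:
    """One maximal common run of domain tokens between two strings."""

    a_start: int
    b_start: int
    length: int
    contains_core: bool
    reverse: bool

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("negative run length")
        if self.contains_core and self.length < 1:
            raise ValueError("a zero-length run cannot contain core domains")


def _oriented_b(B: DomainString, reverse: bool) -> tuple[list[str], list[bool]]:
    tokens = B.tokens
    flags = list(B.core_flags)
    if reverse:
        return tokens[::-1], flags[::-1]
    return tokens, flags


def _maximal_runs(
    a_tokens: list[str],
    b_tokens: list[str],
    a_core: list[bool],
    b_core: list[bool],
    reverse: bool,
) -> list[LcsCandidate]:
    """All maximal (inextensible) common contiguous runs, via the classic
    suffix-run dynamic program."""
    n, m = len(a_tokens), len(b_tokens)
    prev = [0] * (m + 1)
    out: list[LcsCandidate] = []
    for i in range(n):
        cur = [0] * (m + 1)
        for j in range(m):
            if a_tokens[i] == b_tokens[j]:
                cur[j + 1] = prev[j] + 1
                ends_here = (
                    i + 1 == n or j + 1 == m or a_tokens[i + 1] != b_tokens[j + 1]
                )
                if ends_here:
                    length = cur[j + 1]
                    a0 = i + 1 - length
                    b0 = j + 1 - length
                    core = any(a_core[a0 : a0 + length]) or any(
                        b_core[b0 : b0 + length]
                    )
                    out.append(LcsCandidate(a0, b0, length, core, reverse))
        prev = cur
    return out


def _subsequence_candidate(
    a_tokens: list[str],
    b_tokens: list[str],
    a_core: list[bool],
    b_core: list[bool],
    reverse: bool,
) -> list[LcsCandidate]:
    """Gapped-subsequence variant: the span of one longest common
    subsequence, reported as a single candidate whose length is the span on
    A.  Exposed behind ``variant='subsequence'``; not equivalent to the
    contiguous-run default."""
    n, m = len(a_tokens), len(b_tokens)
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            if a_tokens[i] == b_tokens[j]:
                dp[i][j] = dp[i + 1][j + 1] + 1
            else:
                dp[i][j] = max(dp[i + 1][j], dp[i][j + 1])
    if dp[0][0] == 0:
        return []
    matched_a: list[int] = []
    matched_b: list[int] = []
    i = j = 0
    while i < n and j < m:
        if a_tokens[i] == b_tokens[j] and dp[i][j] == dp[i + 1][j + 1] + 1:
            matched_a.append(i)
            matched_b.append(j)
            i += 1
            j += 1
        elif dp[i + 1][j] >= dp[i][j + 1]:
            i += 1
        else:
            j += 1
    a0, a1 = matched_a[0], matched_a[-1] + 1
    b0, b1 = matched_b[0], matched_b[-1] + 1
    core = any(a_core[a0:a1]) or any(b_core[b0:b1])
    # span lengths on the two strings may differ; report the A span and
    # remember the B span via b_start (extend() re-derives b_stop).
    return [LcsCandidate(a0, b0, a1 - a0, core, reverse)]


def find_lcs(
    A: DomainString, B: DomainString, variant: str = "contiguous"
) -> list[LcsCandidate]:
    """All maximal common runs of domain tokens, forward and B-reversed.

    A run "contains core" when any of its positions is core-flagged in
    either record.  When the two strings share no token at all, a single
    zero-length candidate is returned so that downstream stages can handle
    the degenerate pair explicitly.
    """
    if len(A) == 0 or len(B) == 0:
        raise ValueError("find_lcs requires two non-empty domain strings")
    a_tokens, a_core = A.tokens, list(A.core_flags)
    finder = _maximal_runs if variant == "contiguous" else _subsequence_candidate
    candidates: list[LcsCandidate] = []
    for reverse in (False, True):
        b_tokens, b_core = _oriented_b(B, reverse)
        candidates.extend(finder(a_tokens, b_tokens, a_core, b_core, reverse))
    if not candidates:
        return [LcsCandidate(0, 0, 0, False, False)]
    return candidates


def select_lcs(
    candidates: list[LcsCandidate], a_len: int | None = None
) -> LcsCandidate:
    """Pick the anchor run, preferring runs containing core domains.

    Among core-containing candidates the longest wins; if none contains
    core, the longest overall wins.  Ties break towards forward
    orientation, then the run most central on record A, then smaller
    a_start, then smaller b_start.
    """
    if not candidates:
        raise ValueError("no candidates to select from")
    core = [c for c in candidates if c.contains_core]
    pool = core if core else candidates
    best_len = max(c.length for c in pool)
    pool = [c for c in pool if c.length == best_len]

    def sort_key(c: LcsCandidate):
        if a_len is not None:
            centrality = abs((c.a_start + c.length / 2) - a_len / 2)
        else:
            centrality = 0.0
        return (c.reverse, centrality, c.a_start, c.b_start)

    return min(pool, key=sort_key)


def _walk(
    primary: list[str],
    p_edge: int,
    partner: list[str],
    q_edge: int,
    scores: tuple[float, float, float],
    legacy_gaps: bool,
    direction: int,
) -> tuple[int, int]:
    """Score-driven extension walk of one record's arm on one side.

    ``direction`` +1 walks right from ``p_edge`` (an exclusive stop index),
    −1 walks left from ``p_edge`` (an inclusive start index).  Each primary
    position whose token is still available in the partner's outward arm
    multiset counts as a match and consumes the nearest available
    occurrence; otherwise it counts as a mismatch.  With ``legacy_gaps``
    each consumption additionally charges the gap score per partner
    position skipped since the previous consumption.  The boundary lands at
    the maximum of the running score if positive, else stays at the edge;
    the partner boundary is pushed outward to cover the farthest occurrence
    consumed before that maximum.

    Returns the new (primary boundary, partner boundary) for this side.
    """
    match, mismatch, gap = scores
    occ: dict[str, deque[int]] = defaultdict(deque)
    if direction > 0:
        primary_indices = range(p_edge, len(primary))
        partner_indices = range(q_edge, len(partner))
        jprev = q_edge - 1
    else:
        primary_indices = range(p_edge - 1, -1, -1)
        partner_indices = range(q_edge - 1, -1, -1)
        jprev = q_edge
    for j in partner_indices:
        occ[partner[j]].append(j)

    score = 0.0
    best_score = 0.0
    best_i: int | None = None
    best_far: int | None = None
    far: int | None = None
    consumed: set[int] = set()
    for i in primary_indices:
        tok = primary[i]
        if occ[tok]:
            j = occ[tok].popleft()
            if legacy_gaps:
                if direction > 0:
                    gap_span = range(jprev + 1, j)
                    advanced = j > jprev
                else:
                    gap_span = range(j + 1, jprev)
                    advanced = j < jprev
                skipped = sum(1 for x in gap_span if x not in consumed) if advanced else 0
                score += match + gap * skipped
                jprev = max(jprev, j) if direction > 0 else min(jprev, j)
            else:
                score += match
            consumed.add(j)
            far = j if far is None else (max(far, j) if direction > 0 else min(far, j))
        else:
            score += mismatch
        if score > best_score:
            best_score = score
            best_i = i
            best_far = far
    if best_i is None:
        return p_edge, q_edge
    if direction > 0:
        return best_i + 1, (q_edge if best_far is None else max(q_edge, best_far + 1))
    return best_i, (q_edge if best_far is None else min(q_edge, best_far))


def _greedy_bound(
    primary: list[str], p_edge: int, partner_tokens: set[str], direction: int
) -> int:
    """Outermost primary position (beyond the edge) whose token occurs
    anywhere in the partner; everything between is included."""
    if direction > 0:
        for i in range(len(primary) - 1, p_edge - 1, -1):
            if primary[i] in partner_tokens:
                return i + 1
        return p_edge
    for i in range(0, p_edge):
        if primary[i] in partner_tokens:
            return i
    return p_edge


def extend(
    A: DomainString,
    B: DomainString,
    lcs: LcsCandidate,
    strategy: str = "legacy",
    scores: tuple[float, float, float] = DEFAULT_EXTEND_SCORES,
) -> ComparableRegion:
    """Grow the anchor run outward on both sides of both records.

    ``greedy`` includes everything up to the outermost position whose token
    occurs anywhere in the partner record; ``simple_match`` and ``legacy``
    run the score-driven walk (see :func:`_walk`), ``legacy`` additionally
    charging gap penalties for partner positions skipped between
    consecutive matches.  Each record extends independently on each side;
    a record's boundary may also be pushed outward by the partner's walk to
    cover the occurrences that walk consumed.
    """
    if strategy not in EXTEND_STRATEGIES:
        raise ValueError(f"unknown extension strategy {strategy!r}")
    if lcs.length == 0:
        return ComparableRegion(
            lcs.a_start, lcs.a_start, lcs.b_start, lcs.b_start, lcs.reverse
        )
    a_tokens = A.tokens
    b_tokens, _ = _oriented_b(B, lcs.reverse)
    a_start, a_stop = lcs.a_start, lcs.a_start + lcs.length
    b_start = lcs.b_start
    b_stop = min(lcs.b_start + lcs.length, len(b_tokens))

    if strategy == "greedy":
        a_set, b_set = set(a_tokens), set(b_tokens)
        a_stop = _greedy_bound(a_tokens, a_stop, b_set, +1)
        b_stop = _greedy_bound(b_tokens, b_stop, a_set, +1)
        a_start = _greedy_bound(a_tokens, a_start, b_set, -1)
        b_start = _greedy_bound(b_tokens, b_start, a_set, -1)
        return ComparableRegion(a_start, a_stop, b_start, b_stop, lcs.reverse)

    legacy_gaps = strategy == "legacy"
    # right side: walk A against B's right arm, and B against A's right arm
    new_a_stop, push_b_stop = _walk(
        a_tokens, a_stop, b_tokens, b_stop, scores, legacy_gaps, +1
    )
    new_b_stop, push_a_stop = _walk(
        b_tokens, b_stop, a_tokens, a_stop, scores, legacy_gaps, +1
    )
    a_stop2 = max(new_a_stop, push_a_stop)
    b_stop2 = max(new_b_stop, push_b_stop)
    # left side
    new_a_start, push_b_start = _walk(
        a_tokens, a_start, b_tokens, b_start, scores, legacy_gaps, -1
    )
    new_b_start, push_a_start = _walk(
        b_tokens, b_start, a_tokens, a_start, scores, legacy_gaps, -1
    )
    a_start2 = min(new_a_start, push_a_start)
    b_start2 = min(new_b_start, push_b_start)
    return ComparableRegion(a_start2, a_stop2, b_start2, b_stop2, lcs.reverse)


def apply_mode(
    A: DomainString,
    B: DomainString,
    region: ComparableRegion,
    mode: str = "glocal",
) -> ComparableRegion:
    """Adjust the extended region according to the alignment mode.

    ``local`` keeps the extended region; ``global`` compares all domains of
    both records regardless of the anchor; ``glocal`` additionally includes,
    on each side independently, the full remaining arm of whichever record
    has the shorter remaining arm on that side.  A degenerate (no shared
    token) region stays empty under ``local`` and falls back to the full
    global spans under ``glocal``.
    """
    if mode not in ALIGNMENT_MODES:
        raise ValueError(f"unknown alignment mode {mode!r}")
    if mode == "local":
        return region
    if mode == "global":
        return ComparableRegion(0, len(A), 0, len(B), False)
    # glocal
    if region.is_empty:
        return ComparableRegion(0, len(A), 0, len(B), False)
    a_start, a_stop = region.a_start, region.a_stop
    b_start, b_stop = region.b_start, region.b_stop
    # left arms
    left_a, left_b = region.a_start, region.b_start
    if left_a <= left_b:
        a_start = 0
    if left_b <= left_a:
        b_start = 0
    # right arms
    a_arm = len(A) - a_stop
    b_arm = len(B) - b_stop
    if a_arm <= b_arm:
        a_stop = len(A)
    if b_arm <= a_arm:
        b_stop = len(B)
    return replace(region, a_start=a_start, a_stop=a_stop, b_start=b_start, b_stop=b_stop)


def comparable_region(
    A: DomainString,
    B: DomainString,
    mode: str = "glocal",
    strategy: str = "legacy",
    scores: tuple[float, float, float] = DEFAULT_EXTEND_SCORES,
    lcs_variant: str = "contiguous",
) -> ComparableRegion:
    """Full pipeline: LCS search, anchor selection, extension, mode."""
    candidates = find_lcs(A, B, variant=lcs_variant)
    anchor = select_lcs(candidates, a_len=len(A))
    region = extend(A, B, anchor, strategy=strategy, scores=scores)
    return apply_mode(A, B, region, mode=mode)
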