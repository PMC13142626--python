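"""Minimum unique substrings, maximal repeats, and anchor occurrence lookup.

A *minimum unique substring* (MUS) of a text is a substring that occurs
exactly once in the uniqueness scope and is minimal in both directions:
dropping its first character or its last character yields a string that
occurs at least twice.  MUSs sit at the boundaries of maximal repeats,
which makes them natural variable-length anchors for assembly: at most one
MUS starts at any text position, and no MUS is a substring of another.

The uniqueness scope is configurable: a single (optionally circular)
genome, or the whole read set (forward strands, optionally plus reverse
complements).  Coordinates in the public API are 1-based and closed on
both ends.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .index import Segment, lcp_array, build_suffix_array, make_index

DNA_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_NON_ACGT = re.compile("[^ACGT]+")


class ContractViolation(ValueError):
    """An operation was invoked outside its stated precondition."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def sanitize_sequence(seq: str) -> str:
    """Uppercase and validate a DNA string; non-ACGT characters are an error."""
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"non-ACGT characters after sanitization: {sorted(bad)}")
    return seq


def split_ambiguous(seq: str) -> list[str]:
    """Split an uppercased sequence at runs of non-ACGT characters."""
    return [part for part in _NON_ACGT.split(seq.upper()) if part]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Read:
    id: str
    seq: str


@dataclass
class ReadSet:
    """An ordered collection of named DNA reads over {A,C,G,T}."""

    reads: list[Read]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for read in self.reads:
            if read.id in seen:
                raise ValueError(f"duplicate read id: {read.id!r}")
            seen.add(read.id)
            sanitize_sequence(read.seq)

    @classmethod
    def from_pairs(cls, pairs) -> "ReadSet":
        return cls([Read(str(i), sanitize_sequence(s)) for i, s in pairs])

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def __getitem__(self, k: int) -> Read:
        return self.reads[k]


@dataclass(frozen=True)
class UniquenessConfig:
    """Where and how occurrence counts are taken for uniqueness tests."""

    scope: str = "genome"  # "genome" | "reads"
    use_reverse_complement: bool = False
    circular: bool = False  # genome scope only
    backend: str = "suffix_array"

    def __post_init__(self) -> None:
        if self.scope not in ("genome", "reads"):
            raise ValueError(f"scope must be 'genome' or 'reads', got {self.scope!r}")


@dataclass(frozen=True, order=True)
class Anchor:
    word: str

    @property
    def length(self) -> int:
        return len(self.word)


@dataclass
class AnchorSet:
    """The MUS collection used as graph nodes, in lexicographic order."""

    anchors: list[Anchor]
    scope: UniquenessConfig = field(default_factory=UniquenessConfig)

    def __post_init__(self) -> None:
        self.anchors = sorted(set(self.anchors))

    @classmethod
    def from_words(cls, words, scope: UniquenessConfig | None = None) -> "AnchorSet":
        return cls([Anchor(sanitize_sequence(w)) for w in words],
                   scope or UniquenessConfig())

    @property
    def words(self) -> list[str]:
        return [a.word for a in self.anchors]

    def __len__(self) -> int:
        return len(self.anchors)

    def __iter__(self):
        return iter(self.anchors)


@dataclass(frozen=True)
class MusOccurrence:
    """One exact match of an anchor word in one read; 1-based closed interval."""

    word: str
    read_index: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end != self.start + len(self.word) - 1:
            raise ValueError("inconsistent occurrence interval")


@dataclass(frozen=True)
class MaximalRepeat:
    word: str
    occurrence_count: int
    positions: tuple[int, ...]  # 1-based starts, ascending


# ---------------------------------------------------------------------------
# occurrence counting
# ---------------------------------------------------------------------------


def count_occurrences(
    text: str, word: str, circular: bool = False, use_rc: bool = False
) -> int:
    """Number of distinct start positions of `word` in `text` by direct scan.

    Circular counting places starts on the original coordinates (matches may
    wrap).  With `use_rc`, reverse-strand matches (occurrences of the reverse
    complement) are counted as well.
    """
    if not word:
        raise ValueError("word must be non-empty")

    def scan(t: str, w: str, limit: int) -> int:
        n = 0
        i = t.find(w)
        while 0 <= i < limit:
            n += 1
            i = t.find(w, i + 1)
        return n

    targets = [word]
    if use_rc:
        targets.append(reverse_complement(word))
    total = 0
    for w in targets:
        if circular and len(text) > 1:
            doubled = text + text[: len(w) - 1]
            total += scan(doubled, w, len(text))
        else:
            total += scan(text, w, len(text))
    return total


def _scope_segments(
    texts: list[str], config: UniquenessConfig
) -> tuple[list[Segment], list[tuple[str, int]]]:
    """Build index segments plus (candidate text, max word length) pairs.

    For a circular genome the indexed segment is the doubled text with the
    countable-start limit at the original length, and candidate words may
    wrap up to the full genome length.
    """
    segments: list[Segment] = []
    candidates: list[tuple[str, int]] = []
    if config.scope == "genome":
        (genome,) = texts
        n = len(genome)
        if config.circular and n > 1:
            segments.append(Segment(genome + genome[: n - 1], limit=n))
            candidates.append((genome + genome, n))
            if config.use_reverse_complement:
                rc = reverse_complement(genome)
                segments.append(Segment(rc + rc[: n - 1], limit=n))
        else:
            segments.append(Segment(genome))
            candidates.append((genome, n))
            if config.use_reverse_complement:
                segments.append(Segment(reverse_complement(genome)))
    else:
        for t in texts:
            segments.append(Segment(t))
            candidates.append((t, len(t)))
        if config.use_reverse_complement:
            for t in texts:
                segments.append(Segment(reverse_complement(t)))
    return segments, candidates


def extract_mus(text_or_reads, config: UniquenessConfig | None = None) -> AnchorSet:
    """Extract all minimum unique substrings under the configured scope.

    Returns the anchors in lexicographic order.  Each anchor occurs exactly
    once in scope; its proper prefix and proper suffix each occur at least
    twice (single-character anchors are minimal by convention).
    """
    config = config or UniquenessConfig()
    if isinstance(text_or_reads, str):
        if config.scope == "reads":
            raise ValueError("reads scope requires a ReadSet")
        texts = [sanitize_sequence(text_or_reads)]
    else:
        reads = list(text_or_reads)
        if not reads:
            raise ValueError("empty read set")
        texts = [sanitize_sequence(r.seq) for r in reads]
        if config.scope == "genome":
            if len(texts) != 1:
                raise ValueError("genome scope requires a single text")
    if not texts or not all(texts):
        raise ValueError("empty input")

    segments, candidates = _scope_segments(texts, config)
    index = make_index(segments, config.backend)
    words: set[str] = set()
    for ctext, max_len in candidates:
        n = max_len  # number of candidate start positions
        for i in range(n):
            hi = min(max_len, len(ctext) - i)
            if hi < 1:
                continue
            if index.count(ctext[i : i + hi]) > 1:
                continue  # nothing unique starts here
            lo = 1
            while lo < hi:  # smallest length whose count is exactly 1
                mid = (lo + hi) // 2
                if index.count(ctext[i : i + mid]) == 1:
                    hi = mid
                else:
                    lo = mid + 1
            word = ctext[i : i + lo]
            if lo == 1 or index.count(word[1:]) >= 2:
                words.add(word)
    return AnchorSet([Anchor(w) for w in words], scope=config)


def locate_occurrences(read, k: int, anchors: AnchorSet) -> list[MusOccurrence]:
    """All exact anchor matches in one read, sorted by 1-based start.

    At most one anchor can start at any position (anchors are prefix-free),
    so sorting by start gives a total order.
    """
    if not len(anchors):
        raise ValueError("anchor set is empty")
    _, seq = read
    occurrences: list[MusOccurrence] = []
    for word in anchors.words:
        i = seq.find(word)
        while i >= 0:
            occurrences.append(
                MusOccurrence(word=word, read_index=k, start=i + 1, end=i + len(word))
            )
            i = seq.find(word, i + 1)
    occurrences.sort(key=lambda o: o.start)
    return occurrences


# ---------------------------------------------------------------------------
# maximal repeats
# ---------------------------------------------------------------------------


def extract_maximal_repeats(text: str) -> list[MaximalRepeat]:
    """All maximal repeats of a linear text, with 1-based occurrence starts.

    A maximal repeat occurs at least twice and cannot be extended left or
    right at all of its occurrences while remaining a repeat.  Right-maximal
    candidates are the LCP-interval words of the suffix array; left-maximality
    is checked on the preceding characters.  The alphabet is not restricted
    to A/C/G/T so small synthetic examples over toy alphabets work too.
    """
    if not text:
        raise ValueError("empty input")
    n = len(text)
    sa = build_suffix_array(text)
    lcp = lcp_array(text, sa)
    repeats: list[MaximalRepeat] = []

    def emit(depth: int, lb: int, rb: int) -> None:
        if depth <= 0:
            return
        starts = sorted(int(sa[r]) for r in range(lb, rb + 1))
        preceding = {text[p - 1] if p > 0 else ("^", p) for p in starts}
        if len(preceding) >= 2:
            repeats.append(
                MaximalRepeat(
                    word=text[starts[0] : starts[0] + depth],
                    occurrence_count=len(starts),
                    positions=tuple(p + 1 for p in starts),
                )
            )

    stack: list[tuple[int, int]] = []  # (lcp depth, left boundary)
    for i in range(1, n + 1):
        current = int(lcp[i]) if i < n else 0
        lb = i - 1
        while stack and stack[-1][0] > current:
            depth, lb = stack.pop()
            emit(depth, lb, i - 1)
        if not stack or stack[-1][0] < current:
            stack.append((current, lb))
    repeats.sort(key=lambda r: (r.positions[0], len(r.word)))
    return repeats
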