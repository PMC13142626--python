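"""Substring-occurrence indexes over one or more text segments.

The uniqueness queries behind anchor extraction reduce to one primitive:
*how many times does an A/C/G/T word start inside the countable region of
a segment collection?*  Three interchangeable backends answer it:

``brute_force``
    Direct string scanning.  Serves as the independent oracle.
``suffix_array``
    Suffix array over the sentinel-joined segments (numpy prefix doubling)
    with an O(|w| log n) range search per query.
``suffix_tree``
    A compressed suffix tree built by inserting suffixes one at a time.
    Construction is O(n^2) in the worst case, which is fine at the scales
    this package targets (reads and small genomes, kilobases).

Segments carry a ``limit``: only matches starting before it are counted.
A circular genome is indexed as the doubled text with ``limit`` equal to
the original length, so wrap-around occurrences are counted exactly once.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

SENTINEL = "\x00"


@dataclass(frozen=True)
class Segment:
    """One text plus the exclusive bound on countable match starts."""

    text: str
    limit: int | None = None

    @property
    def start_limit(self) -> int:
        return len(self.text) if self.limit is None else self.limit


# ---------------------------------------------------------------------------
# suffix array / LCP primitives (shared by the SA backend and repeat finding)
# ---------------------------------------------------------------------------


def build_suffix_array(text: str) -> np.ndarray:
    """Suffix array by prefix doubling (Karp–Miller–Rosenberg), O(n log^2 n)."""
    n = len(text)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    rank = np.frombuffer(text.encode("latin-1"), dtype=np.uint8).astype(np.int64)
    order = np.argsort(rank, kind="stable")
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        if k < n:
            key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r1, r2 = rank[order], key2[order]
        diff = np.empty(n, dtype=bool)
        diff[0] = True
        diff[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(diff) - 1
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order
        k *= 2


def lcp_array(text: str, sa: np.ndarray) -> np.ndarray:
    """Kasai's algorithm; lcp[r] = LCP(suffix sa[r-1], suffix sa[r]), lcp[0]=0."""
    n = len(text)
    lcp = np.zeros(n, dtype=np.int64)
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = int(sa[r - 1])
            while i + h < n and j + h < n and text[i + h] == text[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp


# ---------------------------------------------------------------------------
# backends
# ---------------------------------------------------------------------------


class OccurrenceIndex:
    """Interface: exact count of word starts within the countable regions."""

    def count(self, word: str) -> int:  # pragma: no cover - interface
        raise NotImplementedError


class BruteForceIndex(OccurrenceIndex):
    def __init__(self, segments: list[Segment]):
        self._segments = segments

    def count(self, word: str) -> int:
        if not word:
            raise ValueError("word must be non-empty")
        total = 0
        for seg in self._segments:
            limit = seg.start_limit
            i = seg.text.find(word)
            while 0 <= i < limit:
                total += 1
                i = seg.text.find(word, i + 1)
        return total


class SuffixArrayIndex(OccurrenceIndex):
    """Sentinel-joined suffix array with O(1) countable-prefix sums."""

    def __init__(self, segments: list[Segment]):
        parts: list[str] = []
        ok_parts: list[np.ndarray] = []
        for seg in segments:
            parts.append(seg.text)
            ok = np.zeros(len(seg.text) + 1, dtype=np.int64)
            ok[: seg.start_limit] = 1
            ok_parts.append(ok)
        self._text = SENTINEL.join(parts) + SENTINEL if parts else ""
        self._sa = build_suffix_array(self._text)
        countable = np.concatenate(ok_parts) if ok_parts else np.zeros(0, np.int64)
        in_order = countable[self._sa] if len(self._sa) else countable
        self._prefix = np.concatenate(([0], np.cumsum(in_order)))
        self._keys = [self._SuffixKey(self._text, int(p)) for p in self._sa]

    class _SuffixKey:
        __slots__ = ("text", "pos")

        def __init__(self, text: str, pos: int):
            self.text, self.pos = text, pos

        def __lt__(self, word: str) -> bool:
            return self.text[self.pos : self.pos + len(word)] < word

    def _range(self, word: str) -> tuple[int, int]:
        # "\x7f" sorts above A/C/G/T and the NUL sentinel, so this brackets
        # exactly the suffixes having `word` as a prefix.
        lo = bisect.bisect_left(self._keys, word)
        hi = bisect.bisect_left(self._keys, word + "\x7f")
        return lo, hi

    def count(self, word: str) -> int:
        if not word:
            raise ValueError("word must be non-empty")
        lo, hi = self._range(word)
        return int(self._prefix[hi] - self._prefix[lo])


class _TreeNode:
    __slots__ = ("start", "end", "children", "leaf_pos", "ok_leaves")

    def __init__(self, start: int, end: int):
        self.start = start  # edge label = text[start:end]
        self.end = end
        self.children: dict[str, _TreeNode] = {}
        self.leaf_pos: int | None = None
        self.ok_leaves = 0


class SuffixTreeIndex(OccurrenceIndex):
    """Compressed suffix tree via naive suffix insertion with leaf counts."""

    def __init__(self, segments: list[Segment]):
        parts: list[str] = []
        ok_parts: list[np.ndarray] = []
        for seg in segments:
            parts.append(seg.text)
            ok = np.zeros(len(seg.text) + 1, dtype=bool)
            ok[: seg.start_limit] = True
            ok_parts.append(ok)
        self._text = SENTINEL.join(parts) + SENTINEL if parts else SENTINEL
        self._ok = (
            np.concatenate(ok_parts + [np.zeros(0, bool)])
            if ok_parts
            else np.zeros(1, bool)
        )
        self._root = _TreeNode(0, 0)
        for i in range(len(self._text)):
            self._insert(i)
        self._accumulate(self._root)

    def _insert(self, pos: int) -> None:
        text = self._text
        node, i = self._root, pos
        while True:
            ch = text[i]
            child = node.children.get(ch)
            if child is None:
                leaf = _TreeNode(i, len(text))
                leaf.leaf_pos = pos
                node.children[ch] = leaf
                return
            # walk down the compressed edge to the first mismatch
            j, k = child.start, i
            while j < child.end and k < len(text) and text[j] == text[k]:
                j += 1
                k += 1
            if j == child.end:
                node, i = child, k
                continue
            # split the edge at the mismatch
            mid = _TreeNode(child.start, j)
            child.start = j
            mid.children[text[j]] = child
            leaf = _TreeNode(k, len(text))
            leaf.leaf_pos = pos
            mid.children[text[k]] = leaf
            node.children[ch] = mid
            return

    def _accumulate(self, root: _TreeNode) -> None:
        # iterative post-order; tree depth can reach O(n) on repetitive text
        stack: list[tuple[_TreeNode, bool]] = [(root, False)]
        while stack:
            node, expanded = stack.pop()
            if not expanded:
                stack.append((node, True))
                for child in node.children.values():
                    stack.append((child, False))
            else:
                total = 0
                if node.leaf_pos is not None and node.leaf_pos < len(self._ok):
                    total += int(self._ok[node.leaf_pos])
                for child in node.children.values():
                    total += child.ok_leaves
                node.ok_leaves = total

    def count(self, word: str) -> int:
        if not word:
            raise ValueError("word must be non-empty")
        text = self._text
        node, i = self._root, 0
        while i < len(word):
            child = node.children.get(word[i])
            if child is None:
                return 0
            j = child.start
            while j < child.end and i < len(word):
                if text[j] != word[i]:
                    return 0
                i += 1
                j += 1
            node = child
        return node.ok_leaves


_BACKENDS = {
    "brute_force": BruteForceIndex,
    "suffix_array": SuffixArrayIndex,
    "suffix_tree": SuffixTreeIndex,
}


def make_index(segments: list[Segment], backend: str) -> OccurrenceIndex:
    try:
        cls = _BACKENDS[backend]
    except KeyError:
        raise ValueError(
            f"unknown backend {backend!r}; expected one of {sorted(_BACKENDS)}"
        ) from None
    return cls(segments)
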