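"""Aho-Corasick multi-pattern matching over amino-acid strings.

The automaton is a trie over all query peptides augmented with failure
links (longest proper suffix that is also a trie prefix) and output links,
so one left-to-right pass over a translated read reports every occurrence
of every peptide — including overlapping and nested occurrences — in
O(max pattern length + text length + number of matches).
"""

from __future__ import annotations

from collections import deque
from typing import Iterator, Sequence

__all__ = ["AhoCorasick"]


class AhoCorasick:
    """Multi-pattern string automaton.

    Parameters
    ----------
    patterns
        Non-empty strings to search for. Duplicates are collapsed; each
        reported match carries the index of the pattern in the deduplicated
        ``self.patterns`` list.
    """

    __slots__ = ("patterns", "pattern_lengths", "_goto", "_fail", "_out")

    def __init__(self, patterns: Sequence[str]) -> None:
        pats: list[str] = []
        seen: dict[str, int] = {}
        for p in patterns:
            if not p:
                raise ValueError("empty pattern")
            if p not in seen:
                seen[p] = len(pats)
                pats.append(p)
        if not pats:
            raise ValueError("at least one pattern is required")
        self.patterns = pats
        self.pattern_lengths = [len(p) for p in pats]

        # trie construction
        goto: list[dict[str, int]] = [{}]
        out: list[list[int]] = [[]]
        for idx, pat in enumerate(pats):
            node = 0
            for ch in pat:
                nxt = goto[node].get(ch)
                if nxt is None:
                    nxt = len(goto)
                    goto[node][ch] = nxt
                    goto.append({})
                    out.append([])
                node = nxt
            out[node].append(idx)

        # failure links via BFS; output links merged into each node so a
        # match report never walks the failure chain at scan time
        fail = [0] * len(goto)
        queue: deque[int] = deque()
        for child in goto[0].values():
            queue.append(child)
        while queue:
            node = queue.popleft()
            for ch, child in goto[node].items():
                queue.append(child)
                f = fail[node]
                while f and ch not in goto[f]:
                    f = fail[f]
                fail[child] = goto[f].get(ch, 0)
                if fail[child] == child:
                    fail[child] = 0
                if out[fail[child]]:
                    out[child] = out[child] + out[fail[child]]

        self._goto = goto
        self._fail = fail
        self._out = [tuple(o) for o in out]

    def iter_matches(self, text: str) -> Iterator[tuple[int, int]]:
        """Yield ``(end_index, pattern_index)`` for every occurrence.

        ``end_index`` is the index of the last character of the match in
        ``text``; the match spans
        ``text[end_index - len(pattern) + 1 : end_index + 1]``.
        """
        goto = self._goto
        fail = self._fail
        out = self._out
        node = 0
        for i, ch in enumerate(text):
            while node and ch not in goto[node]:
                node = fail[node]
            node = goto[node].get(ch, 0)
            if out[node]:
                for pat_idx in out[node]:
                    yield i, pat_idx

    def __len__(self) -> int:
        return len(self.patterns)
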