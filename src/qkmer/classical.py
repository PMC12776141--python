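"""Classical multi-pattern matchers: the ground truth for every quantum run.

Two independent routes — a brute-force window scan and an Aho–Corasick
automaton — that must agree with each other; the quantum stack is then
validated against either.  Positions are 0-based window start indices.
Cyclic matching treats the text as circular (every index 0..n-1 starts a
valid window, wrapping past the end) and is realized by scanning the text
extended with its own first L-1 characters, reporting positions modulo n.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Mapping, Sequence

from .encoding import validate_dna


class MatcherError(ValueError):
    pass


@dataclass(frozen=True)
class MatchSet:
    """All match start positions, overall and per pattern."""

    positions: tuple[int, ...]
    per_pattern: Mapping[str, tuple[int, ...]]

    @classmethod
    def from_per_pattern(cls, per_pattern: Mapping[str, Sequence[int]]) -> "MatchSet":
        merged = sorted({i for ps in per_pattern.values() for i in ps})
        return cls(
            positions=tuple(merged),
            per_pattern={p: tuple(sorted(ps)) for p, ps in per_pattern.items()},
        )


def _checked(text: str, patterns: Sequence[str]) -> tuple[str, list[str], int]:
    text = validate_dna(text, what="text")
    pats = [validate_dna(p, what="pattern") for p in patterns]
    if not pats:
        raise MatcherError("need at least one pattern")
    L = len(pats[0])
    if L == 0:
        raise MatcherError("patterns must be non-empty")
    if any(len(p) != L for p in pats):
        raise MatcherError("patterns must all have the same length (fixed-L dictionaries only)")
    return text, pats, L


def match_naive(text: str, patterns: Sequence[str], addressing: str = "linear") -> MatchSet:
    """Brute-force scan over every window; the defining oracle."""
    text, pats, L = _checked(text, patterns)
    n = len(text)
    per: dict[str, list[int]] = {p: [] for p in pats}
    if addressing == "linear":
        for i in range(n - L + 1):
            w = text[i : i + L]
            if w in per:
                per[w].append(i)
    elif addressing == "cyclic":
        for i in range(n):
            w = "".join(text[(i + j) % n] for j in range(L))
            if w in per:
                per[w].append(i)
    else:
        raise MatcherError(f"unknown addressing {addressing!r}")
    return MatchSet.from_per_pattern(per)


class ACAutomaton:
    """Aho–Corasick automaton: trie + BFS failure links + merged outputs."""

    def __init__(self, patterns: Sequence[str]):
        pats = [validate_dna(p, what="pattern") for p in patterns]
        if not pats or any(len(p) == 0 for p in pats):
            raise MatcherError("patterns must be non-empty")
        self.patterns = list(pats)
        # state 0 is the root; goto is a list of dicts char -> state
        self.goto: list[dict[str, int]] = [{}]
        self.fail: list[int] = [0]
        self.out: list[list[str]] = [[]]
        for p in pats:
            s = 0
            for ch in p:
                if ch not in self.goto[s]:
                    self.goto.append({})
                    self.fail.append(0)
                    self.out.append([])
                    self.goto[s][ch] = len(self.goto) - 1
                s = self.goto[s][ch]
            self.out[s].append(p)
        # failure links by BFS; outputs inherited along the failure chain
        q: deque[int] = deque()
        for s in self.goto[0].values():
            self.fail[s] = 0
            q.append(s)
        while q:
            r = q.popleft()
            for ch, s in self.goto[r].items():
                q.append(s)
                f = self.fail[r]
                while f and ch not in self.goto[f]:
                    f = self.fail[f]
                self.fail[s] = self.goto[f].get(ch, 0) if self.goto[f].get(ch, 0) != s else 0
                self.out[s] = self.out[s] + self.out[self.fail[s]]

    @property
    def state_count(self) -> int:
        return len(self.goto)

    def step(self, state: int, ch: str) -> int:
        while state and ch not in self.goto[state]:
            state = self.fail[state]
        return self.goto[state].get(ch, 0)


def build_automaton(patterns: Sequence[str]) -> ACAutomaton:
    return ACAutomaton(patterns)


def match_ac(
    automaton: ACAutomaton, text: str, addressing: str = "linear"
) -> MatchSet:
    """Single-pass automaton scan; contractually identical to match_naive."""
    text = validate_dna(text, what="text")
    pats = automaton.patterns
    Ls = {len(p) for p in pats}
    if len(Ls) != 1:
        raise MatcherError("fixed-length dictionaries only")
    L = Ls.pop()
    n = len(text)
    per: dict[str, list[int]] = {p: [] for p in pats}
    if addressing == "linear":
        scan, limit = text, n
    elif addressing == "cyclic":
        scan, limit = text + text[: max(0, L - 1)], n
    else:
        raise MatcherError(f"unknown addressing {addressing!r}")
    state = 0
    for idx, ch in enumerate(scan):
        state = automaton.step(state, ch)
        for p in automaton.out[state]:
            start = idx - len(p) + 1
            if 0 <= start < limit:
                per[p].append(start % n if addressing == "cyclic" else start)
    return MatchSet.from_per_pattern(per)
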