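"""Linear design matrices built from named columns, with interaction terms.

A term is a tuple of column names: ``()`` is the intercept, ``("a",)`` a main
effect and ``("a", "b")`` the elementwise product ``a*b``.  Designs are pruned
once against the fitting data (constant and duplicate columns dropped) and the
surviving term list is then reused verbatim when the design is evaluated on
simulated data, so fitted coefficients always line up.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

Term = tuple[str, ...]


def term_name(term: Term) -> str:
    return "const" if not term else ":".join(term)


def main_effects(columns: Sequence[str]) -> list[Term]:
    return [(c,) for c in columns]


def pairwise_interactions(columns: Sequence[str]) -> list[Term]:
    """All unordered pairs of distinct columns, in sorted order."""
    cols = sorted(columns)
    out: list[Term] = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            out.append((a, b))
    return out


def _canon(term: Term) -> Term:
    return tuple(sorted(term))


@dataclass
class LinearDesign:
    """Ordered list of terms with an intercept, evaluable on any column source."""

    terms: list[Term]
    include_intercept: bool = True
    dropped: list[str] = field(default_factory=list)
    _pruned: bool = False

    def __post_init__(self) -> None:
        seen: set[Term] = set()
        uniq: list[Term] = []
        for t in self.terms:
            c = _canon(t)
            if c not in seen:
                seen.add(c)
                uniq.append(t)
        self.terms = uniq

    @property
    def term_names(self) -> list[str]:
        names = ["const"] if self.include_intercept else []
        return names + [term_name(t) for t in self.terms]

    def required_columns(self) -> set[str]:
        return {c for t in self.terms for c in t}

    def matrix(self, values: Mapping[str, np.ndarray], n: int | None = None) -> np.ndarray:
        cols: list[np.ndarray] = []
        if n is None:
            for t in self.terms:
                if t:
                    n = len(np.asarray(values[t[0]], dtype=float))
                    break
            else:
                raise ValueError("cannot infer n for an intercept-only design")
        if self.include_intercept:
            cols.append(np.ones(n))
        for t in self.terms:
            col = np.ones(n)
            for name in t:
                if name not in values:
                    raise KeyError(f"design requires column {name!r}")
                col = col * np.asarray(values[name], dtype=float)
            cols.append(col)
        return np.column_stack(cols) if cols else np.empty((n, 0))

    def prune(self, values: Mapping[str, np.ndarray], n: int | None = None) -> "LinearDesign":
        """Drop constant and exactly duplicated columns, keeping the intercept."""
        if self._pruned:
            return self
        mat = self.matrix(values, n=n)
        start = 1 if self.include_intercept else 0
        kept: list[Term] = []
        dropped: list[str] = []
        seen_keys: set[bytes] = set()
        if self.include_intercept:
            seen_keys.add(np.ascontiguousarray(mat[:, 0]).tobytes())
        for j, t in enumerate(self.terms):
            col = mat[:, start + j]
            if np.ptp(col) == 0.0:
                dropped.append(term_name(t))
                continue
            key = np.ascontiguousarray(col).tobytes()
            if key in seen_keys:
                dropped.append(term_name(t))
                continue
            seen_keys.add(key)
            kept.append(t)
        if dropped:
            logger.info("design pruning dropped %d degenerate column(s): %s",
                        len(dropped), ", ".join(dropped))
        out = LinearDesign(kept, include_intercept=self.include_intercept, dropped=dropped)
        out._pruned = True
        return out
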