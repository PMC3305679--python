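"""Splitting a monograph title into ingredient and route terms.

Monograph titles follow an "ingredient(s) + optional route" pattern:
"Diclofenac Ophthalmic" discusses the eye-drop products of diclofenac,
while plain "Diclofenac" covers the unqualified drug.  Segmentation scans
the title for the leftmost token that appears in a closed lexicon of
route-indicating markers; that token and everything after it become the
route terms R, everything before it the ingredient terms I.  The route
terms later enrich evidence sentences (a sentence "It also comes as a
solution" from "Propranolol Oral" must match "Oral Solution"), and the
ingredient terms drive the first-token evidence pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

#: Route markers attested in monograph titles.  The shipped lexicon file
#: (data/route_markers.txt) carries the same defaults and can be replaced
#: per run.
DEFAULT_ROUTE_MARKERS = frozenset({
    "nasal", "ophthalmic", "otic", "oral", "rectal", "vaginal",
    "topical", "transdermal", "injection", "inhalation",
})


@dataclass(frozen=True)
class RouteLexicon:
    """A nonempty set of lowercase route-marker terms."""

    markers: frozenset[str]

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("route lexicon is empty")
        if any(m != m.lower() for m in self.markers):
            raise ValueError("route markers must be lowercase")

    def __contains__(self, token: str) -> bool:
        return token.lower() in self.markers


def default_lexicon() -> RouteLexicon:
    return RouteLexicon(DEFAULT_ROUTE_MARKERS)


def load_route_lexicon(path: str | Path) -> RouteLexicon:
    """Load a marker lexicon: one term per line, ``#`` comments allowed."""
    markers = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        term = line.split("#", 1)[0].strip().lower()
        if term:
            markers.add(term)
    return RouteLexicon(frozenset(markers))


@dataclass(frozen=True)
class TitleSegmentation:
    """Result of splitting a title into ingredient terms I and route
    terms R; ``marker_position`` is the 1-based index q of the leftmost
    route marker, or None when the title has no route suffix."""

    ingredient_terms: tuple[str, ...]
    route_terms: tuple[str, ...]
    marker_position: int | None

    @property
    def tokens(self) -> tuple[str, ...]:
        return self.ingredient_terms + self.route_terms


def _title_tokens(title: str) -> list[str]:
    # titles are short; commas in multi-ingredient titles are stripped,
    # everything else kept verbatim
    return [tok for tok in title.replace(",", " ").split() if tok]


def segment_title(title: str, lexicon: RouteLexicon | None = None) -> TitleSegmentation:
    """Segment *title* at the leftmost route marker.

    Matching is whole-token and case-insensitive.  When no marker occurs
    — or the title's very first token is a marker, since a title is never
    pure route — the whole title is ingredient and R is empty.
    """
    if not title or not title.strip():
        raise ValueError("empty monograph title")
    lexicon = lexicon or default_lexicon()
    tokens = _title_tokens(title)
    for pos, token in enumerate(tokens):
        if pos > 0 and token.lower() in lexicon.markers:
            return TitleSegmentation(
                ingredient_terms=tuple(tokens[:pos]),
                route_terms=tuple(tokens[pos:]),
                marker_position=pos + 1,
            )
    return TitleSegmentation(
        ingredient_terms=tuple(tokens), route_terms=(), marker_position=None
    )
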