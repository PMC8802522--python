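"""Basic text mining over step descriptions.

Four repeating textual patterns carry most of the machine-readable signal in
wet-lab step descriptions:

* **parameters** — a number immediately followed by a measurement unit
  ("5min", "37°C", "7.9Hz", "1.5 ml"); each maps to a unit-ontology class;
* **mixtures** — recipes of the form
  ``89% [Culture Medium] DMEM + 10% [Serum] FCS + 1% [Antibiotic] Gentamicin``,
  optionally followed by an attribution note;
* **resource mentions** — ``[Category] Name`` with optional passage
  (``P25``) and lot (``LOT 57840088``) tokens;
* **head verbs** — the leading verb of a step selects ontology classes from
  a configured mapping ("wash" -> washing, "incubate" -> incubation, ...).

Only regular expressions and lookup tables are used — no statistical NLP.
Ties resolve to the first match; the first recognised verb wins.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .config import DEFAULT_CONFIG, PipelineConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParameterMention:
    value: float
    unit_token: str
    unit_class: str
    char_span: tuple[int, int]


@dataclass(frozen=True)
class MixtureComponent:
    fraction_percent: float
    category: str
    name: str

    def __post_init__(self) -> None:
        if not self.fraction_percent > 0:
            raise ValueError("fraction_percent must be > 0")


@dataclass(frozen=True)
class MixtureSpec:
    components: tuple[MixtureComponent, ...]
    attribution: str | None
    source_text: str

    def __post_init__(self) -> None:
        if len(self.components) < 2:
            raise ValueError("a mixture needs at least two components")

    def recipe_key(self) -> tuple[tuple[float, str, str], ...]:
        """Identity of the recipe: the ordered component list."""
        return tuple((c.fraction_percent, c.category, c.name) for c in self.components)


@dataclass(frozen=True)
class ResourceMention:
    category: str
    name: str
    passage_number: int | None
    lot_number: str | None
    char_span: tuple[int, int]


@dataclass
class VerbMapping:
    entries: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = {k.lower(): list(v) for k, v in self.entries.items()}


def _number(tok: str) -> float:
    return float(tok.replace(",", "."))


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

def _parameter_regex(config: PipelineConfig) -> re.Pattern[str]:
    # longest unit token first so overlapping matches resolve to the longest
    units = "|".join(re.escape(u) for u in config.unit_tokens_longest_first())
    return re.compile(
        rf"(?<![\w.,])({config.number_pattern})\s*({units})(?![A-Za-zµ°])"
    )


def extract_parameters(
    text: str, config: PipelineConfig = DEFAULT_CONFIG
) -> list[ParameterMention]:
    """Every maximal number+unit occurrence, left to right.

    Decimal commas are normalised to points.  Tokens whose unit is not in the
    configured unit table are not parameters and are skipped.
    """
    out: list[ParameterMention] = []
    for m in _parameter_regex(config).finditer(text):
        unit_token = m.group(2)
        unit_class = config.unit_map.get(unit_token)
        if unit_class is None:  # pragma: no cover - regex only admits known units
            logger.debug("unknown unit %r ignored", unit_token)
            continue
        out.append(
            ParameterMention(
                value=_number(m.group(1)),
                unit_token=unit_token,
                unit_class=unit_class,
                char_span=m.span(),
            )
        )
    return out


# --------------------------------------------------------------------------
# mixtures
# --------------------------------------------------------------------------

# percent "[" category "]" name, joined by "+"; names may contain
# parentheticals ("HEPES I (isotonic)") but not "+" or "[".
_COMPONENT = r"(\d+(?:[.,]\d+)?)\s*%\s*\[([^\]]+)\]\s*([^+\[]+?)"
_ATTRIBUTION_RE = re.compile(r"\(Attributed to\s+([^)]+)\)")


def _mixture_regex() -> re.Pattern[str]:
    return re.compile(
        rf"{_COMPONENT}(?:\s*\+\s*{_COMPONENT})+"
        r"(?=\s*(?:\(Attributed to[^)]*\))?\s*(?:[.,;]|$))"
    )


_COMPONENT_RE = re.compile(_COMPONENT + r"\s*(?=\+|$)")


def parse_mixture(text: str) -> MixtureSpec | None:
    """Parse the first mixture recipe in *text*, if any.

    Returns ``None`` unless at least two ``percent [Category] Name``
    components joined by ``+`` are present (the strict bracketed-category
    grammar); a trailing ``(Attributed to NAME)`` is captured.
    """
    m = _mixture_regex().search(text)
    if m is None:
        return None
    source = m.group(0).strip()
    components = tuple(
        MixtureComponent(
            fraction_percent=_number(c.group(1)),
            category=c.group(2).strip(),
            name=c.group(3).strip(),
        )
        for c in _COMPONENT_RE.finditer(source)
    )
    if len(components) < 2:
        return None
    attribution = None
    attr = _ATTRIBUTION_RE.search(text, m.end())
    if attr:
        attribution = attr.group(1).strip()
    return MixtureSpec(components=components, attribution=attribution, source_text=source)


# --------------------------------------------------------------------------
# resource mentions
# --------------------------------------------------------------------------

# name stops at the next bracket, '+', parenthesis, punctuation, a passage or
# lot token, or a short connective ("at", "in", "with", ...).
_STOPWORDS = r"(?:at|in|with|on|to|for|into|from|of|and|as)"
_RESOURCE_RE = re.compile(
    r"\[([^\]]+)\]\s*"
    r"((?:(?!\s+P\d+\b)(?!\s+LOT\b)(?!\s+" + _STOPWORDS + r"\b)[^\[\]+(.,;:])+)"
    r"(?:\s+P(\d+)\b)?"
    r"(?:\s+LOT\s+(\S+))?"
)


def parse_resource_mention(text: str) -> list[ResourceMention]:
    """All ``[Category] Name`` occurrences with optional passage/lot tokens.

    Mentions never overlap (the scan is a single left-to-right pass).
    """
    out: list[ResourceMention] = []
    for m in _RESOURCE_RE.finditer(text):
        category = m.group(1).strip()
        name = m.group(2).strip()
        if not category or not name:
            continue
        passage = int(m.group(3)) if m.group(3) else None
        lot = m.group(4).rstrip(".,;)") if m.group(4) else None
        out.append(
            ResourceMention(
                category=category, name=name,
                passage_number=passage, lot_number=lot,
                char_span=m.span(),
            )
        )
    return out


# --------------------------------------------------------------------------
# activity classification and attribution
# --------------------------------------------------------------------------

_WORD_RE = re.compile(r"[A-Za-zäöüÄÖÜß-]+")


def classify_activity(
    step_text: str,
    mapping: VerbMapping | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[str]:
    """Ontology classes for the first recognised verb lemma in *step_text*.

    Words are lower-cased and reduced through a small built-in lemma table;
    the first word with a mapping entry wins.  No mapped verb -> empty list
    (the activity keeps only its generic types).
    """
    entries = mapping.entries if mapping is not None else {
        k.lower(): v for k, v in config.verb_map.items()
    }
    if not entries:
        raise ValueError("verb mapping must be non-empty")
    lemmas = config.lemma_table
    for word in _WORD_RE.findall(step_text):
        lemma = word.lower()
        lemma = lemmas.get(lemma, lemma)
        if lemma in entries:
            return list(entries[lemma])
    return []


def extract_attribution(text: str) -> str | None:
    """NAME from the first ``(Attributed to NAME)`` occurrence, else None."""
    m = _ATTRIBUTION_RE.search(text)
    return m.group(1).strip() if m else None
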