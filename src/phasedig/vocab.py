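"""Controlled vocabulary of surfactant-water phase-state labels.

A *phase state* is either a single phase (``"L1"``, ``"La"``, ...) or a
two-phase coexistence region written as the two single-phase codes joined by
``"+"`` in alphabetical order (``"W+X1"``, never ``"X1+W"``).  The packaged
vocabulary carries the single-phase labels with their typical literature
aliases (the same lamellar phase appears in sources as ``D``, ``G`` or
``L_α``), plus the canonical list of the 118 distinct states observed across
the digitized corpus.  The reserved label ``"U"`` marks unknown regions of
incomplete diagrams and is excluded from the canonical list.
"""

from __future__ import annotations

import json
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .exceptions import ArityError, VocabularyError

__all__ = [
    "UNMAPPED",
    "PhaseLabel",
    "PhaseState",
    "Vocabulary",
    "canonical_state",
    "resolve_alias",
    "enumerate_states",
    "load_vocabulary",
]

#: Sentinel returned by :func:`resolve_alias` for labels it cannot map.
#: Resolution never silently guesses.
UNMAPPED = "unmapped"

UNKNOWN_CODE = "U"

_GREEK = {"α": "a", "β": "b", "Α": "a", "Β": "b"}


def _normalize_alias(text: str) -> str:
    """Case-, subscript- and typography-insensitive key for alias lookup."""
    out = []
    for ch in unicodedata.normalize("NFKC", text):
        ch = _GREEK.get(ch, ch)
        if ch in "_-'’":
            continue
        out.append(ch.lower())
    return " ".join("".join(out).split())


@dataclass(frozen=True)
class PhaseLabel:
    """One single-phase label of the controlled vocabulary."""

    code: str
    description: str
    literature_aliases: tuple[str, ...] = ()


@dataclass(frozen=True)
class PhaseState:
    """A one- or two-phase state in canonical form."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(sorted(self.labels)))

    @property
    def canonical_string(self) -> str:
        return "+".join(self.labels)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical_string


@dataclass
class Vocabulary:
    """Single-phase labels, alias map and the canonical observed-state list."""

    single_phase: dict[str, PhaseLabel]
    canonical_states: tuple[str, ...]
    provenance: str = ""
    reconstructed_states: tuple[str, ...] = ()
    _alias_map: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._alias_map:
            for label in self.single_phase.values():
                self._alias_map[_normalize_alias(label.code)] = label.code
                for alias in label.literature_aliases:
                    self._alias_map[_normalize_alias(alias)] = label.code

    # -- state handling ---------------------------------------------------

    def canonical_state(self, labels: list[str] | tuple[str, ...] | str) -> PhaseState:
        """Canonicalize 1-2 single-phase codes into a :class:`PhaseState`.

        Codes are sorted alphabetically and joined with ``"+"`` so that the
        result is invariant under input order (``["X1","W"]`` -> ``"W+X1"``).
        """
        if isinstance(labels, str):
            labels = labels.split("+")
        labels = [str(c) for c in labels]
        if not 1 <= len(labels) <= 2:
            raise ArityError(
                f"a phase state has one or two labels, got {len(labels)}: {labels!r}"
            )
        for code in labels:
            if code not in self.single_phase:
                raise VocabularyError(f"unknown phase label {code!r}")
        if len(labels) == 2 and labels[0] == labels[1]:
            raise ArityError(f"two-phase state repeats the label {labels[0]!r}")
        return PhaseState(tuple(labels))

    def resolve_alias(self, lit_label: str) -> str:
        """Map a literature label (e.g. ``"L_α"``) to its dataset code.

        Unknown aliases return the :data:`UNMAPPED` sentinel; an empty string
        is an input error.
        """
        if not isinstance(lit_label, str) or not lit_label.strip():
            raise ValueError("literature label must be a non-empty string")
        return self._alias_map.get(_normalize_alias(lit_label), UNMAPPED)

    def enumerate_states(self) -> list[PhaseState]:
        """The canonical observed-state list (118 states, ``U`` excluded)."""
        return [PhaseState(tuple(s.split("+"))) for s in self.canonical_states]

    def is_valid_state(self, state: str, allow_unknown: bool = False) -> bool:
        """Whether *state* is built from known labels with valid arity."""
        parts = state.split("+")
        if not 1 <= len(parts) <= 2 or len(set(parts)) != len(parts):
            return False
        for code in parts:
            if code == UNKNOWN_CODE:
                if not allow_unknown:
                    return False
            elif code not in self.single_phase:
                return False
        return True


def load_vocabulary(path: str | Path | None = None) -> Vocabulary:
    """Load the packaged vocabulary, or a user override via *path*."""
    if path is None:
        text = resources.files("phasedig.data").joinpath("vocabulary.json").read_text()
    else:
        text = Path(path).read_text()
    doc = json.loads(text)
    single = {
        entry["code"]: PhaseLabel(
            entry["code"],
            entry.get("description", ""),
            tuple(entry.get("literature_aliases", ())),
        )
        for entry in doc["single_phase"]
    }
    states = tuple(doc["canonical_states"])
    for s in states:
        if UNKNOWN_CODE in s.split("+"):
            raise VocabularyError("the canonical state list must exclude 'U'")
        for code in s.split("+"):
            if code not in single:
                raise VocabularyError(f"state {s!r} uses unknown label {code!r}")
    return Vocabulary(
        single_phase=single,
        canonical_states=states,
        provenance=doc.get("provenance", ""),
        reconstructed_states=tuple(doc.get("reconstructed_states", ())),
    )


_DEFAULT: Vocabulary | None = None


def _default_vocab() -> Vocabulary:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_vocabulary()
    return _DEFAULT


def canonical_state(labels: list[str] | tuple[str, ...] | str) -> PhaseState:
    """Module-level convenience over the packaged vocabulary."""
    return _default_vocab().canonical_state(labels)


def resolve_alias(lit_label: str) -> str:
    """Module-level convenience over the packaged vocabulary."""
    return _default_vocab().resolve_alias(lit_label)


def enumerate_states() -> list[PhaseState]:
    """Module-level convenience over the packaged vocabulary."""
    return _default_vocab().enumerate_states()
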