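"""Regularisation of author-supplied chemical names.

Names recorded in crystallographic data files accumulate formatting
artefacts — surrounding quotes, trailing dots, mixture-proportion
suffixes, CIF superscript notation, recurrent misspellings — that trip
up downstream name-to-structure conversion.  This module is the
standalone text filter that cleans them up; it never attempts to parse
nomenclature itself.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

__all__ = ["NameRecord", "regularise_name", "SPELLING_FIXES"]

#: Corrections of widespread minor spelling mistakes.  Extensible: the
#: shipped table carries the documented pairs; callers may pass their own.
SPELLING_FIXES: Dict[str, str] = {
    "napthalen": "naphthalen",
}

# Mixture-proportion suffixes.  The exact shapes vary across depositions;
# these patterns (trailing parenthesised or bare integer ratios, and the
# word "solvate" with an optional multiplier) are documented approximations.
_RATIO_PAREN = re.compile(r"\s*\(\d+(?:[:/]\d+)+\)\s*$")
_RATIO_BARE = re.compile(r"\s+\d+(?:[:/]\d+)+\s*$")
_SOLVATE = re.compile(r"\s+(?:\d+(?:\.\d+)?\s*)?solvate\s*$", re.IGNORECASE)

_SUPERSCRIPT = re.compile(r"\^([^^]*)\^")


@dataclass
class NameRecord:
    """A chemical name before and after regularisation."""

    raw: str
    regularised: str
    applied_rules: List[str] = field(default_factory=list)
    flags: List[str] = field(default_factory=list)


def _strip_quotes_and_dots(name: str) -> Tuple[str, bool]:
    changed = False
    text = name.strip()
    while True:  # quotes and dots can nest ("'name'." needs both passes)
        before = text
        while len(text) >= 2 and text[0] == text[-1] and text[0] in "'\"`":
            text = text[1:-1].strip()
        while text.endswith("."):
            text = text[:-1].rstrip()
        if text == before:
            break
        changed = True
    return text, changed or text != name


def _balanced(text: str) -> bool:
    counts = {"(": 0, "[": 0, "{": 0}
    closing = {")": "(", "]": "[", "}": "{"}
    for ch in text:
        if ch in counts:
            counts[ch] += 1
        elif ch in closing:
            counts[closing[ch]] -= 1
            if counts[closing[ch]] < 0:
                return False
    return all(v == 0 for v in counts.values())


def regularise_name(raw: str, spelling_fixes: Dict[str, str] = SPELLING_FIXES) -> NameRecord:
    """Clean a chemical name for downstream name-to-structure conversion.

    Rules are applied in a fixed order: (1) strip surrounding quotes and
    terminating dots; (2) remove mixture-proportion suffixes (numeric
    ratios and the word "solvate"); (3) convert ``^...^`` superscript
    notation to plain locants; (4) apply the spelling-fix table.  Names
    with unbalanced parentheses are passed through but flagged — they are
    clearly erroneous yet need expert curation.
    """
    applied: List[str] = []
    text = raw.strip()
    # A later rule can expose material for an earlier one (e.g. removing a
    # superscript may leave a terminating dot), so the pass repeats until
    # the name is stable; regularisation is then idempotent by construction.
    while True:
        start = text

        stripped, _ = _strip_quotes_and_dots(text)
        # Never reduce a non-empty name to nothing: a bare "''" stays as given.
        if stripped and stripped != text:
            applied.append("strip-quotes-dots")
            text = stripped

        before = text
        cleaned = _RATIO_PAREN.sub("", text)
        cleaned = _RATIO_BARE.sub("", cleaned)
        cleaned = _SOLVATE.sub("", cleaned)
        if cleaned.strip() and cleaned != before:
            applied.append("mixture-proportions")
            text = cleaned.strip()

        before = text
        converted = _SUPERSCRIPT.sub(r"\1", text)
        if converted != before:
            applied.append("superscripts")
            text = converted

        before = text
        for wrong, right in sorted(spelling_fixes.items()):
            # protect corrected occurrences so fixes whose replacement
            # contains the misspelling (e.g. fluorid -> fluoride) settle
            parts = text.split(right)
            text = right.join(p.replace(wrong, right) for p in parts)
        if text != before:
            applied.append("spelling")

        if text == start:
            break

    flags = [] if _balanced(text) else ["unbalanced-parentheses"]
    return NameRecord(raw=raw, regularised=text, applied_rules=applied, flags=flags)
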