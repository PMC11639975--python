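"""Clinical-report parsing: the EHR guidance signal.

A radiology or pathology report mentions many locations — the current
determinate tumor, incidental indeterminate nodules, previously treated
disease — and the guidance signal the pipeline needs is only the lobe(s) of
the *current determinate* tumor plus any malignant lymph stations.  Two
backends produce that signal:

* :func:`extract_findings_rules` — a deterministic sentence-level extractor
  (the default; fully offline and reproducible);
* :func:`extract_findings_llm` — zero-shot prompting of a pluggable
  language-model client at temperature 0, with the exact prompt wording in
  :func:`build_prompts`.  The client is dependency-injected so nothing in
  the package ever needs network access.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Protocol

__all__ = [
    "LOBE_CODES",
    "LOBE_NAMES",
    "PromptBundle",
    "ExtractionResult",
    "LLMClient",
    "build_prompts",
    "normalize_lobe_term",
    "lobe_code_to_name",
    "extract_findings_rules",
    "extract_findings_llm",
]

#: The five pulmonary lobes, in label order 1..5.
LOBE_CODES: tuple[str, ...] = ("RUL", "RML", "RLL", "LUL", "LLL")

#: Canonical full names for each lobe code.
LOBE_NAMES: dict[str, str] = {
    "RUL": "right upper lobe",
    "RML": "right middle lobe",
    "RLL": "right lower lobe",
    "LUL": "left upper lobe",
    "LLL": "left lower lobe",
}

# full-name and abbreviation synonyms -> code ("inferior"/"superior" are the
# anatomical synonyms of lower/upper; RIL/LIL style abbreviations follow)
_TERM_TO_CODE: dict[str, str] = {}
for _code, _name in LOBE_NAMES.items():
    _TERM_TO_CODE[_name] = _code
    _TERM_TO_CODE[_code.lower()] = _code
_TERM_TO_CODE.update(
    {
        "right inferior lobe": "RLL",
        "left inferior lobe": "LLL",
        "right superior lobe": "RUL",
        "left superior lobe": "LUL",
        "ril": "RLL",
        "lil": "LLL",
        "rsl": "RUL",
        "lsl": "LUL",
        "middle lobe": "RML",
    }
)

_TUMOR_WORDS = ("tumor", "tumour", "carcinoma", "malignancy", "adenocarcinoma", "cancer")
_HISTORY_CUES = ("previously", "status post", "history of", "prior ", "s/p", "was treated", "underwent")
_STATION_RE = re.compile(r"\bstation\s+(\d{1,2}[RLrl]?)\b", re.IGNORECASE)
_LOBE_RE = re.compile(
    r"\b(" + "|".join(sorted(_TERM_TO_CODE, key=len, reverse=True)) + r")\b",
    re.IGNORECASE,
)


@dataclass(frozen=True)
class PromptBundle:
    """Zero-shot prompts for tumor-lobe and malignant-lymph extraction."""

    assistant_prompt: str
    user_prompt_lobe: str
    user_prompt_lymph: str
    temperature: float = 0.0


@dataclass
class ExtractionResult:
    """Confirmed tumor lobe(s) and malignant lymph stations from one report."""

    lobes: set[str] = field(default_factory=set)
    lymph_stations: list[str] = field(default_factory=list)
    provenance: str = "rule"
    raw_response: str = ""

    def __post_init__(self) -> None:
        bad = self.lobes - set(LOBE_CODES)
        if bad:
            raise ValueError(f"invalid lobe codes: {sorted(bad)}")

    @property
    def has_guidance(self) -> bool:
        return bool(self.lobes)


class LLMClient(Protocol):
    """Contract for a chat-completion backend (injected, never constructed here)."""

    def complete(self, assistant_prompt: str, user_prompt: str, temperature: float) -> str:
        ...


def build_prompts() -> PromptBundle:
    """The engineered zero-shot prompts, with temperature pinned to 0.

    The lobe prompt carries three load-bearing keywords: *current* (skip
    treated historical disease), *determinate* (skip indeterminate
    nodules), and the synonym list *tumor/carcinoma/malignancy* (reports
    vary in word choice).
    """
    options = ", ".join(f"{name} ({code})" for code, name in LOBE_NAMES.items())
    return PromptBundle(
        assistant_prompt=(
            "You extract structured findings from lung cancer clinical reports. "
            f"Answer with exactly one of the following options: {options}."
        ),
        user_prompt_lobe=(
            "Find the current lung lobe that the determinate "
            "tumor/carcinoma/malignancy is involved in this report:"
        ),
        user_prompt_lymph="Find out what lymph station/node is malignant in this report:",
        temperature=0.0,
    )


def lobe_code_to_name(code: str) -> str:
    """Full English name for a lobe code (inverse of :func:`normalize_lobe_term`)."""
    try:
        return LOBE_NAMES[code.upper()]
    except KeyError:
        raise ValueError(f"unknown lobe code: {code!r}") from None


def normalize_lobe_term(term: str) -> str | None:
    """Map a lobe mention (full name, abbreviation, inferior/superior synonym)
    onto one of RUL/RML/RLL/LUL/LLL; ``None`` when unmappable — never a guess."""
    if not term or not term.strip():
        raise ValueError("empty lobe term")
    key = re.sub(r"\s+", " ", term.strip().lower())
    if key in _TERM_TO_CODE:
        return _TERM_TO_CODE[key]
    m = _LOBE_RE.search(key)
    if m:
        return _TERM_TO_CODE[m.group(1).lower()]
    return None


def _split_sentences(text: str) -> list[str]:
    parts = re.split(r"[.;\n]+", text)
    return [p.strip() for p in parts if p.strip()]


def extract_findings_rules(report: str) -> ExtractionResult:
    """Deterministic sentence-level extraction of the guidance signal.

    A sentence contributes a confirmed lobe when it mentions a lobe and a
    tumor word (tumor/carcinoma/malignancy/...), and is neither qualified
    as *indeterminate* nor phrased as treatment history (lexical cues such
    as "previously", "status post", dated history).  Lymph stations are
    collected from sentences in which stations co-occur with
    "malignant"/"positive".  Pure function: same text, same result.
    """
    if not report or not report.strip():
        raise ValueError("empty report text")
    lobes: set[str] = set()
    stations: list[str] = []
    for sentence in _split_sentences(report):
        low = sentence.lower()
        station_ids = _STATION_RE.findall(sentence)
        if station_ids and ("malignant" in low or "positive" in low):
            for sid in station_ids:
                norm = f"station {sid.upper()}"
                if norm not in stations:
                    stations.append(norm)
        if "indeterminate" in low:
            continue
        if any(cue in low for cue in _HISTORY_CUES):
            continue
        if re.search(r"\bin (19|20)\d\d\b", low):
            continue
        if not any(w in low for w in _TUMOR_WORDS):
            continue
        for m in _LOBE_RE.finditer(low):
            code = _TERM_TO_CODE[m.group(1).lower()]
            lobes.add(code)
    return ExtractionResult(lobes=lobes, lymph_stations=stations, provenance="rule", raw_response=report)


def extract_findings_llm(
    report: str,
    bundle: PromptBundle | None = None,
    client: LLMClient | None = None,
) -> ExtractionResult:
    """Zero-shot extraction through an injected language-model client.

    Issues one lobe query and one lymph query, both at the bundle's
    temperature.  Responses are normalised through
    :func:`normalize_lobe_term`; an unmappable lobe response raises rather
    than guessing.
    """
    if not report or not report.strip():
        raise ValueError("empty report text")
    if client is None:
        raise ValueError("extract_findings_llm requires a language-model client")
    bundle = bundle or build_prompts()
    try:
        lobe_resp = client.complete(
            bundle.assistant_prompt, f"{bundle.user_prompt_lobe}\n\n{report}", bundle.temperature
        )
        lymph_resp = client.complete(
            bundle.assistant_prompt, f"{bundle.user_prompt_lymph}\n\n{report}", bundle.temperature
        )
    except Exception as exc:  # propagate with context
        raise RuntimeError(f"language-model client failed: {exc}") from exc
    code = normalize_lobe_term(lobe_resp)
    if code is None:
        raise ValueError(f"unparseable lobe response from client: {lobe_resp!r}")
    stations = [f"station {sid.upper()}" for sid in _STATION_RE.findall(lymph_resp)]
    return ExtractionResult(
        lobes={code},
        lymph_stations=stations,
        provenance="llm",
        raw_response=f"{lobe_resp}\n{lymph_resp}",
    )
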