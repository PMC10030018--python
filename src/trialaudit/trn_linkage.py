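"""Bidirectional registry↔publication linkage.

One direction: find trial registration numbers (TRNs) in publication
abstracts and full texts with registry-specific regular expressions.
The other: find the publication's DOI or PMID among the references a
registration carries. Each flag is ternary — True/False when the trial
enters the metric's denominator, ``None`` when the denominator condition
fails (no PMID, no full text, no DOI/PMID, or a dissertation).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .partialdates import PartialDate
from .registry_io import TrialRecord, normalize_trn

# Registry-documented identifier formats. Detection tolerates one optional
# space or hyphen between prefix and digits and is case-insensitive; a
# digit immediately before/after the match rejects truncated or overlong
# identifiers.
@dataclass(frozen=True)
class TRNPattern:
    registry_key: str
    pattern: re.Pattern

    def canonicalize(self, raw: str) -> str:
        if self.registry_key == "eudract":
            digits = re.sub(r"[^\d]", "", raw)
            return f"{digits[:4]}-{digits[4:10]}-{digits[10:12]}"
        return normalize_trn(raw)


DEFAULT_PATTERNS: tuple[TRNPattern, ...] = (
    TRNPattern("ctgov", re.compile(r"(?<![A-Z0-9])NCT[ -]?(\d{8})(?!\d)", re.IGNORECASE)),
    TRNPattern("drks", re.compile(r"(?<![A-Z0-9])DRKS[ -]?(\d{8})(?!\d)", re.IGNORECASE)),
    TRNPattern("isrctn", re.compile(r"(?<![A-Z0-9])ISRCTN[ -]?(\d{8})(?!\d)", re.IGNORECASE)),
    TRNPattern(
        "eudract",
        re.compile(r"(?<![A-Z0-9])(?:EUDRACT[ -]?)?(\d{4}-\d{6}-\d{2})(?![\d-])", re.IGNORECASE),
    ),
)


@dataclass(frozen=True)
class TRNHit:
    registry_key: str
    canonical_id: str
    char_offset: int
    source: str = "text"


@dataclass
class Publication:
    """A results article with identifiers, texts and a dissertation flag."""

    pub_id: str
    doi: Optional[str] = None
    pmid: Optional[str] = None
    publication_date: Optional[PartialDate] = None
    is_dissertation: bool = False
    abstract: Optional[str] = None
    full_text: Optional[str] = None


@dataclass
class LinkAssessment:
    """Ternary link flags for one trial-publication pair.

    ``None`` means the pair is outside the metric's denominator, never
    "assessed false".
    """

    trial_trn: str
    pub_id: Optional[str]
    trn_in_abstract: Optional[bool] = None
    trn_in_full_text: Optional[bool] = None
    trn_in_both: Optional[bool] = None
    publication_linked_in_registry: Optional[bool] = None


def detect_trns(
    text: str,
    patterns: Sequence[TRNPattern] = DEFAULT_PATTERNS,
    source: str = "text",
) -> list[TRNHit]:
    """Find all TRNs in free text.

    Case-insensitive; tolerates one space or hyphen between registry prefix
    and digits. Canonical IDs are deduplicated per registry, keeping the
    offset of the first occurrence.
    """
    hits: list[TRNHit] = []
    if not text:
        return hits
    for pat in patterns:
        seen: set[str] = set()
        for m in pat.pattern.finditer(text):
            canonical = pat.canonicalize(m.group(0))
            if canonical in seen:
                continue
            seen.add(canonical)
            hits.append(TRNHit(pat.registry_key, canonical, m.start(), source))
    hits.sort(key=lambda h: h.char_offset)
    return hits


def normalize_doi(text: str) -> str:
    """Canonicalize a DOI: strip resolver prefixes, lowercase, trim.

    Raises ``ValueError`` when the remainder does not start with ``10.``.
    """
    if not text or not str(text).strip():
        raise ValueError("empty DOI")
    s = str(text).strip()
    s = re.sub(r"^(https?://(dx\.)?doi\.org/|doi:)\s*", "", s, flags=re.IGNORECASE)
    s = s.strip().rstrip(".,;:")
    if not s.startswith("10."):
        raise ValueError(f"not a DOI: {text!r}")
    return s.lower()


def _trial_trns(trial: TrialRecord) -> set[str]:
    return {trial.trn, *map(normalize_trn, trial.cross_registered_trns)}


def _contains_trial_trn(text: str, trial: TrialRecord) -> bool:
    wanted = _trial_trns(trial)
    return any(hit.canonical_id in wanted for hit in detect_trns(text))


def assess_trn_in_abstract(trial: TrialRecord, pub: Optional[Publication]) -> Optional[bool]:
    """TRN-in-abstract flag; denominator requires a PMID and an abstract.

    A TRN of any known cross-registration of the trial also counts: the
    deduplicated trial is one study under either identifier.
    """
    if pub is None or pub.is_dissertation or not pub.pmid or pub.abstract is None:
        return None
    return _contains_trial_trn(pub.abstract, trial)


def assess_trn_in_full_text(trial: TrialRecord, pub: Optional[Publication]) -> Optional[bool]:
    """TRN-in-full-text flag; denominator requires a retrieved full text."""
    if pub is None or pub.is_dissertation or pub.full_text is None:
        return None
    return _contains_trial_trn(pub.full_text, trial)


def assess_publication_link_in_registry(
    trial: TrialRecord, pub: Optional[Publication]
) -> Optional[bool]:
    """Is the results publication linked from the registration?

    Denominator: the publication carries a DOI or a PMID. True when any
    registry reference matches the publication's normalized DOI or PMID.
    """
    if pub is None or pub.is_dissertation or not (pub.doi or pub.pmid):
        return None
    pub_doi = None
    if pub.doi:
        try:
            pub_doi = normalize_doi(pub.doi)
        except ValueError:
            pub_doi = None
    pub_pmid = str(pub.pmid) if pub.pmid else None
    for ref in trial.references:
        if pub_doi and ref.doi:
            try:
                if normalize_doi(ref.doi) == pub_doi:
                    return True
            except ValueError:
                pass
        if pub_pmid and ref.pmid and str(ref.pmid) == pub_pmid:
            return True
    return False


def assess_links(trial: TrialRecord, pub: Optional[Publication]) -> LinkAssessment:
    """All bidirectional link flags for one trial-publication pair."""
    in_abs = assess_trn_in_abstract(trial, pub)
    in_ft = assess_trn_in_full_text(trial, pub)
    both = (in_abs and in_ft) if (in_abs is not None and in_ft is not None) else None
    return LinkAssessment(
        trial_trn=trial.trn,
        pub_id=pub.pub_id if pub else None,
        trn_in_abstract=in_abs,
        trn_in_full_text=in_ft,
        trn_in_both=both,
        publication_linked_in_registry=assess_publication_link_in_registry(trial, pub),
    )


# ---------------------------------------------------------------------------
# Publication input


def _opt(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return s or None


def publication_from_row(row: dict, base_dir: Optional[Path] = None) -> Publication:
    """Build a :class:`Publication` from one raw row.

    Accepts full text either inline (``full_text``) or as a plain-text file
    referenced by ``full_text_path`` relative to ``base_dir``.
    """
    from .registry_io import _as_bool, _as_date  # shared coercions

    full_text = _opt(row.get("full_text"))
    path = _opt(row.get("full_text_path"))
    if full_text is None and path:
        p = Path(path)
        if base_dir is not None and not p.is_absolute():
            p = base_dir / p
        full_text = p.read_text(encoding="utf-8")
    return Publication(
        pub_id=str(row["pub_id"]),
        doi=_opt(row.get("doi")),
        pmid=_opt(row.get("pmid")),
        publication_date=_as_date(row.get("publication_date")),
        is_dissertation=_as_bool(row.get("is_dissertation")),
        abstract=_opt(row.get("abstract_text") if "abstract_text" in row else row.get("abstract")),
        full_text=full_text,
    )


def read_publications(path: Union[str, Path]) -> dict[str, Publication]:
    """Read publication metadata from CSV or JSON-lines, keyed by pub_id."""
    path = Path(path)
    if path.suffix in {".jsonl", ".ndjson", ".json"}:
        rows = [json.loads(line) for line in path.read_text(encoding="utf-8").splitlines() if line.strip()]
    else:
        rows = pd.read_csv(path, dtype=str).to_dict(orient="records")
    pubs = [publication_from_row(row, base_dir=path.parent) for row in rows]
    return {p.pub_id: p for p in pubs}


def read_trial_publication_links(path: Union[str, Path]) -> dict[str, str]:
    """Read the (trn, pub_id) mapping of earliest results publications."""
    df = pd.read_csv(path, dtype=str)
    return {normalize_trn(trn): pub for trn, pub in zip(df["trn"], df["pub_id"])}
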