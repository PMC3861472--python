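"""Tag annotation: description adequacy, best-hit selection and GO summaries.

Anchored unitags inherit annotation from their reference targets.  A hit with
a usable (non-placeholder) description and GO terms is more informative than
one with only a description or only GO terms, which in turn beats one with
neither; within an informativeness class the focal species beats related
legumes, which beat other angiosperms, and residual ties fall back on the
alignment (score, length, identity).  This three-round redundancy elimination
yields one best hit per tag.

GO summaries count distinct up- and down-regulated tags per GO term; a tag
annotated with k terms contributes to k rows, so column sums can exceed the
distinct-tag count.  No GO-DAG ancestor propagation is performed: terms are
counted as assigned.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .diffexpr import DR, NS, UR

GO_ID_RE = re.compile(r"^GO:\d{7}$")
GO_NAMESPACES = ("BP", "MF", "CC")

#: description substrings that mark a hit as uninformative (word-boundary,
#: case-insensitive); "hypothetical" is a common extra, off by default
DEFAULT_BLACKLIST = ("unknown", "clone", "chromosome")

#: taxon -> tier: 1 focal species, 2 related legume, 3 other angiosperm.
#: Unlisted taxa default to tier 4.
DEFAULT_TAXON_TIERS = {
    "Glycine max": 1,
    "Phaseolus vulgaris": 2,
    "Phaseolus coccineus": 2,
    "Vigna unguiculata": 2,
    "Medicago truncatula": 2,
    "Lotus japonicus": 2,
    "Cicer arietinum": 2,
    "Pisum sativum": 2,
    "Arachis hypogaea": 2,
    "Arabidopsis thaliana": 3,
}


def is_adequate(description: str, blacklist: Sequence[str] = DEFAULT_BLACKLIST) -> bool:
    """Whether a hit description counts as an informative gene/function description.

    Empty descriptions and descriptions containing any blacklisted word
    (word-boundary, case-insensitive) are inadequate.
    """
    if not description or not description.strip():
        return False
    for pattern in blacklist:
        if re.search(rf"\b{re.escape(pattern)}\b", description, flags=re.IGNORECASE):
            return False
    return True


@dataclass(frozen=True)
class AnnotationRecord:
    """Annotation attached to one reference target."""

    target_id: str
    description: str = ""
    go_terms: frozenset[str] = frozenset()
    taxon: str = ""
    blacklist: tuple[str, ...] = DEFAULT_BLACKLIST
    taxon_tiers: Mapping[str, int] = field(default_factory=lambda: DEFAULT_TAXON_TIERS)

    def __post_init__(self) -> None:
        for go in self.go_terms:
            if not GO_ID_RE.match(go):
                raise ValueError(f"malformed GO id: {go!r}")

    @property
    def adequate(self) -> bool:
        return is_adequate(self.description, self.blacklist)

    @property
    def taxon_tier(self) -> int:
        return self.taxon_tiers.get(self.taxon, 4)

    @property
    def informativeness_class(self) -> int:
        """3: description + GO; 2: exactly one of them; 1: neither."""
        has_desc = self.adequate
        has_go = bool(self.go_terms)
        if has_desc and has_go:
            return 3
        if has_desc or has_go:
            return 2
        return 1


@dataclass(frozen=True)
class ScoredHit:
    """One tag-target alignment with its annotation and alignment quality.

    ``alignment_score`` surrogates a full BLAST bit score as 26 - 2*mismatches,
    preserving the ordering perfect > one-mismatch.
    """

    tag: str
    record: AnnotationRecord
    alignment_score: int
    alignment_length: int = 26
    identity: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.identity <= 1):
            raise ValueError("identity must be in (0, 1]")
        if self.alignment_length > 26:
            raise ValueError("alignment length cannot exceed the tag length")


def score_from_mismatches(mismatches: int, penalty: int = 2) -> int:
    return 26 - penalty * mismatches


def select_best_hit(hits: Sequence[ScoredHit]) -> ScoredHit | None:
    """Best hit after three-round redundancy elimination.

    The most informative class wins outright; inside it the order is taxon
    tier ascending, alignment score descending, alignment length descending,
    identity descending, target id lexicographic.  Deterministic and
    permutation-invariant.  Returns None for an empty list.
    """
    if not hits:
        return None
    tags = {h.tag for h in hits}
    if len(tags) > 1:
        raise ValueError(f"hits for multiple tags passed together: {sorted(tags)}")
    return min(
        hits,
        key=lambda h: (
            -h.record.informativeness_class,
            h.record.taxon_tier,
            -h.alignment_score,
            -h.alignment_length,
            -h.identity,
            h.record.target_id,
        ),
    )


def characterization_class(record: AnnotationRecord | None) -> str:
    """Four-way partition key: desc_and_go / desc_only / go_only / neither."""
    if record is None:
        return "neither"
    has_desc = record.adequate
    has_go = bool(record.go_terms)
    if has_desc and has_go:
        return "desc_and_go"
    if has_desc:
        return "desc_only"
    if has_go:
        return "go_only"
    return "neither"


def summarize_go(
    calls: Mapping[str, str],
    annotations: Mapping[str, AnnotationRecord],
    go_namespaces: Mapping[str, str] | None = None,
    go_labels: Mapping[str, str] | None = None,
    contrast_id: str = "",
) -> pd.DataFrame:
    """Count UR and DR tags per GO term for one contrast.

    ``calls`` maps tag -> UR/DR/NS (tags absent from the map are treated as
    NS); ``annotations`` maps tag -> its selected AnnotationRecord.  Optional
    ``go_namespaces``/``go_labels`` attach the BP/MF/CC root and a readable
    label per GO id.  Rows are sorted by descending n_UR + n_DR, then GO id.
    """
    counts: dict[str, dict[str, int]] = {}
    for tag, record in annotations.items():
        call = calls.get(tag, NS)
        if call not in (UR, DR):
            continue
        for go in record.go_terms:
            row = counts.setdefault(go, {UR: 0, DR: 0})
            row[call] += 1
    rows = [
        {
            "go_id": go,
            "namespace": (go_namespaces or {}).get(go, ""),
            "label": (go_labels or {}).get(go, ""),
            "n_UR": c[UR],
            "n_DR": c[DR],
            "contrast_id": contrast_id,
        }
        for go, c in counts.items()
    ]
    df = pd.DataFrame(
        rows, columns=["go_id", "namespace", "label", "n_UR", "n_DR", "contrast_id"]
    )
    if len(df):
        df = df.sort_values(
            by=["n_UR", "n_DR", "go_id"],
            key=lambda s: s if s.name == "go_id" else -s,
            kind="mergesort",
        ).reset_index(drop=True)
    return df


def load_annotations(
    path: str | Path,
    blacklist: Sequence[str] = DEFAULT_BLACKLIST,
    taxon_tiers: Mapping[str, int] | None = None,
) -> dict[str, AnnotationRecord]:
    """Read an annotation TSV: target_id, description, go_terms (semicolon-sep), taxon."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"target_id", "description", "go_terms", "taxon"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    tiers = dict(DEFAULT_TAXON_TIERS if taxon_tiers is None else taxon_tiers)
    out = {}
    for row in df.itertuples(index=False):
        terms = frozenset(t for t in str(row.go_terms).split(";") if t)
        out[row.target_id] = AnnotationRecord(
            target_id=row.target_id,
            description=row.description,
            go_terms=terms,
            taxon=row.taxon,
            blacklist=tuple(blacklist),
            taxon_tiers=tiers,
        )
    return out
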