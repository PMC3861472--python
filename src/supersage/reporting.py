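"""Contrast orchestration, summary tables, Venn partitions and characterization.

The study design compares four libraries pairwise: stress bulk vs control
within each accession, control vs control, and stress vs stress.  This module
runs those contrasts, renders count/percentage summary tables (percentages
round half-up to one decimal), computes exclusive Venn regions of UR/DR tag
sets, and partitions tag sets by annotation characterization
(description+GO / description only / GO only / neither).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import round_half_up
from .annotation import AnnotationRecord, characterization_class
from .diffexpr import ContrastResults, LibraryContrast
from .tagging import TagLibrary


@dataclass(frozen=True)
class ContrastSpec:
    contrast_id: str
    library_1: str
    library_2: str

    def __post_init__(self) -> None:
        if self.library_1 == self.library_2:
            raise ValueError("a contrast needs two distinct libraries")


#: the four contrasts of the study design, in terms of default library ids
DEFAULT_CONTRASTS = (
    ContrastSpec("ET1-6_vs_ET0", "ET1-6", "ET0"),
    ContrastSpec("BT1-6_vs_BT0", "BT1-6", "BT0"),
    ContrastSpec("ET0_vs_BT0", "ET0", "BT0"),
    ContrastSpec("ET1-6_vs_BT1-6", "ET1-6", "BT1-6"),
)


def run_contrast(
    spec: ContrastSpec,
    libraries: Mapping[str, TagLibrary],
    alpha: float = 0.05,
) -> ContrastResults:
    """Fit one two-library contrast over the union of the libraries' unitags."""
    for lib_id in (spec.library_1, spec.library_2):
        if lib_id not in libraries:
            raise KeyError(f"unknown library id: {lib_id!r}")
    model = LibraryContrast(
        libraries[spec.library_1],
        libraries[spec.library_2],
        contrast_id=spec.contrast_id,
        alpha=alpha,
    )
    return model.fit()


def run_contrasts(
    specs: Iterable[ContrastSpec],
    libraries: Mapping[str, TagLibrary],
    alpha: float = 0.05,
) -> dict[str, ContrastResults]:
    return {s.contrast_id: run_contrast(s, libraries, alpha) for s in specs}


def summary_table(results: Mapping[str, ContrastResults] | Mapping[str, Mapping[str, int]]) -> pd.DataFrame:
    """Per-contrast UR/DR/NS counts with half-up one-decimal percentages.

    Accepts fitted :class:`~supersage.diffexpr.ContrastResults` or plain
    ``{"UR": n, "DR": n, "NS": n}`` count mappings (so published count tables
    can be re-rendered without the underlying libraries).
    """
    rows = []
    for cid, res in results.items():
        if isinstance(res, ContrastResults):
            n_ur, n_dr, n_ns = res.n_ur, res.n_dr, res.n_ns
        else:
            n_ur, n_dr, n_ns = int(res["UR"]), int(res["DR"]), int(res["NS"])
        total = n_ur + n_dr + n_ns
        if total == 0:
            pct = {"UR": 0.0, "DR": 0.0, "NS": 0.0}
        else:
            pct = {
                "UR": round_half_up(n_ur / total * 100),
                "DR": round_half_up(n_dr / total * 100),
                "NS": round_half_up(n_ns / total * 100),
            }
        rows.append(
            {
                "contrast": cid,
                "n_UR": n_ur, "n_DR": n_dr, "n_NS": n_ns, "n_total": total,
                "pct_UR": pct["UR"], "pct_DR": pct["DR"], "pct_NS": pct["NS"],
            }
        )
    return pd.DataFrame(rows)


def venn_sets(sets: Mapping[str, set]) -> dict[tuple[str, ...], set]:
    """Exclusive Venn regions of 2-4 named sets.

    Returns all 2^k - 1 regions keyed by the sorted tuple of member labels;
    each element of the union appears in exactly one region, so region sizes
    sum to the union size.
    """
    labels = list(sets)
    if not (2 <= len(labels) <= 4):
        raise ValueError("venn_sets supports 2 to 4 sets")
    regions: dict[tuple[str, ...], set] = {}
    for k in range(1, len(labels) + 1):
        for combo in combinations(labels, k):
            inside = set.intersection(*(set(sets[l]) for l in combo))
            outside = set.union(
                set(), *(set(sets[l]) for l in labels if l not in combo)
            )
            regions[tuple(sorted(combo))] = inside - outside
    return regions


def venn_counts(sets: Mapping[str, set]) -> dict[tuple[str, ...], int]:
    return {k: len(v) for k, v in venn_sets(sets).items()}


def characterize(
    tags: Iterable[str],
    annotations: Mapping[str, AnnotationRecord],
) -> dict[str, int]:
    """Four-way annotation partition of a tag set, plus its total.

    Tags missing from ``annotations`` fall in "neither".
    """
    counts = {"desc_and_go": 0, "desc_only": 0, "go_only": 0, "neither": 0}
    total = 0
    for tag in tags:
        counts[characterization_class(annotations.get(tag))] += 1
        total += 1
    counts["total"] = total
    return counts


def characterization_table(partition: Mapping[str, int]) -> pd.DataFrame:
    order = ["desc_and_go", "desc_only", "go_only", "neither", "total"]
    labels = {
        "desc_and_go": "With description / with GO",
        "desc_only": "With description / no GO",
        "go_only": "No description / with GO",
        "neither": "No description / no GO",
        "total": "Total",
    }
    return pd.DataFrame(
        [{"class": labels[k], "n": partition[k]} for k in order]
    )
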