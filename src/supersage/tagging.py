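"""SuperSAGE tag extraction and library construction.

A SuperSAGE tag is the 26-mer released by EcoP15I downstream of an NlaIII
restriction site: the anchoring ``CATG`` plus the 22 bases 3' of it.  Counting
identical tags across a deeply sequenced library gives a digital expression
measurement per transcript; the distinct tag sequences are called *unitags*.

This module extracts tags from reference sequences, aggregates sequenced tag
multisets into :class:`TagLibrary` objects (excluding *singlets*, tags seen
exactly once), and detects *sister unitags* — pairs of unitags differing at a
single base, which may represent SNPs, alternative transcripts or sequencing
errors.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from ._util import validate_dna

logger = logging.getLogger(__name__)

TAG_LENGTH = 26
ANCHOR = "CATG"
#: bases downstream of the CATG anchor in a full-length tag
TAG_TAIL = TAG_LENGTH - len(ANCHOR)


def is_valid_tag(sequence: str) -> bool:
    """True for a 26-mer over {A,C,G,T} starting with the CATG anchor."""
    return (
        len(sequence) == TAG_LENGTH
        and sequence.startswith(ANCHOR)
        and all(b in "ACGT" for b in sequence)
    )


def check_tag(sequence: str) -> str:
    seq = sequence.upper()
    if not is_valid_tag(seq):
        raise ValueError(f"not a valid {TAG_LENGTH}-bp CATG-anchored tag: {sequence!r}")
    return seq


def extract_tags(
    sequence: str,
    mode: str = "three_prime_most",
    fallback_upstream: bool = True,
) -> list[str]:
    """Extract CATG-anchored 26-bp tags from a nucleotide sequence.

    Parameters
    ----------
    sequence:
        Nucleotide string over {A,C,G,T,N}; case-insensitive.
    mode:
        ``"three_prime_most"`` returns at most one tag, from the 3'-most
        qualifying CATG site (the biological expectation under complete NlaIII
        digestion); ``"all_sites"`` returns one tag per qualifying site,
        emulating partial digestion.
    fallback_upstream:
        In ``three_prime_most`` mode, whether a 3'-most CATG with fewer than 22
        downstream bases yields the next qualifying site upstream instead of no
        tag.

    Tags containing ``N`` are dropped.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if mode not in ("three_prime_most", "all_sites"):
        raise ValueError(f"unknown mode: {mode!r}")
    seq = validate_dna(sequence, allow_n=True)

    sites = []
    start = seq.find(ANCHOR)
    while start != -1:
        sites.append(start)
        start = seq.find(ANCHOR, start + 1)

    def tag_at(pos: int) -> str | None:
        if pos + TAG_LENGTH > len(seq):
            return None
        tag = seq[pos : pos + TAG_LENGTH]
        return None if "N" in tag else tag

    if mode == "all_sites":
        return [t for pos in sites if (t := tag_at(pos)) is not None]

    # three_prime_most: walk sites from the 3' end
    for pos in reversed(sites):
        tag = tag_at(pos)
        if tag is not None:
            return [tag]
        if not fallback_upstream:
            break
    return []


@dataclass
class TagLibrary:
    """One sequenced tag library: unitag counts plus the sequenced-tag mass.

    ``total_sequenced`` is the library size *before* singlet exclusion; it is
    the N used to normalize counts to tags-per-million, so excluding singlets
    does not change normalization.
    """

    library_id: str
    counts: dict[str, int]
    total_sequenced: int
    accession: str | None = None
    condition: str | None = None
    n_singlets_excluded: int = 0

    def __post_init__(self) -> None:
        if self.total_sequenced <= 0:
            raise ValueError("total_sequenced must be positive")
        mass = sum(self.counts.values())
        if mass + self.n_singlets_excluded > self.total_sequenced:
            raise ValueError(
                "stored counts plus excluded singlets exceed total_sequenced"
            )

    @property
    def n_unitags(self) -> int:
        return len(self.counts)

    def __contains__(self, tag: str) -> bool:
        return tag in self.counts

    def get(self, tag: str) -> int:
        return self.counts.get(tag, 0)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            sorted(self.counts.items()), columns=["tag", "count"]
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        library_id: str,
        total_sequenced: int | None = None,
        **meta,
    ) -> "TagLibrary":
        df = pd.read_csv(path, sep="\t", dtype={"tag": str, "count": int})
        if list(df.columns[:2]) != ["tag", "count"]:
            raise ValueError(f"{path}: expected header 'tag<TAB>count'")
        counts = dict(zip(df["tag"], df["count"]))
        total = total_sequenced if total_sequenced is not None else sum(counts.values())
        return cls(library_id=library_id, counts=counts, total_sequenced=total, **meta)


def build_library(
    tag_multiset: Iterable[str],
    library_id: str,
    accession: str | None = None,
    condition: str | None = None,
    exclude_singlets: bool = True,
) -> TagLibrary:
    """Aggregate a multiset of sequenced tags into a :class:`TagLibrary`.

    Singlets (tags sequenced exactly once) are removed when
    ``exclude_singlets`` is set, but the pre-exclusion mass is retained as
    ``total_sequenced``.
    """
    counter: Counter[str] = Counter()
    for tag in tag_multiset:
        counter[check_tag(tag)] += 1
    total = sum(counter.values())
    if total == 0:
        raise ValueError("empty tag multiset: a library must contain at least one tag")
    n_singlets = 0
    if exclude_singlets:
        n_singlets = sum(1 for c in counter.values() if c == 1)
        counter = Counter({t: c for t, c in counter.items() if c >= 2})
        logger.info(
            "library %s: excluded %d singlets of %d sequenced tags",
            library_id, n_singlets, total,
        )
    return TagLibrary(
        library_id=library_id,
        counts=dict(counter),
        total_sequenced=total,
        accession=accession,
        condition=condition,
        n_singlets_excluded=n_singlets,
    )


@dataclass(frozen=True, order=True)
class SisterPair:
    """Two unitags at Hamming distance exactly one (outside the shared anchor)."""

    tag_a: str
    tag_b: str
    position: int

    def __post_init__(self) -> None:
        if self.position < len(ANCHOR):
            raise ValueError("sister pairs cannot differ inside the CATG anchor")


def find_sisters(unitags: Iterable[str]) -> list[SisterPair]:
    """Find every unordered pair of unitags differing at exactly one base.

    Uses a masked-position hash index: each tag is filed under its 22
    one-position-masked variants (positions 4–25; the CATG anchor is shared by
    all valid tags), so candidate pairs collide in a bucket instead of
    requiring an all-pairs scan.  Output is lexicographic by (tag_a, tag_b)
    with tag_a < tag_b.
    """
    tags = sorted({check_tag(t) for t in unitags})
    buckets: dict[tuple[int, str], list[str]] = defaultdict(list)
    for tag in tags:
        for pos in range(len(ANCHOR), TAG_LENGTH):
            buckets[(pos, tag[:pos] + tag[pos + 1 :])].append(tag)
    pairs: set[SisterPair] = set()
    for (pos, _), members in buckets.items():
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                pairs.add(SisterPair(min(a, b), max(a, b), pos))
    return sorted(pairs)
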