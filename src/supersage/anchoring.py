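"""Anchoring unitags on reference sequences and classifying genomic regions.

A unitag is accepted on a reference when the full 26-mer aligns with at most
one mismatch, the mismatch (if any) lying outside the CATG anchor: positions
0-3 must match exactly on the aligned strand, guaranteeing the tag's identity.
This "tolerate a single mismatch" rule replaces heuristic local alignment —
for a 26-mer a full-length <=1-mismatch match strictly dominates any
permissive e-value regime, and exact matching is deterministic.

Genomic anchor sites are classified against gene models as exon, intron,
exon/intron border or intergenic by interval arithmetic on the 26-nt hit.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from ._util import revcomp, validate_dna
from .tagging import ANCHOR, TAG_LENGTH, check_tag

EXON = "exon"
INTRON = "intron"
BORDER = "exon_intron_border"
INTERGENIC = "intergenic"


@dataclass
class ReferenceSet:
    """Named nucleotide sequences of one kind (EST, chromosome or scaffold)."""

    records: dict[str, str]
    kind: str = "EST"

    def __post_init__(self) -> None:
        if self.kind not in ("EST", "chromosome", "scaffold"):
            raise ValueError(f"unknown reference kind: {self.kind!r}")
        for rid, seq in self.records.items():
            if not seq:
                raise ValueError(f"empty reference sequence: {rid}")
            self.records[rid] = validate_dna(seq, allow_n=True)
        self._index: "_MismatchIndex | None" = None

    @classmethod
    def from_fasta(cls, path: str | Path, kind: str = "EST") -> "ReferenceSet":
        records: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate reference id: {rec.id}")
            records[rec.id] = str(rec.seq).upper()
        return cls(records=records, kind=kind)

    @property
    def default_strands(self) -> str:
        # transcripts are oriented; genomic sequences carry genes on both strands
        return "plus_only" if self.kind == "EST" else "both"


@dataclass(frozen=True, order=True)
class AnchorHit:
    """Placement of a tag on a reference: 0-based half-open [start, start+26)."""

    target_id: str
    start: int
    strand: str
    mismatches: int
    mismatch_position: int | None = None
    tag: str = ""


class _MismatchIndex:
    """Hash index of CATG-anchored reference windows for <=1-mismatch lookup.

    Every window whose first four bases are CATG (on either strand) is filed
    under its exact sequence and its 22 one-position-masked variants, so a
    query tag finds all candidate placements by dictionary lookups.
    """

    def __init__(self, refs: ReferenceSet, strands: str):
        self.strands = strands
        self.exact: dict[str, list[tuple[str, int, str]]] = defaultdict(list)
        self.masked: dict[tuple[int, str], list[tuple[str, int, str, str]]] = defaultdict(list)
        for rid, seq in refs.records.items():
            self._add(rid, seq, "+")
            if strands == "both":
                self._add(rid, revcomp(seq), "-")

    def _add(self, rid: str, seq: str, strand: str) -> None:
        pos = seq.find(ANCHOR)
        n = len(seq)
        while pos != -1:
            if pos + TAG_LENGTH <= n:
                window = seq[pos : pos + TAG_LENGTH]
                if "N" not in window:
                    if strand == "+":
                        start = pos
                    else:  # coordinates on the forward strand of the target
                        start = n - pos - TAG_LENGTH
                    self.exact[window].append((rid, start, strand))
                    for i in range(len(ANCHOR), TAG_LENGTH):
                        key = (i, window[:i] + window[i + 1 :])
                        self.masked[key].append((rid, start, strand, window))
            pos = seq.find(ANCHOR, pos + 1)

    def query(self, tag: str, max_mismatch: int) -> list[AnchorHit]:
        hits: dict[tuple[str, int, str], AnchorHit] = {}
        for rid, start, strand in self.exact.get(tag, ()):
            hits[(rid, start, strand)] = AnchorHit(rid, start, strand, 0, None, tag)
        if max_mismatch >= 1:
            for i in range(len(ANCHOR), TAG_LENGTH):
                key = (i, tag[:i] + tag[i + 1 :])
                for rid, start, strand, window in self.masked.get(key, ()):
                    loc = (rid, start, strand)
                    if loc not in hits and window[i] != tag[i]:
                        hits[loc] = AnchorHit(rid, start, strand, 1, i, tag)
        return sorted(hits.values())


def match_tag(
    tag: str,
    refs: ReferenceSet,
    max_mismatch: int = 1,
    strands: str | None = None,
) -> list[AnchorHit]:
    """All placements of *tag* on *refs* with at most ``max_mismatch`` mismatches.

    The CATG anchor must match exactly on the aligned strand; a mismatch is
    only tolerated in tag positions 4-25.  ``strands`` defaults to the
    reference kind's policy (plus-only for ESTs, both for genomic sequences).
    Results are sorted by (target_id, start, strand).
    """
    tag = check_tag(tag)
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    if strands is None:
        strands = refs.default_strands
    if strands not in ("plus_only", "both"):
        raise ValueError(f"unknown strand policy: {strands!r}")
    index = getattr(refs, "_index", None)
    if index is None or index.strands != strands:
        index = _MismatchIndex(refs, strands)
        refs._index = index
    hits = index.query(tag, max_mismatch)
    if strands == "plus_only":
        hits = [h for h in hits if h.strand == "+"]
    return hits


def match_tag_bruteforce(
    tag: str,
    refs: ReferenceSet,
    max_mismatch: int = 1,
    strands: str | None = None,
) -> list[AnchorHit]:
    """Sliding-window Hamming scan; the independent oracle for :func:`match_tag`."""
    tag = check_tag(tag)
    if strands is None:
        strands = refs.default_strands
    out = []
    for rid, seq in refs.records.items():
        n = len(seq)
        scans = [("+", seq)]
        if strands == "both":
            scans.append(("-", revcomp(seq)))
        for strand, s in scans:
            # the anchoring rule requires an exact CATG at the window start,
            # so only CATG sites can host a hit; each is Hamming-scanned fully
            pos = s.find(ANCHOR)
            while pos != -1:
                if pos + TAG_LENGTH <= n:
                    window = s[pos : pos + TAG_LENGTH]
                    if "N" not in window:
                        mism = [
                            i for i in range(TAG_LENGTH) if window[i] != tag[i]
                        ]
                        if not any(i < 4 for i in mism) and len(mism) <= max_mismatch:
                            start = pos if strand == "+" else n - pos - TAG_LENGTH
                            out.append(
                                AnchorHit(
                                    rid, start, strand, len(mism),
                                    mism[0] if mism else None, tag,
                                )
                            )
                pos = s.find(ANCHOR, pos + 1)
    # a palindromic window can match on both strands at one locus; keep both,
    # as the index does, but drop exact duplicates
    return sorted(set(out))


@dataclass
class GeneModel:
    """Exon structure of one gene on a target sequence (0-based half-open exons)."""

    gene_id: str
    target_id: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        ex = sorted(self.exons)
        if ex != self.exons:
            raise ValueError(f"gene {self.gene_id}: exons must be sorted")
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if e1 > s2:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        for s, e in ex:
            if s < 0 or e <= s:
                raise ValueError(f"gene {self.gene_id}: bad exon interval ({s}, {e})")

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @classmethod
    def from_gff3_record(
        cls, gene_id: str, target_id: str, strand: str,
        exons_1based: Sequence[tuple[int, int]],
    ) -> "GeneModel":
        """Build from GFF3 1-based inclusive exon coordinates."""
        return cls(
            gene_id=gene_id,
            target_id=target_id,
            strand=strand,
            exons=sorted((s - 1, e) for s, e in exons_1based),
        )


def load_gene_models(gff3_path: str | Path) -> list[GeneModel]:
    """Read gene models (gene + exon features) from a GFF3 file via gffutils."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique",
        keep_order=True,
    )
    models = []
    for gene in db.features_of_type("gene"):
        exons = [(f.start, f.end) for f in db.children(gene, featuretype="exon")]
        if not exons:
            exons = [(gene.start, gene.end)]
        models.append(
            GeneModel.from_gff3_record(gene.id, gene.seqid, gene.strand, exons)
        )
    return models


def classify_region(hit: AnchorHit, models: Iterable[GeneModel]) -> str:
    """Classify a 26-nt anchor site as exon / intron / exon-intron border / intergenic.

    Per overlapping gene: exon when the interval lies entirely inside one
    exon; intron when entirely inside one intron; border otherwise (it spans a
    boundary).  Across genes the most specific category wins
    (exon > intron > border); with no overlapping gene the site is intergenic.
    """
    lo, hi = hit.start, hit.start + TAG_LENGTH
    best: str | None = None
    rank = {EXON: 0, INTRON: 1, BORDER: 2}
    for gene in models:
        if gene.target_id != hit.target_id:
            continue
        g_lo, g_hi = gene.span
        if hi <= g_lo or lo >= g_hi:
            continue
        cat = BORDER
        for s, e in gene.exons:
            if lo >= s and hi <= e:
                cat = EXON
                break
        else:
            for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
                if lo >= e1 and hi <= s2:
                    cat = INTRON
                    break
        if best is None or rank[cat] < rank[best]:
            best = cat
    return best if best is not None else INTERGENIC


def partition_by_evidence(
    est_hits: set[str], chrom_hits: set[str], scaffold_hits: set[str]
) -> dict[tuple[str, ...], set[str]]:
    """Three-set Venn partition of tag ids by anchoring evidence.

    Returns a map from the tuple of set labels defining each exclusive region
    (e.g. ``("est", "chromosome")``) to its members; all seven regions are
    present, empty or not.
    """
    from .reporting import venn_sets

    return venn_sets(
        {"est": est_hits, "chromosome": chrom_hits, "scaffold": scaffold_hits}
    )


def hits_to_frame(hits: Iterable[AnchorHit], regions: Mapping[AnchorHit, str] | None = None):
    """Tabulate hits as the hits-TSV layout (tag, target, start, strand, ...)."""
    import pandas as pd

    rows = []
    for h in hits:
        rows.append(
            {
                "tag": h.tag,
                "target": h.target_id,
                "start": h.start,
                "strand": h.strand,
                "mismatches": h.mismatches,
                "mismatch_pos": "" if h.mismatch_position is None else h.mismatch_position,
                "region": regions.get(h, "") if regions else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["tag", "target", "start", "strand", "mismatches", "mismatch_pos", "region"],
    )
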