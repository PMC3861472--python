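"""Published count tables from a soybean root-dehydration SuperSAGE study.

These are the printed marginal counts of a DeepSuperSAGE survey of two
contrasting soybean accessions (drought-tolerant 'Embrapa 48' and sensitive
'BR 16') under root dehydration, shipped as a reference dataset so the
reporting arithmetic (percentages, Venn partitions, characterization tables)
can be exercised and checked against the published figures.  Only the
summary-level counts are public; the underlying tag libraries are not
bundled.
"""

from __future__ import annotations

import pandas as pd

#: total sequenced tags per accession (control + stress bulk)
TOTAL_SEQUENCED = {"tolerant": 1_030_443, "sensitive": 1_520_843}

#: distinct unitags across the four libraries after singlet exclusion
TOTAL_UNITAGS = 120_770

#: UR/DR/NS unitag counts per contrast (stress-vs-control within accession,
#: the two stress bulks, and the two controls)
CONTRAST_COUNTS = {
    "ET1-6_vs_ET0": {"UR": 13_532, "DR": 7_423, "NS": 53_878},
    "BT1-6_vs_BT0": {"UR": 10_751, "DR": 5_587, "NS": 72_867},
    "ET1-6_vs_BT1-6": {"UR": 12_347, "DR": 7_634, "NS": 53_826},
    "ET0_vs_BT0": {"UR": 6_468, "DR": 3_135, "NS": 73_067},
}

#: primary annotation marginals: EST matches tolerating a single mismatch
ANNOTATION_COUNTS = {
    "unitags": 120_770,
    "no_hit": 63_160,
    "with_hits": 57_610,
    "with_hits_single_mismatch": 26_911,
    "with_hits_perfect": 30_699,
    "with_description": 32_373,
    "with_description_single_mismatch": 17_470,
    "with_description_perfect": 14_903,
    "without_description": 25_237,
    "with_go": 35_985,
}

#: anchoring evidence set sizes (EST / chromosome / scaffold Venn marginals)
ANCHORING_COUNTS = {
    "est_aligned": 71_171,
    "genome_anchored": 77_163,
    "est_only": 1_448,
    "est_and_chromosome": 69_645,
    "est_and_scaffold": 78,
    "genomic_only": 7_440,
    "genomic_only_chromosome": 7_423,
    "genomic_only_scaffold": 17,
}

#: chromosome-1 region classification of 296 anchored unitags
CHR1_REGIONS = {"intron": 82, "exon_intron_border": 35, "intergenic": 179}

#: four-way characterization of the tolerant-exclusive and shared UR sets
CHARACTERIZATION = {
    "tolerant_exclusive_UR": {
        "desc_and_go": 484, "desc_only": 162, "go_only": 209, "neither": 272,
    },
    "shared_I_and_IV_UR": {
        "desc_and_go": 1_734, "desc_only": 561, "go_only": 809, "neither": 1_037,
    },
}


def contrast_counts() -> dict[str, dict[str, int]]:
    """Per-contrast UR/DR/NS counts, suitable for reporting.summary_table."""
    return {k: dict(v) for k, v in CONTRAST_COUNTS.items()}


def contrast_counts_frame() -> pd.DataFrame:
    rows = [
        {"contrast": cid, **counts, "total": sum(counts.values())}
        for cid, counts in CONTRAST_COUNTS.items()
    ]
    return pd.DataFrame(rows)
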