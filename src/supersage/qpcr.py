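"""Efficiency-corrected relative qPCR expression with randomization significance.

The amplification efficiency E of an assay comes from its standard-curve
slope, E = 10^(-1/slope) - 1, so a perfectly doubling reaction
(slope = -1/log10(2) ~ -3.3219) has E = 1 and amplification base 1 + E = 2.

The relative expression ratio of a target gene between treatment and control
follows the REST convention: for each gene, dCt = mean Ct(control) - mean
Ct(treatment) with technical replicates averaged within biological replicate
first; the gene's expression factor is (1+E)^dCt; and the reported ratio
(MRGEL, mean relative gene expression level) divides the target factor by the
geometric mean of the reference-gene factors.  With one reference gene and
E = 1 everywhere this reduces to the classic 2^-ddCt.

Significance uses a pair-wise fixed-reallocation randomization test: whole
biological-replicate samples (all genes jointly) are reassigned between
control and treatment, the ratio recomputed, and the two-sided p-value is the
fraction of reallocations with |log ratio| at least the observed one
(observed included).  The reallocation space is enumerated exhaustively when
small; otherwise sampled with a seeded generator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexpr import DR, NS, UR

CONTROL = "control"
TREATMENT = "treatment"

CT_COLUMNS = ["gene", "group", "bio_rep", "tech_rep", "ct"]

EXHAUSTIVE_LIMIT = 10_000


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency E = 10^(-1/slope) - 1 from a standard-curve slope."""
    if slope >= 0:
        raise ValueError("standard-curve slope must be negative")
    e = 10.0 ** (-1.0 / slope) - 1.0
    if not (0.6 <= e <= 1.1):
        warnings.warn(f"efficiency {e:.3f} outside the typical range [0.6, 1.1]")
    return e


@dataclass(frozen=True)
class QpcrAssay:
    """One gene's assay: efficiency as a fraction; amplification base is 1 + E."""

    gene: str
    efficiency: float

    @classmethod
    def from_slope(cls, gene: str, slope: float) -> "QpcrAssay":
        return cls(gene=gene, efficiency=efficiency_from_slope(slope))

    @property
    def base(self) -> float:
        return 1.0 + self.efficiency


def load_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct TSV: gene, group, bio_rep, tech_rep, ct."""
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return validate_ct_table(df)


def validate_ct_table(ct: pd.DataFrame) -> pd.DataFrame:
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    bad = set(ct["group"]) - {CONTROL, TREATMENT}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    return ct


def _bio_rep_means(ct: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct per (gene, group, bio_rep): technical replicates collapse first."""
    return (
        ct.groupby(["gene", "group", "bio_rep"], sort=True)["ct"]
        .mean()
        .reset_index()
    )


def _ratio_from_means(
    means: pd.DataFrame,
    target: str,
    references: Sequence[str],
    assays: Mapping[str, QpcrAssay],
) -> float:
    log_factors = {}
    for gene in [target, *references]:
        sub = means[means["gene"] == gene]
        ct_c = sub.loc[sub["group"] == CONTROL, "ct"]
        ct_t = sub.loc[sub["group"] == TREATMENT, "ct"]
        if ct_c.empty or ct_t.empty:
            raise ValueError(f"gene {gene!r}: missing a group")
        d_ct = ct_c.mean() - ct_t.mean()
        log_factors[gene] = d_ct * math.log(assays[gene].base)
    log_ref = np.mean([log_factors[g] for g in references])
    return math.exp(log_factors[target] - log_ref)


def rest_ratio(
    ct: pd.DataFrame,
    target: str,
    references: Sequence[str],
    assays: Mapping[str, QpcrAssay],
) -> float:
    """Efficiency-corrected expression ratio of *target* normalized to *references*."""
    if not references:
        raise ValueError("at least one reference gene is required")
    ct = validate_ct_table(ct)
    return _ratio_from_means(_bio_rep_means(ct), target, references, assays)


def _reallocations(samples: list, n_control: int, permutations: int, rng):
    """Yield group reassignments: exhaustive if the space is small, else sampled."""
    n = len(samples)
    total = math.comb(n, n_control)
    if total <= EXHAUSTIVE_LIMIT:
        for combo in combinations(range(n), n_control):
            yield set(combo)
    else:
        for _ in range(permutations):
            yield set(rng.choice(n, size=n_control, replace=False).tolist())


def rest_randomization_test(
    ct: pd.DataFrame,
    target: str,
    references: Sequence[str],
    assays: Mapping[str, QpcrAssay],
    permutations: int = 2000,
    seed: int | None = None,
) -> float:
    """Two-sided fixed-reallocation randomization p-value for the REST ratio.

    Biological-replicate samples (each carrying every gene's collapsed Ct) are
    swapped whole between groups; extremeness is measured on |log ratio| and
    the observed allocation is counted, so p >= 1/n_arrangements.
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    ct = validate_ct_table(ct)
    means = _bio_rep_means(ct)

    # samples = distinct (group, bio_rep) pairs; a reallocation relabels them
    samples = sorted(
        means[["group", "bio_rep"]].drop_duplicates().itertuples(index=False, name=None)
    )
    n_control = sum(1 for g, _ in samples if g == CONTROL)
    if n_control < 2 or len(samples) - n_control < 2:
        raise ValueError("the randomization test needs >= 2 biological replicates per group")

    wide = means.pivot_table(
        index=["group", "bio_rep"], columns="gene", values="ct"
    ).loc[list(samples)]
    genes = [target, *references]

    def ratio_for(control_idx: set[int]) -> float:
        log_factors = {}
        for gene in genes:
            cts = wide[gene].to_numpy()
            c_mask = np.zeros(len(samples), dtype=bool)
            c_mask[list(control_idx)] = True
            d_ct = cts[c_mask].mean() - cts[~c_mask].mean()
            log_factors[gene] = d_ct * math.log(assays[gene].base)
        return math.exp(log_factors[target] - np.mean([log_factors[g] for g in references]))

    observed_idx = {i for i, (g, _) in enumerate(samples) if g == CONTROL}
    observed = abs(math.log(ratio_for(observed_idx)))

    rng = np.random.default_rng(seed)
    exhaustive = math.comb(len(samples), n_control) <= EXHAUSTIVE_LIMIT
    # the observed allocation is in the exhaustive enumeration; under Monte
    # Carlo it is counted explicitly so that p >= 1/(permutations + 1)
    n_extreme = 0 if exhaustive else 1
    n_total = 0 if exhaustive else 1
    for control_idx in _reallocations(samples, n_control, permutations, rng):
        n_total += 1
        if abs(math.log(ratio_for(control_idx))) >= observed - 1e-12:
            n_extreme += 1
    return n_extreme / n_total


@dataclass
class ExpressionRatio:
    """One gene x timepoint relative-expression result."""

    gene: str
    group_label: str
    ratio: float
    p_value: float
    alpha: float = 0.05

    @property
    def call(self) -> str:
        if self.p_value < self.alpha:
            return "up" if self.ratio > 1 else "down"
        return "n.s."


class RelativeExpression:
    """REST-style relative-expression model for one target gene (model object)."""

    def __init__(
        self,
        ct: pd.DataFrame,
        target: str,
        references: Sequence[str],
        assays: Mapping[str, QpcrAssay],
        group_label: str = "",
        alpha: float = 0.05,
    ):
        self.ct = validate_ct_table(ct)
        self.target = target
        self.references = list(references)
        self.assays = dict(assays)
        self.group_label = group_label
        self.alpha = alpha

    def fit(self, permutations: int = 2000, seed: int | None = None) -> ExpressionRatio:
        ratio = rest_ratio(self.ct, self.target, self.references, self.assays)
        p = rest_randomization_test(
            self.ct, self.target, self.references, self.assays,
            permutations=permutations, seed=seed,
        )
        return ExpressionRatio(
            gene=self.target, group_label=self.group_label,
            ratio=ratio, p_value=p, alpha=self.alpha,
        )


def signed_mrgel(ratio: float) -> float:
    """Report convention: ratios below one appear as the negative reciprocal."""
    return ratio if ratio >= 1 else -1.0 / ratio


def concordance_check(
    supersage_call: str, qpcr_ratios: Sequence[ExpressionRatio]
) -> bool:
    """Agreement rule between tag-based and qPCR results.

    True when at least one timepoint is significant (p < alpha) with the
    ratio's direction matching the tag-based UR/DR call.
    """
    if not qpcr_ratios:
        raise ValueError("at least one timepoint is required")
    if supersage_call not in (UR, DR):
        return False
    want = "up" if supersage_call == UR else "down"
    return any(r.call == want for r in qpcr_ratios)
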