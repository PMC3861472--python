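"""Differential expression between two tag libraries.

The significance test is the exact Poisson-derived comparison of two counts
introduced for SAGE by Audic & Claverie: conditional on the pooled count
``n = x + y``, the count in library 2 is Binomial(n, N2/(N1+N2)) under the
null of equal underlying transcript frequency.  The two-sided p-value doubles
the smaller conditional tail (including the observed outcome) and is capped at
one.  Everything is computed in log space so libraries of 10^6+ tags are
handled without underflow.

Fold changes follow the SAGE convention: the ratio R of tags-per-million
frequencies, with an absent unitag's zero frequency replaced by one, reported
as R when R >= 1 and as -1/R otherwise, so |FC| >= 1 always and negative
values mean repression.

The two-library contrast is exposed statsmodels-style: build a
:class:`LibraryContrast` from two :class:`~supersage.tagging.TagLibrary`
objects, call :meth:`~LibraryContrast.fit`, and read estimates off the
returned :class:`ContrastResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_up
from .tagging import TagLibrary

UR = "UR"
DR = "DR"
NS = "NS"

DEFAULT_ALPHA = 0.05
DEFAULT_SCALE = 1_000_000  # tags per million


def normalize(count, n_total, scale: float = DEFAULT_SCALE):
    """Normalize a raw count to tags-per-million (or another scale)."""
    count = np.asarray(count, dtype=float)
    n_total = np.asarray(n_total, dtype=float)
    if np.any(n_total <= 0):
        raise ValueError("library size must be positive")
    if np.any(count < 0) or np.any(count > n_total):
        raise ValueError("count must satisfy 0 <= count <= library size")
    out = count / n_total * scale
    return out if out.ndim else float(out)


def audic_claverie_p(x, y, n1, n2):
    """Two-sided exact p-value for counts x (library 1, size n1) vs y (library 2, size n2).

    Vectorized over array inputs; returns a scalar for scalar inputs.
    Degenerate x = y = 0 gives p = 1.
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise ValueError("library sizes must be positive")

    n = x + y
    p2 = n2 / (n1 + n2)
    with np.errstate(divide="ignore"):
        # lower tail P(Y <= y) and upper tail P(Y >= y), both including y
        log_lower = stats.binom.logcdf(y, n, p2)
        log_upper = stats.binom.logsf(y - 1, n, p2)
    log_min_tail = np.minimum(log_lower, log_upper)
    p = np.minimum(1.0, 2.0 * np.exp(log_min_tail))
    p = np.where(n == 0, 1.0, p)
    return p if p.ndim else float(p)


def fold_change(f1, f2):
    """Signed fold change of normalized frequencies with zero->one substitution.

    Vectorized.  Returns R = f1'/f2' when R >= 1, else -1/R, where f' replaces
    an exact zero with one (on the normalized scale).
    """
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    if np.any(f1 < 0) or np.any(f2 < 0):
        raise ValueError("frequencies must be non-negative")
    f1s = np.where(f1 == 0, 1.0, f1)
    f2s = np.where(f2 == 0, 1.0, f2)
    r = f1s / f2s
    fc = np.where(r >= 1, r, -1.0 / r)
    return fc if fc.ndim else float(fc)


def classify(p, fc, alpha: float = DEFAULT_ALPHA):
    """Call each unitag UR / DR / NS from its p-value and signed fold change.

    UR: p < alpha and fc > 1; DR: p < alpha and fc < -1; NS otherwise
    (ties at p == alpha are NS; fc exactly 1 is NS).
    """
    p = np.asarray(p, dtype=float)
    fc = np.asarray(fc, dtype=float)
    call = np.full(p.shape, NS, dtype=object)
    sig = p < alpha
    call[sig & (fc > 1)] = UR
    call[sig & (fc < -1)] = DR
    return call if call.ndim else str(call[()])


class LibraryContrast:
    """Two-library differential-expression contrast (model object).

    The unitag universe is the union of the two libraries' unitags; a unitag
    absent from one library enters with count zero.  ``fit`` runs the exact
    test on raw counts and derives tags-per-million frequencies, signed fold
    changes and UR/DR/NS calls.
    """

    def __init__(
        self,
        library_1: TagLibrary,
        library_2: TagLibrary,
        contrast_id: str | None = None,
        alpha: float = DEFAULT_ALPHA,
        scale: float = DEFAULT_SCALE,
    ):
        if library_1.library_id == library_2.library_id:
            raise ValueError("a contrast needs two distinct libraries")
        self.library_1 = library_1
        self.library_2 = library_2
        self.contrast_id = (
            contrast_id
            if contrast_id is not None
            else f"{library_1.library_id}_vs_{library_2.library_id}"
        )
        self.alpha = alpha
        self.scale = scale

    def fit(self) -> "ContrastResults":
        tags = sorted(set(self.library_1.counts) | set(self.library_2.counts))
        x = np.array([self.library_1.get(t) for t in tags], dtype=np.int64)
        y = np.array([self.library_2.get(t) for t in tags], dtype=np.int64)
        n1 = self.library_1.total_sequenced
        n2 = self.library_2.total_sequenced
        f1 = normalize(x, n1, self.scale) if len(tags) else np.array([])
        f2 = normalize(y, n2, self.scale) if len(tags) else np.array([])
        p = audic_claverie_p(x, y, n1, n2) if len(tags) else np.array([])
        fc = fold_change(f1, f2) if len(tags) else np.array([])
        call = classify(p, fc, self.alpha) if len(tags) else np.array([], dtype=object)
        frame = pd.DataFrame(
            {
                "tag": tags,
                "count_1": x,
                "count_2": y,
                "freq_1": f1,
                "freq_2": f2,
                "p_value": p,
                "fold_change": fc,
                "call": call,
            }
        )
        # deterministic report order: descending |fc|, then tag
        frame = frame.sort_values(
            by=["fold_change", "tag"],
            key=lambda s: -s.abs() if s.name == "fold_change" else s,
            kind="mergesort",
        ).reset_index(drop=True)
        return ContrastResults(self, frame)


@dataclass
class ContrastResults:
    """Fitted results of a :class:`LibraryContrast`."""

    model: LibraryContrast
    frame: pd.DataFrame

    @property
    def contrast_id(self) -> str:
        return self.model.contrast_id

    @property
    def calls(self) -> pd.Series:
        return pd.Series(
            self.frame["call"].values, index=self.frame["tag"].values, name="call"
        )

    def tags_called(self, call: str) -> set[str]:
        return set(self.frame.loc[self.frame["call"] == call, "tag"])

    @property
    def n_ur(self) -> int:
        return int((self.frame["call"] == UR).sum())

    @property
    def n_dr(self) -> int:
        return int((self.frame["call"] == DR).sum())

    @property
    def n_ns(self) -> int:
        return int((self.frame["call"] == NS).sum())

    @property
    def n_total(self) -> int:
        return len(self.frame)

    def summary(self) -> pd.DataFrame:
        """One-row count/percentage summary (percentages round half-up, 1 dp)."""
        n = self.n_total
        row = {
            "contrast": self.contrast_id,
            "n_UR": self.n_ur,
            "n_DR": self.n_dr,
            "n_NS": self.n_ns,
            "n_total": n,
            "pct_UR": round_half_up(self.n_ur / n * 100) if n else 0.0,
            "pct_DR": round_half_up(self.n_dr / n * 100) if n else 0.0,
            "pct_NS": round_half_up(self.n_ns / n * 100) if n else 0.0,
        }
        return pd.DataFrame([row])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)
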