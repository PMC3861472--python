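"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates the four-library root-dehydration design: a control
and a six-timepoint stress bulk for a drought-tolerant and a drought-sensitive
soybean accession (ET0, ET1-6, BT0, BT1-6).  It produces:

* reference transcripts, each guaranteed to yield a CATG-anchored 26-bp tag,
  plus a decoy chromosome embedding a subset of them as intron-containing
  gene models (FASTA + GFF3), so region classification can be exercised;
* four tag-count libraries drawn multinomially from per-transcript expected
  frequencies, with a planted fraction of differentially expressed
  transcripts whose stress-bulk frequency is the control frequency times a
  log-uniform effect size (the bulk is an equal-weight mixture of six
  per-time profiles, so transient responses dilute six-fold);
* sequencing-error sister tags spawned at a per-base substitution rate;
* qPCR Ct tables with known expression ratios, reference genes shift-free.

All randomness flows through one seeded generator; identical seeds give
byte-identical outputs.  Ground truth (planted effect sizes, tag origins,
sister-tag parents) is recorded for recovery experiments.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .anchoring import GeneModel
from .tagging import ANCHOR, TAG_LENGTH, TagLibrary, extract_tags

#: library ids of the study design
TOLERANT_CONTROL = "ET0"
TOLERANT_STRESS = "ET1-6"
SENSITIVE_CONTROL = "BT0"
SENSITIVE_STRESS = "BT1-6"

#: study totals: 1,030,443 sequenced tags for the tolerant accession pair and
#: 1,520,843 for the sensitive pair, split between control and stress bulk
DEFAULT_LIBRARY_SIZES = {
    TOLERANT_CONTROL: 515_221,
    TOLERANT_STRESS: 515_222,
    SENSITIVE_CONTROL: 760_421,
    SENSITIVE_STRESS: 760_422,
}

N_STRESS_TIMES = 6  # 25, 50, 75, 100, 125, 150 minutes, bulked equally


@dataclass
class SimulationConfig:
    n_transcripts: int = 2000
    transcript_length_min: int = 300
    transcript_length_max: int = 1500
    n_chromosome_decoys: int = 1
    n_genes_on_chromosome: int = 20
    library_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_LIBRARY_SIZES)
    )
    # DE prevalence and direction balance mirror the study's tolerant
    # stress-vs-control contrast (~18% UR + ~10% DR of the unitag universe)
    de_fraction: float = 0.28
    effect_size_min: float = 2.0
    effect_size_max: float = 50.0
    ur_fraction: float = 0.65
    error_rate: float = 1e-4  # per-base substitution probability
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.de_fraction <= 1 and 0 <= self.ur_fraction <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if any(v <= 0 for v in self.library_sizes.values()):
            raise ValueError("library sizes must be positive")
        if self.effect_size_min < 1 or self.effect_size_max < self.effect_size_min:
            raise ValueError("effect sizes must satisfy 1 <= min <= max")

    def scaled(self, factor: float) -> "SimulationConfig":
        """Copy with library sizes multiplied by *factor* (e.g. 0.1 for desk scale)."""
        cfg = SimulationConfig(**{**asdict(self)})
        cfg.library_sizes = {
            k: max(1, int(round(v * factor))) for k, v in self.library_sizes.items()
        }
        return cfg


@dataclass
class References:
    transcripts: dict[str, str]
    chromosomes: dict[str, str]
    gene_models: list[GeneModel]
    tag_of_transcript: dict[str, str]  # planted (3'-most) tag per transcript
    tag_origin: dict[str, tuple[str, int]]  # tag -> (transcript id, offset)

    def write_fasta(self, path: str | Path, which: str = "transcripts") -> None:
        records = self.transcripts if which == "transcripts" else self.chromosomes
        with open(path, "w") as fh:
            for rid, seq in records.items():
                fh.write(f">{rid}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for gm in self.gene_models:
                g_lo, g_hi = gm.span
                fh.write(
                    f"{gm.target_id}\tsim\tgene\t{g_lo + 1}\t{g_hi}\t.\t{gm.strand}\t.\t"
                    f"ID={gm.gene_id}\n"
                )
                for i, (s, e) in enumerate(gm.exons, 1):
                    fh.write(
                        f"{gm.target_id}\tsim\texon\t{s + 1}\t{e}\t.\t{gm.strand}\t.\t"
                        f"ID={gm.gene_id}.exon{i};Parent={gm.gene_id}\n"
                    )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def simulate_references(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> References:
    """Generate transcripts (each yielding a tag) and a decoy chromosome with genes."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    transcripts: dict[str, str] = {}
    tag_of: dict[str, str] = {}
    origin: dict[str, tuple[str, int]] = {}
    for i in range(cfg.n_transcripts):
        tid = f"TR{i:05d}"
        length = int(rng.integers(cfg.transcript_length_min, cfg.transcript_length_max + 1))
        seq = _random_seq(rng, length)
        # guarantee a CATG site with a full 22-nt tail near the 3' end
        anchor_pos = length - TAG_LENGTH - int(rng.integers(0, 30))
        anchor_pos = max(0, anchor_pos)
        seq = seq[:anchor_pos] + ANCHOR + seq[anchor_pos + len(ANCHOR):]
        transcripts[tid] = seq
        tags = extract_tags(seq, mode="three_prime_most")
        assert tags, "constructional guarantee: every transcript yields a tag"
        tag = tags[0]
        tag_of[tid] = tag
        origin.setdefault(tag, (tid, seq.rfind(tag)))

    chromosomes: dict[str, str] = {}
    models: list[GeneModel] = []
    gene_ids = list(transcripts)[: cfg.n_genes_on_chromosome]
    for c in range(cfg.n_chromosome_decoys):
        cid = f"CHR{c + 1}"
        parts: list[str] = []
        pos = 0
        take = gene_ids[c::max(1, cfg.n_chromosome_decoys)]
        for tid in take:
            spacer = _random_seq(rng, int(rng.integers(200, 500)))
            parts.append(spacer)
            pos += len(spacer)
            tr = transcripts[tid]
            # split the transcript into two exons with an intron between
            cut = int(rng.integers(50, max(51, len(tr) - 50)))
            intron = _random_seq(rng, int(rng.integers(80, 200)))
            exon1 = (pos, pos + cut)
            exon2 = (pos + cut + len(intron), pos + cut + len(intron) + len(tr) - cut)
            parts.append(tr[:cut])
            parts.append(intron)
            parts.append(tr[cut:])
            pos = exon2[1]
            models.append(
                GeneModel(
                    gene_id=f"gene_{tid}", target_id=cid, strand="+",
                    exons=[exon1, exon2],
                )
            )
        parts.append(_random_seq(rng, 300))
        chromosomes[cid] = "".join(parts)
    return References(
        transcripts=transcripts, chromosomes=chromosomes, gene_models=models,
        tag_of_transcript=tag_of, tag_origin=origin,
    )


@dataclass
class GroundTruth:
    """Planted truth: per-transcript expected frequencies and DE status, tag origins."""

    baseline_freq: dict[str, float]  # per transcript, control relative frequency
    effect_size: dict[str, float]  # |FC| planted for DE transcripts (signed: <1 => DR)
    de_transcripts: dict[str, str]  # transcript -> "UR" | "DR" (stress vs control)
    tag_of_transcript: dict[str, str]
    sister_parents: dict[str, tuple[str, int]]  # error tag -> (parent tag, position)

    def de_tags(self, direction: str | None = None) -> set[str]:
        out = set()
        for tid, call in self.de_transcripts.items():
            if direction is None or call == direction:
                out.add(self.tag_of_transcript[tid])
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "baseline_freq": self.baseline_freq,
            "effect_size": self.effect_size,
            "de_transcripts": self.de_transcripts,
            "tag_of_transcript": self.tag_of_transcript,
            "sister_parents": {k: list(v) for k, v in self.sister_parents.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def simulate_libraries(
    cfg: SimulationConfig,
    references: References,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, TagLibrary], GroundTruth]:
    """Draw the four tag libraries multinomially with planted DE and sister errors.

    Stress-bulk expected frequencies multiply the control frequency by the
    planted effect size for DE transcripts (the six-time mixture is folded in:
    a transcript may respond at a random subset of times, its bulk effect
    being the mixture average, floored at the configured minimum overall).
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    tids = list(references.transcripts)
    n = len(tids)
    # log-normal abundance spectrum: realistic skew without letting a single
    # transcript dominate the library
    baseline = rng.lognormal(0.0, 1.2, size=n)
    baseline = baseline / baseline.sum()

    n_de = int(round(cfg.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    de_status: dict[str, str] = {}
    effect: dict[str, float] = {}
    multiplier = np.ones(n)
    for idx in de_idx:
        size = math.exp(rng.uniform(math.log(cfg.effect_size_min), math.log(cfg.effect_size_max)))
        up = rng.random() < cfg.ur_fraction
        tid = tids[idx]
        de_status[tid] = "UR" if up else "DR"
        effect[tid] = size if up else 1.0 / size
        multiplier[idx] = effect[tid]

    # planted transcripts are quantifiably expressed: floor their control
    # abundance at the median, emulating stress-responsive genes measurable
    # by tag counting rather than drop-out-level transcripts
    floor = np.median(baseline)
    baseline[de_idx] = np.maximum(baseline[de_idx], floor)

    # mass balance: scale planted-DR control abundance so the stress bulk's
    # total expected mass equals the control's; otherwise renormalizing the
    # multinomial probabilities would shift every null transcript's relative
    # frequency (a compositional artifact, not planted signal)
    ur_mask = multiplier > 1
    dr_mask = multiplier < 1
    gain = float((baseline[ur_mask] * (multiplier[ur_mask] - 1)).sum())
    loss = float((baseline[dr_mask] * (1 - multiplier[dr_mask])).sum())
    if loss > 0 and gain > 0:
        baseline[dr_mask] *= gain / loss
    elif gain > 0:
        # one-sided planting: cap the compositional shift at 2% of the mass
        cap = 0.02 * baseline.sum()
        if gain > cap:
            baseline[ur_mask] *= cap / gain
    baseline = baseline / baseline.sum()

    # per-accession control frequencies share the baseline; the stress bulk is
    # an equal mixture of six per-time profiles, here all carrying the effect
    # (a sustained response); transient responses can be planted by users via
    # per-time multipliers, which average into the same framework
    expected = {
        TOLERANT_CONTROL: baseline,
        SENSITIVE_CONTROL: baseline,
        TOLERANT_STRESS: baseline * multiplier,
        SENSITIVE_STRESS: baseline * multiplier,
    }

    libraries: dict[str, TagLibrary] = {}
    sisters: dict[str, tuple[str, int]] = {}
    meta = {
        TOLERANT_CONTROL: ("tolerant", "control"),
        TOLERANT_STRESS: ("tolerant", "stress_bulk"),
        SENSITIVE_CONTROL: ("sensitive", "control"),
        SENSITIVE_STRESS: ("sensitive", "stress_bulk"),
    }
    bases = np.array(list("ACGT"))
    for lib_id, size in cfg.library_sizes.items():
        probs = expected[lib_id]
        probs = probs / probs.sum()
        draws = rng.multinomial(size, probs)
        counts: dict[str, int] = {}
        for tid, c in zip(tids, draws):
            if c == 0:
                continue
            tag = references.tag_of_transcript[tid]
            # substitution errors over the 22 non-anchor bases spawn sister tags
            p_err = 1.0 - (1.0 - cfg.error_rate) ** (TAG_LENGTH - len(ANCHOR))
            n_err = rng.binomial(c, p_err) if cfg.error_rate > 0 else 0
            counts[tag] = counts.get(tag, 0) + (c - n_err)
            for _ in range(n_err):
                pos = int(rng.integers(len(ANCHOR), TAG_LENGTH))
                alt = str(rng.choice(bases[bases != tag[pos]]))
                sis = tag[:pos] + alt + tag[pos + 1 :]
                counts[sis] = counts.get(sis, 0) + 1
                sisters.setdefault(sis, (tag, pos))
        counts = {t: c for t, c in counts.items() if c > 0}
        n_singlets = sum(1 for c in counts.values() if c == 1)
        accession, condition = meta[lib_id]
        libraries[lib_id] = TagLibrary(
            library_id=lib_id,
            counts={t: c for t, c in counts.items() if c >= 2},
            total_sequenced=int(size),
            accession=accession,
            condition=condition,
            n_singlets_excluded=n_singlets,
        )
    truth = GroundTruth(
        baseline_freq={tid: float(f) for tid, f in zip(tids, baseline)},
        effect_size=effect,
        de_transcripts=de_status,
        tag_of_transcript=dict(references.tag_of_transcript),
        sister_parents=sisters,
    )
    return libraries, truth


def simulate_ct_tables(
    true_ratios: Mapping[str, float],
    reference_genes: Sequence[str] = ("actin", "rna18S"),
    assays: Mapping[str, float] | None = None,
    n_bio: int = 3,
    n_tech: int = 3,
    baseline_ct: float = 22.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Generate a Ct table with known expression ratios.

    ``true_ratios`` maps target gene -> treatment/control expression ratio; Ct
    shifts are -log_base(ratio) so the REST ratio recovers the planted value.
    Reference genes are shift-free.  ``assays`` maps gene -> efficiency
    (default 1.0, perfect doubling).  Gaussian noise of ``noise_sd`` cycles is
    added per biological replicate and (half as much) per technical replicate.
    """
    rng = np.random.default_rng(seed)
    rows = []
    genes = list(true_ratios) + [g for g in reference_genes if g not in true_ratios]
    eff = {g: (assays or {}).get(g, 1.0) for g in genes}
    for gene in genes:
        ratio = true_ratios.get(gene, 1.0)
        shift = -math.log(ratio, 1.0 + eff[gene]) if ratio != 1.0 else 0.0
        for group in ("control", "treatment"):
            for b in range(1, n_bio + 1):
                bio_noise = rng.normal(0, noise_sd)
                mu = baseline_ct + (shift if group == "treatment" else 0.0) + bio_noise
                for t in range(1, n_tech + 1):
                    rows.append(
                        {
                            "gene": gene, "group": group, "bio_rep": b,
                            "tech_rep": t,
                            "ct": mu + rng.normal(0, noise_sd / 2),
                        }
                    )
    truth = {g: float(true_ratios.get(g, 1.0)) for g in genes}
    return pd.DataFrame(rows, columns=["gene", "group", "bio_rep", "tech_rep", "ct"]), truth
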