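"""Synthetic multi-domain protein corpora.

The generator emulates the statistical structure the linker-index model
assumes: each sequence alternates domain and linker segments (D-L-D-...-D,
starting and ending with a domain), and residues are drawn i.i.d. from a
per-partition amino-acid composition.  The default compositions are the
published linker/domain percentages of the Swiss-Prot-derived linker
benchmark; default segment-length means (147.1 for domains, 12.7 for
linkers) and bounds (domains 25-500 AA, linkers 10-100 AA) follow the same
literature.  A ``divergence_multiplier`` amplifies the compositional
difference between the two partitions for separability and power-style
experiments.

No homology, secondary structure, or residue-order correlation is
simulated; the corpus is exactly as hard as the zeroth-order composition
signal makes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .profiles import PropertyTables
from .sequence_io import (
    AnnotatedCorpus,
    ProteinSequence,
    SegmentAnnotation,
    STANDARD_AA,
    segments_from_labels,
)


def _default_compositions() -> tuple[dict[str, float], dict[str, float]]:
    tables = PropertyTables.default()
    return dict(tables.linker_freq), dict(tables.domain_freq)


def diverge_compositions(
    linker: Mapping[str, float],
    domain: Mapping[str, float],
    multiplier: float,
) -> tuple[dict[str, float], dict[str, float]]:
    """Scale the log-ratio between two compositions about its geometric mean.

    With multiplier m, each amino acid's linker/domain ratio r becomes r**m
    while the geometric mean sqrt(linker*domain) is preserved, then both
    compositions are renormalized to 100%.  m = 1 is the identity up to
    renormalization; m > 1 makes the partitions easier to tell apart.
    """
    if multiplier < 1:
        raise ValueError("divergence multiplier must be >= 1")
    aas = list(linker)
    l = np.array([linker[a] for a in aas], dtype=float)
    d = np.array([domain[a] for a in aas], dtype=float)
    if (l <= 0).any() or (d <= 0).any():
        raise ValueError("compositions must be strictly positive to diverge")
    g = np.sqrt(l * d)
    r = l / d
    l2 = g * r ** (multiplier / 2)
    d2 = g * r ** (-multiplier / 2)
    l2 *= 100.0 / l2.sum()
    d2 *= 100.0 / d2.sum()
    return dict(zip(aas, l2)), dict(zip(aas, d2))


@dataclass(frozen=True)
class LengthLaw:
    """Rounded Gamma segment-length distribution, truncated by rejection.

    ``mean`` parameterizes the untruncated Gamma (scale = mean / shape);
    draws are rounded to integers and redrawn until they land in
    [lower, upper].  Right-skewed and strictly positive, which matches how
    observed segment lengths distribute around their reported means.
    """

    mean: float
    lower: int
    upper: int
    shape: float = 4.0

    def __post_init__(self) -> None:
        if not (self.lower <= self.mean <= self.upper):
            raise ValueError(
                f"mean {self.mean} outside truncation bounds "
                f"[{self.lower}, {self.upper}]"
            )
        if self.shape <= 0:
            raise ValueError("shape must be positive")

    def sample(self, rng: np.random.Generator) -> int:
        scale = self.mean / self.shape
        while True:
            length = int(round(rng.gamma(self.shape, scale)))
            if self.lower <= length <= self.upper:
                return length


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic corpus."""

    n_sequences: int = 100
    domains_per_sequence: tuple[int, int] = (2, 3)
    domain_length_law: LengthLaw = field(
        default_factory=lambda: LengthLaw(mean=147.1, lower=25, upper=500)
    )
    linker_length_law: LengthLaw = field(
        default_factory=lambda: LengthLaw(mean=12.7, lower=10, upper=100)
    )
    linker_composition: dict[str, float] | None = None  # None -> packaged table
    domain_composition: dict[str, float] | None = None
    divergence_multiplier: float = 1.0
    seed: int = 0

    def resolved_compositions(self) -> tuple[dict[str, float], dict[str, float]]:
        linker, domain = _default_compositions()
        if self.linker_composition is not None:
            linker = dict(self.linker_composition)
        if self.domain_composition is not None:
            domain = dict(self.domain_composition)
        for name, comp in (("linker", linker), ("domain", domain)):
            if set(comp) != set(STANDARD_AA):
                raise ValueError(f"{name} composition must cover the 20 standard AAs")
            total = sum(comp.values())
            if abs(total - 100.0) > 0.1:
                raise ValueError(
                    f"{name} composition sums to {total:.2f}, expected 100 +- 0.1"
                )
            comp.update({aa: 100.0 * v / total for aa, v in comp.items()})
        if self.divergence_multiplier != 1.0:
            linker, domain = diverge_compositions(
                linker, domain, self.divergence_multiplier
            )
        return linker, domain


@dataclass
class CorpusStats:
    """Segment and residue bookkeeping for a labelled corpus."""

    n_sequences: int
    n_domains: int
    n_linkers: int
    mean_domain_length: float
    mean_linker_length: float
    domain_residue_share: float  # percent
    linker_residue_share: float  # percent
    linker_composition: dict[str, float]
    domain_composition: dict[str, float]


def residue_shares(
    n_domains: int,
    mean_domain_length: float,
    n_linkers: int,
    mean_linker_length: float,
) -> tuple[float, float]:
    """Percent of residues in domain vs linker segments from segment counts
    and mean segment lengths."""
    dom = n_domains * mean_domain_length
    link = n_linkers * mean_linker_length
    total = dom + link
    if total == 0:
        return 0.0, 0.0
    return 100.0 * dom / total, 100.0 * link / total


def generate_corpus(
    config: GeneratorConfig = GeneratorConfig(),
) -> tuple[AnnotatedCorpus, list[SegmentAnnotation]]:
    """Draw an annotated corpus; byte-identical for a fixed config."""
    if config.n_sequences < 1:
        raise ValueError("n_sequences must be positive")
    lo, hi = config.domains_per_sequence
    if not (1 <= lo <= hi):
        raise ValueError("invalid domains_per_sequence range")
    rng = np.random.default_rng(config.seed)
    linker_comp, domain_comp = config.resolved_compositions()
    aas = np.array(list(STANDARD_AA))
    p_linker = np.array([linker_comp[a] for a in aas]) / 100.0
    p_domain = np.array([domain_comp[a] for a in aas]) / 100.0

    sequences: list[ProteinSequence] = []
    labels: list[np.ndarray] = []
    annotations: list[SegmentAnnotation] = []
    for s in range(config.n_sequences):
        seq_id = f"syn{s:04d}"
        n_domains = int(rng.integers(lo, hi + 1))
        parts: list[str] = []
        lab_parts: list[np.ndarray] = []
        pos = 0
        for d in range(n_domains):
            dl = config.domain_length_law.sample(rng)
            parts.append("".join(rng.choice(aas, size=dl, p=p_domain)))
            lab_parts.append(np.zeros(dl, dtype=np.int8))
            pos += dl
            if d < n_domains - 1:
                ll = config.linker_length_law.sample(rng)
                parts.append("".join(rng.choice(aas, size=ll, p=p_linker)))
                lab_parts.append(np.ones(ll, dtype=np.int8))
                annotations.append(
                    SegmentAnnotation(seq_id, pos + 1, pos + ll, "linker")
                )
                pos += ll
        sequences.append(ProteinSequence(seq_id, "".join(parts)))
        labels.append(np.concatenate(lab_parts))
    return AnnotatedCorpus(sequences, labels), annotations


def corpus_stats(corpus: AnnotatedCorpus) -> CorpusStats:
    """Count maximal same-label runs as segments and summarize the corpus."""
    domain_lengths: list[int] = []
    linker_lengths: list[int] = []
    linker_counts = dict.fromkeys(STANDARD_AA, 0)
    domain_counts = dict.fromkeys(STANDARD_AA, 0)
    for seq, labels in corpus:
        linker_lengths.extend(
            len(seg) for seg in segments_from_labels(seq.id, labels)
        )
        inverted = 1 - np.asarray(labels)
        domain_lengths.extend(
            len(seg) for seg in segments_from_labels(seq.id, inverted)
        )
        arr = np.frombuffer(seq.residues.encode(), dtype=np.uint8)
        mask = np.asarray(labels, dtype=bool)
        for aa in STANDARD_AA:
            hits = arr == ord(aa)
            linker_counts[aa] += int(np.count_nonzero(hits & mask))
            domain_counts[aa] += int(np.count_nonzero(hits & ~mask))
    n_link = sum(linker_counts.values())
    n_dom = sum(domain_counts.values())
    total = n_link + n_dom
    return CorpusStats(
        n_sequences=len(corpus),
        n_domains=len(domain_lengths),
        n_linkers=len(linker_lengths),
        mean_domain_length=float(np.mean(domain_lengths)) if domain_lengths else 0.0,
        mean_linker_length=float(np.mean(linker_lengths)) if linker_lengths else 0.0,
        domain_residue_share=100.0 * n_dom / total if total else 0.0,
        linker_residue_share=100.0 * n_link / total if total else 0.0,
        linker_composition={
            aa: (100.0 * c / n_link if n_link else 0.0)
            for aa, c in linker_counts.items()
        },
        domain_composition={
            aa: (100.0 * c / n_dom if n_dom else 0.0)
            for aa, c in domain_counts.items()
        },
    )
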