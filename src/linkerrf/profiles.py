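"""Amino-acid property tables and per-residue feature profiles.

A residue is described by seven feature groups: its linker propensity index,
a hydrophobicity encoding (the signed five-bit SARAH1 code by default), and
five categorical physiochemical properties (side-chain charge, polarity,
aromaticity, size, electronic property), one-hot encoded by default.  The
per-residue vectors are then averaged over an odd window sliding along the
sequence, clipped at both termini, so each profile row is a convex
combination of raw encoding rows.

The linker index of residue *i* is

    S_i = -ln(f_i^linker / f_i^domain)

where the ``f`` are the percentage compositions of residue *i* within linker
and within domain residues; negative values mark residues over-represented
in linkers.  A published table of indices is packaged; they can equally be
re-estimated from any labelled corpus.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .sequence_io import STANDARD_AA, AnnotatedCorpus, ProteinSequence

logger = logging.getLogger(__name__)

#: Fixed category orders defining one-hot block layouts (and ordinal codes).
CATEGORY_ORDERS: dict[str, list[str]] = {
    "charge": ["positive", "negative", "neutral"],
    "polarity": ["polar", "nonpolar"],
    "aromaticity": ["aliphatic", "aromatic", "neutral"],
    "size": ["small", "medium", "large"],
    "electronic": [
        "strong_donor", "weak_donor", "neutral", "weak_acceptor", "strong_acceptor",
    ],
}

CATEGORICAL_PROPERTIES = list(CATEGORY_ORDERS)


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("linkerrf.data").joinpath(name)) as p:
        return pd.read_csv(p, sep="\t", comment="#", dtype={"aa": str})


@dataclass
class PropertyTables:
    """All per-amino-acid lookup tables used to encode residues."""

    linker_freq: dict[str, float]
    domain_freq: dict[str, float]
    linker_index: dict[str, float]
    hydro_kcal: dict[str, float]
    hydro_rose: dict[str, float]
    sarah1: dict[str, np.ndarray]
    categories: dict[str, dict[str, str]]  # property -> aa -> category

    def __post_init__(self) -> None:
        full = set(STANDARD_AA)
        for name, table in [
            ("linker_freq", self.linker_freq),
            ("domain_freq", self.domain_freq),
            ("linker_index", self.linker_index),
            ("hydro_kcal", self.hydro_kcal),
            ("hydro_rose", self.hydro_rose),
            ("sarah1", self.sarah1),
        ]:
            if set(table) != full:
                raise ValueError(f"table {name} does not cover the 20 standard AAs")
        for aa, code in self.sarah1.items():
            code = np.asarray(code)
            if code.shape != (5,) or np.count_nonzero(code) != 2:
                raise ValueError(f"SARAH1 code for {aa} must have exactly 2 non-zeros")
        for prop in CATEGORICAL_PROPERTIES:
            mapping = self.categories[prop]
            if set(mapping) != full:
                raise ValueError(f"category map {prop} does not cover all AAs")
            unknown = set(mapping.values()) - set(CATEGORY_ORDERS[prop])
            if unknown:
                raise ValueError(f"unknown {prop} categories {sorted(unknown)}")

    @classmethod
    def default(cls) -> "PropertyTables":
        """Load the packaged tables."""
        comp = _read_packaged("aa_composition.tsv").set_index("aa")
        kcal = _read_packaged("hydrophobicity_kcal.tsv").set_index("aa")
        rose = _read_packaged("hydrophobicity_rose.tsv").set_index("aa")
        sarah = _read_packaged("sarah1.tsv").set_index("aa")
        cats = _read_packaged("categories.tsv").set_index("aa")
        return cls(
            linker_freq=comp["linker_pct"].to_dict(),
            domain_freq=comp["domain_pct"].to_dict(),
            linker_index=comp["linker_index"].to_dict(),
            hydro_kcal=kcal["kcal_per_mol"].to_dict(),
            hydro_rose=rose["rose"].to_dict(),
            sarah1={aa: row.to_numpy(dtype=float) for aa, row in sarah.iterrows()},
            categories={p: cats[p].to_dict() for p in CATEGORICAL_PROPERTIES},
        )

    def with_linker_index(
        self, index: dict[str, float],
        linker_freq: dict[str, float] | None = None,
        domain_freq: dict[str, float] | None = None,
    ) -> "PropertyTables":
        """Copy of the tables with a replacement linker index."""
        return PropertyTables(
            linker_freq=dict(linker_freq or self.linker_freq),
            domain_freq=dict(domain_freq or self.domain_freq),
            linker_index=dict(index),
            hydro_kcal=self.hydro_kcal,
            hydro_rose=self.hydro_rose,
            sarah1=self.sarah1,
            categories=self.categories,
        )


@dataclass(frozen=True)
class EncodingConfig:
    """Which encodings build the per-residue feature vector.

    The default (SARAH1 hydrophobicity, one-hot categories, linker index)
    yields D = 1 + 5 + 3 + 2 + 3 + 3 + 5 = 22 features.
    """

    hydrophobicity_scale: Literal["sarah1", "kcal_ph7", "rose"] = "sarah1"
    categorical_encoding: Literal["one_hot", "ordinal"] = "one_hot"
    use_linker_index: bool = True
    linker_index_source: Literal["packaged_table", "estimated_from_training"] = (
        "estimated_from_training"
    )

    def feature_names(self) -> list[str]:
        names: list[str] = []
        if self.use_linker_index:
            names.append("linker_index")
        if self.hydrophobicity_scale == "sarah1":
            names += [f"hydrophobicity_sarah1_b{i}" for i in range(1, 6)]
        elif self.hydrophobicity_scale == "kcal_ph7":
            names.append("hydrophobicity_kcal_ph7")
        elif self.hydrophobicity_scale == "rose":
            names.append("hydrophobicity_rose")
        else:
            raise ValueError(f"unknown scale {self.hydrophobicity_scale!r}")
        for prop in CATEGORICAL_PROPERTIES:
            if self.categorical_encoding == "one_hot":
                names += [f"{prop}_{cat}" for cat in CATEGORY_ORDERS[prop]]
            elif self.categorical_encoding == "ordinal":
                names.append(f"{prop}_ordinal")
            else:
                raise ValueError(
                    f"unknown categorical encoding {self.categorical_encoding!r}"
                )
        return names

    @property
    def n_features(self) -> int:
        return len(self.feature_names())

    def feature_groups(self) -> dict[str, list[int]]:
        """Map each of the seven property groups to its column indices."""
        groups: dict[str, list[int]] = {}
        for j, name in enumerate(self.feature_names()):
            if name == "linker_index":
                key = "linker_index"
            elif name.startswith("hydrophobicity"):
                key = "hydrophobicity"
            else:
                key = next(p for p in CATEGORICAL_PROPERTIES if name.startswith(p))
            groups.setdefault(key, []).append(j)
        return groups


@dataclass
class ResidueProfile:
    """Window-averaged L x D feature matrix for one sequence."""

    seq_id: str
    matrix: np.ndarray
    feature_names: list[str]
    window: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.feature_names):
            raise ValueError("matrix shape does not match feature names")


def compute_linker_index(
    corpus: AnnotatedCorpus, pseudocount: float = 0.0
) -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
    """Estimate per-AA linker indices from a labelled corpus.

    Returns ``(index, linker_freq, domain_freq)`` where the frequency maps
    are percentage compositions within the linker and the domain partition
    (each sums to 100) and ``index[aa] = -ln((f_l + c) / (f_d + c))`` with
    pseudocount ``c``.

    An amino acid absent from both partitions gets index 0 with a warning.
    With ``pseudocount = 0`` an amino acid present in exactly one partition
    would produce an infinite index; this raises with an instruction to pass
    a positive pseudocount.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    linker_counts = dict.fromkeys(STANDARD_AA, 0)
    domain_counts = dict.fromkeys(STANDARD_AA, 0)
    for seq, labels in corpus:
        arr = np.frombuffer(seq.residues.encode(), dtype=np.uint8)
        mask = np.asarray(labels, dtype=bool)
        for aa in STANDARD_AA:
            hits = arr == ord(aa)
            linker_counts[aa] += int(np.count_nonzero(hits & mask))
            domain_counts[aa] += int(np.count_nonzero(hits & ~mask))
    n_linker = sum(linker_counts.values())
    n_domain = sum(domain_counts.values())
    if n_linker == 0 or n_domain == 0:
        raise ValueError("corpus must contain both linker and domain residues")
    linker_freq = {aa: 100.0 * c / n_linker for aa, c in linker_counts.items()}
    domain_freq = {aa: 100.0 * c / n_domain for aa, c in domain_counts.items()}
    index: dict[str, float] = {}
    for aa in STANDARD_AA:
        fl, fd = linker_freq[aa], domain_freq[aa]
        if fl == 0.0 and fd == 0.0:
            warnings.warn(f"amino acid {aa} absent from corpus; linker index set to 0")
            index[aa] = 0.0
            continue
        if pseudocount == 0.0 and (fl == 0.0 or fd == 0.0):
            raise ValueError(
                f"amino acid {aa} occurs in only one partition; pass a positive "
                "pseudocount to regularize the log-ratio"
            )
        index[aa] = float(-np.log((fl + pseudocount) / (fd + pseudocount)))
    return index, linker_freq, domain_freq


def encode_residue(
    aa: str, tables: PropertyTables, config: EncodingConfig = EncodingConfig()
) -> np.ndarray:
    """Encode one amino acid as a length-D feature vector.

    Block order is fixed: [linker index | hydrophobicity | charge | polarity
    | aromaticity | size | electronic].
    """
    if aa not in set(STANDARD_AA):
        raise ValueError(f"non-standard residue {aa!r}; sanitize sequences upstream")
    parts: list[np.ndarray] = []
    if config.use_linker_index:
        parts.append(np.array([tables.linker_index[aa]]))
    if config.hydrophobicity_scale == "sarah1":
        parts.append(np.asarray(tables.sarah1[aa], dtype=float))
    elif config.hydrophobicity_scale == "kcal_ph7":
        parts.append(np.array([tables.hydro_kcal[aa]]))
    else:
        parts.append(np.array([tables.hydro_rose[aa]]))
    for prop in CATEGORICAL_PROPERTIES:
        cat = tables.categories[prop][aa]
        order = CATEGORY_ORDERS[prop]
        if config.categorical_encoding == "one_hot":
            block = np.zeros(len(order))
            block[order.index(cat)] = 1.0
            parts.append(block)
        else:
            parts.append(np.array([float(order.index(cat))]))
    return np.concatenate(parts)


def encoding_matrix(
    tables: PropertyTables, config: EncodingConfig = EncodingConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Precompute a 20 x D encoding table plus an ASCII lookup vector.

    Returns ``(table, lut)`` where ``lut[ord(aa)]`` indexes the table row.
    """
    table = np.stack([encode_residue(aa, tables, config) for aa in STANDARD_AA])
    lut = np.full(128, -1, dtype=np.int64)
    for i, aa in enumerate(STANDARD_AA):
        lut[ord(aa)] = i
    return table, lut


def window_average(raw: np.ndarray, w: int) -> np.ndarray:
    """Average each row of ``raw`` over an odd window clipped at the termini.

    Output row j is the mean of raw rows i in [max(0, j-h), min(L-1, j+h)]
    with h = (w-1)/2, the denominator being the number of rows actually in
    range, so terminal windows shrink instead of padding.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if w < 1 or w % 2 == 0:
        raise ValueError(f"window size must be a positive odd integer, got {w}")
    L = raw.shape[0]
    if L == 0:
        raise ValueError("empty profile")
    if w == 1:
        return raw.copy()
    h = (w - 1) // 2
    # cumulative-sum sliding mean with clipped bounds
    csum = np.vstack([np.zeros((1, raw.shape[1])), np.cumsum(raw, axis=0)])
    j = np.arange(L)
    lo = np.maximum(j - h, 0)
    hi = np.minimum(j + h, L - 1)
    totals = csum[hi + 1] - csum[lo]
    return totals / (hi - lo + 1)[:, None]


def build_profile(
    seq: ProteinSequence,
    tables: PropertyTables,
    config: EncodingConfig = EncodingConfig(),
    w: int = 41,
    _precomputed: tuple[np.ndarray, np.ndarray] | None = None,
) -> ResidueProfile:
    """Encode every residue of ``seq`` and window-average the result."""
    table, lut = _precomputed if _precomputed is not None else encoding_matrix(tables, config)
    idx = lut[np.frombuffer(seq.residues.encode(), dtype=np.uint8)]
    raw = table[idx]
    return ResidueProfile(
        seq_id=seq.id,
        matrix=window_average(raw, w),
        feature_names=config.feature_names(),
        window=w,
    )


def build_profiles(
    sequences: list[ProteinSequence],
    tables: PropertyTables,
    config: EncodingConfig = EncodingConfig(),
    w: int = 41,
) -> list[ResidueProfile]:
    """Profiles for many sequences, sharing one precomputed encoding table."""
    pre = encoding_matrix(tables, config)
    return [build_profile(s, tables, config, w, _precomputed=pre) for s in sequences]
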