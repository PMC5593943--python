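"""Synthetic reference catalogs, immunoprecipitation read libraries and fixtures.

The generator emulates the statistical structure the analysis consumes,
without modelling immunoprecipitation chemistry: a catalog of random
nucleotide references (seven categories, definition lines that exercise the
keyword classifier), and per-library read sets drawn multinomially over
categories with configurable per-library category weights.  Reads are 125 bp
substrings at uniform positions and random strands, with i.i.d. substitution
errors; unmappable background is emulated with random "decoy" reads.

The default configuration mirrors the study conditions this package
re-implements: four libraries ({precocious, normal} x {MeDIP, hMeDIP}) with
hMeDIP category weights and library sizes proportional to the published
per-category count table (so that normal:precocious count ratios come out
~3.0-3.6 for nuclear categories and 0.57 for mitochondrial rRNA), MeDIP
weights equal across conditions (ratio 1) at the published mapped totals,
and a decoy background of 99.7% so that mapped fractions echo the
~0.1-0.45% scale of real libraries.  Scaled-down presets for fast runs are
provided by :func:`study_preset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import CATEGORY_ORDER, Catalog, Category, RrnaRecord
from .counts import ASSAYS, CONDITIONS, CategoryCountMatrix
from .mapper import CleanRead

#: The published per-category hydroxymethylation counts
#: (precocious, normal), in canonical category order.
TABLE2_COUNTS: dict[str, tuple[float, float]] = {
    "18S": (24187.06, 74019.88),
    "5S": (2120.44, 7052.29),
    "28S": (46389.50, 162399.36),
    "ITS": (1994.27, 6530.58),
    "MERGED": (16595.53, 59321.41),
    "MITO_RRNA": (129.68, 73.36),
    "MITO_ITS": (916.52, 3040.54),
}

#: Mapped clean-read totals of the four study libraries (raw scale).
STUDY_MAPPED_TOTALS: dict[tuple[str, str], int] = {
    ("precocious", "MeDIP"): 56_281,
    ("normal", "MeDIP"): 48_469,
    ("precocious", "hMeDIP"): 105_377,
    ("normal", "hMeDIP"): 268_299,
}

#: Default library sizes of the study-like preset.  The hMeDIP sizes are
#: the column totals of the published per-category table (its normalized
#: scale), so that simulated per-category count ratios reproduce the
#: published fold changes (~3.0-3.6 nuclear, 0.57 mitochondrial rRNA);
#: the raw mapped totals above sit on a different scale whose ratio
#: (2.55) would distort every fold change.  MeDIP sizes are the raw
#: mapped totals (ratio ~1.16, matching the published near-equality).
PRESET_LIBRARY_SIZES: dict[tuple[str, str], int] = {
    ("precocious", "MeDIP"): 56_281,
    ("normal", "MeDIP"): 48_469,
    ("precocious", "hMeDIP"): 92_333,
    ("normal", "hMeDIP"): 312_437,
}


def table2_fixture() -> CategoryCountMatrix:
    """The published per-category hMeDIP count table, verbatim."""
    return CategoryCountMatrix.from_dict(
        {
            ("precocious", "hMeDIP"): {c: v[0] for c, v in TABLE2_COUNTS.items()},
            ("normal", "hMeDIP"): {c: v[1] for c, v in TABLE2_COUNTS.items()},
        },
        provenance="fixture",
    )


def mapped_totals_fixture() -> dict[tuple[str, str], int]:
    """Mapped clean-read totals per library, as published."""
    return dict(STUDY_MAPPED_TOTALS)


class SimulationError(ValueError):
    """Invalid simulation configuration or an unsatisfiable draw."""


def study_weights() -> dict[tuple[str, str], np.ndarray]:
    """Per-library category weights mirroring the published count structure.

    hMeDIP weights are the published per-category counts normalized within
    each condition; MeDIP weights use the pooled hMeDIP shape for both
    conditions, making every MeDIP precocious:normal ratio exactly 1 (the
    per-category methylation composition was never published, only that the
    two conditions were alike).
    """
    prec = np.array([TABLE2_COUNTS[c.value][0] for c in CATEGORY_ORDER])
    norm = np.array([TABLE2_COUNTS[c.value][1] for c in CATEGORY_ORDER])
    pooled = prec + norm
    return {
        ("precocious", "hMeDIP"): prec / prec.sum(),
        ("normal", "hMeDIP"): norm / norm.sum(),
        ("precocious", "MeDIP"): pooled / pooled.sum(),
        ("normal", "MeDIP"): pooled / pooled.sum(),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the synthetic generator.

    ``n_reads`` is the number of catalog-derived reads per library; decoy
    reads are generated on top so that they make up ``decoy_fraction`` of
    the final library.
    """

    seed: int = 0
    n_records_per_category: tuple[int, ...] = (2, 2, 2, 3, 38, 2, 2)
    record_length_range: tuple[int, int] = (600, 2400)
    read_length: int = 125
    n_reads: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: dict(PRESET_LIBRARY_SIZES)
    )
    category_weights: Mapping[tuple[str, str], np.ndarray] = field(
        default_factory=study_weights
    )
    substitution_error_rate: float = 0.005
    decoy_fraction: float = 0.997

    def __post_init__(self) -> None:
        if len(self.n_records_per_category) != len(CATEGORY_ORDER):
            raise SimulationError("need one record count per category (7)")
        lo, hi = self.record_length_range
        if lo > hi or lo < self.read_length:
            raise SimulationError(
                "record lengths must be >= read_length and lo <= hi"
            )
        if not 0 <= self.substitution_error_rate <= 0.2:
            raise SimulationError("substitution error rate must be in [0, 0.2]")
        if not 0 <= self.decoy_fraction < 1:
            raise SimulationError("decoy fraction must be in [0, 1)")
        for lib, w in self.category_weights.items():
            w = np.asarray(w, dtype=float)
            if w.shape != (len(CATEGORY_ORDER),) or (w < 0).any():
                raise SimulationError(f"weights for {lib} must be 7 nonnegative reals")
            if abs(w.sum() - 1.0) > 1e-6:
                raise SimulationError(f"weights for {lib} must sum to 1")


def study_preset(
    scale: float = 1.0,
    decoy_fraction: float = 0.997,
    seed: int = 0,
    substitution_error_rate: float = 0.005,
) -> SimulationConfig:
    """The study-like preset, optionally with scaled-down library sizes.

    ``scale`` multiplies every library's catalog-derived read count; weights
    and everything else stay at the study conditions.
    """
    n_reads = {
        lib: max(1, round(n * scale)) for lib, n in PRESET_LIBRARY_SIZES.items()
    }
    return SimulationConfig(
        seed=seed,
        n_reads=n_reads,
        decoy_fraction=decoy_fraction,
        substitution_error_rate=substitution_error_rate,
    )


_ACC_PREFIX = {
    Category.NUC_18S: "SYN18S",
    Category.NUC_5S: "SYN05S",
    Category.NUC_28S: "SYN28S",
    Category.ITS: "SYNITS",
    Category.MERGED: "SYNMRG",
    Category.MITO_RRNA: "SYNMTR",
    Category.MITO_ITS: "SYNMTI",
}

# Definition-line templates per category; merged records cycle through
# 18S-, 28S- and 5.8S-bearing variants (mirroring a catalog in which most
# merged records carry partial 18S/28S gene segments).
_TEMPLATES: dict[Category, tuple[tuple[str, tuple[str, ...]], ...]] = {
    Category.NUC_18S: (
        ("18S ribosomal RNA gene, partial sequence", ("18S",)),
    ),
    Category.NUC_5S: (
        ("5S ribosomal RNA gene, complete sequence", ("5S",)),
    ),
    Category.NUC_28S: (
        ("28S ribosomal RNA gene, partial sequence", ("28S",)),
    ),
    Category.ITS: (
        ("internal transcribed spacer 1, partial sequence", ("ITS1",)),
        ("internal transcribed spacer 2, partial sequence", ("ITS2",)),
    ),
    Category.MERGED: (
        (
            "18S ribosomal RNA gene, partial sequence; and internal "
            "transcribed spacer 1",
            ("18S", "ITS1"),
        ),
        (
            "internal transcribed spacer 2 and 28S ribosomal RNA gene, "
            "partial sequence",
            ("ITS2", "28S"),
        ),
        (
            "internal transcribed spacer 1, 5.8S ribosomal RNA gene, and "
            "internal transcribed spacer 2, complete sequence",
            ("ITS1", "5.8S", "ITS2"),
        ),
    ),
    Category.MITO_RRNA: (
        ("mitochondrial 16S ribosomal RNA gene, partial sequence", ("mito",)),
    ),
    Category.MITO_ITS: (
        (
            "mitochondrial internal transcribed spacer, partial sequence",
            ("mito", "ITS"),
        ),
    ),
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode("ascii")


def make_reference(config: SimulationConfig) -> Catalog:
    """Generate a classified synthetic reference catalog (deterministic per seed)."""
    rng = np.random.default_rng([config.seed, 101])
    lo, hi = config.record_length_range
    records: list[RrnaRecord] = []
    for cat, n in zip(CATEGORY_ORDER, config.n_records_per_category):
        templates = _TEMPLATES[cat]
        for j in range(n):
            definition, features = templates[j % len(templates)]
            length = int(rng.integers(lo, hi + 1))
            records.append(
                RrnaRecord.build(
                    accession=f"{_ACC_PREFIX[cat]}{j + 1:03d}",
                    definition=f"Eriocheir sinensis {definition} (synthetic)",
                    sequence=_random_seq(rng, length),
                    features=features,
                )
            )
    return Catalog(records)


@dataclass(frozen=True)
class GroundTruth:
    """Per-read provenance of a simulated library."""

    condition: str
    assay: str
    read_ids: tuple[str, ...]
    source_accession: tuple[str | None, ...]  # None for decoy reads
    source_category: tuple[str | None, ...]
    expected_proportions: np.ndarray  # configured category weights (7,)
    category_draws: np.ndarray  # multinomial draw per category (7,)
    n_decoys: int

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {c.value: 0 for c in CATEGORY_ORDER}
        for cat in self.source_category:
            if cat is not None:
                counts[cat] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "read_id": self.read_ids,
                "accession": [a or "" for a in self.source_accession],
                "category": [c or "decoy" for c in self.source_category],
            }
        )


def simulate_library(
    catalog: Catalog,
    config: SimulationConfig,
    condition: str,
    assay: str,
) -> tuple[list[CleanRead], GroundTruth]:
    """Draw one library of clean reads from the catalog plus decoy background.

    Reads are drawn multinomially over categories with the configured
    weights, uniformly over each category's eligible records (length >=
    read length) and start positions, on a random strand, then subjected
    to i.i.d. substitution errors.  Deterministic given the config seed;
    each of the four libraries uses an independent seeded stream, so the
    order in which libraries are generated does not matter.
    """
    if (condition, assay) not in config.n_reads:
        raise SimulationError(f"no read count configured for {(condition, assay)}")
    rng = np.random.default_rng(
        [config.seed, 7, CONDITIONS.index(condition), ASSAYS.index(assay)]
    )
    L = config.read_length
    n = int(config.n_reads[(condition, assay)])
    w = np.asarray(config.category_weights[(condition, assay)], dtype=float)
    draws = rng.multinomial(n, w)

    members_by_cat: list[list[RrnaRecord]] = []
    for cat in CATEGORY_ORDER:
        eligible = [catalog.get(a) for a in catalog.members(cat)]
        eligible = [r for r in eligible if r.length >= L]
        members_by_cat.append(eligible)

    seqs: list[str] = []
    accs: list[str] = []
    cats: list[str] = []
    for ci, cat in enumerate(CATEGORY_ORDER):
        cnt = int(draws[ci])
        if cnt == 0:
            continue
        members = members_by_cat[ci]
        if not members:
            raise SimulationError(
                f"category {cat.value} has no record of length >= {L}"
            )
        pick = rng.integers(0, len(members), size=cnt)
        lens = np.array([m.length for m in members])[pick]
        starts = (rng.random(cnt) * (lens - L + 1)).astype(np.int64)
        strands = rng.integers(0, 2, size=cnt)
        n_err = rng.binomial(L, config.substitution_error_rate, size=cnt)
        for idx in range(cnt):
            rec = members[pick[idx]]
            frag = rec.sequence[starts[idx] : starts[idx] + L]
            if strands[idx] == 1:
                frag = frag.translate(_RC)[::-1]
            if n_err[idx]:
                frag = _mutate(rng, frag, int(n_err[idx]))
            seqs.append(frag)
            accs.append(rec.accession)
            cats.append(cat.value)

    n_decoys = (
        int(round(n * config.decoy_fraction / (1.0 - config.decoy_fraction)))
        if config.decoy_fraction > 0
        else 0
    )
    for _ in range(n_decoys):
        seqs.append(_random_seq(rng, L))
        accs.append(None)  # type: ignore[arg-type]
        cats.append(None)  # type: ignore[arg-type]

    read_ids = tuple(
        f"sim:{condition}:{assay}:{i:08d}" for i in range(len(seqs))
    )
    reads = [
        CleanRead(rid, seq, condition, assay) for rid, seq in zip(read_ids, seqs)
    ]
    truth = GroundTruth(
        condition=condition,
        assay=assay,
        read_ids=read_ids,
        source_accession=tuple(accs),
        source_category=tuple(cats),
        expected_proportions=w,
        category_draws=draws,
        n_decoys=n_decoys,
    )
    return reads, truth


_RC = str.maketrans("ACGTN", "TGCAN")


def _mutate(rng: np.random.Generator, seq: str, n_err: int) -> str:
    pos = rng.choice(len(seq), size=n_err, replace=False)
    shift = rng.integers(1, 4, size=n_err)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    code = np.zeros(len(arr), dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code[arr == b] = i
    code[pos] = (code[pos] + shift) % 4
    return bytes(_BASES[code]).decode("ascii")


def write_fastq(reads: Sequence[CleanRead], path: str | Path) -> None:
    """Write reads as plain FASTQ with a constant quality string."""
    with open(path, "w") as out:
        for r in reads:
            out.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)
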