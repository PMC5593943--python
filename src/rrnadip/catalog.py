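"""rRNA gene reference catalog: loading, classification and round-trip I/O.

Every reference record is assigned to exactly one of seven categories:
the nuclear 18S, 5S and 28S genes, stand-alone internal transcribed
spacers (ITS), "merged" records that contain both a spacer and a partial
gene segment (including every 5.8S fragment, which never occurs without
its adjoining spacer in this catalog), and the mitochondrial rRNA genes
and spacers.  The category is the unit of all downstream statistics, so
classification must be deterministic, total over the recognized keyword
set, and auditable.

Classification uses a priority rule list over case-insensitive keywords
extracted from the FASTA definition line; an explicit annotation table
(features and/or a category override per accession) takes precedence
over keyword parsing, because definition lines in public records are
not written consistently.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, TextIO

from Bio import SeqIO


class CatalogError(ValueError):
    """Problem constructing or loading a reference catalog."""


class ClassificationError(CatalogError):
    """A record could not be assigned to any of the seven categories."""


class DuplicateAccessionError(CatalogError):
    """Two records in one catalog share an accession."""


class Category(str, Enum):
    """The seven rRNA reference categories used throughout the analysis."""

    NUC_18S = "18S"
    NUC_5S = "5S"
    NUC_28S = "28S"
    ITS = "ITS"
    MERGED = "MERGED"
    MITO_RRNA = "MITO_RRNA"
    MITO_ITS = "MITO_ITS"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value


#: Canonical row order of the category count matrix (nuclear genes and
#: spacers first, mitochondrial records last).
CATEGORY_ORDER: tuple[Category, ...] = tuple(Category)

#: Structural feature labels a record may carry.
FEATURE_LABELS = frozenset({"18S", "5.8S", "28S", "5S", "ITS1", "ITS2", "ITS", "mito"})

_GENE_FEATURES = frozenset({"18S", "28S", "5S", "5.8S"})
_ITS_FEATURES = frozenset({"ITS", "ITS1", "ITS2"})

_CANONICAL_FEATURE = {f.lower(): f for f in FEATURE_LABELS}
_CANONICAL_FEATURE.update({"mitochondrial": "mito", "mitochondria": "mito", "mt": "mito"})

_RE_MITO = re.compile(r"mitochondri|\bmt\b", re.IGNORECASE)
_RE_MITO_GENE = re.compile(r"\b1[26]s\b|\brrn[ls]\b", re.IGNORECASE)
_RE_18S = re.compile(r"\b18s\b", re.IGNORECASE)
_RE_28S = re.compile(r"\b28s\b", re.IGNORECASE)
_RE_58S = re.compile(r"\b5\.8s\b", re.IGNORECASE)
_RE_5S = re.compile(r"\b5s\b", re.IGNORECASE)
_RE_ITS1 = re.compile(r"internal transcribed spacer 1|\bits1\b", re.IGNORECASE)
_RE_ITS2 = re.compile(r"internal transcribed spacer 2|\bits2\b", re.IGNORECASE)
_RE_ITS = re.compile(r"internal transcribed spacer|\bits\b", re.IGNORECASE)
_RE_RRNA = re.compile(r"\br(ibosomal\s+)?rna\b|\brdna\b", re.IGNORECASE)


def canonical_feature(label: str) -> str:
    """Normalize a feature label (case-insensitive) to its canonical form."""
    try:
        return _CANONICAL_FEATURE[label.strip().lower()]
    except KeyError:
        raise CatalogError(f"unknown feature label: {label!r}") from None


def features_from_definition(definition: str) -> set[str]:
    """Extract structural feature labels from a FASTA definition line.

    The 12S/16S mitochondrial rRNA gene names imply the ``mito`` label on
    their own: in this system (a metazoan nuclear/mitochondrial catalog)
    those genes only occur on the mitochondrial genome.
    """
    feats: set[str] = set()
    if _RE_MITO.search(definition) or _RE_MITO_GENE.search(definition):
        feats.add("mito")
    if _RE_18S.search(definition):
        feats.add("18S")
    if _RE_28S.search(definition):
        feats.add("28S")
    if _RE_58S.search(definition):
        feats.add("5.8S")
    if _RE_5S.search(definition):
        feats.add("5S")
    if _RE_ITS1.search(definition):
        feats.add("ITS1")
    if _RE_ITS2.search(definition):
        feats.add("ITS2")
    if _RE_ITS.search(definition):
        feats.add("ITS")
    return feats


def classify_record(definition: str = "", features: Iterable[str] = ()) -> Category:
    """Assign one of the seven categories from features and/or a definition line.

    Explicit ``features`` win; when none are supplied the definition line is
    parsed with the keyword rules of :func:`features_from_definition`.  The
    priority order is: mitochondrial records are split off first (spacer
    evidence beats gene evidence there, because spacer records routinely
    name their flanking genes); then spacer+gene co-occurrence or any 5.8S
    fragment maps to MERGED; then single-gene and spacer-only records map
    to their own categories.

    Raises
    ------
    ClassificationError
        If no recognized keyword or feature combination applies.
    """
    feats = {canonical_feature(f) for f in features}
    if not feats:
        feats = features_from_definition(definition)
    if not feats:
        raise ClassificationError(
            f"no recognized rRNA keywords in definition {definition!r}"
        )

    gene = feats & _GENE_FEATURES
    its = feats & _ITS_FEATURES

    if "mito" in feats:
        if its:
            return Category.MITO_ITS
        if gene or _RE_MITO_GENE.search(definition) or _RE_RRNA.search(definition):
            return Category.MITO_RRNA
        raise ClassificationError(
            "mitochondrial record without rRNA-gene or spacer evidence "
            f"(definition {definition!r})"
        )

    if "5.8S" in gene:
        if not its:
            warnings.warn(
                "5.8S record without an adjoining spacer classified as MERGED "
                "(5.8S fragments are always folded into the merged category)",
                stacklevel=2,
            )
        return Category.MERGED
    if its and gene:
        return Category.MERGED
    if its:
        return Category.ITS
    if len(gene) == 1:
        return Category(next(iter(gene)))
    raise ClassificationError(
        f"unrecognized feature combination {sorted(feats)!r} "
        f"(definition {definition!r})"
    )


_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class RrnaRecord:
    """One reference sequence with its category label and feature composition."""

    accession: str
    definition: str
    sequence: str
    features: tuple[str, ...]
    category: Category

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise CatalogError(f"empty sequence for {self.accession}")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise CatalogError(
                f"invalid bases {sorted(bad)} in sequence of {self.accession}"
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @classmethod
    def build(
        cls,
        accession: str,
        definition: str,
        sequence: str,
        features: Iterable[str] = (),
        category: Category | str | None = None,
    ) -> "RrnaRecord":
        """Create a record, classifying it unless a category is forced."""
        feats = tuple(canonical_feature(f) for f in features)
        if category is None:
            try:
                cat = classify_record(definition, feats)
            except ClassificationError as exc:
                raise ClassificationError(f"{accession}: {exc}") from None
        else:
            cat = Category(category)
        if not feats:
            feats = tuple(sorted(features_from_definition(definition)))
        return cls(accession, definition, sequence, feats, cat)


class Catalog:
    """An immutable collection of classified reference records.

    Accessions are unique; every record carries exactly one category, so
    the category index is a partition of the accession set.
    """

    def __init__(self, records: Iterable[RrnaRecord]):
        self.records: tuple[RrnaRecord, ...] = tuple(records)
        by_acc: dict[str, RrnaRecord] = {}
        for rec in self.records:
            if rec.accession in by_acc:
                raise DuplicateAccessionError(
                    f"duplicate accession in catalog: {rec.accession}"
                )
            by_acc[rec.accession] = rec
        self._by_acc = by_acc

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, accession: str) -> bool:
        return accession in self._by_acc

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Catalog):
            return NotImplemented
        return self.records == other.records

    def get(self, accession: str) -> RrnaRecord:
        try:
            return self._by_acc[accession]
        except KeyError:
            raise CatalogError(f"accession not in catalog: {accession}") from None

    @property
    def accessions(self) -> tuple[str, ...]:
        return tuple(r.accession for r in self.records)

    @property
    def category_index(self) -> dict[Category, tuple[str, ...]]:
        """Category -> accessions; a partition of the full accession set."""
        idx: dict[Category, list[str]] = {c: [] for c in CATEGORY_ORDER}
        for rec in self.records:
            idx[rec.category].append(rec.accession)
        return {c: tuple(a) for c, a in idx.items()}

    def category_of(self, accession: str) -> Category:
        return self.get(accession).category

    def members(self, category: Category | str) -> tuple[str, ...]:
        return self.category_index[Category(category)]


@dataclass(frozen=True)
class _Annotation:
    features: tuple[str, ...] = ()
    category_override: str | None = None


def read_annotation(source: str | Path | TextIO) -> dict[str, _Annotation]:
    """Read a TSV annotation table: accession, features, [category_override]."""
    close = False
    if isinstance(source, (str, Path)):
        handle = open(source, newline="")
        close = True
    else:
        handle = source
    try:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or "accession" not in reader.fieldnames:
            raise CatalogError("annotation table must have an 'accession' column")
        out: dict[str, _Annotation] = {}
        for row in reader:
            acc = row["accession"].strip()
            feats = tuple(
                f.strip() for f in (row.get("features") or "").split(",") if f.strip()
            )
            override = (row.get("category_override") or "").strip() or None
            out[acc] = _Annotation(feats, override)
        return out
    finally:
        if close:
            handle.close()


def load_catalog(
    fasta_source: str | Path | TextIO,
    annotation_source: str | Path | TextIO | None = None,
) -> Catalog:
    """Load and classify a multi-record FASTA, optionally with an annotation table.

    Records that fail classification are collected and reported together in
    a single :class:`ClassificationError` naming every offending accession;
    nothing is silently dropped.
    """
    annotations = read_annotation(annotation_source) if annotation_source else {}
    records: list[RrnaRecord] = []
    failures: list[str] = []
    for seqrec in SeqIO.parse(fasta_source, "fasta"):
        acc = seqrec.id
        definition = seqrec.description
        if definition.startswith(acc):
            definition = definition[len(acc):].strip()
        ann = annotations.get(acc, _Annotation())
        try:
            records.append(
                RrnaRecord.build(
                    acc,
                    definition,
                    str(seqrec.seq),
                    features=ann.features,
                    category=ann.category_override,
                )
            )
        except ClassificationError as exc:
            failures.append(f"{acc} ({exc})")
    if failures:
        raise ClassificationError(
            "unclassifiable records: " + "; ".join(failures)
        )
    if not records:
        raise CatalogError("no FASTA records found")
    return Catalog(records)


def write_catalog_fasta(catalog: Catalog, path: str | Path, width: int = 70) -> None:
    """Write the catalog as wrapped FASTA (accession + definition on the header)."""
    with open(path, "w") as out:
        for rec in catalog:
            header = f">{rec.accession} {rec.definition}".rstrip()
            out.write(header + "\n")
            for i in range(0, rec.length, width):
                out.write(rec.sequence[i : i + width] + "\n")


def write_catalog_table(catalog: Catalog, path: str | Path) -> None:
    """Write the catalog summary TSV: accession, category, length, features."""
    with open(path, "w", newline="") as out:
        writer = csv.writer(out, delimiter="\t", lineterminator="\n")
        writer.writerow(["accession", "category", "length", "features"])
        for rec in catalog:
            writer.writerow(
                [rec.accession, rec.category.value, rec.length, ",".join(rec.features)]
            )


def write_annotation_table(catalog: Catalog, path: str | Path) -> None:
    """Write an annotation TSV that reloads the catalog byte-identically."""
    with open(path, "w", newline="") as out:
        writer = csv.writer(out, delimiter="\t", lineterminator="\n")
        writer.writerow(["accession", "features", "category_override"])
        for rec in catalog:
            writer.writerow([rec.accession, ",".join(rec.features), rec.category.value])
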