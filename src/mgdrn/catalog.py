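"""Consensus miRNA-target candidate catalog.

Target predictions from several algorithms (TargetScan, miRanda, PicTar, ...)
disagree heavily; requiring a pair to be predicted by at least ``min_sources``
independent sources is the standard way to trade sensitivity for precision.
This module loads per-source pair tables, converts precursor (pre-miRNA)
identifiers to mature-arm identifiers so predictions and expression profiles
share a namespace, and intersects sources into an
:class:`InteractionCatalog`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: mature-arm suffixes; an id ending in one of these is never warned about
#: when it is absent from a precursor map.
_MATURE_SUFFIXES = ("-3p", "-5p")


def normalize_id(identifier: str) -> str:
    """Lower-case and strip an identifier; no further munging.

    Prediction-table dialects vary (case, stray whitespace); anything beyond
    case/whitespace normalization risks silently rewriting ids.
    """
    return identifier.strip().lower()


@dataclass(frozen=True)
class PredictionTable:
    """miRNA→gene candidate pairs from one prediction source."""

    source_name: str
    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for mirna, gene in self.pairs:
            if not mirna or not gene:
                raise ValueError(
                    f"source {self.source_name!r}: empty identifier in pair "
                    f"({mirna!r}, {gene!r})"
                )


@dataclass(frozen=True)
class MatureMap:
    """Precursor-miRNA → mature-miRNA(s) correspondence."""

    entries: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for pre, matures in self.entries.items():
            if len(matures) == 0:
                raise ValueError(f"pre-miRNA {pre!r} maps to no mature ids")
            if len(set(matures)) != len(matures):
                raise ValueError(f"pre-miRNA {pre!r} has duplicate mature ids")

    @property
    def mature_namespace(self) -> frozenset[str]:
        return frozenset(m for ms in self.entries.values() for m in ms)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MatureMap":
        """Read a ``pre_id<TAB>mature_id`` table (one row per mapping)."""
        entries: dict[str, list[str]] = {}
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    logger.warning("%s:%d: fewer than 2 columns, skipped", path, lineno)
                    continue
                pre, mature = normalize_id(fields[0]), normalize_id(fields[1])
                entries.setdefault(pre, [])
                if mature not in entries[pre]:
                    entries[pre].append(mature)
        return cls(entries={k: tuple(v) for k, v in entries.items()})

    @classmethod
    def empty(cls) -> "MatureMap":
        return cls(entries={})


@dataclass(frozen=True)
class CatalogRecord:
    mirna_id: str
    gene_id: str
    sources: frozenset[str]

    @property
    def source_count(self) -> int:
        return len(self.sources)


@dataclass
class InteractionCatalog:
    """Consensus miRNA→gene pairs with per-source evidence."""

    records: dict[tuple[str, str], CatalogRecord] = field(default_factory=dict)

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self.records)

    @property
    def genes(self) -> set[str]:
        return {g for (_, g) in self.records}

    @property
    def mirnas(self) -> set[str]:
        return {m for (m, _) in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.records

    def write_tsv(self, path: str | Path) -> None:
        """Write ``mirna<TAB>gene<TAB>source_count<TAB>sources`` rows."""
        with open(path, "w") as handle:
            handle.write("mirna\tgene\tsource_count\tsources\n")
            for (mirna, gene), rec in sorted(self.records.items()):
                handle.write(
                    f"{mirna}\t{gene}\t{rec.source_count}\t"
                    f"{','.join(sorted(rec.sources))}\n"
                )


def _read_pair_file(path: str | Path, source_name: str) -> PredictionTable:
    pairs: set[tuple[str, str]] = set()
    try:
        handle = open(path)
    except OSError as exc:
        raise FileNotFoundError(f"cannot read prediction table {path!r}: {exc}") from exc
    with handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                logger.warning("%s:%d: fewer than 2 columns, row skipped", path, lineno)
                continue
            mirna, gene = normalize_id(fields[0]), normalize_id(fields[1])
            if lineno == 1 and {mirna, gene} & {"mirna", "mirna_id", "gene", "gene_id"}:
                continue  # optional header
            pairs.add((mirna, gene))
    return PredictionTable(source_name=source_name, pairs=frozenset(pairs))


def load_prediction_tables(
    paths: Sequence[str | Path], source_names: Sequence[str]
) -> list[PredictionTable]:
    """Load one 2-column TSV (mirna, gene) per source, in input order.

    Duplicate rows within a file collapse; identifiers are lower-cased and
    stripped; ``#`` comment lines and an optional header row are ignored.
    Rows with fewer than two non-empty columns are skipped with a warning;
    an unreadable file is fatal.
    """
    if len(paths) != len(source_names):
        raise ValueError(
            f"{len(paths)} paths but {len(source_names)} source names"
        )
    return [_read_pair_file(p, s) for p, s in zip(paths, source_names)]


def map_to_mature(table: PredictionTable, mature_map: MatureMap) -> PredictionTable:
    """Replace precursor miRNA ids with their mature-arm ids.

    A pair whose miRNA id is a known precursor becomes one pair per mapped
    mature id. Ids already in the mature namespace (or carrying a -3p/-5p arm
    suffix) pass through unchanged; unmapped precursor-style ids also pass
    through, with a warning, so partial maps remain usable.
    """
    mature_ns = mature_map.mature_namespace
    out: set[tuple[str, str]] = set()
    unmapped: set[str] = set()
    for mirna, gene in table.pairs:
        if mirna in mature_map.entries:
            for mature in mature_map.entries[mirna]:
                out.add((mature, gene))
        else:
            if (
                mirna not in mature_ns
                and not mirna.endswith(_MATURE_SUFFIXES)
                and mature_map.entries
            ):
                unmapped.add(mirna)
            out.add((mirna, gene))
    if unmapped:
        logger.warning(
            "source %s: %d precursor-style ids not in the mature map "
            "(passed through): %s",
            table.source_name, len(unmapped), ", ".join(sorted(unmapped)[:5]),
        )
    return PredictionTable(source_name=table.source_name, pairs=frozenset(out))


def build_catalog(
    tables: Iterable[PredictionTable], min_sources: int = 2
) -> InteractionCatalog:
    """Intersect prediction sources into a consensus catalog.

    A pair is kept iff it appears in at least ``min_sources`` distinct
    sources (a pair listed twice inside one source counts that source once).
    Default 2: a single-algorithm prediction is weak evidence, while
    requiring 3+ of 7 algorithms empties the catalog on real data.
    """
    tables = list(tables)
    if min_sources < 1:
        raise ValueError(f"min_sources must be >= 1, got {min_sources}")
    if min_sources > len(tables):
        raise ValueError(
            f"min_sources={min_sources} exceeds the number of prediction "
            f"sources ({len(tables)})"
        )
    membership: dict[tuple[str, str], set[str]] = {}
    for table in tables:
        for pair in table.pairs:
            membership.setdefault(pair, set()).add(table.source_name)
    records = {
        pair: CatalogRecord(pair[0], pair[1], frozenset(sources))
        for pair, sources in membership.items()
        if len(sources) >= min_sources
    }
    return InteractionCatalog(records=records)
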