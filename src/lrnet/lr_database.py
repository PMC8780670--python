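"""Curated ligand-receptor pair databases.

A ligand-receptor (L-R) pair is a *directed* gene pair: a secreted or
cell-surface ligand gene and its cognate receptor gene. Published catalogues
overlap heavily, so analyses typically merge several lists and deduplicate on
the (ligand, receptor) key. Gene symbols are canonicalized (upper-cased,
whitespace-stripped) before comparison; no synonym or alias resolution is
attempted, so the merge is reproducible without an external symbol service.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

log = logging.getLogger(__name__)

__all__ = ["LRPair", "LRDatabase", "LoadReport", "canonical_symbol", "load_pairs"]


def canonical_symbol(symbol: str) -> str:
    """Canonical form of a gene symbol: stripped of flanking whitespace, upper-cased."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class LRPair:
    """One directed ligand -> receptor gene pair.

    ``source`` is a free-text provenance tag (e.g. the name of the catalogue
    the pair came from); it does not participate in identity.
    """

    ligand: str
    receptor: str
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "ligand", canonical_symbol(self.ligand))
        object.__setattr__(self, "receptor", canonical_symbol(self.receptor))
        if not self.ligand or not self.receptor:
            raise ValueError("ligand and receptor symbols must be non-empty")

    @property
    def key(self) -> tuple[str, str]:
        return (self.ligand, self.receptor)


@dataclass
class LoadReport:
    """Bookkeeping for one CSV load: how many rows survived canonicalization."""

    rows_read: int = 0
    rows_kept: int = 0
    duplicates_removed: int = 0
    rows_rejected: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "rows_read": self.rows_read,
                "rows_kept": self.rows_kept,
                "duplicates_removed": self.duplicates_removed,
                "rows_rejected": self.rows_rejected,
            }
        )


class LRDatabase:
    """An ordered, deduplicated collection of :class:`LRPair`.

    Uniqueness is on the canonicalized ``(ligand, receptor)`` tuple; direction
    matters, so ``(A, B)`` and ``(B, A)`` are distinct entries. Self-pairs
    (ligand == receptor) are retained if present in the input. Insertion
    order of first occurrence is preserved.
    """

    def __init__(self, pairs: Iterable[LRPair] = ()):  # noqa: D107
        self._pairs: dict[tuple[str, str], LRPair] = {}
        for p in pairs:
            self._pairs.setdefault(p.key, p)
        self.load_report: LoadReport | None = None

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self) -> Iterator[LRPair]:
        return iter(self._pairs.values())

    def __contains__(self, key: tuple[str, str]) -> bool:
        return (canonical_symbol(key[0]), canonical_symbol(key[1])) in self._pairs

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LRDatabase):
            return NotImplemented
        return set(self._pairs) == set(other._pairs)

    @property
    def size(self) -> int:
        return len(self)

    @property
    def keys(self) -> set[tuple[str, str]]:
        return set(self._pairs)

    @property
    def ligands(self) -> set[str]:
        """Distinct ligand genes across all pairs."""
        return {p.ligand for p in self}

    @property
    def receptors(self) -> set[str]:
        """Distinct receptor genes across all pairs."""
        return {p.receptor for p in self}

    def merge(self, other: "LRDatabase") -> "LRDatabase":
        """Union of two databases on the (ligand, receptor) key.

        Commutative in content; when both sides carry the same key the pair
        object (hence its ``source`` tag) from ``self`` wins, which does not
        affect identity.
        """
        return LRDatabase(list(self) + list(other))

    def to_csv(self, path: str | Path) -> None:
        """Write the database as ``ligand,receptor,source`` CSV (UTF-8)."""
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["ligand", "receptor", "source"])
            for p in self:
                w.writerow([p.ligand, p.receptor, p.source])


def load_pairs(path: str | Path, source: str | None = None) -> LRDatabase:
    """Load an L-R pair list from CSV with header columns ``ligand,receptor[,source]``.

    Rows with an empty gene field are rejected (and logged); duplicate keys
    after canonicalization collapse to the first occurrence. The resulting
    database carries a :class:`LoadReport` on its ``load_report`` attribute.

    Raises
    ------
    ValueError
        If the required ``ligand`` and ``receptor`` columns are missing.
    """
    path = Path(path)
    report = LoadReport()
    pairs: list[LRPair] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        cols = [c.strip().lower() for c in (reader.fieldnames or [])]
        if "ligand" not in cols or "receptor" not in cols:
            raise ValueError(
                f"{path}: expected header columns 'ligand,receptor', got {reader.fieldnames}"
            )
        colmap = {c.strip().lower(): c for c in (reader.fieldnames or [])}
        for row in reader:
            report.rows_read += 1
            lig = (row.get(colmap["ligand"]) or "").strip()
            rec = (row.get(colmap["receptor"]) or "").strip()
            if not lig or not rec:
                report.rows_rejected += 1
                log.warning("%s: row %d rejected (empty gene field)", path, report.rows_read)
                continue
            src = source
            if src is None:
                src = (row.get(colmap.get("source", ""), "") or "").strip() if "source" in colmap else ""
            pairs.append(LRPair(lig, rec, src or ""))
    db = LRDatabase(pairs)
    report.rows_kept = len(db)
    report.duplicates_removed = report.rows_read - report.rows_rejected - report.rows_kept
    db.load_report = report
    return db
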