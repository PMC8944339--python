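"""Hierarchical administrative-unit registry (region > province > municipality > barangay).

Modelled on the Philippine Standard Geographic Code: every unit has a level, a
canonical name, a parent at the level above (regions have none) and optional
name variants (alternate spellings, "<name> Province" style forms).  Lookups
are performed on normalized names; fuzzy lookup finds the unique canonical
name within the misspelling threshold, if any.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._text import damerau_levenshtein, edit_threshold, normalize_name

LEVELS = ("region", "province", "municipality", "barangay")


@dataclass(frozen=True)
class GazetteerEntry:
    level: str
    name: str
    parent: str | None
    variants: tuple[str, ...] = ()


@dataclass
class Gazetteer:
    """Registry of administrative units with parent links and variants."""

    entries: list[GazetteerEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_level: dict[str, dict[str, GazetteerEntry]] = {
            lv: {} for lv in LEVELS
        }
        # normalized name (canonical or variant) -> (level, canonical name)
        self._lookup: dict[str, tuple[str, str]] = {}
        for e in self.entries:
            self._register(e)

    def _register(self, e: GazetteerEntry) -> None:
        if e.level not in LEVELS:
            raise ValueError(f"unknown level {e.level!r}")
        level_names = self._by_level[e.level]
        if e.name in level_names:
            raise ValueError(f"duplicate {e.level} name {e.name!r}")
        if e.level != "region":
            parent_level = LEVELS[LEVELS.index(e.level) - 1]
            if e.parent not in self._by_level[parent_level]:
                raise ValueError(
                    f"{e.level} {e.name!r} has unknown parent {e.parent!r}"
                )
        level_names[e.name] = e
        for alias in (e.name, *e.variants):
            self._lookup[normalize_name(alias)] = (e.level, e.name)

    def add(self, e: GazetteerEntry) -> None:
        self.entries.append(e)
        self._register(e)

    def names(self, level: str) -> list[str]:
        return list(self._by_level[level])

    def entry(self, level: str, name: str) -> GazetteerEntry:
        return self._by_level[level][name]

    def parent(self, level: str, name: str) -> str | None:
        return self._by_level[level][name].parent

    def children(self, level: str, parent: str) -> list[str]:
        child_level = LEVELS[LEVELS.index(level) + 1]
        return [
            e.name
            for e in self._by_level[child_level].values()
            if e.parent == parent
        ]

    def region_of_province(self, province: str) -> str:
        parent = self.parent("province", province)
        assert parent is not None
        return parent

    # -- matching ---------------------------------------------------------

    def lookup(self, token_norm: str) -> tuple[str, str] | None:
        """Exact (canonical or variant) match of a normalized token."""
        return self._lookup.get(token_norm)

    def fuzzy_lookup(self, token_norm: str) -> tuple[str, str] | None:
        """Unique near-match of a token that matches nothing exactly.

        Returns (level, canonical name) when exactly one canonical unit lies
        within the edit-distance threshold of the token; None when no unit or
        more than one distinct unit qualifies.
        """
        hits: set[tuple[str, str]] = set()
        for alias_norm, ref in self._lookup.items():
            if damerau_levenshtein(token_norm, alias_norm) <= edit_threshold(
                alias_norm
            ):
                hits.add(ref)
                if len(hits) > 1:
                    return None
        if len(hits) == 1:
            return next(iter(hits))
        return None

    # -- serialization ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": [e.level for e in self.entries],
                "name": [e.name for e in self.entries],
                "parent": [e.parent or "" for e in self.entries],
                "variants": [";".join(e.variants) for e in self.entries],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Gazetteer":
        entries = []
        for row in frame.itertuples(index=False):
            variants = tuple(
                v for v in str(row.variants or "").split(";") if v
            )
            parent = str(row.parent) if str(row.parent or "") else None
            entries.append(
                GazetteerEntry(str(row.level), str(row.name), parent, variants)
            )
        return cls(entries)

    @classmethod
    def read_csv(cls, path) -> "Gazetteer":
        frame = pd.read_csv(path, keep_default_na=False)
        return cls.from_frame(frame)
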