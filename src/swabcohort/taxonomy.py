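"""Rank-prefixed lineage strings and rank aggregation labels.

Lineages follow the SILVA/QIIME-like dialect ``k__...;p__...;c__...;o__...;
f__...;g__...``. An empty value after a rank prefix means the rank is
unassigned; such taxa are labeled ``Unclassified <nearest classified
ancestor>`` when aggregating at that rank, so unclassified bins stay
distinct per parent clade.
"""

from __future__ import annotations

from dataclasses import dataclass

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__")

UNCLASSIFIED = "Unclassified"


class LineageError(ValueError):
    """Raised for malformed lineage strings."""


@dataclass(frozen=True)
class Lineage:
    """A six-rank taxonomic lineage (kingdom through genus).

    Unassigned ranks are stored as empty strings. Family and genus slots
    must be present in the string (they may be empty = unassigned), because
    downstream domination calling aggregates at those two ranks.
    """

    kingdom: str = ""
    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""

    @property
    def names(self) -> tuple[str, ...]:
        return (self.kingdom, self.phylum, self.class_, self.order,
                self.family, self.genus)

    @classmethod
    def parse(cls, text: str) -> "Lineage":
        """Parse a rank-prefixed, semicolon-separated lineage string."""
        parts = [p.strip() for p in text.strip().rstrip(";").split(";")]
        if len(parts) != len(RANK_PREFIXES):
            raise LineageError(
                f"expected {len(RANK_PREFIXES)} rank fields, got "
                f"{len(parts)}: {text!r}")
        names = []
        for part, prefix in zip(parts, RANK_PREFIXES):
            if not part.startswith(prefix):
                raise LineageError(
                    f"rank field {part!r} lacks prefix {prefix!r} in {text!r}")
            names.append(part[len(prefix):])
        return cls(*names)

    def format(self) -> str:
        """Serialize back to the rank-prefixed dialect (inverse of parse)."""
        return ";".join(p + n for p, n in zip(RANK_PREFIXES, self.names))

    def label_at(self, rank: str) -> str:
        """Aggregation label at ``rank`` (one of RANKS).

        If the rank is unassigned the label is ``Unclassified <parent>``
        using the nearest classified ancestor, or plain ``Unclassified``
        when no rank is classified at all.
        """
        try:
            idx = RANKS.index(rank)
        except ValueError:
            raise LineageError(f"unknown rank {rank!r}; expected one of {RANKS}")
        name = self.names[idx]
        if name:
            return name
        for ancestor in reversed(self.names[:idx]):
            if ancestor:
                return f"{UNCLASSIFIED} {ancestor}"
        return UNCLASSIFIED

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.format()
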