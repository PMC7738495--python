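"""Binary protein-family profiles and their elementary set statistics.

A genome or metagenome is represented here purely by the set of protein-family
identifiers (e.g. Pfam accessions) it contains — a presence/absence view of its
functional potential.  Everything downstream (consortium selection, cohort
aggregation, group-separation testing) consumes these profiles through the small
set algebra defined in this module: Jaccard similarity, profile unions, and the
functional coverage of a metagenome by a candidate consortium.

The on-disk format is a strict tab-separated matrix: a header row starting with
the literal cell ``id`` followed by family identifiers, then one row per entity
with 0/1 cells.  The dialect is deliberately rigid (tabs, UTF-8, no quoting,
trailing newline) so that ``write_profile_matrix(read_profile_matrix(f))``
reproduces ``f`` byte for byte.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "FamilyProfile",
    "ProfileMatrix",
    "ReferencePanel",
    "ProfileFormatError",
    "UnknownEntityError",
    "read_profile_matrix",
    "write_profile_matrix",
    "jaccard_index",
    "union_profile",
    "functional_coverage",
]


class ProfileFormatError(ValueError):
    """Raised when a profile-matrix file violates the fixed TSV dialect."""


class UnknownEntityError(KeyError):
    """Raised when a genome or sample identifier is not known to a container."""


@dataclass(frozen=True)
class FamilyProfile:
    """The set of protein families present in one entity (genome or metagenome)."""

    entity_id: str
    families: frozenset[str]

    def __post_init__(self) -> None:
        if not self.entity_id:
            raise ValueError("entity_id must be non-empty")
        if not isinstance(self.families, frozenset):
            object.__setattr__(self, "families", frozenset(self.families))

    def __len__(self) -> int:
        return len(self.families)

    def __contains__(self, family: str) -> bool:
        return family in self.families


@dataclass(frozen=True)
class ProfileMatrix:
    """An entities × families presence/absence matrix with stable ordering.

    Rows are entities (genomes or metagenome samples), columns are family
    identifiers; entries are exactly 0 or 1.  Row and column order is preserved
    from the source so that file round trips are the identity.
    """

    entity_ids: tuple[str, ...]
    family_ids: tuple[str, ...]
    presence: np.ndarray  # shape (n_entities, n_families), dtype uint8

    def __post_init__(self) -> None:
        object.__setattr__(self, "entity_ids", tuple(self.entity_ids))
        object.__setattr__(self, "family_ids", tuple(self.family_ids))
        presence = np.asarray(self.presence, dtype=np.uint8)
        object.__setattr__(self, "presence", presence)
        if len(set(self.entity_ids)) != len(self.entity_ids):
            raise ValueError("duplicate entity identifiers")
        if len(set(self.family_ids)) != len(self.family_ids):
            raise ValueError("duplicate family identifiers")
        if presence.shape != (len(self.entity_ids), len(self.family_ids)):
            raise ValueError(
                f"presence shape {presence.shape} does not match "
                f"{len(self.entity_ids)} entities × {len(self.family_ids)} families"
            )
        if presence.size and not np.isin(presence, (0, 1)).all():
            raise ValueError("presence entries must be exactly 0 or 1")

    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)

    @property
    def n_families(self) -> int:
        return len(self.family_ids)

    def profile(self, entity_id: str) -> FamilyProfile:
        """Extract one row as a :class:`FamilyProfile`."""
        try:
            i = self.entity_ids.index(entity_id)
        except ValueError:
            raise UnknownEntityError(entity_id) from None
        cols = np.flatnonzero(self.presence[i])
        return FamilyProfile(entity_id, frozenset(self.family_ids[j] for j in cols))

    def profiles(self) -> list[FamilyProfile]:
        """All rows as profiles, in matrix order."""
        fam = np.asarray(self.family_ids, dtype=object)
        return [
            FamilyProfile(eid, frozenset(fam[self.presence[i].astype(bool)]))
            for i, eid in enumerate(self.entity_ids)
        ]

    @classmethod
    def from_profiles(
        cls,
        profiles: Sequence[FamilyProfile],
        family_ids: Sequence[str] | None = None,
    ) -> "ProfileMatrix":
        """Build a matrix from profiles.

        ``family_ids`` fixes the column order; by default the union of all
        families, sorted, is used.
        """
        if family_ids is None:
            universe: set[str] = set()
            for p in profiles:
                universe |= p.families
            family_ids = sorted(universe)
        col = {f: j for j, f in enumerate(family_ids)}
        presence = np.zeros((len(profiles), len(family_ids)), dtype=np.uint8)
        for i, p in enumerate(profiles):
            for f in p.families:
                presence[i, col[f]] = 1
        return cls(tuple(p.entity_id for p in profiles), tuple(family_ids), presence)


@dataclass(frozen=True)
class ReferencePanel:
    """A named collection of genome profiles used as the selection database."""

    genomes: Mapping[str, FamilyProfile]
    family_universe: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        genomes = dict(self.genomes)
        object.__setattr__(self, "genomes", genomes)
        if not genomes:
            raise ValueError("a reference panel needs at least one genome")
        universe = frozenset(self.family_universe) or frozenset().union(
            *(p.families for p in genomes.values())
        )
        object.__setattr__(self, "family_universe", universe)
        for gid, prof in genomes.items():
            if not prof.families <= universe:
                raise ValueError(f"genome {gid!r} has families outside the panel universe")

    def __len__(self) -> int:
        return len(self.genomes)

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self.genomes

    def __getitem__(self, genome_id: str) -> FamilyProfile:
        try:
            return self.genomes[genome_id]
        except KeyError:
            raise UnknownEntityError(genome_id) from None

    @property
    def genome_ids(self) -> tuple[str, ...]:
        return tuple(self.genomes)

    @classmethod
    def from_matrix(cls, matrix: ProfileMatrix) -> "ReferencePanel":
        return cls(
            {p.entity_id: p for p in matrix.profiles()},
            frozenset(matrix.family_ids),
        )


# ---------------------------------------------------------------------------
# File I/O — strict TSV dialect
# ---------------------------------------------------------------------------

def read_profile_matrix(path: str | Path) -> ProfileMatrix:
    """Read a presence/absence matrix from the strict TSV dialect.

    The header must start with the literal cell ``id``; every data cell must be
    the single character ``0`` or ``1``.  Violations raise
    :class:`ProfileFormatError` naming the offending row and column.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    if not lines:
        raise ProfileFormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[0] != "id":
        raise ProfileFormatError(f"{path}: first header cell must be 'id', got {header[0]!r}")
    family_ids = header[1:]
    entity_ids: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ProfileFormatError(
                f"{path}:{lineno}: expected {len(header)} cells, got {len(cells)}"
            )
        entity_ids.append(cells[0])
        row = []
        for j, cell in enumerate(cells[1:]):
            if cell not in ("0", "1"):
                raise ProfileFormatError(
                    f"{path}:{lineno}: entity {cells[0]!r}, family {family_ids[j]!r}: "
                    f"cell must be 0 or 1, got {cell!r}"
                )
            row.append(int(cell))
        rows.append(row)
    try:
        return ProfileMatrix(
            tuple(entity_ids),
            tuple(family_ids),
            np.array(rows, dtype=np.uint8).reshape(len(entity_ids), len(family_ids)),
        )
    except ValueError as exc:
        raise ProfileFormatError(f"{path}: {exc}") from exc


def write_profile_matrix(matrix: ProfileMatrix, path: str | Path) -> None:
    """Write the matrix in the strict TSV dialect (inverse of the reader)."""
    path = Path(path)
    out = ["\t".join(("id", *matrix.family_ids))]
    for i, eid in enumerate(matrix.entity_ids):
        out.append("\t".join((eid, *(str(int(v)) for v in matrix.presence[i]))))
    path.write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Set statistics
# ---------------------------------------------------------------------------

def jaccard_index(a: FamilyProfile, b: FamilyProfile) -> float:
    """|a ∩ b| / |a ∪ b|.  Two empty profiles are defined as identical (1.0)."""
    union = len(a.families | b.families)
    if union == 0:
        return 1.0
    return len(a.families & b.families) / union


def union_profile(
    genome_ids: Sequence[str],
    panel: ReferencePanel,
    joiner: str = "+",
) -> FamilyProfile:
    """Pooled profile of a consortium: the set union of its members' families.

    The entity id is the deterministic ``joiner``-join of the member ids in the
    order given; the family set itself is order-invariant.
    """
    families: set[str] = set()
    for gid in genome_ids:
        families |= panel[gid].families
    entity_id = joiner.join(genome_ids) if genome_ids else "(empty)"
    return FamilyProfile(entity_id, frozenset(families))


def functional_coverage(meta: FamilyProfile, consortium: FamilyProfile) -> float:
    """Fraction of the metagenome's families contained in the consortium.

    |meta ∩ consortium| / |meta|; undefined (error) for an empty metagenome.
    """
    if not meta.families:
        raise ValueError("functional coverage is undefined for an empty metagenome profile")
    return len(meta.families & consortium.families) / len(meta.families)
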