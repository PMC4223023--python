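"""Domain types shared by all syntrefine modules.

Coordinate convention
---------------------
All in-memory coordinates are 0-based half-open (``start`` inclusive,
``end`` exclusive), the convention of BED and of all internal arithmetic.
The tabular gene/region/ortholog formats on disk are 1-based inclusive
(ENSEMBL convention); :mod:`syntrefine.io` converts at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class DataWarning(UserWarning):
    """Non-fatal data issue (duplicate rows, degenerate vectors, ...)."""


@dataclass(frozen=True)
class Gene:
    """One annotated gene in one species.

    ``start``/``end`` are 0-based half-open base-pair coordinates on
    ``chromosome``; ``species`` tags which genome ("A" or "B") the gene
    belongs to and ``strand`` is "+" or "-".
    """

    id: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.id!r}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.id!r}: bad strand {self.strand!r}")
        if self.species not in ("A", "B"):
            raise ValidationError(f"gene {self.id!r}: species must be 'A' or 'B'")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class SyntenicRegionPair:
    """A pre-computed syntenic region: one interval in each species.

    ``orientation`` annotates whether the two intervals are aligned in the
    same or opposite reading direction; ``None`` is treated as "same".
    """

    region_id: str
    chrom_A: str
    start_A: int
    end_A: int
    chrom_B: str
    start_B: int
    end_B: int
    orientation: Optional[str] = None  # "same" | "opposite" | None

    def __post_init__(self) -> None:
        for sp, s, e in (("A", self.start_A, self.end_A), ("B", self.start_B, self.end_B)):
            if s >= e:
                raise ValidationError(
                    f"region {self.region_id!r}: start >= end in species {sp}"
                )
        if self.orientation not in (None, "same", "opposite"):
            raise ValidationError(
                f"region {self.region_id!r}: bad orientation {self.orientation!r}"
            )

    def interval(self, species: str) -> tuple[str, int, int]:
        if species == "A":
            return (self.chrom_A, self.start_A, self.end_A)
        return (self.chrom_B, self.start_B, self.end_B)


@dataclass(frozen=True)
class OrthologyLink:
    """A pairwise orthology relationship with percent identities in both
    directions (A-vs-B and B-vs-A)."""

    gene_A: str
    gene_B: str
    identity_AB: float
    identity_BA: float

    def __post_init__(self) -> None:
        for name, v in (("identity_AB", self.identity_AB), ("identity_BA", self.identity_BA)):
            if not (0.0 <= v <= 100.0):
                raise ValidationError(
                    f"link {self.gene_A}-{self.gene_B}: {name}={v} outside [0, 100]"
                )

    @property
    def combined_identity(self) -> float:
        """Mean of the two directional identities; the ranking score used
        whenever a single 'sequence identity' is needed."""
        return 0.5 * (self.identity_AB + self.identity_BA)


#: Ortholog-group classes (relationship taxonomy for a gene's group within
#: one syntenic region pair).
GROUP_CLASSES = (
    "no_ortholog",
    "one_internal",
    "many_internal",
    "one_external",
    "many_external",
    "other",
)


@dataclass
class OrthologGroup:
    """Connected component of the bipartite orthology-link graph within a
    syntenic region.

    ``genes_A``/``genes_B`` are gene ids in genomic order; ``rank_A``/
    ``rank_B`` give each gene's order index among *all* genes of the region
    in its species (used for deterministic tie-breaking).
    """

    genes_A: tuple[str, ...]
    genes_B: tuple[str, ...]
    links: tuple[OrthologyLink, ...]
    cls: str = "other"
    rank_A: dict = field(default_factory=dict)
    rank_B: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cls not in GROUP_CLASSES:
            raise ValidationError(f"bad ortholog-group class {self.cls!r}")
        sa, sb = set(self.genes_A), set(self.genes_B)
        for ln in self.links:
            if ln.gene_A not in sa or ln.gene_B not in sb:
                raise ValidationError(
                    f"link {ln.gene_A}-{ln.gene_B} has an endpoint outside the group"
                )

    @property
    def n(self) -> int:
        return len(self.genes_A)

    @property
    def m(self) -> int:
        return len(self.genes_B)


PROVENANCES = ("direct", "one_to_many_reduced", "order_split", "external")


@dataclass(frozen=True)
class ResolvedPair:
    """A syntenic one-to-one ortholog pair surviving pre-processing."""

    gene_A: str
    gene_B: str
    provenance: str = "direct"

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValidationError(f"bad provenance {self.provenance!r}")


REGION_TYPES = ("original", "internal", "external")
REARRANGEMENTS = ("none", "translocation", "inversion")


@dataclass(frozen=True)
class RefinedRegion:
    """An output syntenic region: the collinear backbone of an input region
    ("original"), a micro-rearranged block within it ("internal"), or a
    cross-region translocation ("external")."""

    region_id: str
    parent_region_id: Optional[str]
    type: str
    rearrangement: str
    chrom_A: str
    start_A: int
    end_A: int
    chrom_B: str
    start_B: int
    end_B: int
    member_pairs: tuple[ResolvedPair, ...] = ()

    def __post_init__(self) -> None:
        if self.type not in REGION_TYPES:
            raise ValidationError(f"bad region type {self.type!r}")
        if self.rearrangement not in REARRANGEMENTS:
            raise ValidationError(f"bad rearrangement {self.rearrangement!r}")
        if self.type == "internal" and self.parent_region_id is None:
            raise ValidationError(
                f"internal region {self.region_id!r} must have a parent"
            )


@dataclass
class FeatureTrack:
    """A positional feature track (BED semantics, 0-based half-open).

    ``elements`` is a list of ``(chromosome, start, end, weight)`` tuples;
    ``weight`` is ``None`` for every element of an unweighted track and a
    float for every element of a weighted one (``has_weights``).
    """

    elements: list
    has_weights: bool

    def __post_init__(self) -> None:
        for chrom, start, end, weight in self.elements:
            if start >= end:
                raise ValidationError(
                    f"track element {chrom}:{start}-{end}: start must be < end"
                )
            if self.has_weights and weight is None:
                raise ValidationError("weighted track contains an unweighted element")
            if not self.has_weights and weight is not None:
                raise ValidationError("unweighted track contains a weighted element")

    def __len__(self) -> int:
        return len(self.elements)

    def by_chromosome(self) -> dict:
        out: dict = {}
        for el in self.elements:
            out.setdefault(el[0], []).append(el)
        return out


@dataclass
class GenomePairDataset:
    """The full input bundle for one genome-pair analysis."""

    genes_A: list
    genes_B: list
    regions: list
    links: list

    def swapped(self) -> "GenomePairDataset":
        """Return the dataset with the roles of species A and B exchanged
        (reference-genome swap)."""
        return GenomePairDataset(
            genes_A=[replace(g, species="A") for g in self.genes_B],
            genes_B=[replace(g, species="B") for g in self.genes_A],
            regions=[
                SyntenicRegionPair(
                    region_id=r.region_id,
                    chrom_A=r.chrom_B,
                    start_A=r.start_B,
                    end_A=r.end_B,
                    chrom_B=r.chrom_A,
                    start_B=r.start_A,
                    end_B=r.end_A,
                    orientation=r.orientation,
                )
                for r in self.regions
            ],
            links=[
                OrthologyLink(
                    gene_A=ln.gene_B,
                    gene_B=ln.gene_A,
                    identity_AB=ln.identity_BA,
                    identity_BA=ln.identity_AB,
                )
                for ln in self.links
            ],
        )


def region_sort_key(region_id: str) -> tuple:
    """Natural sort key for region ids like "7", "7_2", "r12_3"."""
    parts = region_id.split("_")
    key = []
    for p in parts:
        key.append((0, int(p), "") if p.isdigit() else (1, 0, p))
    return tuple(key)
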