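"""Readers and writers for the tabular genome-pair inputs, BED tracks and
the two refinement output files.

Tabular dialects: tab-separated, one header row, lines starting with ``#``
ignored. Gene/region/ortholog tables use 1-based inclusive coordinates on
disk; BED is 0-based half-open. Everything is converted to the in-memory
0-based half-open convention on load.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .model import (
    DataWarning,
    FeatureTrack,
    Gene,
    OrthologyLink,
    RefinedRegion,
    ResolvedPair,
    SyntenicRegionPair,
    ValidationError,
    region_sort_key,
)


class ParseError(ValueError):
    """Malformed input row; the message names the offending file and line."""


def _rows(path) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for data rows of a TSV file,
    skipping blank lines and '#' comments. The first data row is the header
    and is yielded too."""
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def _header(path, it, expected: Sequence[str]) -> None:
    try:
        lineno, fields = next(it)
    except StopIteration:
        raise ParseError(f"{path}: empty file, expected header {list(expected)}")
    if fields != list(expected):
        raise ParseError(
            f"{path}:{lineno}: bad header {fields!r}, expected {list(expected)}"
        )


def _int(path, lineno, name, value) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: field {name!r} is not an integer: {value!r}")


def _float(path, lineno, name, value) -> float:
    try:
        return float(value)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: field {name!r} is not numeric: {value!r}")


# ---------------------------------------------------------------------------
# gene tables
# ---------------------------------------------------------------------------

GENE_COLUMNS = ("gene_id", "chromosome", "start", "end", "strand")


def load_gene_table(path, species: str) -> list[Gene]:
    """Load a per-species gene table (1-based inclusive coordinates).

    Duplicate gene ids and start > end are rejected.
    """
    it = _rows(path)
    _header(path, it, GENE_COLUMNS)
    genes: list[Gene] = []
    seen: set[str] = set()
    for lineno, fields in it:
        if len(fields) != len(GENE_COLUMNS):
            raise ParseError(
                f"{path}:{lineno}: expected {len(GENE_COLUMNS)} fields, got {len(fields)}"
            )
        gid, chrom, start, end, strand = fields
        if gid in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate gene id {gid!r}")
        seen.add(gid)
        s1 = _int(path, lineno, "start", start)
        e1 = _int(path, lineno, "end", end)
        if s1 > e1:
            raise ValidationError(
                f"{path}:{lineno}: gene {gid!r} has start ({s1}) > end ({e1})"
            )
        genes.append(
            Gene(id=gid, species=species, chromosome=chrom, start=s1 - 1, end=e1, strand=strand)
        )
    return genes


def write_gene_table(genes: Sequence[Gene], path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(GENE_COLUMNS) + "\n")
        for g in genes:
            fh.write(f"{g.id}\t{g.chromosome}\t{g.start + 1}\t{g.end}\t{g.strand}\n")


# ---------------------------------------------------------------------------
# syntenic region tables
# ---------------------------------------------------------------------------

REGION_COLUMNS = ("region_id", "chrom_A", "start_A", "end_A", "chrom_B", "start_B", "end_B")


def load_region_table(path) -> list[SyntenicRegionPair]:
    """Load the syntenic-region pair table.

    Within one species, regions may not overlap on the same chromosome;
    an overlap raises :class:`ValidationError` naming both regions.
    """
    it = _rows(path)
    _header(path, it, REGION_COLUMNS)
    regions: list[SyntenicRegionPair] = []
    seen: set[str] = set()
    for lineno, fields in it:
        if len(fields) != len(REGION_COLUMNS):
            raise ParseError(
                f"{path}:{lineno}: expected {len(REGION_COLUMNS)} fields, got {len(fields)}"
            )
        rid, ca, sa, ea, cb, sb, eb = fields
        if rid in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate region id {rid!r}")
        seen.add(rid)
        regions.append(
            SyntenicRegionPair(
                region_id=rid,
                chrom_A=ca,
                start_A=_int(path, lineno, "start_A", sa) - 1,
                end_A=_int(path, lineno, "end_A", ea),
                chrom_B=cb,
                start_B=_int(path, lineno, "start_B", sb) - 1,
                end_B=_int(path, lineno, "end_B", eb),
            )
        )
    validate_region_disjointness(regions)
    return regions


def validate_region_disjointness(regions: Sequence[SyntenicRegionPair]) -> None:
    """Reject region sets where two regions overlap on the same chromosome
    of the same species."""
    for species in ("A", "B"):
        by_chrom: dict = {}
        for r in regions:
            chrom, start, end = r.interval(species)
            by_chrom.setdefault(chrom, []).append((start, end, r.region_id))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1, id1), (s2, e2, id2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValidationError(
                        f"regions {id1!r} and {id2!r} overlap on species {species} "
                        f"chromosome {chrom}"
                    )


def write_region_table(
    regions: Sequence[SyntenicRegionPair], path, header_lines: Sequence[str] = ()
) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(REGION_COLUMNS) + "\n")
        for r in regions:
            fh.write(
                f"{r.region_id}\t{r.chrom_A}\t{r.start_A + 1}\t{r.end_A}\t"
                f"{r.chrom_B}\t{r.start_B + 1}\t{r.end_B}\n"
            )


# ---------------------------------------------------------------------------
# ortholog tables
# ---------------------------------------------------------------------------

ORTHOLOG_COLUMNS = ("gene_A", "gene_B", "identity_AB", "identity_BA")


def load_ortholog_table(
    path,
    genes_A: Optional[Sequence[Gene]] = None,
    genes_B: Optional[Sequence[Gene]] = None,
) -> list[OrthologyLink]:
    """Load the pairwise ortholog table.

    Identities outside [0, 100] are an error. Duplicate (gene_A, gene_B)
    rows are collapsed keeping the maximum identity per direction, with a
    :class:`DataWarning`. If gene tables are supplied, link endpoints are
    cross-checked against them.
    """
    it = _rows(path)
    _header(path, it, ORTHOLOG_COLUMNS)
    merged: dict[tuple[str, str], tuple[float, float]] = {}
    order: list[tuple[str, str]] = []
    n_dup = 0
    for lineno, fields in it:
        if len(fields) != len(ORTHOLOG_COLUMNS):
            raise ParseError(
                f"{path}:{lineno}: expected {len(ORTHOLOG_COLUMNS)} fields, got {len(fields)}"
            )
        ga, gb, iab, iba = fields
        vab = _float(path, lineno, "identity_AB", iab)
        vba = _float(path, lineno, "identity_BA", iba)
        for name, v in (("identity_AB", vab), ("identity_BA", vba)):
            if not (0.0 <= v <= 100.0):
                raise ValidationError(
                    f"{path}:{lineno}: {name}={v} outside [0, 100]"
                )
        key = (ga, gb)
        if key in merged:
            n_dup += 1
            old = merged[key]
            merged[key] = (max(old[0], vab), max(old[1], vba))
        else:
            merged[key] = (vab, vba)
            order.append(key)
    if n_dup:
        warnings.warn(
            f"{path}: collapsed {n_dup} duplicate ortholog row(s), keeping the "
            "maximum identity per direction",
            DataWarning,
            stacklevel=2,
        )
    if genes_A is not None or genes_B is not None:
        known_A = {g.id for g in genes_A} if genes_A is not None else None
        known_B = {g.id for g in genes_B} if genes_B is not None else None
        for ga, gb in order:
            if known_A is not None and ga not in known_A:
                raise ValidationError(f"{path}: unknown species-A gene id {ga!r}")
            if known_B is not None and gb not in known_B:
                raise ValidationError(f"{path}: unknown species-B gene id {gb!r}")
    return [
        OrthologyLink(gene_A=ga, gene_B=gb, identity_AB=merged[(ga, gb)][0],
                      identity_BA=merged[(ga, gb)][1])
        for ga, gb in order
    ]


def write_ortholog_table(
    links: Sequence[OrthologyLink], path, header_lines: Sequence[str] = ()
) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(ORTHOLOG_COLUMNS) + "\n")
        for ln in links:
            fh.write(f"{ln.gene_A}\t{ln.gene_B}\t{ln.identity_AB:g}\t{ln.identity_BA:g}\n")


# ---------------------------------------------------------------------------
# region assignment
# ---------------------------------------------------------------------------


@dataclass
class RegionAssignment:
    """Result of assigning genes to syntenic regions.

    ``by_region`` maps region_id to (genes_A, genes_B), each sorted by start
    coordinate (ties: end, then id). ``unassigned`` lists genes whose
    midpoint falls in no region ("syntenic-block-free" genes).
    """

    by_region: dict
    unassigned: list

    def order_index(self, region_id: str, species: str) -> dict:
        """Map gene id -> 0-based genomic order index within the region."""
        genes = self.by_region[region_id][0 if species == "A" else 1]
        return {g.id: i for i, g in enumerate(genes)}


def _gene_order_key(g: Gene) -> tuple:
    return (g.start, g.end, g.id)


def assign_genes_to_regions(
    genes: Sequence[Gene], regions: Sequence[SyntenicRegionPair]
) -> RegionAssignment:
    """Assign each gene to the region whose interval (matching species and
    chromosome) contains the gene's midpoint.

    Regions are non-overlapping within a species, so each gene lands in at
    most one region; genes contained in no region are returned unassigned.
    """
    index: dict = {}
    for species in ("A", "B"):
        by_chrom: dict = {}
        for r in regions:
            chrom, start, end = r.interval(species)
            by_chrom.setdefault(chrom, []).append((start, end, r.region_id))
        for chrom in by_chrom:
            by_chrom[chrom].sort()
        index[species] = by_chrom

    by_region = {r.region_id: ([], []) for r in regions}
    unassigned: list[Gene] = []
    for g in genes:
        ivs = index.get(g.species, {}).get(g.chromosome, [])
        mid = g.midpoint
        pos = bisect.bisect_right(ivs, (mid, float("inf"), "")) - 1
        if pos >= 0 and ivs[pos][0] <= mid < ivs[pos][1]:
            by_region[ivs[pos][2]][0 if g.species == "A" else 1].append(g)
        else:
            unassigned.append(g)
    for rid in by_region:
        by_region[rid][0].sort(key=_gene_order_key)
        by_region[rid][1].sort(key=_gene_order_key)
    return RegionAssignment(by_region=by_region, unassigned=unassigned)


# ---------------------------------------------------------------------------
# BED tracks and chromosome sizes
# ---------------------------------------------------------------------------


def load_bed(path) -> FeatureTrack:
    """Load a BED3 or BED4-with-numeric-score file (0-based half-open).

    The track is weighted iff column 4 is present and numeric on every row;
    mixing weighted and unweighted rows is an error.
    """
    elements = []
    has_weights: Optional[bool] = None
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (3, 4):
                raise ParseError(
                    f"{path}:{lineno}: expected 3 or 4 BED fields, got {len(fields)}"
                )
            chrom = fields[0]
            start = _int(path, lineno, "start", fields[1])
            end = _int(path, lineno, "end", fields[2])
            if start >= end:
                raise ValidationError(
                    f"{path}:{lineno}: start ({start}) must be < end ({end})"
                )
            weight = _float(path, lineno, "weight", fields[3]) if len(fields) == 4 else None
            row_weighted = weight is not None
            if has_weights is None:
                has_weights = row_weighted
            elif has_weights != row_weighted:
                raise ValidationError(
                    f"{path}:{lineno}: mixed weighted and unweighted BED rows"
                )
            elements.append((chrom, start, end, weight))
    return FeatureTrack(elements=elements, has_weights=bool(has_weights))


def write_bed(track: FeatureTrack, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for chrom, start, end, weight in track.elements:
            if track.has_weights:
                fh.write(f"{chrom}\t{start}\t{end}\t{weight:g}\n")
            else:
                fh.write(f"{chrom}\t{start}\t{end}\n")


def load_chrom_sizes(path) -> dict:
    """Two-column TSV (name, length) -> dict."""
    sizes: dict = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
            sizes[fields[0]] = _int(path, lineno, "length", fields[1])
    return sizes


def write_chrom_sizes(sizes: dict, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for name in sorted(sizes):
            fh.write(f"{name}\t{sizes[name]}\n")


# ---------------------------------------------------------------------------
# refinement output files
# ---------------------------------------------------------------------------

REFINED_COLUMNS = (
    "region_id",
    "parent_region_id",
    "type",
    "rearrangement",
    "chrom_A",
    "start_A",
    "end_A",
    "chrom_B",
    "start_B",
    "end_B",
)

ORTHOLOG_MAP_COLUMNS = ("region_id", "gene_A", "gene_B", "provenance")


def _refined_sorted(regions: Sequence[RefinedRegion]) -> list[RefinedRegion]:
    return sorted(regions, key=lambda r: (region_sort_key(r.region_id), r.start_A))


def write_refined_regions(
    regions: Sequence[RefinedRegion], path, header_lines: Sequence[str] = ()
) -> None:
    """Output file (a): coordinates of all refined syntenic regions
    (1-based inclusive on disk), sorted by region id then coordinate."""
    with open(path, "wt", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(REFINED_COLUMNS) + "\n")
        for r in _refined_sorted(regions):
            parent = r.parent_region_id if r.parent_region_id is not None else ""
            fh.write(
                f"{r.region_id}\t{parent}\t{r.type}\t{r.rearrangement}\t"
                f"{r.chrom_A}\t{r.start_A + 1}\t{r.end_A}\t"
                f"{r.chrom_B}\t{r.start_B + 1}\t{r.end_B}\n"
            )


def write_ortholog_map(
    regions: Sequence[RefinedRegion], path, header_lines: Sequence[str] = ()
) -> None:
    """Output file (b): syntenic orthologs per refined region, in region
    order then member order (member pairs are kept in A-coordinate order)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(ORTHOLOG_MAP_COLUMNS) + "\n")
        for r in _refined_sorted(regions):
            for p in r.member_pairs:
                fh.write(f"{r.region_id}\t{p.gene_A}\t{p.gene_B}\t{p.provenance}\n")


def read_refined_regions(regions_path, orthologs_path=None) -> list[RefinedRegion]:
    """Read output files (a) and optionally (b) back into RefinedRegions."""
    pairs_by_region: dict[str, list[ResolvedPair]] = {}
    if orthologs_path is not None:
        it = _rows(orthologs_path)
        _header(orthologs_path, it, ORTHOLOG_MAP_COLUMNS)
        for lineno, fields in it:
            if len(fields) != len(ORTHOLOG_MAP_COLUMNS):
                raise ParseError(
                    f"{orthologs_path}:{lineno}: expected "
                    f"{len(ORTHOLOG_MAP_COLUMNS)} fields, got {len(fields)}"
                )
            rid, ga, gb, prov = fields
            pairs_by_region.setdefault(rid, []).append(
                ResolvedPair(gene_A=ga, gene_B=gb, provenance=prov)
            )

    it = _rows(regions_path)
    _header(regions_path, it, REFINED_COLUMNS)
    out: list[RefinedRegion] = []
    for lineno, fields in it:
        if len(fields) != len(REFINED_COLUMNS):
            raise ParseError(
                f"{regions_path}:{lineno}: expected {len(REFINED_COLUMNS)} fields, "
                f"got {len(fields)}"
            )
        rid, parent, rtype, rearr, ca, sa, ea, cb, sb, eb = fields
        out.append(
            RefinedRegion(
                region_id=rid,
                parent_region_id=parent or None,
                type=rtype,
                rearrangement=rearr,
                chrom_A=ca,
                start_A=_int(regions_path, lineno, "start_A", sa) - 1,
                end_A=_int(regions_path, lineno, "end_A", ea),
                chrom_B=cb,
                start_B=_int(regions_path, lineno, "start_B", sb) - 1,
                end_B=_int(regions_path, lineno, "end_B", eb),
                member_pairs=tuple(pairs_by_region.get(rid, ())),
            )
        )
    return out
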