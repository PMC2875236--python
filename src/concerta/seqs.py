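"""Gene records with region annotations in biologist-style gene coordinates.

Coordinates are 1-based and inclusive; position 1 is the first base of the
start codon, upstream positions are negative and **position 0 does not
exist** (as in GenBank-style promoter annotation, e.g. a promoter spanning
-805..-1 is 805 bp long).  A :class:`GeneRecord` stores the gene coordinate
of the first base of its sequence (``start_coord``), so converting between
gene coordinates and string offsets is an exact bijection.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import translate

logger = logging.getLogger(__name__)

VALID_CHARS = set("ACGTN-")
REGION_NAMES = ("promoter", "exon1", "exon2", "exon3", "intron1", "intron2", "three_prime", "cds")
_EXON_RE = re.compile(r"^exon(\d+)$")


class RegionError(ValueError):
    pass


def span_length(start: int, end: int) -> int:
    """Length of an inclusive span in no-zero coordinates."""
    if start == 0 or end == 0:
        raise RegionError("coordinate 0 does not exist")
    if start > end:
        raise RegionError(f"start {start} > end {end}")
    return end - start + 1 - (1 if start < 0 < end else 0)


@dataclass(frozen=True)
class Region:
    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        span_length(self.start, self.end)  # validates

    @property
    def length(self) -> int:
        return span_length(self.start, self.end)


@dataclass
class GeneRecord:
    """One gene's sequence plus named region spans.

    ``start_coord`` is the gene coordinate of ``sequence[0]`` (negative when
    the stored sequence includes upstream promoter, never 0).
    """

    id: str
    sequence: str
    species: str = ""
    regions: list[Region] = field(default_factory=list)
    start_coord: int = 1

    def __post_init__(self) -> None:
        if self.start_coord == 0:
            raise RegionError("start_coord 0 does not exist")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_CHARS
        if bad:
            logger.warning("record %s: mapping unknown characters %s to N", self.id, sorted(bad))
            self.sequence = "".join(c if c in VALID_CHARS else "N" for c in self.sequence)
        if not self.species and "|" in self.id:
            self.species = self.id.split("|", 1)[0]

    # -- coordinate bijection ------------------------------------------------
    def offset(self, coord: int) -> int:
        """Gene coordinate -> 0-based string offset."""
        if coord == 0:
            raise RegionError("coordinate 0 does not exist")
        off = coord - self.start_coord
        if self.start_coord < 0 < coord:
            off -= 1
        if not 0 <= off < len(self.sequence):
            raise RegionError(f"coordinate {coord} outside sequence of {self.id}")
        return off

    def coord(self, offset: int) -> int:
        """0-based string offset -> gene coordinate."""
        if not 0 <= offset < len(self.sequence):
            raise RegionError(f"offset {offset} outside sequence of {self.id}")
        c = self.start_coord + offset
        if self.start_coord < 0 <= c:
            c += 1
        return c

    @property
    def end_coord(self) -> int:
        return self.coord(len(self.sequence) - 1)

    # -- regions -------------------------------------------------------------
    def region(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise RegionError(f"record {self.id} has no region {name!r}")

    def has_region(self, name: str) -> bool:
        return any(r.name == name for r in self.regions)

    def region_seq(self, name_or_region: str | Region) -> str:
        r = self.region(name_or_region) if isinstance(name_or_region, str) else name_or_region
        return self.sequence[self.offset(r.start) : self.offset(r.end) + 1]

    def exons(self) -> list[Region]:
        ex = [r for r in self.regions if _EXON_RE.match(r.name)]
        return sorted(ex, key=lambda r: int(_EXON_RE.match(r.name).group(1)))

    def cds(self) -> str:
        """Concatenation of the exon spans (or the 'cds' region if annotated)."""
        if self.has_region("cds"):
            return self.region_seq("cds")
        ex = self.exons()
        if not ex:
            raise RegionError(f"record {self.id} has no exon or cds annotation")
        return "".join(self.region_seq(r) for r in ex)

    def cds_coords(self) -> list[int]:
        """Gene coordinate of every CDS base, in CDS order."""
        regions = [self.region("cds")] if self.has_region("cds") else self.exons()
        coords: list[int] = []
        for r in regions:
            o0 = self.offset(r.start)
            coords.extend(self.coord(o) for o in range(o0, o0 + r.length))
        return coords

    def protein(self) -> str:
        prot, internal = translate(self.cds(), strip_terminal_stop=True)
        if internal:
            logger.warning("record %s: internal stop codon in CDS", self.id)
        return prot


# -- FASTA -------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[GeneRecord]:
    """Read a (possibly aligned) FASTA file into :class:`GeneRecord` objects.

    Headers of the form ``species|gene`` populate the species field.
    Sequences are uppercased; characters outside ``ACGTN-`` are mapped to N
    with a warning.  Empty files and duplicate ids are errors.
    """
    records = [GeneRecord(id=r.id, sequence=str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate FASTA id {r.id!r} in {path}")
        seen.add(r.id)
    return records


def write_fasta(records: list[GeneRecord], path: str | Path, *, width: int = 70) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records],
        str(path),
        "fasta",
    )


# -- region annotation TSV ----------------------------------------------------
# Columns: gene_id <TAB> region_name <TAB> start <TAB> end   (gene coordinates)

def read_regions(path: str | Path, records: list[GeneRecord]) -> list[GeneRecord]:
    """Attach region annotations from a tab-delimited file to *records*.

    When a gene has negative-coordinate annotations, its ``start_coord`` is
    inferred as the 5'-most annotated position (the stored sequence is then
    assumed to begin at that position).  Rows naming unknown ids, spans with
    coordinate 0, spans outside the sequence, or overlapping exons raise an
    error naming the offending row.
    """
    by_id = {r.id: r for r in records}
    rows: list[tuple[int, str, str, int, int]] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise RegionError(f"{path} line {ln}: expected 4 tab-separated columns")
        gid, name, s, e = parts
        try:
            start, end = int(s), int(e)
        except ValueError as exc:
            raise RegionError(f"{path} line {ln}: non-integer coordinate") from exc
        if gid not in by_id:
            raise RegionError(f"{path} line {ln}: unknown gene id {gid!r}")
        if start == 0 or end == 0:
            raise RegionError(f"{path} line {ln}: coordinate 0 does not exist")
        rows.append((ln, gid, name, start, end))

    for gid in {r[1] for r in rows}:
        rec = by_id[gid]
        mine = [r for r in rows if r[1] == gid]
        min_start = min(r[3] for r in mine)
        if min_start < 0 and rec.start_coord == 1:
            rec.start_coord = min_start
        for ln, _, name, start, end in mine:
            try:
                rec.offset(start), rec.offset(end)
            except RegionError as exc:
                raise RegionError(f"{path} line {ln}: {exc}") from exc
            rec.regions.append(Region(name, start, end))
        ex = rec.exons()
        for a, b in zip(ex, ex[1:]):
            if a.end >= b.start:
                raise RegionError(f"record {gid}: exons {a.name} and {b.name} overlap or are unordered")
    return records


def write_regions(records: list[GeneRecord], path: str | Path) -> None:
    lines = ["# gene_id\tregion\tstart\tend"]
    for rec in records:
        for r in rec.regions:
            lines.append(f"{rec.id}\t{r.name}\t{r.start}\t{r.end}")
    Path(path).write_text("\n".join(lines) + "\n")
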