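"""Reference genome, annotation and target-interval handling.

All coordinates inside the toolkit are 0-based half-open.  GFF3/GTF input
(1-based inclusive) is converted at parse time; BED output is natively
0-based half-open; VCF positions are converted where needed.  Target
regions are kept sorted, non-overlapping and non-adjacent: overlapping or
book-ended intervals are merged into the canonical minimal set.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from gffutils.feature import feature_from_line

log = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")
# IUPAC ambiguity codes (and anything else alphabetic) collapse to N.
_TO_N = {c: "N" for c in "RYSWKMBDHVU"}
_CLEAN = str.maketrans({**_TO_N, **{c.lower(): "N" for c in _TO_N}})


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome/contig: uppercase DNA over {A,C,G,T,N}."""

    name: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


Genome = dict  # name -> GenomeSequence


def _open_maybe_gzip(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def load_genome(path) -> dict[str, GenomeSequence]:
    """Read a FASTA file (plain or gzip/bgzip) into a name-keyed genome.

    Sequences are uppercased; ambiguity codes other than N are mapped to N
    with a logged warning.  Duplicate record names raise ``ValueError``.
    """
    path = Path(path)
    genome: dict[str, GenomeSequence] = {}
    with _open_maybe_gzip(path) as handle:
        head = handle.read(4096)
        stripped = head.lstrip()
        if stripped and not stripped.startswith(">"):
            raise ValueError(f"{path}: not FASTA (first record does not start with '>')")
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in genome:
                raise ValueError(f"{path}: duplicate sequence name {rec.id!r}")
            seq = str(rec.seq).upper()
            cleaned = seq.translate(_CLEAN)
            if cleaned != seq:
                n_mapped = sum(a != b for a, b in zip(seq, cleaned))
                log.warning(
                    "record %s: %d ambiguity base(s) mapped to N", rec.id, n_mapped
                )
            bad = set(cleaned) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"{path}: record {rec.id!r} contains invalid characters {sorted(bad)}"
                )
            genome[rec.id] = GenomeSequence(rec.id, cleaned)
    if not genome:
        log.warning("%s: empty FASTA, no records loaded", path)
    return genome


def chrom_lengths(genome: Mapping[str, GenomeSequence]) -> dict[str, int]:
    return {name: gs.length for name, gs in genome.items()}


@dataclass(frozen=True)
class Feature:
    """A genomic feature in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    kind: str = "CDS"
    gene_id: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start},{self.end}) on {self.chrom}")

    @property
    def length(self) -> int:
        return self.end - self.start


_GENE_KEYS = ("gene_id", "gene", "gene_name", "Parent", "ID")


def _gene_id_of(attrs) -> str:
    for key in _GENE_KEYS:
        if key in attrs and attrs[key]:
            return str(attrs[key][0])
    return ""


def load_features(
    path,
    kinds: Iterable[str] = ("CDS",),
    genome: Mapping[str, GenomeSequence] | None = None,
) -> list[Feature]:
    """Parse GFF3 or GTF, keeping only feature kinds in ``kinds``.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    When ``genome`` is given, features on unknown chromosomes are dropped
    with a warning and features extending past the chromosome end raise.
    """
    kinds = set(kinds)
    feats: list[Feature] = []
    with _open_maybe_gzip(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ValueError(
                    f"{path}:{lineno}: unparseable feature line "
                    "(expected 9 tab-separated columns)"
                )
            try:
                gf = feature_from_line(line)
            except Exception as exc:  # gffutils raises several types
                raise ValueError(f"{path}:{lineno}: unparseable feature line: {exc}") from exc
            if gf.featuretype not in kinds:
                continue
            if genome is not None and gf.seqid not in genome:
                log.warning(
                    "%s:%d: feature on unknown chromosome %s dropped", path, lineno, gf.seqid
                )
                continue
            start, end = gf.start - 1, gf.end
            if genome is not None and end > genome[gf.seqid].length:
                raise ValueError(
                    f"{path}:{lineno}: feature end {end} beyond chromosome "
                    f"{gf.seqid} length {genome[gf.seqid].length}"
                )
            feats.append(
                Feature(
                    chrom=gf.seqid,
                    start=start,
                    end=end,
                    strand=gf.strand if gf.strand in "+-" else ".",
                    kind=gf.featuretype,
                    gene_id=_gene_id_of(gf.attributes),
                )
            )
    return feats


@dataclass(frozen=True)
class TargetRegion:
    chrom: str
    start: int
    end: int
    source_gene_ids: frozenset = field(default_factory=frozenset)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RegionSet:
    """Sorted, non-overlapping, non-adjacent target regions."""

    regions: list = field(default_factory=list)

    @property
    def total_bases(self) -> int:
        return sum(r.length for r in self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def by_chrom(self) -> dict[str, list]:
        out: dict[str, list] = {}
        for r in self.regions:
            out.setdefault(r.chrom, []).append(r)
        return out


def _merge_intervals(items: Sequence[tuple[str, int, int, frozenset]]) -> list[TargetRegion]:
    """Merge overlapping or book-ended intervals, unioning gene ids."""
    merged: list[TargetRegion] = []
    for chrom, start, end, genes in sorted(items, key=lambda t: (t[0], t[1], t[2])):
        if merged and merged[-1].chrom == chrom and start <= merged[-1].end:
            last = merged[-1]
            merged[-1] = TargetRegion(
                chrom, last.start, max(last.end, end), last.source_gene_ids | genes
            )
        else:
            merged.append(TargetRegion(chrom, start, end, genes))
    return merged


def consolidate_targets(features: Iterable[Feature]) -> RegionSet:
    """Union features into a strand-agnostic, non-overlapping region set."""
    items = [
        (f.chrom, f.start, f.end, frozenset([f.gene_id]) if f.gene_id else frozenset())
        for f in features
    ]
    return RegionSet(_merge_intervals(items))


def consolidate_regions(regions: Iterable[TargetRegion]) -> RegionSet:
    items = [(r.chrom, r.start, r.end, r.source_gene_ids) for r in regions]
    return RegionSet(_merge_intervals(items))


def adjust_regions(
    rs: RegionSet,
    pad: int,
    chrom_lengths: Mapping[str, int] | None = None,
) -> RegionSet:
    """Grow (pad > 0) or shrink (pad < 0) every region by ``pad`` on each side.

    Results are clipped to [0, chromosome length] when lengths are known,
    then re-consolidated.  Regions that would vanish under negative padding
    are dropped with a warning.
    """
    kept: list[TargetRegion] = []
    for r in rs:
        start, end = r.start - pad, r.end + pad
        if start >= end:
            log.warning(
                "region %s:%d-%d vanished under pad=%d and was dropped",
                r.chrom, r.start, r.end, pad,
            )
            continue
        start = max(0, start)
        if chrom_lengths is not None and r.chrom in chrom_lengths:
            end = min(end, chrom_lengths[r.chrom])
        if start >= end:
            log.warning("region %s:%d-%d clipped away, dropped", r.chrom, r.start, r.end)
            continue
        kept.append(TargetRegion(r.chrom, start, end, r.source_gene_ids))
    return consolidate_regions(kept)


# --- BED6 I/O ---------------------------------------------------------------

_BED_HEADER = "#chrom\tstart\tend\tname\tscore\tstrand"


def write_bed(rs: RegionSet, path) -> None:
    """Write a RegionSet as BED6 (name = comma-joined gene ids, score 0)."""
    with open(path, "w", newline="\n") as fh:
        fh.write(_BED_HEADER + "\n")
        for r in rs:
            name = ",".join(sorted(r.source_gene_ids)) or "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t.\n")


def read_bed(path) -> RegionSet:
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            genes: frozenset = frozenset()
            if len(parts) >= 4 and parts[3] not in (".", ""):
                genes = frozenset(parts[3].split(","))
            regions.append(TargetRegion(chrom, start, end, genes))
    return consolidate_regions(regions)
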