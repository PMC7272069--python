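"""Readers and writers for the external formats the pipeline consumes.

All in-memory coordinates are 0-based, half-open.  BED files are read and
written as-is; GFF3 records are converted on load (start shifted by -1, end
unchanged); cytosine reports use 1-based positions on disk and are converted
the same way.  Writers emit tab-separated UTF-8 with header lines prefixed
by ``#``.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

LIBRARIES = ("MspI", "HpaII")
FEATURE_KINDS = ("gene", "exon", "intron", "UTR", "TE")
CONTEXTS = ("CG", "CHG", "CHH")

_VALID_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class GenomeSequence:
    """Reference genome held as uppercase per-chromosome strings."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - _VALID_ALPHABET
            if bad:
                raise FormatError(
                    f"chromosome {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def chromosomes(self) -> list[str]:
        return list(self.sequences)

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences


@dataclass(frozen=True)
class AlignmentRecord:
    """A mapped single-end read interval.

    ``sample_id`` is a ``(tissue, replicate)`` pair; ``library`` names the
    frequent-cutter library the read came from (PstI-MspI or PstI-HpaII).
    """

    chrom: str
    start: int
    end: int
    strand: str
    sample_id: tuple[str, str]
    library: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(f"bad interval [{self.start},{self.end}) on {self.chrom}")
        if self.strand not in ("+", "-"):
            raise FormatError(f"bad strand {self.strand!r}")
        if self.library not in LIBRARIES:
            raise FormatError(f"unknown library {self.library!r}; expected one of {LIBRARIES}")

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class Feature:
    chrom: str
    start: int
    end: int
    strand: str
    kind: str
    attributes: dict = field(default_factory=dict, hash=False, compare=False)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(f"feature with start >= end: [{self.start},{self.end})")

    @property
    def id(self) -> Optional[str]:
        return self.attributes.get("id")

    @property
    def parent(self) -> Optional[str]:
        return self.attributes.get("parent")


@dataclass
class FeatureSet:
    """Gene/TE annotation intervals with parent links for gene children."""

    features: list[Feature]

    def by_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def with_introns(self) -> "FeatureSet":
        """Return a copy with intronic space derived as gene minus exon/UTR."""
        out = list(self.features)
        children: dict[str, list[Feature]] = {}
        for f in self.features:
            if f.kind in ("exon", "UTR") and f.parent is not None:
                children.setdefault(f.parent, []).append(f)
        for gene in self.by_kind("gene"):
            if gene.id is None:
                continue
            covered = sorted(
                (c.start, c.end) for c in children.get(gene.id, ())
            )
            cursor = gene.start
            gaps = []
            for s, e in covered:
                if s > cursor:
                    gaps.append((cursor, min(s, gene.end)))
                cursor = max(cursor, e)
            if cursor < gene.end:
                gaps.append((cursor, gene.end))
            # a gene with no exon/UTR children contributes no introns
            if children.get(gene.id):
                for s, e in gaps:
                    if s < e:
                        out.append(
                            Feature(gene.chrom, s, e, gene.strand, "intron",
                                    {"parent": gene.id})
                        )
        return FeatureSet(out)


@dataclass(frozen=True)
class CytosineRecord:
    """Per-cytosine bisulfite evidence (position already 0-based)."""

    chrom: str
    pos: int
    strand: str
    count_methylated: int
    count_unmethylated: int
    context: str

    def __post_init__(self) -> None:
        if self.count_methylated < 0 or self.count_unmethylated < 0:
            raise FormatError("negative counts in cytosine record")
        if self.context not in CONTEXTS:
            raise FormatError(f"unknown context token {self.context!r}")
        if self.strand not in ("+", "-"):
            raise FormatError(f"bad strand {self.strand!r}")

    @property
    def count_total(self) -> int:
        return self.count_methylated + self.count_unmethylated


# ---------------------------------------------------------------------------
# loaders


def load_genome(path: str | os.PathLike) -> GenomeSequence:
    """Load a FASTA reference, uppercasing sequences.

    Duplicate headers and text before the first ``>`` are rejected.
    """
    from Bio import SeqIO

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}: line {lineno}: expected FASTA header, got {line.strip()[:30]!r}"
                    )
                break
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"duplicate chromosome name {rec.id!r} in {path}")
        sequences[rec.id] = str(rec.seq).upper()
    return GenomeSequence(sequences)


def _load_alignments_bed(path, sample_id, library):
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "+"
            records.append(
                AlignmentRecord(chrom, start, end, strand, tuple(sample_id), library)
            )
    return records


def _load_alignments_pysam(path, sample_id, library, min_mapq):
    import pysam

    mode = "r" if str(path).endswith(".sam") else "rb"
    records = []
    with pysam.AlignmentFile(str(path), mode) as bam:
        for aln in bam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if min_mapq is not None and aln.mapping_quality < min_mapq:
                continue
            records.append(
                AlignmentRecord(
                    aln.reference_name,
                    aln.reference_start,
                    aln.reference_end,  # reference-consumed span (M/D/N/=/X)
                    "-" if aln.is_reverse else "+",
                    tuple(sample_id),
                    library,
                )
            )
    return records


def load_alignments(
    path: str | os.PathLike,
    sample_id: Sequence[str],
    library: str,
    genome: Optional[GenomeSequence] = None,
    min_mapq: Optional[int] = None,
) -> list[AlignmentRecord]:
    """Load read alignments from BAM/SAM (via pysam) or BED.

    Records are returned sorted by (chrom, start, end).  When a genome is
    given, intervals outside chromosome bounds raise an error.  ``min_mapq``
    defaults to None, i.e. the file is taken as given.
    """
    if library not in LIBRARIES:
        raise FormatError(f"unknown library {library!r}; expected one of {LIBRARIES}")
    p = str(path)
    if p.endswith((".bam", ".sam", ".cram")):
        records = _load_alignments_pysam(path, sample_id, library, min_mapq)
    else:
        records = _load_alignments_bed(path, sample_id, library)
    if genome is not None:
        lengths = genome.lengths
        for rec in records:
            if rec.chrom not in lengths:
                raise FormatError(f"alignment on unknown chromosome {rec.chrom!r}")
            if rec.end > lengths[rec.chrom]:
                raise FormatError(
                    f"alignment [{rec.start},{rec.end}) beyond end of {rec.chrom}"
                )
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    return records


_GFF_KIND_MAP = {
    "gene": "gene",
    "exon": "exon",
    "five_prime_UTR": "UTR",
    "three_prime_UTR": "UTR",
    "UTR": "UTR",
    "transposable_element": "TE",
    "transposable_element_gene": "TE",
    "repeat_region": "TE",
}


def load_features(
    path: str | os.PathLike,
    feature_kind: Optional[str] = None,
    derive_introns: bool = True,
) -> FeatureSet:
    """Load gene/TE annotations from GFF3 or BED.

    GFF3 coordinates (1-based closed) are converted to 0-based half-open.
    Exon/UTR children are linked to their gene through the Parent chain;
    children whose parent cannot be resolved go to an orphan bucket with a
    warning.  For BED input ``feature_kind`` labels every row; an optional
    7th column carries a class attribute (e.g. the TE class).
    """
    p = str(path)
    if p.endswith((".gff", ".gff3")):
        feats = _load_features_gff3(path)
    else:
        if feature_kind is None:
            raise FormatError("feature_kind is required for BED feature input")
        feats = _load_features_bed(path, feature_kind)
    fs = FeatureSet(feats)
    return fs.with_introns() if derive_introns else fs


def _load_features_bed(path, feature_kind):
    feats = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            attrs = {}
            if len(parts) >= 4 and parts[3] != ".":
                attrs["id"] = parts[3]
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "+"
            if len(parts) >= 7:
                attrs["class"] = parts[6]
            feats.append(Feature(chrom, start, end, strand, feature_kind, attrs))
    return feats


def _load_features_gff3(path):
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )

    def _gene_ancestor(feat):
        for anc in db.parents(feat):
            if anc.featuretype == "gene":
                return anc.id
        return None

    feats = []
    orphans = 0
    for feat in db.all_features():
        kind = _GFF_KIND_MAP.get(feat.featuretype)
        if kind is None:
            continue
        if feat.start > feat.end:
            raise FormatError(f"GFF3 record with start > end: {feat.id}")
        attrs = {"id": feat.id}
        if kind in ("exon", "UTR"):
            gene_id = _gene_ancestor(feat)
            if gene_id is None:
                orphans += 1
                attrs["orphan"] = True
            else:
                attrs["parent"] = gene_id
        if "class" in feat.attributes:
            attrs["class"] = feat.attributes["class"][0]
        feats.append(
            Feature(feat.seqid, feat.start - 1, feat.end,
                    feat.strand if feat.strand in ("+", "-") else "+", kind, attrs)
        )
    if orphans:
        warnings.warn(f"{orphans} exon/UTR records without a resolvable gene parent")
    return feats


def load_cytosine_report(path: str | os.PathLike) -> list[CytosineRecord]:
    """Load a per-cytosine bisulfite report.

    Columns: chrom, 1-based position, strand, methylated count, unmethylated
    count, context.  Positions are converted to 0-based.  Zero-coverage rows
    are retained.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "pos", "strand", "meth", "unmeth", "context"],
        dtype={"chrom": str, "pos": int, "strand": str, "meth": int,
               "unmeth": int, "context": str},
    )
    return [
        CytosineRecord(r.chrom, int(r.pos) - 1, r.strand, int(r.meth),
                       int(r.unmeth), r.context)
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# writers


def write_fasta(genome: GenomeSequence, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in genome.chromosomes:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bed(
    intervals: Iterable[tuple],
    path: str | os.PathLike,
    header: Optional[str] = None,
) -> None:
    """Write (chrom, start, end[, name[, score[, strand]]]) tuples as BED."""
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        for iv in intervals:
            chrom, start, end = iv[0], iv[1], iv[2]
            name = iv[3] if len(iv) > 3 else "."
            score = iv[4] if len(iv) > 4 else 0
            strand = iv[5] if len(iv) > 5 else "+"
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def load_bed_intervals(path: str | os.PathLike) -> list[tuple]:
    """Read a BED file back as (chrom, start, end, name, score, strand) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            score = int(parts[4]) if len(parts) > 4 else 0
            strand = parts[5] if len(parts) > 5 else "+"
            out.append((chrom, start, end, name, score, strand))
    return out


def write_cytosine_report(records: Iterable[CytosineRecord], path: str | os.PathLike) -> None:
    """Write cytosine records back to the on-disk 1-based TSV layout."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# chrom\tpos\tstrand\tcount_methylated\tcount_unmethylated\tcontext\n")
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t{r.strand}\t{r.count_methylated}\t"
                f"{r.count_unmethylated}\t{r.context}\n"
            )
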