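"""Derivation of MSD-tags and MSD-sites from alignments.

An MSD-tag is the genomic interval from a PstI restriction boundary to the
terminating MspI/HpaII (CCGG) site on the same strand; its read count in the
two isoschizomer libraries reports on the methylation status of that CCGG
site (the MSD-site).  On '+' a tag spans [pstI_start+1, ccgg_start+1); on
'-' it spans [ccgg_start+3, pstI_start+5), i.e. the read-strand retained
sequence after double digestion.

Reads are assigned to tags by their PstI anchor and by the first CCGG
boundary at or past their 3' end — an alignment extending past a CCGG
implies that site was uncut in that molecule, so the tag skips it.  Nested
tags sharing one anchor therefore never compete for a read; the literal
"attribute the longer tag's count to the nested shorter ones" correction is
available as an explicit post-step (:func:`correct_overlap_counts`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .digest import RestrictionSiteMap
from .io_formats import AlignmentRecord

PSTI_NAME = "PstI"
# the frequent cutter position list is shared by MspI/HpaII (same CCGG sites)
CCGG_NAMES = ("MspI", "HpaII", "CCGG")


@dataclass(frozen=True)
class MSDTag:
    tag_id: str
    chrom: str
    strand: str
    start: int
    end: int
    pstI_recognition_start: int
    msd_site_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("tag with start >= end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MSDSite:
    site_id: str
    chrom: str
    ccgg_start: int
    tag_ids: list[str] = field(default_factory=list)

    @property
    def internal_cytosines(self) -> tuple[tuple[int, str], tuple[int, str]]:
        """The two strand-symmetric internal (CG-context) cytosines."""
        return ((self.ccgg_start + 1, "+"), (self.ccgg_start + 2, "-"))


@dataclass
class CountMatrix:
    """Tags x (tissue, replicate, library) non-negative integer counts."""

    data: pd.DataFrame  # index tag_id, columns MultiIndex (tissue, replicate, library)
    overlap_corrected: bool = False
    spill: int = 0  # alignments not anchored to any tag

    def __post_init__(self) -> None:
        if (self.data.values < 0).any():
            raise ValueError("negative counts")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate column labels")

    @property
    def tissues(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values(0)))

    def library_columns(self, tissue: str, library: str) -> pd.DataFrame:
        cols = [c for c in self.data.columns if c[0] == tissue and c[2] == library]
        return self.data[cols]


@dataclass
class TagDerivation:
    tags: list[MSDTag]
    sites: list[MSDSite]
    n_unanchored: int = 0
    n_no_terminator: int = 0

    def __iter__(self):
        yield self.tags
        yield self.sites


def _ccgg_positions(sites: RestrictionSiteMap, chrom: str) -> np.ndarray:
    for name in CCGG_NAMES:
        pos = sites.positions(chrom, name)
        if pos.size:
            return pos
    return sites.positions(chrom, CCGG_NAMES[0])


def site_id_for(chrom: str, ccgg_start: int) -> str:
    return f"{chrom}:{ccgg_start}"


def tag_id_for(chrom: str, strand: str, start: int, end: int) -> str:
    return f"{chrom}:{strand}:{start}-{end}"


def _match_anchor(pst: np.ndarray, boundary: int, offset: int, tol: int):
    """Find a PstI recognition start p with p+offset == boundary (within tol)."""
    target = boundary - offset
    i = np.searchsorted(pst, target - tol)
    while i < pst.size and pst[i] <= target + tol:
        if abs(pst[i] - target) <= tol:
            return int(pst[i])
        i += 1
    return None


def _resolve_tag(
    aln: AlignmentRecord, pst: np.ndarray, ccgg: np.ndarray, tol: int
):
    """Return (pstI_start, ccgg_start, tag_start, tag_end) or a failure code."""
    if aln.strand == "+":
        p = _match_anchor(pst, aln.start, 1, tol)
        if p is None:
            return "unanchored"
        # first CCGG whose read-strand boundary (c+1) is >= alignment 3' end
        idx = np.searchsorted(ccgg + 1, aln.end, side="left")
        if idx >= ccgg.size:
            return "no_terminator"
        c = int(ccgg[idx])
        return (p, c, p + 1, c + 1)
    else:
        p = _match_anchor(pst, aln.end, 5, tol)
        if p is None:
            return "unanchored"
        # last CCGG whose read-strand boundary (c+3) is <= alignment start
        idx = np.searchsorted(ccgg + 3, aln.start, side="right") - 1
        if idx < 0:
            return "no_terminator"
        c = int(ccgg[idx])
        return (p, c, c + 3, p + 5)


def derive_observed_tags(
    alignments: list[AlignmentRecord],
    sites: RestrictionSiteMap,
    anchor_tolerance: int = 0,
) -> TagDerivation:
    """Derive the MSD-tag and MSD-site universe from read alignments.

    An alignment anchors a tag iff its read-strand 5' end coincides (within
    ``anchor_tolerance``) with a PstI boundary.  Each distinct
    (anchor, strand, terminating CCGG) triple yields one tag; tags ending at
    the same CCGG from either side share one MSD-site.  The universe is the
    union over all samples and libraries.
    """
    tags: dict[str, MSDTag] = {}
    site_map: dict[str, MSDSite] = {}
    n_unanchored = 0
    n_no_term = 0
    cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for aln in alignments:
        if aln.chrom not in cache:
            cache[aln.chrom] = (
                sites.positions(aln.chrom, PSTI_NAME),
                _ccgg_positions(sites, aln.chrom),
            )
        pst, ccgg = cache[aln.chrom]
        res = _resolve_tag(aln, pst, ccgg, anchor_tolerance)
        if res == "unanchored":
            n_unanchored += 1
            continue
        if res == "no_terminator":
            n_no_term += 1
            continue
        p, c, start, end = res
        tid = tag_id_for(aln.chrom, aln.strand, start, end)
        if tid not in tags:
            sid = site_id_for(aln.chrom, c)
            if sid not in site_map:
                site_map[sid] = MSDSite(sid, aln.chrom, c)
            site_map[sid].tag_ids.append(tid)
            tags[tid] = MSDTag(tid, aln.chrom, aln.strand, start, end, p, sid)
    tag_list = sorted(tags.values(), key=lambda t: (t.chrom, t.start, t.end, t.strand))
    site_list = sorted(site_map.values(), key=lambda s: (s.chrom, s.ccgg_start))
    return TagDerivation(tag_list, site_list, n_unanchored, n_no_term)


def count_reads(
    alignments: list[AlignmentRecord],
    tags: list[MSDTag],
    sites: RestrictionSiteMap,
    anchor_tolerance: int = 0,
) -> CountMatrix:
    """Count reads per tag per (tissue, replicate, library) column.

    Each qualifying alignment increments exactly one tag — the tag on its
    strand sharing its PstI anchor whose CCGG end is the first at or past the
    alignment's 3' end.  Alignments matching no tag go to the spill bucket.
    """
    from collections import Counter

    tag_ids = {t.tag_id for t in tags}
    columns = sorted({(a.sample_id[0], a.sample_id[1], a.library) for a in alignments})
    index = [t.tag_id for t in tags]
    col_index = (
        pd.MultiIndex.from_tuples(columns, names=["tissue", "replicate", "library"])
        if columns
        else pd.MultiIndex.from_arrays([[], [], []], names=["tissue", "replicate", "library"])
    )
    hits: Counter = Counter()
    spill = 0
    cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    known_chroms = set(sites.chromosomes)
    for aln in alignments:
        if aln.chrom not in known_chroms:
            raise ValueError(f"alignment references unknown chromosome {aln.chrom!r}")
        if aln.chrom not in cache:
            cache[aln.chrom] = (
                sites.positions(aln.chrom, PSTI_NAME),
                _ccgg_positions(sites, aln.chrom),
            )
        pst, ccgg = cache[aln.chrom]
        res = _resolve_tag(aln, pst, ccgg, anchor_tolerance)
        if isinstance(res, str):
            spill += 1
            continue
        _, _, start, end = res
        tid = tag_id_for(aln.chrom, aln.strand, start, end)
        if tid not in tag_ids:
            spill += 1
            continue
        hits[(tid, (aln.sample_id[0], aln.sample_id[1], aln.library))] += 1
    arr = np.zeros((len(index), len(columns)), dtype=np.int64)
    row_of = {tid: i for i, tid in enumerate(index)}
    col_of = {c: j for j, c in enumerate(columns)}
    for (tid, col), n in hits.items():
        arr[row_of[tid], col_of[col]] = n
    mat = pd.DataFrame(arr, index=index, columns=col_index)
    return CountMatrix(mat, overlap_corrected=False, spill=spill)


def correct_overlap_counts(counts: CountMatrix, tags: list[MSDTag]) -> CountMatrix:
    """Attribute each longer tag's counts to the nested tags it contains.

    For every maximal group of tags sharing (chrom, strand, PstI anchor),
    sorted by increasing length, corrected(T) = raw(T) + sum of raw(U) over
    longer tags U in the group, per column.  The corrected count of a tag
    then matches the total read evidence for its MSD-site from that anchor.
    Calling this twice is an error (idempotence guard).
    """
    if counts.overlap_corrected:
        raise ValueError("count matrix is already overlap-corrected")
    groups: dict[tuple, list[MSDTag]] = {}
    for t in tags:
        groups.setdefault((t.chrom, t.strand, t.pstI_recognition_start), []).append(t)
    data = counts.data.copy()
    for members in groups.values():
        if len(members) < 2:
            continue
        members = sorted(members, key=lambda t: t.length)
        ids = [t.tag_id for t in members]
        block = data.loc[ids].values
        # cumulative sum from the largest tag down: each tag gains the
        # counts of every strictly longer tag in its group
        suffix = np.zeros_like(block)
        suffix[:-1] = block[::-1].cumsum(axis=0)[::-1][1:]
        data.loc[ids] = block + suffix
    return CountMatrix(data, overlap_corrected=True, spill=counts.spill)


def tags_to_bed(tags: list[MSDTag]):
    """BED6 rows for the tag universe; name = tag_id|site_id."""
    return [
        (t.chrom, t.start, t.end, f"{t.tag_id}|{t.msd_site_id}", 0, t.strand)
        for t in tags
    ]
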