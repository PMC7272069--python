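"""Synthetic MS-DArT-seq data with known truth.

Generates genomes with planted PstI (CTGCAG) and CCGG sites, per-site
methylation states (internal CG full/hemi, external CHG), enzyme blocking,
replicate negative-binomial count noise, read alignments for both libraries
and a matched bisulfite cytosine report — everything needed to exercise the
pipeline end to end against a recorded ground truth.

Methylation states are per-site-per-genome (a homogeneous molecule
population); the enzymology follows the assay: MspI cuts CCGG unless the
external cytosine carries CHG methylation, HpaII additionally requires the
internal cytosine to be unmethylated on both strands, and PstI sites can be
methylation-blocked with a configured probability.  Reads are single-end,
77 bp, starting at the PstI boundary of each sequenceable mixed fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    AlignmentRecord,
    CytosineRecord,
    Feature,
    FeatureSet,
    GenomeSequence,
)
from .tagbuilder import CountMatrix, MSDSite, MSDTag, site_id_for, tag_id_for

STATES = ("unmethylated", "fully", "hemi_plus", "hemi_minus")


@dataclass
class SimParams:
    """Study conditions for the synthetic data generator.

    Defaults mirror the assay's design: three tissues with three biological
    replicates each, 77-cycle single-end reads, a mean tag depth of 30 with
    negative-binomial dispersion 0.05, a sequenceable fragment window of
    100-600 bp, and a bisulfite non-conversion rate of 0.005.  Roughly a
    fifth of CCGG sites carry internal methylation (mostly fully methylated,
    a small hemi fraction); external CHG methylation, which hides the site
    from both libraries, co-occurs with internal methylation and is rare at
    internally unmethylated sites; CCGG placement is enriched
    in genic space to emulate the assay's hypomethylated-region bias.
    """

    chrom_length: int = 200_000
    n_chromosomes: int = 2
    gc_content: float = 0.4
    n_ccgg_per_chrom: int = 200
    n_psti_per_chrom: int = 120
    frac_fully_methylated: float = 0.15
    frac_hemi_methylated: float = 0.03
    # external CHG methylation co-occurs with internal CG methylation in
    # plant genomes; CHG-only CCGG sites are rare
    p_external_chg: float = 0.2  # given the site is internally methylated
    p_external_chg_solo: float = 0.002  # given the site is internally unmethylated
    p_psti_blocked: float = 0.05
    genic_ccgg_enrichment: float = 0.6  # probability a CCGG lands in genic space
    read_depth: float = 30.0
    dispersion: float = 0.05
    replicates: int = 3
    tissues: tuple[str, ...] = ("adult_leaves", "juvenile_leaves", "xylem")
    tissue_state_flip_prob: float = 0.03
    digestion_efficiency: float = 1.0
    size_min: int = 100
    size_max: int = 600
    read_length: int = 77
    wgbs_coverage: float = 30.0
    non_conversion_rate: float = 0.005
    bisulfite_error: float = 0.01
    n_genes_per_chrom: int = 30
    gene_length: int = 2_500
    n_tes_per_chrom: int = 20
    te_length: int = 800

    def validate(self) -> None:
        for p in (self.gc_content, self.frac_fully_methylated,
                  self.frac_hemi_methylated, self.p_external_chg,
                  self.p_external_chg_solo,
                  self.p_psti_blocked, self.genic_ccgg_enrichment,
                  self.tissue_state_flip_prob, self.digestion_efficiency,
                  self.non_conversion_rate, self.bisulfite_error):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.frac_fully_methylated + self.frac_hemi_methylated > 1.0:
            raise ValueError("methylated fractions sum above 1")
        if self.read_depth <= 0 or self.dispersion < 0:
            raise ValueError("depth must be > 0 and dispersion >= 0")
        needed = (self.n_ccgg_per_chrom + self.n_psti_per_chrom) * 20
        if needed > self.chrom_length:
            raise ValueError("site density infeasible for the chromosome length")


@dataclass
class SimTruth:
    """Planted ground truth: site positions, states, blocking, tag universe."""

    psti_positions: dict[str, np.ndarray]
    ccgg_positions: dict[str, np.ndarray]
    psti_blocked: dict[str, np.ndarray]
    internal_state: dict[str, dict[str, np.ndarray]]  # tissue -> chrom -> codes
    external_chg: dict[str, np.ndarray]
    tags: list[MSDTag] = field(default_factory=list)
    sites: list[MSDSite] = field(default_factory=list)

    def state_of(self, tissue: str, chrom: str, ccgg_start: int) -> str:
        pos = self.ccgg_positions[chrom]
        idx = int(np.searchsorted(pos, ccgg_start))
        return STATES[self.internal_state[tissue][chrom][idx]]

    def methylated_site_ids(self, tissue: str) -> set[str]:
        """Sites with internal methylation (the detectable truth set)."""
        out = set()
        for chrom, pos in self.ccgg_positions.items():
            codes = self.internal_state[tissue][chrom]
            for p, c in zip(pos, codes):
                if c != 0:
                    out.add(site_id_for(chrom, int(p)))
        return out


_MOTIFS = ("CTGCAG", "CCGG")


def _scrub_motifs(seq: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Destroy every CTGCAG/CCGG occurrence by mutating one internal base."""
    text = seq.tobytes().decode()
    bases = "ACGT"
    for _ in range(50):
        dirty = []
        for motif in _MOTIFS:
            start = 0
            while True:
                i = text.find(motif, start)
                if i < 0:
                    break
                dirty.append((i, len(motif)))
                start = i + 1
        if not dirty:
            return np.frombuffer(text.encode(), dtype="S1").copy()
        arr = np.frombuffer(text.encode(), dtype="S1").copy()
        for i, m in dirty:
            j = i + int(rng.integers(1, m - 1))
            old = arr[j].decode()
            arr[j] = rng.choice([b for b in bases if b != old]).encode()
        text = arr.tobytes().decode()
    raise RuntimeError("failed to scrub background motifs")


def _spaced_positions(
    rng: np.random.Generator, length: int, n: int, min_gap: int, lo: int, hi: int
) -> np.ndarray:
    """Draw n positions in [lo, hi) with pairwise gaps >= min_gap."""
    for _ in range(200):
        cand = np.sort(rng.integers(lo, hi, size=3 * n + 8))
        keep = [int(cand[0])] if cand.size else []
        for c in cand[1:]:
            if c - keep[-1] >= min_gap:
                keep.append(int(c))
            if len(keep) == n:
                break
        if len(keep) == n:
            return np.asarray(keep, dtype=np.int64)
    raise ValueError("could not place the requested number of sites")


def simulate_genome(params: SimParams, seed: int):
    """Build genome, features and planted truth.

    Returns (GenomeSequence, SimTruth, FeatureSet).  The background sequence
    is i.i.d. at the stated GC content with accidental CTGCAG/CCGG
    occurrences scrubbed; planted motifs are verified to be the only
    occurrences.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    gc = params.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    sequences: dict[str, str] = {}
    psti_pos: dict[str, np.ndarray] = {}
    ccgg_pos: dict[str, np.ndarray] = {}
    features: list[Feature] = []
    for ci in range(params.n_chromosomes):
        chrom = f"chr{ci + 1}"
        L = params.chrom_length
        seq = rng.choice(bases, size=L, p=probs)
        seq = _scrub_motifs(seq, rng)
        # plant gene and TE models
        gene_ivs = []
        gene_slots = _spaced_positions(
            rng, L, params.n_genes_per_chrom, params.gene_length + 400,
            200, L - params.gene_length - 200,
        )
        for gi, g0 in enumerate(gene_slots):
            g1 = g0 + params.gene_length
            gid = f"{chrom}.g{gi + 1}"
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(Feature(chrom, int(g0), int(g1), strand, "gene", {"id": gid}))
            # simple 2-exon model with UTR caps and one intron
            utr = 150
            mid = (g0 + g1) // 2
            features.append(Feature(chrom, int(g0), int(g0 + utr), strand, "UTR",
                                    {"id": f"{gid}.u5", "parent": gid}))
            features.append(Feature(chrom, int(g0 + utr), int(mid - 200), strand, "exon",
                                    {"id": f"{gid}.e1", "parent": gid}))
            features.append(Feature(chrom, int(mid + 200), int(g1 - utr), strand, "exon",
                                    {"id": f"{gid}.e2", "parent": gid}))
            features.append(Feature(chrom, int(g1 - utr), int(g1), strand, "UTR",
                                    {"id": f"{gid}.u3", "parent": gid}))
            gene_ivs.append((int(g0), int(g1)))
        te_slots = _spaced_positions(
            rng, L, params.n_tes_per_chrom, params.te_length + 200,
            100, L - params.te_length - 100,
        )
        te_classes = ("LTR", "LINE", "MITE", "Helitron")
        for ti, t0 in enumerate(te_slots):
            features.append(
                Feature(chrom, int(t0), int(t0 + params.te_length), "+", "TE",
                        {"id": f"{chrom}.te{ti + 1}",
                         "class": te_classes[int(rng.integers(len(te_classes)))]})
            )
        # choose motif positions: CCGG enriched in genic space
        def _in_gene(p):
            return any(g0 <= p < g1 - 6 for g0, g1 in gene_ivs)

        all_slots = _spaced_positions(
            rng, L, params.n_ccgg_per_chrom * 3 + params.n_psti_per_chrom,
            12, 100, L - 100,
        )
        rng.shuffle(all_slots)
        genic = [int(p) for p in all_slots if _in_gene(p)]
        intergenic = [int(p) for p in all_slots if not _in_gene(p)]
        ccgg: list[int] = []
        for _ in range(params.n_ccgg_per_chrom):
            use_genic = rng.random() < params.genic_ccgg_enrichment and genic
            pool = genic if use_genic else (intergenic or genic)
            ccgg.append(pool.pop())
        remaining = sorted(genic + intergenic)
        rng.shuffle(remaining)
        psti = sorted(remaining[: params.n_psti_per_chrom])
        ccgg = sorted(ccgg)
        for p in psti:
            seq[p : p + 6] = np.frombuffer(b"CTGCAG", dtype="S1")
        for c in ccgg:
            seq[c : c + 4] = np.frombuffer(b"CCGG", dtype="S1")
        text = seq.tobytes().decode()
        # planting verification: exactly the planted occurrences, no extras
        for motif, planted in (("CTGCAG", psti), ("CCGG", ccgg)):
            found = []
            start = 0
            while True:
                i = text.find(motif, start)
                if i < 0:
                    break
                found.append(i)
                start = i + 1
            if found != list(planted):
                raise RuntimeError(f"motif planting produced extra {motif} occurrences")
        sequences[chrom] = text
        psti_pos[chrom] = np.asarray(psti, dtype=np.int64)
        ccgg_pos[chrom] = np.asarray(ccgg, dtype=np.int64)
    genome = GenomeSequence(sequences)
    # planted states: reference tissue drawn from the stated fractions,
    # other tissues flip with tissue_state_flip_prob
    internal: dict[str, dict[str, np.ndarray]] = {t: {} for t in params.tissues}
    external: dict[str, np.ndarray] = {}
    blocked: dict[str, np.ndarray] = {}
    p_full = params.frac_fully_methylated
    p_hemi = params.frac_hemi_methylated
    state_p = np.array([1 - p_full - p_hemi, p_full, p_hemi / 2, p_hemi / 2])
    ref = params.tissues[0]
    for chrom in genome.chromosomes:
        n = ccgg_pos[chrom].size
        codes = rng.choice(4, size=n, p=state_p)
        internal[ref][chrom] = codes
        for tissue in params.tissues[1:]:
            flip = rng.random(n) < params.tissue_state_flip_prob
            tcodes = codes.copy()
            # a flip toggles internal methylation on/off (full <-> none)
            tcodes[flip & (codes != 0)] = 0
            tcodes[flip & (codes == 0)] = 1
            internal[tissue][chrom] = tcodes
        external[chrom] = np.where(
            codes != 0,
            rng.random(n) < params.p_external_chg,
            rng.random(n) < params.p_external_chg_solo,
        )
        blocked[chrom] = rng.random(psti_pos[chrom].size) < params.p_psti_blocked
    truth = SimTruth(psti_pos, ccgg_pos, blocked, internal, external)
    return genome, truth, FeatureSet(features).with_introns()


def _library_cuts(
    truth: SimTruth, tissue: str, chrom: str, library: str
) -> np.ndarray:
    """CCGG positions cut by the given library in the given tissue."""
    codes = truth.internal_state[tissue][chrom]
    ext = truth.external_chg[chrom]
    pos = truth.ccgg_positions[chrom]
    if library == "MspI":
        keep = ~ext
    else:  # HpaII: blocked by external CHG or any internal methylation
        keep = (~ext) & (codes == 0)
    return pos[keep]


def _walk_fragments(params: SimParams, truth: SimTruth, tissue: str, chrom: str,
                    library: str, chrom_length: int):
    """Yield (strand, psti_start, ccgg_start, tag_start, tag_end) fragments."""
    psti = truth.psti_positions[chrom][~truth.psti_blocked[chrom]]
    cuts = _library_cuts(truth, tissue, chrom, library)
    for p in psti:
        # rightward ('+') fragment: next cut of either enzyme after p
        nxt_c = cuts[np.searchsorted(cuts, p + 6)] if np.searchsorted(cuts, p + 6) < cuts.size else None
        nxt_p = psti[np.searchsorted(psti, p + 1)] if np.searchsorted(psti, p + 1) < psti.size else None
        if nxt_c is not None and (nxt_p is None or nxt_c < nxt_p):
            start, end = int(p) + 1, int(nxt_c) + 1
            if params.size_min <= end - start <= params.size_max:
                yield ("+", int(p), int(nxt_c), start, end)
        # leftward ('-') fragment: previous cut of either enzyme before p
        i_c = np.searchsorted(cuts, p) - 1
        prv_c = cuts[i_c] if i_c >= 0 else None
        i_p = np.searchsorted(psti, p) - 1
        prv_p = psti[i_p] if i_p >= 0 else None
        if prv_c is not None and (prv_p is None or prv_c > prv_p + 6):
            start, end = int(prv_c) + 3, int(p) + 5
            if params.size_min <= end - start <= params.size_max:
                yield ("-", int(p), int(prv_c), start, end)


def simulate_msdart(genome: GenomeSequence, truth: SimTruth, params: SimParams,
                    seed: int, emit_alignments: bool = True):
    """Sample library counts and emit read alignments plus expected counts.

    For every tissue, library and unblocked PstI site, the realized mixed
    fragment runs to the nearest CCGG the library can cut (methylation-
    skipped sites extend the fragment); fragments inside the size window are
    sequenceable, and each replicate draws its count from NB(depth *
    efficiency, dispersion) — dispersion 0 is the deterministic degenerate
    mode.  Reads start at the PstI boundary with length
    min(read_length, fragment length).  Fills ``truth.tags``/``truth.sites``
    with the union tag universe and returns (alignments, CountMatrix).
    """
    params.validate()
    rng = np.random.default_rng(seed)
    tag_index: dict[str, MSDTag] = {}
    site_index: dict[str, MSDSite] = {}
    columns = [
        (t, f"rep{r + 1}", lib)
        for t in params.tissues
        for r in range(params.replicates)
        for lib in ("MspI", "HpaII")
    ]
    counts: dict[str, np.ndarray] = {}
    alignments: list[AlignmentRecord] = []
    mean = params.read_depth * params.digestion_efficiency
    for chrom in genome.chromosomes:
        L = len(genome[chrom])
        for tissue in params.tissues:
            for lib in ("MspI", "HpaII"):
                for strand, p, c, start, end in _walk_fragments(
                    params, truth, tissue, chrom, lib, L
                ):
                    tid = tag_id_for(chrom, strand, start, end)
                    if tid not in tag_index:
                        sid = site_id_for(chrom, c)
                        if sid not in site_index:
                            site_index[sid] = MSDSite(sid, chrom, c)
                        site_index[sid].tag_ids.append(tid)
                        tag_index[tid] = MSDTag(tid, chrom, strand, start, end, p, sid)
                        counts[tid] = np.zeros(len(columns), dtype=np.int64)
                    frag_len = end - start
                    rl = min(params.read_length, frag_len)
                    for r in range(params.replicates):
                        if params.dispersion == 0:
                            n_reads = int(round(mean))
                        else:
                            lam = rng.gamma(1.0 / params.dispersion,
                                            mean * params.dispersion)
                            n_reads = int(rng.poisson(lam))
                        col = columns.index((tissue, f"rep{r + 1}", lib))
                        counts[tid][col] += n_reads
                        if emit_alignments:
                            if strand == "+":
                                a_start, a_end = start, start + rl
                            else:
                                a_start, a_end = end - rl, end
                            for _ in range(n_reads):
                                alignments.append(
                                    AlignmentRecord(chrom, a_start, a_end, strand,
                                                    (tissue, f"rep{r + 1}"), lib)
                                )
    tags = sorted(tag_index.values(), key=lambda t: (t.chrom, t.start, t.end, t.strand))
    sites = sorted(site_index.values(), key=lambda s: (s.chrom, s.ccgg_start))
    truth.tags = tags
    truth.sites = sites
    index = [t.tag_id for t in tags]
    mat = pd.DataFrame(
        np.vstack([counts[t] for t in index]) if index else np.zeros((0, len(columns)), dtype=np.int64),
        index=index,
        columns=pd.MultiIndex.from_tuples(columns, names=["tissue", "replicate", "library"]),
    )
    alignments.sort(key=lambda a: (a.chrom, a.start, a.end))
    return alignments, CountMatrix(mat)


def simulate_wgbs(
    genome: GenomeSequence, truth: SimTruth, params: SimParams, seed: int,
    tissue: str | None = None,
) -> list[CytosineRecord]:
    """Emit a bisulfite cytosine report for every CCGG cytosine.

    Four records per CCGG site: the internal CG pair and the external CHG
    pair on both strands.  Coverage is Poisson; methylated read counts are
    binomial with success 1 - bisulfite_error for truly methylated cytosines
    and the non-conversion rate otherwise.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    tissue = tissue or params.tissues[0]
    records: list[CytosineRecord] = []
    for chrom in genome.chromosomes:
        codes = truth.internal_state[tissue][chrom]
        ext = truth.external_chg[chrom]
        for pos, code, e in zip(truth.ccgg_positions[chrom], codes, ext):
            state = STATES[code]
            cytosines = (
                (int(pos) + 1, "+", "CG", state in ("fully", "hemi_plus")),
                (int(pos) + 2, "-", "CG", state in ("fully", "hemi_minus")),
                (int(pos), "+", "CHG", bool(e)),
                (int(pos) + 3, "-", "CHG", bool(e)),
            )
            for cpos, strand, context, is_meth in cytosines:
                cov = int(rng.poisson(params.wgbs_coverage))
                pi = 1.0 - params.bisulfite_error if is_meth else params.non_conversion_rate
                m = int(rng.binomial(cov, pi)) if cov > 0 else 0
                records.append(
                    CytosineRecord(chrom, cpos, strand, m, cov - m, context)
                )
    return records


def simulate_dataset(params: SimParams, seed: int):
    """Convenience wrapper: genome + truth + features + reads + WGBS report."""
    genome, truth, features = simulate_genome(params, seed)
    alignments, expected = simulate_msdart(genome, truth, params, seed + 1)
    report = simulate_wgbs(genome, truth, params, seed + 2)
    return genome, truth, features, alignments, expected, report
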