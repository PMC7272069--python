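"""Genomic-context classification of MSD-sites and comparative statistics.

Classification mirrors the genomic-context table of the assay: each site
falls in exactly one category (exon, intron/UTR, TE inside a gene, TE in
intergenic space, overlapping genes, TE overlapping a gene, or intergenic),
with the "feature overlap" buckets kept conservative because they often flag
annotation errors.  The statistical battery covers the tissue-comparison
workflow: Cochran's Q on matched binary methylation states, pairwise sign
tests with BH correction, chi-square association with Pearson standardized
residuals, a one-sided Fisher test for genic sampling bias, chi-square
window-uniformity tests, 10-kb vicinity profiles and an interval-shuffle
colocalization test with an empirical null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .io_formats import FeatureSet
from .stats_base import TestResult, bh_adjust
from .tagbuilder import MSDSite

CATEGORIES = (
    "gene_exon",
    "gene_intron_or_utr",
    "te_in_gene",
    "te_intergenic",
    "overlapping_genes",
    "te_overlapping_gene",
    "intergenic",
)


@dataclass
class ContextAnnotation:
    site_id: str
    category: str
    nearest_gene_distance: int
    nearest_te_distance: int
    gene_id: Optional[str] = None
    te_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.nearest_gene_distance < 0 or self.nearest_te_distance < 0:
            raise ValueError("distances must be >= 0")


@dataclass
class ColocResult:
    observed_intersections: int
    observed_bases: int
    shuffled_mean_intersections: float
    shuffled_sd_intersections: float
    shuffled_mean_bases: float
    shuffled_sd_bases: float
    p_intersections: float
    p_bases: float
    n_shuffles: int
    seed: int


# ---------------------------------------------------------------------------
# interval helpers


class _IntervalIndex:
    """Sorted-array interval index: overlap queries and edge-gap distances."""

    def __init__(self, intervals: Sequence[tuple[int, int, object]]):
        ivs = sorted(intervals)
        self.starts = np.array([iv[0] for iv in ivs], dtype=np.int64)
        self.ends = np.array([iv[1] for iv in ivs], dtype=np.int64)
        self.payload = [iv[2] for iv in ivs]
        # max end seen up to each index, for overlap scans
        self.max_end = np.maximum.accumulate(self.ends) if len(ivs) else self.ends

    def overlapping(self, start: int, end: int) -> list:
        if self.starts.size == 0:
            return []
        hi = int(np.searchsorted(self.starts, end, side="left"))
        out = []
        for i in range(hi - 1, -1, -1):
            if self.max_end[i] <= start:
                break
            if self.ends[i] > start:
                out.append(self.payload[i])
        return out[::-1]

    def nearest_distance(self, start: int, end: int) -> int:
        """Gap to the closest interval edge; 0 if overlapping; large if empty."""
        if self.starts.size == 0:
            return np.iinfo(np.int64).max
        if self.overlapping(start, end):
            return 0
        right = int(np.searchsorted(self.starts, end, side="left"))
        best = np.iinfo(np.int64).max
        if right < self.starts.size:
            best = min(best, int(self.starts[right] - end))
        left_ends = self.ends[:right]
        if left_ends.size:
            best = min(best, int(start - left_ends.max()))
        return max(best, 0)


def _index_features(features: FeatureSet, kind: str) -> dict[str, _IntervalIndex]:
    per_chrom: dict[str, list] = {}
    for f in features.by_kind(kind):
        per_chrom.setdefault(f.chrom, []).append((f.start, f.end, f))
    return {c: _IntervalIndex(v) for c, v in per_chrom.items()}


_EMPTY = _IntervalIndex([])


def classify_context(
    sites: Iterable[MSDSite],
    features: FeatureSet,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> list[ContextAnnotation]:
    """Assign each MSD-site (the CCGG interval) to one genomic category.

    Decision order: (1) inside two or more distinct genes -> overlapping
    genes; (2) inside a TE that intersects exon space or straddles a gene
    boundary -> TE overlapping gene; (3) inside one gene: exon (outside UTR)
    -> exon, otherwise intron/UTR, or TE-in-gene when the position is also
    inside a TE wholly contained in that gene's intron/UTR space; (4) inside
    a TE only -> intergenic TE; (5) otherwise intergenic.
    """
    genes = _index_features(features, "gene")
    exons = _index_features(features, "exon")
    utrs = _index_features(features, "UTR")
    tes = _index_features(features, "TE")
    out = []
    for site in sites:
        start, end = site.ccgg_start, site.ccgg_start + 4
        if chrom_lengths is not None:
            if end > chrom_lengths.get(site.chrom, np.iinfo(np.int64).max):
                raise ValueError(f"site {site.site_id} beyond chromosome end")
        g_idx = genes.get(site.chrom, _EMPTY)
        e_idx = exons.get(site.chrom, _EMPTY)
        u_idx = utrs.get(site.chrom, _EMPTY)
        t_idx = tes.get(site.chrom, _EMPTY)
        genes_hit = g_idx.overlapping(start, end)
        tes_hit = t_idx.overlapping(start, end)
        gene_id = genes_hit[0].id if genes_hit else None
        te_id = tes_hit[0].id if tes_hit else None
        if len(genes_hit) >= 2:
            category = "overlapping_genes"
        else:
            te_overlaps_gene = False
            te_wholly_intronic = False
            for te in tes_hit:
                te_genes = g_idx.overlapping(te.start, te.end)
                if not te_genes:
                    continue
                inside = any(
                    g.start <= te.start and te.end <= g.end for g in te_genes
                )
                hits_exonic = bool(
                    e_idx.overlapping(te.start, te.end)
                    or u_idx.overlapping(te.start, te.end)
                )
                if inside and not hits_exonic:
                    te_wholly_intronic = True
                else:
                    te_overlaps_gene = True
            if te_overlaps_gene:
                category = "te_overlapping_gene"
            elif genes_hit:
                in_utr = bool(u_idx.overlapping(start, end))
                in_exon = bool(e_idx.overlapping(start, end)) and not in_utr
                if in_exon:
                    category = "gene_exon"
                elif tes_hit and te_wholly_intronic:
                    category = "te_in_gene"
                else:
                    category = "gene_intron_or_utr"
            elif tes_hit:
                category = "te_intergenic"
            else:
                category = "intergenic"
        d_gene = g_idx.nearest_distance(start, end)
        d_te = t_idx.nearest_distance(start, end)
        out.append(
            ContextAnnotation(site.site_id, category, int(d_gene), int(d_te),
                              gene_id=gene_id, te_id=te_id)
        )
    return out


# ---------------------------------------------------------------------------
# profiles and enrichment tests


def vicinity_profile(
    annotations: Iterable[ContextAnnotation],
    background_distances: Sequence[int],
    max_dist: int = 10_000,
    bin_size: int = 1_000,
    which: str = "gene",
) -> tuple[np.ndarray, TestResult]:
    """Distance-to-nearest-feature profile of intergenic sites vs background.

    Bins the distances of intergenic sites to the nearest gene (or TE) into
    ``max_dist / bin_size`` bins and compares against expected counts from
    the background proportions (all CCGG sites binned identically) with a
    chi-square goodness-of-fit test; Pearson standardized residuals per bin
    are reported in the result's aux field.
    """
    n_bins = max_dist // bin_size
    dists = [
        a.nearest_gene_distance if which == "gene" else a.nearest_te_distance
        for a in annotations
        if a.category == "intergenic"
    ]
    dists = [d for d in dists if 0 < d <= max_dist]
    obs = np.zeros(n_bins)
    for d in dists:
        obs[min((d - 1) // bin_size, n_bins - 1)] += 1
    bg = np.asarray([d for d in background_distances if 0 < d <= max_dist])
    bg_counts = np.zeros(n_bins)
    for d in bg:
        bg_counts[min((d - 1) // bin_size, n_bins - 1)] += 1
    if bg_counts.sum() == 0:
        raise ValueError("empty background distance distribution")
    expected = obs.sum() * bg_counts / bg_counts.sum()
    floored = expected.copy()
    if np.any((floored == 0) & (obs > 0)):
        warnings.warn("empty background bin with nonzero observed; flooring expected")
        floored[(floored == 0) & (obs > 0)] = 0.5
        floored = floored * obs.sum() / floored.sum()
    keep = floored > 0
    chi2 = float(((obs[keep] - floored[keep]) ** 2 / floored[keep]).sum())
    df = int(keep.sum()) - 1
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    total = obs.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = np.where(
            floored > 0,
            (obs - floored) / np.sqrt(floored * (1 - floored / max(total, 1))),
            0.0,
        )
    return obs, TestResult(
        "chi2_gof_vicinity", chi2, p,
        aux={"df": df, "residuals": resid, "expected": expected},
    )


def genic_bias_fisher(
    n_genic_sampled: int,
    n_genic_total: int,
    n_intergenic_sampled: int,
    n_intergenic_total: int,
) -> TestResult:
    """One-sided Fisher test for sampling bias toward genic space."""
    cells = [
        [n_genic_sampled, n_genic_total - n_genic_sampled],
        [n_intergenic_sampled, n_intergenic_total - n_intergenic_sampled],
    ]
    if min(min(row) for row in cells) < 0:
        raise ValueError("negative derived cell in the 2x2 table")
    odds, p = stats.fisher_exact(cells, alternative="greater")
    return TestResult("fisher_one_sided", float(odds), float(p),
                      aux={"table": cells})


def window_uniformity_test(
    positions_by_chrom: dict[str, Sequence[int]],
    chrom_lengths: dict[str, int],
    window_size: int,
) -> TestResult:
    """Chi-square GOF of site counts per genomic window vs window lengths."""
    obs = []
    lengths = []
    n_sites = 0
    for chrom, length in chrom_lengths.items():
        pos = np.asarray(positions_by_chrom.get(chrom, ()), dtype=np.int64)
        n_sites += pos.size
        for w0 in range(0, length, window_size):
            w1 = min(w0 + window_size, length)
            obs.append(int(((pos >= w0) & (pos < w1)).sum()))
            lengths.append(w1 - w0)
    if len(obs) < 2:
        raise ValueError("need at least 2 windows")
    if n_sites < len(obs) * 5:
        warnings.warn("fewer than 5 sites per window on average; chi-square approximate")
    obs = np.asarray(obs, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    expected = obs.sum() * lengths / lengths.sum()
    chi2, p = stats.chisquare(obs, expected)
    return TestResult("chi2_window_uniformity", float(chi2), float(p),
                      aux={"df": len(obs) - 1, "n_windows": len(obs)})


# ---------------------------------------------------------------------------
# colocalization by interval shuffling


def _merge_intervals(ivs: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    if not ivs:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    ivs = sorted(ivs)
    starts, ends = [ivs[0][0]], [ivs[0][1]]
    for s, e in ivs[1:]:
        if s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


def _overlap_metrics(qs: np.ndarray, qe: np.ndarray, rs: np.ndarray, re_: np.ndarray):
    """(n intersection segments, total intersected bases) vs merged refs."""
    if rs.size == 0 or qs.size == 0:
        return 0, 0
    prefix = np.concatenate([[0], np.cumsum(re_ - rs)])
    lo = np.searchsorted(re_, qs, side="right")
    hi = np.searchsorted(rs, qe, side="left")
    n_pairs = np.maximum(hi - lo, 0)
    bases = prefix[hi] - prefix[lo]
    has = n_pairs > 0
    # trim the partially-overlapped first and last reference segments
    first_cut = np.where(has, np.maximum(qs - rs[np.minimum(lo, rs.size - 1)], 0), 0)
    last_cut = np.where(has, np.maximum(re_[np.maximum(hi - 1, 0)] - qe, 0), 0)
    bases = np.where(has, bases - first_cut - last_cut, 0)
    return int(n_pairs.sum()), int(np.maximum(bases, 0).sum())


def colocalization_shuffle(
    query_intervals: Sequence[tuple[str, int, int]],
    reference_intervals: Sequence[tuple[str, int, int]],
    chrom_lengths: dict[str, int],
    n_shuffles: int = 1000,
    seed: int = 0,
) -> ColocResult:
    """Empirical colocalization test by within-chromosome interval shuffling.

    Query intervals are repositioned uniformly within their own chromosome,
    preserving lengths and counts (overlaps permitted).  Metrics are the
    number of intersection segments against the merged reference set and the
    total intersected bases; p-values are empirical upper tails with +1/+1
    pseudocounts.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    refs_by_chrom: dict[str, list] = {}
    for chrom, s, e in reference_intervals:
        refs_by_chrom.setdefault(chrom, []).append((s, e))
    merged = {c: _merge_intervals(v) for c, v in refs_by_chrom.items()}
    q_by_chrom: dict[str, list] = {}
    for chrom, s, e in query_intervals:
        if e - s > chrom_lengths[chrom]:
            raise ValueError("query interval longer than its chromosome")
        q_by_chrom.setdefault(chrom, []).append((s, e))
    obs_n = obs_b = 0
    for chrom, ivs in q_by_chrom.items():
        rs, re_ = merged.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
        qs = np.asarray([s for s, _ in ivs], dtype=np.int64)
        qe = np.asarray([e for _, e in ivs], dtype=np.int64)
        n, b = _overlap_metrics(qs, qe, rs, re_)
        obs_n += n
        obs_b += b
    rng = np.random.default_rng(seed)
    sh_n = np.zeros(n_shuffles, dtype=np.int64)
    sh_b = np.zeros(n_shuffles, dtype=np.int64)
    for chrom, ivs in q_by_chrom.items():
        rs, re_ = merged.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
        lengths = np.asarray([e - s for s, e in ivs], dtype=np.int64)
        L = chrom_lengths[chrom]
        highs = L - lengths + 1
        starts = (rng.random((n_shuffles, lengths.size)) * highs[None, :]).astype(np.int64)
        for i in range(n_shuffles):
            n, b = _overlap_metrics(starts[i], starts[i] + lengths, rs, re_)
            sh_n[i] += n
            sh_b[i] += b
    p_n = (1 + int((sh_n >= obs_n).sum())) / (n_shuffles + 1)
    p_b = (1 + int((sh_b >= obs_b).sum())) / (n_shuffles + 1)
    return ColocResult(
        observed_intersections=obs_n,
        observed_bases=obs_b,
        shuffled_mean_intersections=float(sh_n.mean()),
        shuffled_sd_intersections=float(sh_n.std()),
        shuffled_mean_bases=float(sh_b.mean()),
        shuffled_sd_bases=float(sh_b.std()),
        p_intersections=p_n,
        p_bases=p_b,
        n_shuffles=n_shuffles,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# matched binary-state comparisons across tissues


def cochran_q(binary_matrix) -> TestResult:
    """Cochran's Q test on a sites x tissues binary matrix."""
    x = np.asarray(binary_matrix)
    if not np.isin(x, (0, 1)).all():
        raise ValueError("matrix entries must be 0/1")
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 columns")
    k = x.shape[1]
    col = x.sum(axis=0).astype(float)
    row = x.sum(axis=1).astype(float)
    n_total = x.sum()
    denom = k * row.sum() - (row ** 2).sum()
    if denom == 0:
        return TestResult("cochran_q", 0.0, 1.0, aux={"df": k - 1})
    q = k * (k - 1) * ((col - n_total / k) ** 2).sum() / denom
    p = float(stats.chi2.sf(q, k - 1))
    return TestResult("cochran_q", float(q), p, aux={"df": k - 1})


def wilcoxon_sign_pairwise(binary_matrix, labels: Optional[Sequence[str]] = None):
    """Exact pairwise sign tests on discordant rows, BH-corrected.

    Returns a list of TestResult, one per column pair, with the pair labels
    and the BH-adjusted p-value in aux.
    """
    x = np.asarray(binary_matrix)
    if not np.isin(x, (0, 1)).all():
        raise ValueError("matrix entries must be 0/1")
    k = x.shape[1]
    labels = list(labels) if labels is not None else [str(i) for i in range(k)]
    results = []
    pvals = []
    for i in range(k):
        for j in range(i + 1, k):
            b = int(((x[:, i] == 1) & (x[:, j] == 0)).sum())
            c = int(((x[:, i] == 0) & (x[:, j] == 1)).sum())
            n = b + c
            p = 1.0 if n == 0 else float(stats.binomtest(b, n, 0.5).pvalue)
            results.append(
                TestResult("sign_test", float(b - c), p,
                           aux={"pair": (labels[i], labels[j]), "n_discordant": n})
            )
            pvals.append(p)
    for r, q in zip(results, bh_adjust(pvals)):
        r.aux["fdr"] = float(q)
    return results


def category_association_test(contingency) -> TestResult:
    """Chi-square independence test with Pearson standardized residuals."""
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need a table with >= 2 rows and >= 2 columns")
    if (table < 0).any():
        raise ValueError("counts must be >= 0")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero marginal in contingency table")
    n = table.sum()
    expected = np.outer(row, col) / n
    chi2 = float(((table - expected) ** 2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df))
    resid = (table - expected) / np.sqrt(
        expected * (1 - row / n)[:, None] * (1 - col / n)[None, :]
    )
    return TestResult("chi2_independence", chi2, p,
                      aux={"df": df, "residuals": resid, "expected": expected})


# ---------------------------------------------------------------------------
# methylated feature roll-up


@dataclass
class FeatureRollup:
    genes_per_tissue: dict[str, set]
    tes_per_tissue: dict[str, set]
    gene_intersections: dict[tuple, int] = field(default_factory=dict)
    te_intersections: dict[tuple, int] = field(default_factory=dict)


def _venn(sets: dict[str, set]) -> dict[tuple, int]:
    from itertools import combinations

    out = {}
    names = list(sets)
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inter = set.intersection(*(sets[n] for n in combo)) if combo else set()
            out[combo] = len(inter)
    return out


def rollup_methylated_features(
    annotations: Iterable[ContextAnnotation],
    methylated_sites_per_tissue: dict[str, set],
) -> FeatureRollup:
    """Per-tissue sets of methylated genes/TEs (>= 1 methylated site) + Venn."""
    ann = list(annotations)
    genes_per: dict[str, set] = {}
    tes_per: dict[str, set] = {}
    for tissue, site_ids in methylated_sites_per_tissue.items():
        genes_per[tissue] = {
            a.gene_id for a in ann if a.site_id in site_ids and a.gene_id
        }
        tes_per[tissue] = {
            a.te_id for a in ann if a.site_id in site_ids and a.te_id
        }
    return FeatureRollup(
        genes_per_tissue=genes_per,
        tes_per_tissue=tes_per,
        gene_intersections=_venn(genes_per),
        te_intersections=_venn(tes_per),
    )
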