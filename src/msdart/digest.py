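"""In silico restriction digestion.

Locates recognition sites for methylation-relevant restriction enzymes,
predicts double-digest ("mixed") fragments anchored by a rare cutter (PstI)
on one end and a frequent cutter (MspI/HpaII) on the other, and computes the
fragment-size statistics and bootstrap Kolmogorov-Smirnov distribution
comparison used to assess genome-reduction representativeness.

All enzymes supported in v1 are palindromic, so scanning the forward strand
finds every site.  Cut offsets are part of :class:`EnzymeDef` and measured
from the recognition start on the top strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .io_formats import GenomeSequence
from .stats_base import TestResult

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class EnzymeDef:
    """A restriction enzyme: recognition sequence, cut offsets, 5mC blocking.

    ``cut_top``/``cut_bottom`` are offsets of the cleaved phosphodiester bond
    from the recognition start, top and bottom strand.  The sensitivity flags
    describe blocking by 5mC at the internal (CG-context) or external
    (CHG-context) cytosine of the CCGG-style site.
    """

    name: str
    recognition: str
    cut_top: int
    cut_bottom: int
    blocked_by_internal_5mC: bool = False
    blocked_by_external_5mC: bool = False

    def __post_init__(self) -> None:
        if len(self.recognition) < 4:
            raise ValueError("recognition length must be >= 4")
        if not set(self.recognition) <= set(IUPAC):
            raise ValueError(f"bad recognition sequence {self.recognition!r}")
        for off in (self.cut_top, self.cut_bottom):
            if not 0 <= off <= len(self.recognition):
                raise ValueError("cut offset outside recognition sequence")

    def is_palindromic(self) -> bool:
        rc = self.recognition.translate(_COMPLEMENT)[::-1]
        return rc == self.recognition


# Standard enzymology; offsets follow the assay convention: PstI CTGCA^G,
# MspI/HpaII C^CGG.  MspI is insensitive to internal-C methylation, HpaII is
# blocked by it; both are blocked by external-C (CHG) methylation.
PSTI = EnzymeDef("PstI", "CTGCAG", cut_top=5, cut_bottom=1)
MSPI = EnzymeDef("MspI", "CCGG", cut_top=1, cut_bottom=3,
                 blocked_by_internal_5mC=False, blocked_by_external_5mC=True)
HPAII = EnzymeDef("HpaII", "CCGG", cut_top=1, cut_bottom=3,
                  blocked_by_internal_5mC=True, blocked_by_external_5mC=True)
BAMHI = EnzymeDef("BamHI", "GGATCC", cut_top=1, cut_bottom=5)
ECORI = EnzymeDef("EcoRI", "GAATTC", cut_top=1, cut_bottom=5)

ENZYMES = {e.name: e for e in (PSTI, MSPI, HPAII, BAMHI, ECORI)}


@dataclass
class RestrictionSiteMap:
    """Per-chromosome, per-enzyme sorted recognition-start positions."""

    sites: dict[str, dict[str, np.ndarray]]
    enzymes: dict[str, EnzymeDef] = field(default_factory=dict)

    def positions(self, chrom: str, enzyme: str) -> np.ndarray:
        return self.sites.get(chrom, {}).get(enzyme, np.empty(0, dtype=np.int64))

    @property
    def chromosomes(self) -> list[str]:
        return list(self.sites)


@dataclass(frozen=True)
class PredictedFragment:
    chrom: str
    start: int
    end: int
    left_enzyme: str
    right_enzyme: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("fragment with start >= end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SizeStats:
    n: int
    mean: float
    sd: float
    cv: float
    deciles: np.ndarray  # 1st..9th

    def __post_init__(self) -> None:
        if np.any(np.diff(self.deciles) < 0):
            raise ValueError("deciles must be non-decreasing")


def _pattern(enzyme: EnzymeDef) -> re.Pattern:
    body = "".join(
        c if len(IUPAC[c]) == 1 else "[" + IUPAC[c] + "]" for c in enzyme.recognition
    )
    return re.compile(f"(?=({body}))")  # lookahead: overlapping occurrences


def find_sites(genome: GenomeSequence, enzymes: list[EnzymeDef]) -> RestrictionSiteMap:
    """Scan the forward strand for every recognition occurrence per enzyme.

    Only palindromic enzymes are supported, which makes reverse-strand
    scanning redundant; overlapping occurrences are all reported.
    """
    for enz in enzymes:
        if not enz.is_palindromic():
            raise ValueError(f"{enz.name}: non-palindromic enzymes unsupported in v1")
    sites: dict[str, dict[str, np.ndarray]] = {}
    for chrom in genome.chromosomes:
        seq = genome[chrom]
        per = {}
        for enz in enzymes:
            pat = _pattern(enz)
            per[enz.name] = np.fromiter(
                (m.start() for m in pat.finditer(seq)), dtype=np.int64
            )
        sites[chrom] = per
    return RestrictionSiteMap(sites, {e.name: e for e in enzymes})


def predict_fragments(
    sites: RestrictionSiteMap,
    rare: EnzymeDef,
    frequent: EnzymeDef,
    size_min: int | None = None,
    size_max: int | None = None,
    coordinates: str = "cut",
) -> list[PredictedFragment]:
    """Predict double-digest fragments flanked by two *different* enzymes.

    Cut positions of both enzymes are merged per chromosome (leftmost-cut
    sweep); adjacent cut pairs from different enzymes yield mixed fragments.
    ``coordinates="cut"`` places boundaries at the top-strand cut positions;
    ``coordinates="tag"`` uses the read-strand retained sequence convention
    (a rightward fragment begins at PstI start+1 and ends at CCGG start+1),
    matching MSD-tag intervals.
    """
    if size_min is not None and size_max is not None and size_min > size_max:
        raise ValueError("size_min > size_max")
    if coordinates not in ("cut", "tag"):
        raise ValueError("coordinates must be 'cut' or 'tag'")
    frags: list[PredictedFragment] = []
    for chrom in sites.chromosomes:
        rp = sites.positions(chrom, rare.name)
        fp = sites.positions(chrom, frequent.name)
        cuts = np.concatenate([rp + rare.cut_top, fp + frequent.cut_top])
        labels = np.concatenate(
            [np.zeros(len(rp), dtype=int), np.ones(len(fp), dtype=int)]
        )
        recog = np.concatenate([rp, fp])
        order = np.argsort(cuts, kind="stable")
        cuts, labels, recog = cuts[order], labels[order], recog[order]
        names = (rare.name, frequent.name)
        for i in range(len(cuts) - 1):
            if labels[i] == labels[i + 1]:
                continue
            if coordinates == "cut":
                start, end = int(cuts[i]), int(cuts[i + 1])
            else:
                # read-strand retained: fragment keeps the PstI remnant base
                # and runs to the frequent cutter's top cut
                if labels[i] == 0:  # rare on the left: '+' orientation tag
                    start = int(recog[i]) + 1
                    end = int(recog[i + 1]) + frequent.cut_top
                else:  # rare on the right: '-' orientation tag
                    start = int(recog[i]) + frequent.cut_bottom
                    end = int(recog[i + 1]) + rare.cut_top
            if start >= end:
                continue
            length = end - start
            if size_min is not None and length < size_min:
                continue
            if size_max is not None and length > size_max:
                continue
            frags.append(
                PredictedFragment(chrom, start, end,
                                  names[labels[i]], names[labels[i + 1]])
            )
    return frags


def single_enzyme_fragments(
    sites: RestrictionSiteMap, enzyme: EnzymeDef, chrom_lengths: dict[str, int]
) -> list[PredictedFragment]:
    """Complete single-enzyme digestion; fragments tile each chromosome."""
    frags = []
    for chrom, length in chrom_lengths.items():
        cuts = sites.positions(chrom, enzyme.name) + enzyme.cut_top
        cuts = cuts[(cuts > 0) & (cuts < length)]
        bounds = np.concatenate([[0], cuts, [length]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            if a < b:
                frags.append(PredictedFragment(chrom, int(a), int(b),
                                               enzyme.name, enzyme.name))
    return frags


def fragment_size_stats(lengths) -> SizeStats:
    """Mean, sample sd, CV and the nine deciles (linear-interpolation)."""
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        raise ValueError("empty length list")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    cv = sd / mean if mean != 0 else float("nan")
    deciles = np.quantile(arr, np.arange(1, 10) / 10.0, method="linear")
    return SizeStats(n=int(arr.size), mean=mean, sd=sd, cv=cv, deciles=deciles)


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    grid = np.concatenate([a, b])
    grid.sort(kind="mergesort")
    ca = np.searchsorted(np.sort(a), grid, side="right") / a.size
    cb = np.searchsorted(np.sort(b), grid, side="right") / b.size
    return float(np.abs(ca - cb).max())


def ks_bootstrap_test(
    sizes_a, sizes_b, n_boot: int = 1000, seed: int = 0
) -> TestResult:
    """Two-sample KS test with a bootstrap p-value suitable for discrete data.

    The null distribution of D is approximated by pooled-sample resampling
    with replacement (sample sizes preserved); the p-value carries a +1/+1
    continuity correction, so it is bounded below by 1/(n_boot + 1).
    """
    a = np.asarray(sizes_a, dtype=float)
    b = np.asarray(sizes_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    d_obs = _ks_statistic(a, b)
    pool = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    na, nb = a.size, b.size
    # vectorised resampling: one (n_boot x (na+nb)) index draw
    idx = rng.integers(0, pool.size, size=(n_boot, na + nb))
    samples = pool[idx]
    sa = np.sort(samples[:, :na], axis=1)
    sb = np.sort(samples[:, na:], axis=1)
    grid = np.sort(samples, axis=1)
    hits = 0
    for i in range(n_boot):  # per-row searchsorted; rows are independent
        ca = np.searchsorted(sa[i], grid[i], side="right") / na
        cb = np.searchsorted(sb[i], grid[i], side="right") / nb
        if np.abs(ca - cb).max() >= d_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_boot + 1)
    return TestResult("ks_bootstrap", d_obs, min(1.0, p),
                      aux={"n_boot": n_boot, "seed": seed})
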