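"""Bisulfite (WGBS) methylation calling and MSD-site validation.

Per-cytosine calls use an upper-tail binomial test whose null success
probability is the bisulfite non-conversion rate; BH correction runs across
every cytosine in the report (the whole methylome is called first, then
MSD-sites are looked up).  A CCGG MSD-site is classified from its two
strand-symmetric internal (CG-context) cytosines: both methylated ->
fully methylated, exactly one -> hemi (side recorded), neither ->
unmethylated; sites lacking >= min_reads coverage on either strand are not
assessable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy.stats import binom

from .caller import MethylationCall
from .io_formats import CytosineRecord
from .stats_base import bh_adjust
from .tagbuilder import MSDSite

METHYLATED_STATES = frozenset({"fully_methylated", "hemi_plus", "hemi_minus"})


@dataclass
class CytosineCall:
    record: CytosineRecord
    p_value: float
    fdr: float
    call: str  # methylated | unmethylated | no_call


@dataclass
class SiteMethylationState:
    site_id: str
    state: str  # fully_methylated | hemi_plus | hemi_minus | unmethylated | not_assessable


@dataclass
class ConcordanceReport:
    n_msd_called: int
    n_covered_by_wgbs: int
    n_confirmed: int
    n_fully: int
    n_hemi: int

    @property
    def precision(self) -> Optional[float]:
        if self.n_covered_by_wgbs == 0:
            return None
        return self.n_confirmed / self.n_covered_by_wgbs


def binomial_tail(count_methylated: int, count_total: int, rate: float) -> float:
    """Upper-tail P(X >= m | n, rate); the per-cytosine null p-value."""
    if count_total == 0:
        return 1.0
    return float(binom.sf(count_methylated - 1, count_total, rate))


def call_cytosines(
    records: Iterable[CytosineRecord],
    non_conversion_rate: float,
    alpha: float = 0.01,
    min_reads: int = 3,
) -> list[CytosineCall]:
    """Binomial methylation call per cytosine with BH across the whole report."""
    if not (0.0 < non_conversion_rate < 1.0):
        raise ValueError("non_conversion_rate must lie strictly in (0, 1)")
    records = list(records)
    pvals = np.array(
        [binomial_tail(r.count_methylated, r.count_total, non_conversion_rate)
         for r in records]
    )
    fdrs = bh_adjust(pvals) if len(records) else pvals
    calls = []
    for r, p, q in zip(records, pvals, fdrs):
        if r.count_total < min_reads:
            call = "no_call"
        elif q <= alpha:
            call = "methylated"
        else:
            call = "unmethylated"
        calls.append(CytosineCall(r, float(p), float(q), call))
    return calls


def classify_sites(
    sites: Iterable[MSDSite],
    calls: Iterable[CytosineCall],
    min_reads: int = 3,
) -> list[SiteMethylationState]:
    """Classify each MSD-site from its internal CG cytosines' WGBS calls."""
    index: dict[tuple[str, int, str], CytosineCall] = {}
    for c in calls:
        if c.record.context == "CG":
            index[(c.record.chrom, c.record.pos, c.record.strand)] = c
    out = []
    for site in sites:
        (pos_p, str_p), (pos_m, str_m) = site.internal_cytosines
        call_p = index.get((site.chrom, pos_p, str_p))
        call_m = index.get((site.chrom, pos_m, str_m))
        covered = (
            call_p is not None and call_p.record.count_total >= min_reads
            and call_m is not None and call_m.record.count_total >= min_reads
        )
        if not covered:
            state = "not_assessable"
        else:
            meth_p = call_p.call == "methylated"
            meth_m = call_m.call == "methylated"
            if meth_p and meth_m:
                state = "fully_methylated"
            elif meth_p:
                state = "hemi_plus"
            elif meth_m:
                state = "hemi_minus"
            else:
                state = "unmethylated"
        out.append(SiteMethylationState(site.site_id, state))
    return out


def concordance(
    msd_calls: list[MethylationCall],
    states: list[SiteMethylationState],
    site_rule: str = "any",
) -> ConcordanceReport:
    """Compare MSD-methylated sites with their WGBS states.

    The denominator is restricted to MSD-methylated sites assessable by
    WGBS; a site is confirmed when WGBS finds it fully or hemi methylated.
    An empty denominator yields precision None, not an exception.
    """
    from .caller import methylated_sites

    state_of = {s.site_id: s.state for s in states}
    called = methylated_sites(msd_calls, rule=site_rule)
    covered = {
        s for s in called if state_of.get(s, "not_assessable") != "not_assessable"
    }
    confirmed = {s for s in covered if state_of[s] in METHYLATED_STATES}
    n_fully = sum(1 for s in confirmed if state_of[s] == "fully_methylated")
    return ConcordanceReport(
        n_msd_called=len(called),
        n_covered_by_wgbs=len(covered),
        n_confirmed=len(confirmed),
        n_fully=n_fully,
        n_hemi=len(confirmed) - n_fully,
    )
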