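"""Summary tables, rates, and the variance-ratio (F) test.

Reported rates use half-up rounding at the requested precision; raw
values are always retained so every printed number can be recomputed
from its integer inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

#: the rearrangement categories of the hybrid-diploid summary
DEFAULT_CATEGORIES = (
    "SNV",
    "insertion",
    "deletion",
    "aneuploid",
    "BIR",
    "SGC",
    "TL_non_homologous",
    "TL_homologous",
)


def round_half_up(x: float, decimals: int) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SummaryTable:
    frame: pd.DataFrame
    rounding: str = "half_up"
    metadata: dict = field(default_factory=dict)


def tally_events(
    events: list,
    categories: tuple[str, ...] = DEFAULT_CATEGORIES,
    category_of: dict[str, str] | None = None,
) -> pd.Series:
    """Event counts per category.

    ``events`` are truth or call objects with ``type`` (and optionally
    ``mechanism``) attributes, or plain category strings.  Translocation
    events split into non-homologous vs homologous by mechanism; InDel
    events split into insertion/deletion when a ``net`` attribute or an
    explicit mapping says which.
    """
    counts = {c: 0 for c in categories}
    for ev in events:
        if isinstance(ev, str):
            cat = ev
        else:
            etype = getattr(ev, "type")
            mech = getattr(ev, "mechanism", None)
            if etype == "TL":
                cat = "TL_homologous" if mech == "homologous" else "TL_non_homologous"
            elif etype in ("aneuploidy_gain", "aneuploidy_loss"):
                cat = "aneuploid"
            elif etype == "InDel":
                cat = "insertion"
            elif etype == "tandem_duplication":
                cat = "insertion"
            else:
                cat = etype
            if category_of and etype in category_of:
                cat = category_of[etype]
        if cat not in counts:
            raise ValueError(f"unknown category {cat!r}")
        counts[cat] += 1
    return pd.Series(counts, name="events")


def rate_per_individual(event_count: int, n_individuals: int, decimals: int = 3) -> float:
    """Events per individual, half-up rounded (e.g. 22/80 -> 0.275)."""
    if n_individuals == 0:
        raise ValueError("n_individuals must be positive")
    return round_half_up(event_count / n_individuals, decimals)


def percent_with_event(n_with: int, n_total: int, decimals: int = 1) -> float:
    """Percentage of individuals with >=1 event (e.g. 37/80 -> 46.3)."""
    if n_total == 0:
        raise ValueError("n_total must be positive")
    return round_half_up(100.0 * n_with / n_total, decimals)


def summary_table(
    rows: list[tuple[str, int, int, int]], decimals_rate: int = 3, decimals_pct: int = 1
) -> SummaryTable:
    """Rows of (category, event_count, n_with_event, n_total) -> rates table."""
    out = []
    for category, count, n_with, n_total in rows:
        out.append(
            {
                "category": category,
                "events": count,
                "individuals_with_event": n_with,
                "individuals_total": n_total,
                "rate_per_individual": rate_per_individual(count, n_total, decimals_rate),
                "rate_raw": count / n_total,
                "percent_with_event": percent_with_event(n_with, n_total, decimals_pct),
                "percent_raw": 100.0 * n_with / n_total,
            }
        )
    return SummaryTable(frame=pd.DataFrame(out), metadata={"rounding": "half_up"})


def variance_ratio_test(
    sample_a=None,
    sample_b=None,
    var_a: float | None = None,
    n_a: int | None = None,
    var_b: float | None = None,
    n_b: int | None = None,
    larger_over_smaller: bool = False,
) -> tuple[float, float, float]:
    """Two-sided F-test of equal variances.

    Accepts raw samples or (variance, n) summaries.  Returns
    ``(ratio, F, p)`` with ratio = varA/varB (optionally the larger over
    the smaller) and the two-sided p-value from F(nA-1, nB-1).
    """
    if sample_a is not None:
        sample_a = np.asarray(sample_a, dtype=float)
        var_a, n_a = float(sample_a.var(ddof=1)), len(sample_a)
    if sample_b is not None:
        sample_b = np.asarray(sample_b, dtype=float)
        var_b, n_b = float(sample_b.var(ddof=1)), len(sample_b)
    if None in (var_a, n_a, var_b, n_b):
        raise ValueError("need samples or (variance, n) for both groups")
    if var_b == 0 or (larger_over_smaller and min(var_a, var_b) == 0):
        raise ValueError("zero variance in denominator")
    if larger_over_smaller and var_b > var_a:
        var_a, var_b = var_b, var_a
        n_a, n_b = n_b, n_a
    ratio = var_a / var_b
    f_stat = ratio
    dist = stats.f(n_a - 1, n_b - 1)
    p = 2.0 * min(dist.cdf(f_stat), dist.sf(f_stat))
    return ratio, f_stat, min(p, 1.0)


def export_circular_links(
    calls: list,
    chrom_lengths: dict[tuple[str, str], int],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Karyotype and BEDPE-compatible link tables for circular plots.

    ``calls`` may mix junction calls (``junction`` attribute or
    ``locus_a``/``locus_b``) and homolog events (BIR links run from the
    breakpoint to the homolog chromosome end).  Unknown chromosomes are
    an error.
    """
    karyotype = pd.DataFrame(
        [
            {"chrom": f"{h}_{c}", "length": l, "parent": h}
            for (h, c), l in chrom_lengths.items()
        ]
    )
    links = []
    for call in calls:
        junc = getattr(call, "junction", call)
        if hasattr(junc, "locus_a"):
            la, lb = junc.locus_a, junc.locus_b
            ends = [
                (la.haplotype, la.chrom, la.pos, la.pos + 1),
                (lb.haplotype, lb.chrom, lb.pos, lb.pos + 1),
            ]
            name = getattr(getattr(call, "mechanism", None), "mechanism", "junction")
        elif getattr(call, "type", None) in ("BIR", "SGC"):
            end_pos = (
                chrom_lengths[(call.donor_haplotype, call.donor_chrom)]
                if call.type == "BIR"
                else call.end
            )
            ends = [
                (call.acceptor_haplotype, call.chrom, call.start, call.start + 1),
                (call.donor_haplotype, call.donor_chrom, max(0, end_pos - 1), end_pos),
            ]
            name = call.type
        else:
            continue
        for h, c, _s, _e in ends:
            if (h, c) not in chrom_lengths:
                raise ValueError(f"call references unknown chromosome {h}_{c}")
        links.append(
            {
                "chrom1": f"{ends[0][0]}_{ends[0][1]}",
                "start1": ends[0][2],
                "end1": ends[0][3],
                "chrom2": f"{ends[1][0]}_{ends[1][1]}",
                "start2": ends[1][2],
                "end2": ends[1][3],
                "name": name,
            }
        )
    links_df = pd.DataFrame(
        links, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name"]
    )
    return karyotype, links_df
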