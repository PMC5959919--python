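"""Post-filters for raw small-variant calls.

Two rule sets, applied downstream of external variant callers:

* yeast (hybrid diploid resequencing): drop calls in AT-rich, rDNA and
  telomeric masks, calls in regions below 50% of the sample's average
  coverage, and calls shared by every sample (systematic artefacts).
* plant (reference-based resequencing vs a control): drop control-shared
  calls, keep allele frequency strictly > 0.4; InDels additionally need
  fewer than 2 supporting reads in the control and locus uniqueness (no
  second candidate InDel within the record's footprint); SNVs at
  multi-allelic loci are excluded.

Every rule is a pure predicate on one record (plus fixed side tables),
so the survivor set is independent of rule application order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: required columns of a call table
CALL_COLUMNS = ["chrom", "pos", "ref", "alt", "type", "depth", "alt_count", "sample"]


def _validate(calls: pd.DataFrame) -> pd.DataFrame:
    missing = set(CALL_COLUMNS) - set(calls.columns)
    if missing:
        raise ValueError(f"call table missing columns {sorted(missing)}")
    bad = (calls["alt_count"] < 0) | (calls["alt_count"] > calls["depth"])
    if bad.any():
        raise ValueError("alt_count outside [0, depth]")
    return calls


def variant_frequency(calls: pd.DataFrame) -> pd.Series:
    return calls["alt_count"] / calls["depth"]


@dataclass
class FilterReport:
    """Per-rule removal counts; survivors = input − sum(removed by any rule)."""

    n_input: int
    removed_by_rule: dict[str, int] = field(default_factory=dict)
    n_survivors: int = 0
    notes: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": k, "removed": v} for k, v in self.removed_by_rule.items()]
        rows.append({"rule": "survivors", "removed": self.n_survivors})
        return pd.DataFrame(rows)


def _in_masks(
    calls: pd.DataFrame, masks: dict[str, list[tuple[int, int]]]
) -> pd.Series:
    flags = np.zeros(len(calls), dtype=bool)
    for i, (chrom, pos) in enumerate(zip(calls["chrom"], calls["pos"])):
        for s, e in masks.get(chrom, []):
            if s <= pos < e:
                flags[i] = True
                break
    return pd.Series(flags, index=calls.index)


def filter_yeast_variants(
    calls: pd.DataFrame,
    coverage_ratio: pd.Series | None = None,
    masks: dict[str, list[tuple[int, int]]] | None = None,
    all_samples: list[str] | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Hybrid-diploid post-filter.

    ``coverage_ratio`` is each record's local coverage over its sample's
    genome-average coverage (column ``coverage_ratio`` of ``calls`` may
    carry it instead); records strictly below 0.5 are removed.
    ``all_samples`` lists every sequenced sample; a variant key present
    in all of them is removed as a shared artefact.
    """
    calls = _validate(calls)
    if coverage_ratio is None:
        if "coverage_ratio" not in calls.columns:
            raise ValueError("coverage statistics required (coverage_ratio)")
        coverage_ratio = calls["coverage_ratio"]
    masks = masks or {}
    report = FilterReport(n_input=len(calls))

    in_mask = _in_masks(calls, masks)
    low_cov = coverage_ratio < 0.5

    if all_samples is None:
        all_samples = sorted(calls["sample"].unique())
    if len(all_samples) >= 2:
        key = calls[["chrom", "pos", "ref", "alt"]].apply(tuple, axis=1)
        samples_per_key = (
            pd.DataFrame({"key": key, "sample": calls["sample"]})
            .groupby("key")["sample"]
            .nunique()
        )
        universal = key.map(samples_per_key) >= len(all_samples)
    else:
        universal = pd.Series(False, index=calls.index)

    report.removed_by_rule = {
        "masked_region": int(in_mask.sum()),
        "low_coverage": int(low_cov.sum()),
        "common_in_all_samples": int(universal.sum()),
    }
    keep = ~(in_mask | low_cov | universal)
    survivors = calls[keep].copy()
    report.n_survivors = len(survivors)
    return survivors, report


def filter_plant_variants(
    calls: pd.DataFrame,
    control_calls: pd.DataFrame,
    control_indel_reads: dict[tuple[str, int], int] | None = None,
    uniqueness_window: int = 10,
) -> tuple[pd.DataFrame, FilterReport]:
    """Control-subtracted plant post-filter.

    Rules: (1) drop calls whose (chrom, pos, ref, alt) occurs in the
    control; (2) keep allele frequency strictly > 0.4; (3) InDels need
    < 2 control reads containing an InDel at the locus — an InDel with
    no control-evidence entry is held back as unresolved, not passed —
    and locus uniqueness: no other candidate InDel within
    ``uniqueness_window`` bp; (4) SNVs at loci with more than one ALT
    candidate (multi-allelic) are excluded.
    """
    calls = _validate(calls)
    control_indel_reads = control_indel_reads or {}
    report = FilterReport(n_input=len(calls))

    ctrl_keys = set(
        map(tuple, control_calls[["chrom", "pos", "ref", "alt"]].itertuples(index=False))
    )
    in_control = calls[["chrom", "pos", "ref", "alt"]].apply(
        lambda r: tuple(r) in ctrl_keys, axis=1
    )
    low_freq = variant_frequency(calls) <= 0.4

    is_indel = calls["type"] == "InDel"
    ctrl_reads = calls.apply(
        lambda r: control_indel_reads.get((r["chrom"], r["pos"])), axis=1
    )
    indel_unresolved = is_indel & ctrl_reads.isna()
    indel_ctrl_fail = is_indel & ~ctrl_reads.isna() & (ctrl_reads >= 2)

    not_unique = pd.Series(False, index=calls.index)
    indels = calls[is_indel]
    for i, row in indels.iterrows():
        near = indels[
            (indels["chrom"] == row["chrom"])
            & (indels.index != i)
            & ((indels["pos"] - row["pos"]).abs() <= uniqueness_window)
        ]
        if len(near):
            not_unique[i] = True

    is_snv = calls["type"] == "SNV"
    alts_per_locus = calls[is_snv].groupby(["chrom", "pos"])["alt"].nunique()
    multi = pd.Series(False, index=calls.index)
    snv_keys = list(zip(calls.loc[is_snv, "chrom"], calls.loc[is_snv, "pos"]))
    multi.loc[is_snv] = np.array([alts_per_locus.get(k, 0) > 1 for k in snv_keys], dtype=bool)

    report.removed_by_rule = {
        "in_control": int(in_control.sum()),
        "frequency_le_0.4": int(low_freq.sum()),
        "indel_control_reads_ge_2": int(indel_ctrl_fail.sum()),
        "indel_control_evidence_missing": int(indel_unresolved.sum()),
        "indel_not_unique": int(not_unique.sum()),
        "snv_multiallelic_locus": int(multi.sum()),
    }
    report.notes["indel_uniqueness_window_bp"] = uniqueness_window
    keep = ~(in_control | low_freq | indel_ctrl_fail | indel_unresolved | not_unique | multi)
    survivors = calls[keep].copy()
    report.n_survivors = len(survivors)
    return survivors, report


def at_rich_mask(
    sequences: dict[str, str], window: int = 100, at_fraction: float = 0.80
) -> dict[str, list[tuple[int, int]]]:
    """Windows with A+T fraction above the cutoff, merged when adjacent.

    Convenience for runs without a curated AT-rich BED; the choice of
    window and cutoff is deliberately explicit and overridable.
    """
    masks: dict[str, list[tuple[int, int]]] = {}
    for chrom, seq in sequences.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_at = (arr == ord("A")) | (arr == ord("T"))
        n_win = len(seq) // window
        out: list[tuple[int, int]] = []
        for w in range(n_win):
            frac = is_at[w * window : (w + 1) * window].mean()
            if frac > at_fraction:
                s, e = w * window, (w + 1) * window
                if out and out[-1][1] == s:
                    out[-1] = (out[-1][0], e)
                else:
                    out.append((s, e))
        if out:
            masks[chrom] = out
    return masks
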