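"""Small-variant post-filters against brute-force rule application."""

import itertools

import numpy as np
import pandas as pd
import pytest

from taqsv.filters import (
    at_rich_mask,
    filter_plant_variants,
    filter_yeast_variants,
)


def make_calls(rows):
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "type", "depth", "alt_count", "sample"],
    )


def test_yeast_low_coverage_boundary_is_strict():
    calls = make_calls([("c1", 10, "A", "G", "SNV", 40, 30, "s1")])
    survivors, _ = filter_yeast_variants(calls, coverage_ratio=pd.Series([0.49]))
    assert len(survivors) == 0  # 0.49 < 0.5 removed
    survivors, _ = filter_yeast_variants(calls, coverage_ratio=pd.Series([0.50]))
    assert len(survivors) == 1  # exactly 0.5 kept


def test_yeast_universal_variant_removed():
    rows = [("c1", 5, "A", "T", "SNV", 50, 40, f"s{i}") for i in range(14)]
    rows.append(("c1", 9, "G", "C", "SNV", 50, 40, "s3"))
    calls = make_calls(rows)
    survivors, report = filter_yeast_variants(
        calls, coverage_ratio=pd.Series(np.ones(len(calls))),
        all_samples=[f"s{i}" for i in range(14)],
    )
    assert report.removed_by_rule["common_in_all_samples"] == 14
    assert list(survivors["pos"]) == [9]


def test_yeast_toy_table_matches_brute_force():
    """10 records: 3 masked, 2 low-coverage, 1 universal -> 4 survive."""
    masks = {"c1": [(100, 200)]}
    samples = ["s1", "s2"]
    rows = [
        ("c1", 150, "A", "G", "SNV", 50, 30, "s1"),   # masked
        ("c1", 160, "C", "T", "SNV", 50, 30, "s1"),   # masked
        ("c1", 199, "G", "A", "SNV", 50, 30, "s2"),   # masked
        ("c1", 300, "T", "C", "SNV", 50, 30, "s1"),   # low coverage
        ("c1", 400, "A", "C", "SNV", 50, 30, "s2"),   # low coverage
        ("c1", 500, "G", "T", "SNV", 50, 30, "s1"),   # universal (both samples)
        ("c1", 500, "G", "T", "SNV", 50, 30, "s2"),   # universal pair record
        ("c1", 600, "A", "G", "SNV", 50, 30, "s1"),
        ("c1", 700, "C", "A", "SNV", 50, 30, "s2"),
        ("c1", 800, "T", "G", "InDel", 50, 30, "s1"),
    ]
    cov = pd.Series([1.0, 1.0, 1.0, 0.3, 0.4, 1.0, 1.0, 1.0, 1.0, 1.0])
    calls = make_calls(rows)
    survivors, report = filter_yeast_variants(calls, cov, masks, samples)
    # brute force: apply each pure predicate independently
    keep = []
    key_samples = calls.groupby(["chrom", "pos", "ref", "alt"])["sample"].nunique()
    for i, r in calls.iterrows():
        masked = any(s <= r["pos"] < e for s, e in masks.get(r["chrom"], []))
        low = cov[i] < 0.5
        universal = key_samples[(r["chrom"], r["pos"], r["ref"], r["alt"])] >= len(samples)
        if not (masked or low or universal):
            keep.append(i)
    assert list(survivors.index) == keep
    assert len(survivors) == 4 - 1  # positions 600, 700, 800 survive


def test_plant_frequency_boundary_is_strict():
    calls = make_calls([("c1", 10, "A", "G", "SNV", 100, 40, "p1")])
    empty = make_calls([])
    survivors, _ = filter_plant_variants(calls, empty)
    assert len(survivors) == 0  # 0.40 is not > 0.4
    calls2 = make_calls([("c1", 10, "A", "G", "SNV", 100, 41, "p1")])
    survivors2, _ = filter_plant_variants(calls2, empty)
    assert len(survivors2) == 1


def test_plant_indel_control_read_boundary():
    calls = make_calls([("c1", 50, "AT", "A", "InDel", 100, 60, "p1")])
    empty = make_calls([])
    surv, _ = filter_plant_variants(calls, empty, {("c1", 50): 2})
    assert len(surv) == 0  # 2 control reads: not < 2
    surv, _ = filter_plant_variants(calls, empty, {("c1", 50): 1})
    assert len(surv) == 1
    # missing control evidence: held as unresolved, not passed
    surv, rep = filter_plant_variants(calls, empty, {})
    assert len(surv) == 0
    assert rep.removed_by_rule["indel_control_evidence_missing"] == 1


def test_plant_rules_match_brute_force_oracle():
    rng = np.random.default_rng(17)
    rows = []
    for i in range(30):
        vtype = "SNV" if i % 3 else "InDel"
        depth = int(rng.integers(20, 120))
        alt = int(rng.integers(0, depth + 1))
        rows.append((f"c{i % 2 + 1}", int(rng.integers(0, 5_000)), "A",
                     "G" if vtype == "SNV" else "GT", vtype, depth, alt, "p1"))
    calls = make_calls(rows)
    control = calls.sample(5, random_state=1)[["chrom", "pos", "ref", "alt"]].copy()
    control["type"] = "SNV"; control["depth"] = 50; control["alt_count"] = 25
    control["sample"] = "ctrl"
    control = control[calls.columns]
    ctrl_reads = {
        (r["chrom"], r["pos"]): int(rng.integers(0, 4))
        for _, r in calls[calls["type"] == "InDel"].iterrows()
    }
    survivors, _ = filter_plant_variants(calls, control, ctrl_reads)

    ctrl_keys = set(map(tuple, control[["chrom", "pos", "ref", "alt"]].itertuples(index=False)))
    indels = calls[calls["type"] == "InDel"]
    snvs = calls[calls["type"] == "SNV"]
    alts = snvs.groupby(["chrom", "pos"])["alt"].nunique()
    expected = []
    for i, r in calls.iterrows():
        if tuple(r[["chrom", "pos", "ref", "alt"]]) in ctrl_keys:
            continue
        if not r["alt_count"] / r["depth"] > 0.4:
            continue
        if r["type"] == "InDel":
            cr = ctrl_reads.get((r["chrom"], r["pos"]))
            if cr is None or cr >= 2:
                continue
            near = indels[(indels["chrom"] == r["chrom"]) & (indels.index != i)
                          & ((indels["pos"] - r["pos"]).abs() <= 10)]
            if len(near):
                continue
        else:
            if alts.get((r["chrom"], r["pos"]), 0) > 1:
                continue
        expected.append(i)
    assert list(survivors.index) == expected


def test_filters_are_order_independent():
    """Pure predicates: the survivor set ignores rule application order."""
    calls = make_calls(
        [
            ("c1", 150, "A", "G", "SNV", 50, 30, "s1"),
            ("c1", 300, "T", "C", "SNV", 50, 30, "s1"),
            ("c1", 500, "G", "T", "SNV", 50, 30, "s1"),
            ("c1", 500, "G", "T", "SNV", 50, 30, "s2"),
            ("c1", 700, "C", "A", "SNV", 50, 30, "s2"),
        ]
    )
    masks = {"c1": [(100, 200)]}
    cov = pd.Series([1.0, 0.4, 1.0, 1.0, 1.0])
    rules = {
        "mask": lambda df: df[~df["pos"].between(100, 199)],
        "cov": lambda df: df[cov.reindex(df.index) >= 0.5],
        "univ": lambda df: df[df["pos"] != 500],
    }
    baselines = set()
    for order in itertools.permutations(rules):
        out = calls
        for rule in order:
            out = rules[rule](out)
        baselines.add(tuple(out.index))
    assert len(baselines) == 1
    survivors, _ = filter_yeast_variants(calls, cov, masks, ["s1", "s2"])
    assert tuple(survivors.index) == next(iter(baselines))


def test_at_rich_mask_helper():
    seq = "AT" * 100 + "GC" * 200
    masks = at_rich_mask({"c1": seq}, window=100, at_fraction=0.8)
    assert masks == {"c1": [(0, 200)]}


def test_missing_coverage_stats_error():
    calls = make_calls([("c1", 10, "A", "G", "SNV", 50, 30, "s1")])
    with pytest.raises(ValueError, match="coverage"):
        filter_yeast_variants(calls)
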