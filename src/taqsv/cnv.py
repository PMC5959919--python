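"""CNV and aneuploidy calling from depth ratios with array concordance.

An aneuploidy call requires concordant support from both sequencing
depth and the tiling array: chromosome-wide copy changes seen by only
one platform stay ``unconfirmed``.  Local (sub-chromosomal) CNVs are
segmented by run-length thresholding of the binned depth ratio; runs
spanning an entire chromosome are routed to the aneuploidy logic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import CoverageTrack


@dataclass
class CnvThresholds:
    """Decision thresholds on the depth-ratio and array log10-ratio scales.

    Depth thresholds for ploidy p sit midway between the euploid ratio
    (1.0) and a single-copy change ((p±1)/p): gain at 1 + 0.7/p, loss at
    1 − 0.7/p, i.e. 1.35/0.65 for a diploid.  Array thresholds default
    to ±log10(1.25).
    """

    gain_ratio: float = 1.35
    loss_ratio: float = 0.65
    array_gain: float = float(np.log10(1.25))
    array_loss: float = float(-np.log10(1.25))

    @classmethod
    def for_ploidy(cls, ploidy: int) -> "CnvThresholds":
        return cls(gain_ratio=1 + 0.7 / ploidy, loss_ratio=1 - 0.7 / ploidy)


@dataclass
class CnvCall:
    chrom: str
    start: int
    end: int
    direction: str  # gain | loss
    copy_estimate: float
    whole_chromosome: bool
    seq_support: bool
    array_support: bool
    status: str  # aneuploidy | local_cnv | unconfirmed
    mean_ratio: float

    def __post_init__(self) -> None:
        if self.status == "aneuploidy" and not (self.seq_support and self.array_support):
            raise ValueError("aneuploidy status requires support from both platforms")

    @property
    def length(self) -> int:
        return self.end - self.start


def normalize_coverage(
    track: CoverageTrack, extra_masks: dict[str, list[tuple[int, int]]] | None = None
) -> CoverageTrack:
    """Depth divided by the genome-wide median of unmasked bins.

    ``extra_masks`` adds intervals (bp coordinates) to the built-in mask
    (telomeres/rDNA flagged upstream); masked bins keep their ratio but
    stay excluded from statistics.
    """
    masked = {c: m.copy() for c, m in track.mask.items()}
    if extra_masks:
        for chrom, ivs in extra_masks.items():
            for s, e in ivs:
                masked[chrom][s // track.bin_size : (e + track.bin_size - 1) // track.bin_size] = True
    tmp = CoverageTrack(track.haplotype, track.bin_size, track.values, masked)
    med = tmp.genome_median()
    if med <= 0:
        raise ValueError("genome-wide median depth is zero after masking")
    return CoverageTrack(
        haplotype=track.haplotype,
        bin_size=track.bin_size,
        values={c: v / med for c, v in track.values.items()},
        mask=masked,
    )


def combine_haplotype_ratios(
    ratio_a: CoverageTrack, ratio_b: CoverageTrack, pairing: dict[str, str]
) -> CoverageTrack:
    """Total depth ratio per homolog pair, on haplome-A bins.

    Homologous chromosomes differ in length only by net InDels, far
    below the bin size at realistic divergence, so bins are combined
    positionally and the (shorter) tail padded with the euploid ratio.
    """
    values: dict[str, np.ndarray] = {}
    mask: dict[str, np.ndarray] = {}
    for ca, cb in pairing.items():
        va, vb = ratio_a.values[ca], ratio_b.values[cb]
        n = len(va)
        vb2 = np.ones(n)
        m = min(n, len(vb))
        vb2[:m] = vb[:m]
        values[ca] = (va + vb2) / 2.0
        mb = np.zeros(n, dtype=bool)
        mb[:m] = ratio_b.mask[cb][:m]
        mask[ca] = ratio_a.mask[ca] | mb
    return CoverageTrack("combined", ratio_a.bin_size, values, mask)


def call_aneuploidy(
    ratio_track: CoverageTrack,
    array_track: pd.DataFrame | None,
    thresholds: CnvThresholds | None = None,
    ploidy: int = 2,
) -> list[CnvCall]:
    """Chromosome-wide CNV calls gated on dual-platform support.

    ``ratio_track`` is the combined (all-allele) depth ratio where 1.0
    is euploid.  Per chromosome, the median unmasked ratio is compared
    with the gain/loss thresholds and the median array log10-ratio with
    the array thresholds; only dual-support calls receive status
    ``aneuploidy``.
    """
    thr = thresholds or CnvThresholds.for_ploidy(ploidy)
    if array_track is None:
        warnings.warn("no array platform: chromosome-wide calls stay unconfirmed", stacklevel=2)
    calls: list[CnvCall] = []
    for chrom, ratios in ratio_track.values.items():
        unmasked = ratios[~ratio_track.mask[chrom]]
        if len(unmasked) == 0:
            continue
        med = float(np.median(unmasked))
        direction = "gain" if med >= thr.gain_ratio else "loss" if med <= thr.loss_ratio else None
        if direction is None:
            continue
        arr_med = None
        if array_track is not None:
            probe_vals = array_track.loc[array_track["chrom"] == chrom, "log10_ratio"]
            if len(probe_vals):
                arr_med = float(probe_vals.median())
        arr_support = arr_med is not None and (
            arr_med >= thr.array_gain if direction == "gain" else arr_med <= thr.array_loss
        )
        calls.append(
            CnvCall(
                chrom=chrom,
                start=0,
                end=len(ratios) * ratio_track.bin_size,
                direction=direction,
                copy_estimate=round(med * ploidy, 2),
                whole_chromosome=True,
                seq_support=True,
                array_support=bool(arr_support),
                status="aneuploidy" if arr_support else "unconfirmed",
                mean_ratio=med,
            )
        )
    return calls


def segment_local_cnv(
    ratio_track: CoverageTrack,
    min_length: int = 100_000,
    thresholds: CnvThresholds | None = None,
    merge_gap: int = 1_000,
    ploidy: int = 2,
    array_track: pd.DataFrame | None = None,
) -> list[CnvCall]:
    """Sub-chromosomal CNV segments by run-length thresholding.

    Maximal unmasked runs of bins beyond a threshold are merged across
    gaps of at most ``merge_gap`` bp; segments spanning all unmasked
    bins of a chromosome are dropped here (aneuploidy logic owns them).
    When an array table is supplied, each segment's array support is the
    median probe log-ratio within it.
    """
    thr = thresholds or CnvThresholds.for_ploidy(ploidy)
    if min_length < ratio_track.bin_size:
        raise ValueError("min_length below bin size")
    bs = ratio_track.bin_size
    calls: list[CnvCall] = []
    for chrom, ratios in ratio_track.values.items():
        mask = ratio_track.mask[chrom]
        for direction in ("gain", "loss"):
            if direction == "gain":
                hot = (ratios >= thr.gain_ratio) & ~mask
            else:
                hot = (ratios <= thr.loss_ratio) & ~mask
            for s_bin, e_bin in _runs(hot, merge_gap // bs, bridge=mask):
                length = (e_bin - s_bin) * bs
                if length < min_length:
                    continue
                if np.all(hot[~mask] if mask.any() else hot):
                    continue  # chromosome-wide: aneuploidy logic owns it
                seg = ratios[s_bin:e_bin][~mask[s_bin:e_bin]]
                med = float(np.median(seg)) if len(seg) else float("nan")
                arr_support = False
                if array_track is not None:
                    sel = (
                        (array_track["chrom"] == chrom)
                        & (array_track["pos"] >= s_bin * bs)
                        & (array_track["pos"] < e_bin * bs)
                    )
                    vals = array_track.loc[sel, "log10_ratio"]
                    if len(vals):
                        am = float(vals.median())
                        arr_support = (
                            am >= thr.array_gain if direction == "gain" else am <= thr.array_loss
                        )
                calls.append(
                    CnvCall(
                        chrom=chrom,
                        start=s_bin * bs,
                        end=e_bin * bs,
                        direction=direction,
                        copy_estimate=round(med * ploidy, 2),
                        whole_chromosome=False,
                        seq_support=True,
                        array_support=arr_support,
                        status="local_cnv",
                        mean_ratio=med,
                    )
                )
    return calls


def _runs(hot: np.ndarray, max_gap_bins: int, bridge: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs, merging across gaps of masked or <=max_gap bins."""
    idx = np.flatnonzero(hot)
    if len(idx) == 0:
        return []
    runs: list[tuple[int, int]] = []
    start = prev = int(idx[0])
    for i in idx[1:]:
        i = int(i)
        gap = np.arange(prev + 1, i)
        gap_ok = len(gap) <= max_gap_bins or np.all(bridge[prev + 1 : i])
        if gap_ok:
            prev = i
        else:
            runs.append((start, prev + 1))
            start = prev = i
    runs.append((start, prev + 1))
    return runs


def calls_to_frame(calls: list[CnvCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "direction": c.direction,
                "copy_estimate": c.copy_estimate,
                "whole_chromosome": c.whole_chromosome,
                "seq_support": c.seq_support,
                "array_support": c.array_support,
                "status": c.status,
                "mean_ratio": c.mean_ratio,
            }
            for c in calls
        ]
    )
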