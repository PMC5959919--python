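"""Binned coverage and array-probe signal containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CoverageTrack:
    """Per-chromosome binned read depth for one haplotype.

    ``values[chrom][i]`` is the mean depth over bin
    ``[i*bin_size, (i+1)*bin_size)``; ``mask`` flags bins excluded from
    genome-wide statistics (telomeres, rDNA, user masks).
    """

    haplotype: str
    bin_size: int
    values: dict[str, np.ndarray]
    mask: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, v in self.values.items():
            if chrom not in self.mask:
                self.mask[chrom] = np.zeros(len(v), dtype=bool)
            if len(self.mask[chrom]) != len(v):
                raise ValueError(f"mask/value length mismatch on {chrom}")
            if np.any(v < 0):
                raise ValueError(f"negative depth on {chrom}")

    @property
    def chroms(self) -> list[str]:
        return list(self.values)

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])

    def unmasked_values(self) -> np.ndarray:
        parts = [v[~self.mask[c]] for c, v in self.values.items()]
        return np.concatenate(parts) if parts else np.empty(0)

    def genome_median(self) -> float:
        vals = self.unmasked_values()
        if len(vals) == 0:
            raise ValueError("all bins are masked")
        return float(np.median(vals))

    def bin_interval(self, chrom: str, i: int) -> tuple[int, int]:
        return i * self.bin_size, (i + 1) * self.bin_size

    def copy_with(self, values: dict[str, np.ndarray]) -> "CoverageTrack":
        return CoverageTrack(
            haplotype=self.haplotype,
            bin_size=self.bin_size,
            values=values,
            mask={c: m.copy() for c, m in self.mask.items()},
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, v in self.values.items():
            starts = np.arange(len(v)) * self.bin_size
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts,
                        "end": starts + self.bin_size,
                        "depth": v,
                        "masked": self.mask[chrom],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def array_track(chrom: np.ndarray, pos: np.ndarray, log10_ratio: np.ndarray) -> pd.DataFrame:
    """Canonical aCGH container: sorted probes with finite log10 ratios."""
    df = pd.DataFrame({"chrom": chrom, "pos": pos, "log10_ratio": log10_ratio})
    if not np.all(np.isfinite(df["log10_ratio"])):
        raise ValueError("array log-ratios must be finite")
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return df
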