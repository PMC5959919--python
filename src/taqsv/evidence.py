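"""Junction-evidence records: soft-clip and discordant-pair tables.

Records live on parental-reference coordinates.  A soft-clip record says
that reads aligned at ``(haplotype, chrom)`` stop matching the reference
at ``pos``; ``side`` is ``"R"`` when the clipped tail extends to the
right of ``pos`` (read anchored on the left of the junction) and ``"L"``
when the tail extends left.  Discordant pairs carry both mate
placements with strands oriented toward the junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

CLIP_COLUMNS = ["haplotype", "chrom", "pos", "side", "seq"]
PAIR_COLUMNS = [
    "haplotype_a",
    "chrom_a",
    "pos_a",
    "strand_a",
    "haplotype_b",
    "chrom_b",
    "pos_b",
    "strand_b",
]


def empty_clips() -> pd.DataFrame:
    return pd.DataFrame(columns=CLIP_COLUMNS)


def empty_pairs() -> pd.DataFrame:
    return pd.DataFrame(columns=PAIR_COLUMNS)


@dataclass
class Evidence:
    """Soft-clip and discordant-pair evidence plus sampling metadata."""

    clips: pd.DataFrame = field(default_factory=empty_clips)
    pairs: pd.DataFrame = field(default_factory=empty_pairs)
    depth: float = 0.0
    read_len: int = 300

    def __post_init__(self) -> None:
        missing = set(CLIP_COLUMNS) - set(self.clips.columns)
        if missing:
            raise ValueError(f"clip table missing columns {sorted(missing)}")
        missing = set(PAIR_COLUMNS) - set(self.pairs.columns)
        if missing:
            raise ValueError(f"pair table missing columns {sorted(missing)}")

    def write(self, clips_path: str | Path, pairs_path: str | Path) -> None:
        self.clips.to_csv(clips_path, sep="\t", index=False)
        self.pairs.to_csv(pairs_path, sep="\t", index=False)

    @classmethod
    def read(
        cls, clips_path: str | Path, pairs_path: str | Path, depth: float, read_len: int = 300
    ) -> "Evidence":
        return cls(
            clips=pd.read_csv(clips_path, sep="\t"),
            pairs=pd.read_csv(pairs_path, sep="\t"),
            depth=depth,
            read_len=read_len,
        )
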