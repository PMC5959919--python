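"""Seed-and-extend local alignment with a Karlin–Altschul significance model.

Soft-clipped tails at rearrangement junctions are contiguous copies of
the partner locus, so partner search needs exact-seeded, ungapped local
alignment with an E-value cutoff — not a general gapped aligner.  Seeds
are 11-mers looked up in a sorted 2-bit k-mer index of the combined
reference; each seed diagonal is scored by a maximum-scoring-substring
pass (match +1, mismatch −2 by default).  The expected number of chance
hits at score S follows E = K·m·n·e^(−λS); λ is solved from the scoring
scheme at uniform base composition and K is approximated as 0.3, which
is conservative enough at the e < 1e−4 threshold used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _BASE_CODE[ord(b)] = i
    _BASE_CODE[ord(b.lower())] = i


def encode(seq: str) -> np.ndarray:
    """2-bit encode; non-ACGT bases become 255 (excluded from k-mers)."""
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer code of every k-window; windows containing non-ACGT get -1."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        window = codes[j : j + n]
        out = out * 4 + np.where(window == 255, 0, window)
        bad |= window == 255
    out[bad] = -1
    return out


def karlin_lambda(match: float, mismatch: float) -> float:
    """Solve sum_ij p_i p_j exp(λ s_ij) = 1 for uniform base frequencies."""

    def f(lam: float) -> float:
        return 0.25 * np.exp(lam * match) + 0.75 * np.exp(lam * mismatch) - 1.0

    return float(brentq(f, 1e-9, 10.0))


@dataclass(frozen=True)
class Hit:
    """One local alignment of a query against the indexed reference."""

    chrom_key: tuple[str, str]
    ref_start: int
    ref_end: int
    q_start: int
    q_end: int
    strand: str
    score: float
    evalue: float


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class LocalAligner:
    """K-mer indexed ungapped local aligner over a set of sequences.

    Parameters follow BLASTN-like conventions; gap penalties are part of
    the scoring interface but extension is ungapped (junction clips are
    contiguous copies of their source locus).
    """

    def __init__(
        self,
        sequences: dict[tuple[str, str], str],
        k: int = 11,
        match: float = 1.0,
        mismatch: float = -2.0,
        gap_open: float = -5.0,
        gap_extend: float = -2.0,
        ka_k: float = 0.3,
    ) -> None:
        self.k = k
        self.match = match
        self.mismatch = mismatch
        self.gap_open = gap_open
        self.gap_extend = gap_extend
        self.lam = karlin_lambda(match, mismatch)
        self.ka_k = ka_k
        self.keys = list(sequences)
        self.seqs = {key: sequences[key] for key in self.keys}
        self.codes = {key: encode(sequences[key]) for key in self.keys}
        self.total_len = sum(len(s) for s in sequences.values())
        # concatenated k-mer index: global positions sorted by k-mer code
        self.offsets: dict[tuple[str, str], int] = {}
        parts = []
        offset = 0
        for key in self.keys:
            self.offsets[key] = offset
            km = kmer_codes(self.codes[key], k)
            parts.append(km)
            offset += len(self.seqs[key])
        allk = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
        pos_parts = [
            np.arange(len(km), dtype=np.int64) + self.offsets[key]
            for key, km in zip(self.keys, parts)
        ]
        allpos = np.concatenate(pos_parts) if pos_parts else np.empty(0, dtype=np.int64)
        valid = allk >= 0
        order = np.argsort(allk[valid], kind="stable")
        self._sorted_kmers = allk[valid][order]
        self._sorted_pos = allpos[valid][order]
        bounds = np.cumsum([0] + [len(self.seqs[key]) for key in self.keys])
        self._bounds = bounds
        self._key_index = {key: i for i, key in enumerate(self.keys)}

    def _locate(self, global_pos: int) -> tuple[tuple[str, str], int]:
        i = int(np.searchsorted(self._bounds, global_pos, side="right")) - 1
        return self.keys[i], int(global_pos - self._bounds[i])

    def evalue(self, score: float, query_len: int) -> float:
        return float(self.ka_k * query_len * self.total_len * np.exp(-self.lam * score))

    def search(
        self,
        query: str,
        e_threshold: float = 1e-4,
        max_diagonals: int = 200,
        seed_step: int = 4,
        search_reverse: bool = True,
    ) -> list[Hit]:
        """All significant local hits, best first; ties broken by locus."""
        hits: list[Hit] = []
        strands = [("+", query)]
        if search_reverse:
            strands.append(("-", query.translate(_COMPLEMENT)[::-1]))
        for strand, q in strands:
            hits.extend(self._search_one(q, strand, e_threshold, max_diagonals, seed_step))
        hits.sort(key=lambda h: (-h.score, h.chrom_key, h.ref_start))
        return hits

    def _search_one(
        self, q: str, strand: str, e_threshold: float, max_diagonals: int, seed_step: int
    ) -> list[Hit]:
        k = self.k
        if len(q) < k:
            return []
        qcodes = encode(q)
        qk = kmer_codes(qcodes, k)
        diagonals: set[tuple[int, int]] = set()  # (seq index, ref_pos - q_pos)
        qpos_list = list(range(0, len(qk), seed_step))
        if (len(qk) - 1) not in qpos_list:
            qpos_list.append(len(qk) - 1)
        for qpos in qpos_list:
            code = qk[qpos]
            if code < 0:
                continue
            lo = int(np.searchsorted(self._sorted_kmers, code, side="left"))
            hi = int(np.searchsorted(self._sorted_kmers, code, side="right"))
            if hi - lo > 5_000:  # hyper-repetitive seed, skip
                continue
            for gp in self._sorted_pos[lo:hi]:
                key, rp = self._locate(int(gp))
                diagonals.add((self._key_index[key], rp - qpos))
                if len(diagonals) > max_diagonals * 4:
                    break
        hits: list[Hit] = []
        scored: set[tuple[int, int]] = set()
        for idx, diag in list(diagonals)[: max_diagonals * 4]:
            if (idx, diag) in scored:
                continue
            scored.add((idx, diag))
            hit = self._score_diagonal(q, qcodes, idx, diag, strand)
            if hit is not None and hit.evalue < e_threshold:
                hits.append(hit)
        return hits

    def _score_diagonal(
        self, q: str, qcodes: np.ndarray, idx: int, diag: int, strand: str
    ) -> Hit | None:
        key = self.keys[idx]
        rcodes = self.codes[key]
        # overlap of query [0,len(q)) with reference at offset diag
        q_lo = max(0, -diag)
        q_hi = min(len(q), len(rcodes) - diag)
        if q_hi - q_lo < self.k:
            return None
        qs = qcodes[q_lo:q_hi]
        rs = rcodes[q_lo + diag : q_hi + diag]
        match_mask = (qs == rs) & (qs != 255)
        scores = np.where(match_mask, self.match, self.mismatch)
        # maximum-scoring substring (Kadane)
        best = cur = 0.0
        best_end = best_start = cur_start = 0
        for i, s in enumerate(scores):
            if cur <= 0:
                cur = float(s)
                cur_start = i
            else:
                cur += float(s)
            if cur > best:
                best = cur
                best_start = cur_start
                best_end = i + 1
        if best <= 0:
            return None
        q_start = q_lo + best_start
        q_end = q_lo + best_end
        return Hit(
            chrom_key=key,
            ref_start=q_start + diag,
            ref_end=q_end + diag,
            q_start=q_start,
            q_end=q_end,
            strand=strand,
            score=best,
            evalue=self.evalue(best, len(q)),
        )
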