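"""Proteome-scale sliding-window IDR informatics.

Given IDR annotations over a protein FASTA and a sequence -> end-to-end
distance estimator (simulator-backed, surrogate-backed, or any callable),
this module builds 51-residue sliding-window profiles of the normalized
end-to-end distance (estimate divided by the Gaussian-chain null for the
same window), calls compact/expanded subregions from the pooled 2.5%
distribution tails, counts them per protein, computes per-residue log2
enrichment of the tails against the background, and fits the apparent
power-law scaling of Rg with IDR length.

Coordinates in all file interfaces are 1-based inclusive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .ensembles import afrc_reference
from .seqfeatures import CANONICAL_AA, parse_fasta

__all__ = [
    "IDRAnnotation", "WindowProfile", "SubregionCall",
    "load_idr_annotations", "window_profile", "call_subregions",
    "merge_contiguous_calls", "aa_enrichment", "proteome_scaling_fit",
    "rank_by_abundance",
]


@dataclass(frozen=True)
class IDRAnnotation:
    protein_id: str
    start: int        # 1-based inclusive
    end: int          # 1-based inclusive
    seq: str

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"{self.protein_id}: invalid interval ({self.start}, {self.end})")
        if self.end - self.start + 1 != len(self.seq):
            raise ValueError(f"{self.protein_id}: interval length != sequence length")

    def __len__(self):
        return len(self.seq)


@dataclass
class WindowProfile:
    protein_id: str
    window_starts: np.ndarray     # 1-based, protein coordinates
    values: np.ndarray            # normalized Re per window
    window_seqs: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class SubregionCall:
    protein_id: str
    window_start: int
    label: str                    # "compact" | "expanded"
    value: float


def load_idr_annotations(fasta_path, tsv_path, min_len: int = 35,
                         max_len: int = 3000) -> list[IDRAnnotation]:
    """Read protein_id/start/end rows (1-based inclusive), extract IDR
    substrings and apply the length filter (keep min_len <= L <= max_len).
    Rows failing the filter are reported via a warning; out-of-bounds
    coordinates raise, naming the row."""
    seqs = {rec.id: rec.seq for rec in parse_fasta(fasta_path)}
    table = pd.read_csv(tsv_path, sep="\t", comment="#",
                        names=["protein_id", "start", "end"], header=None,
                        dtype={"protein_id": str})
    # tolerate a header row
    if str(table.iloc[0]["start"]).lower() in ("start",):
        table = table.iloc[1:].reset_index(drop=True)
    out, rejected = [], []
    for rownum, row in table.iterrows():
        pid, start, end = str(row["protein_id"]), int(row["start"]), int(row["end"])
        if pid not in seqs:
            raise ValueError(f"row {rownum}: protein {pid!r} absent from FASTA")
        if start > end:
            raise ValueError(f"row {rownum} ({pid}): start {start} > end {end}")
        if start < 1 or end > len(seqs[pid]):
            raise ValueError(
                f"row {rownum} ({pid}): interval ({start}, {end}) outside protein "
                f"of length {len(seqs[pid])}")
        sub = seqs[pid][start - 1:end]
        if min_len <= len(sub) <= max_len:
            out.append(IDRAnnotation(pid, start, end, sub))
        else:
            rejected.append((pid, start, end, len(sub)))
    if rejected:
        warnings.warn(f"length filter [{min_len}, {max_len}] rejected {len(rejected)} "
                      f"IDR rows: {rejected[:5]}")
    return out


def window_profile(idr: IDRAnnotation, estimator: Callable[[str], float],
                   w: int = 51) -> WindowProfile:
    """Normalized local end-to-end distance over every w-mer window.

    Each window's value is estimator(window) / re_null(window); window
    count is L - w + 1 (empty with a warning for IDRs shorter than w).
    """
    L = len(idr)
    if L < w:
        warnings.warn(f"{idr.protein_id}: IDR length {L} < window {w}; empty profile")
        return WindowProfile(idr.protein_id, np.array([], dtype=int), np.array([]), [])
    starts, values, wseqs = [], [], []
    for off in range(L - w + 1):
        wseq = idr.seq[off:off + w]
        _, re_null = afrc_reference(wseq)
        starts.append(idr.start + off)
        values.append(estimator(wseq) / re_null)
        wseqs.append(wseq)
    return WindowProfile(idr.protein_id, np.array(starts), np.array(values), wseqs)


def call_subregions(profiles: Sequence[WindowProfile], q: float = 0.025,
                    min_per_protein: int = 10):
    """Tail-threshold subregion calling over the pooled window population.

    Thresholds are the empirical q and 1-q tails: with n pooled windows and
    k = floor(n q), the lower threshold is the (k+1)-th ascending order
    statistic and windows strictly below it are "compact" (symmetrically
    above for "expanded"), so k windows are called per tail when values are
    distinct and ties at the threshold are left unlabeled.

    Returns (thresholds dict, calls list, per-protein counts DataFrame).
    The counts table reports raw window counts and merged contiguous-run
    counts per tail, plus pass/fail of the >= min_per_protein filter.
    """
    pooled = np.concatenate([p.values for p in profiles]) if profiles else np.array([])
    n = pooled.size
    if n < 1.0 / q:
        raise ValueError(f"need at least {math.ceil(1 / q)} pooled windows; have {n}")
    srt = np.sort(pooled)
    k = int(math.floor(n * q))
    t_lo = float(srt[k])          # (k+1)-th order statistic
    t_hi = float(srt[n - k - 1])
    thresholds = {"q": q, "lower": t_lo, "upper": t_hi, "n_windows": int(n)}

    calls: list[SubregionCall] = []
    for p in profiles:
        for s, v in zip(p.window_starts, p.values):
            if v < t_lo:
                calls.append(SubregionCall(p.protein_id, int(s), "compact", float(v)))
            elif v > t_hi:
                calls.append(SubregionCall(p.protein_id, int(s), "expanded", float(v)))

    rows = []
    for pid in sorted({p.protein_id for p in profiles}):
        sub = [c for c in calls if c.protein_id == pid]
        for label in ("compact", "expanded"):
            lab = sorted(c.window_start for c in sub if c.label == label)
            raw = len(lab)
            merged = merge_contiguous_calls(lab)
            rows.append({"protein_id": pid, "label": label, "n_windows": raw,
                         "n_merged_runs": len(merged),
                         "passes_min_filter": raw >= min_per_protein})
    return thresholds, calls, pd.DataFrame(rows)


def merge_contiguous_calls(starts: Sequence[int]) -> list[tuple[int, int]]:
    """Collapse sorted window starts into maximal runs of consecutive
    (step-1) windows; returns (first_start, last_start) pairs."""
    runs = []
    for s in sorted(starts):
        if runs and s == runs[-1][1] + 1:
            runs[-1][1] = s
        else:
            runs.append([s, s])
    return [tuple(r) for r in runs]


def _aa_counts(windows: Sequence[str]) -> np.ndarray:
    counts = np.zeros(len(CANONICAL_AA))
    index = {aa: i for i, aa in enumerate(CANONICAL_AA)}
    for w in windows:
        for ch in w:
            counts[index[ch]] += 1
    return counts


def aa_enrichment(tail_windows: Sequence[str], all_windows: Sequence[str],
                  pseudocount: float = 0.5) -> pd.Series:
    """Per-residue log2 fold enrichment of the tail set over the background.

    log2((tail_count + pc) / (tail_total + 20 pc))
    - log2((bg_count + pc) / (bg_total + 20 pc)), defined for all 20
    residues thanks to the pseudocount.
    """
    if not len(tail_windows) or not len(all_windows):
        raise ValueError("both window sets must be non-empty")
    t = _aa_counts(tail_windows)
    b = _aa_counts(all_windows)
    pc = pseudocount
    lf = (np.log2((t + pc) / (t.sum() + 20 * pc))
          - np.log2((b + pc) / (b.sum() + 20 * pc)))
    return pd.Series(lf, index=list(CANONICAL_AA), name="log2_enrichment")


def rank_by_abundance(counts: pd.DataFrame, abundance_tsv, label: str = "compact",
                      min_per_protein: int = 10) -> pd.DataFrame:
    """Join per-protein subregion counts with a protein-abundance table
    (tab-separated protein_id / copy_number) and rank the proteins that
    carry at least ``min_per_protein`` windows of the given label by copy
    number, descending. Proteins absent from the abundance table are kept
    with missing copy numbers and sort last."""
    ab = pd.read_csv(abundance_tsv, sep="\t", comment="#", header=None,
                     names=["protein_id", "copy_number"],
                     dtype={"protein_id": str})
    if str(ab.iloc[0]["copy_number"]).lower() in ("copy_number", "abundance"):
        ab = ab.iloc[1:].reset_index(drop=True)
    ab["copy_number"] = ab["copy_number"].astype(float)
    sub = counts[(counts["label"] == label)
                 & (counts["n_windows"] >= min_per_protein)]
    out = sub.merge(ab, on="protein_id", how="left")
    return out.sort_values("copy_number", ascending=False,
                           na_position="last").reset_index(drop=True)


def proteome_scaling_fit(records: Sequence[tuple[float, float]]):
    """Apparent Rg-length scaling exponent from a log-log least-squares fit.

    ``records`` are (length, rg) pairs; requires >= 10 records spanning at
    least one decade in length. Returns (exponent, prefactor, diagnostics)
    where diagnostics holds the residual norm and per-record deviation of
    log(rg) above (+) or below (-) the fitted line — sequence-specific
    expansion or compaction respectively.
    """
    arr = np.asarray(records, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 10:
        raise ValueError("need >= 10 (length, rg) records")
    lengths, rgs = arr[:, 0], arr[:, 1]
    if lengths.max() / lengths.min() < 10.0:
        raise ValueError("lengths must span at least one decade")
    x, y = np.log(lengths), np.log(rgs)
    A = np.vstack([x, np.ones_like(x)]).T
    (nu, logc), res, *_ = np.linalg.lstsq(A, y, rcond=None)
    deviation = y - (nu * x + logc)
    diagnostics = {"residual_norm": float(np.sqrt(res[0])) if len(res) else 0.0,
                   "deviation": deviation}
    return float(nu), float(np.exp(logc)), diagnostics
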