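"""Conservation of IDR dimensions across homolog sets.

A reference protein's folded/IDR segmentation is projected through a
multiple sequence alignment onto every homolog: each reference domain maps
to a span of alignment columns, insertion columns between domains are
absorbed into the adjacent disordered span, and each member's IDR is its
ungapped residues within that span. Sets are then filtered (more than ten
members with the reference present; reference IDR at least 40 residues;
member IDRs at least 15 residues) and summarized by the dispersion of
member lengths and of estimated end-to-end distances — low Re dispersion
despite high length dispersion is the signature of conformational
buffering. Sequence similarity is scored per column with BLOSUM62 using
SumOfPairs (all row pairs) and StarScore (consensus versus rows), each
normalized by row count and alignment length.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .ensembles import afrc_reference
from .seqfeatures import SequenceRecord

__all__ = [
    "MSA", "HomologIDRSet", "ConservationStats",
    "read_msa", "load_blosum62", "read_substitution_matrix",
    "project_reference_idrs", "extract_homolog_idr_sets",
    "filter_homolog_sets", "conservation_stats", "msa_similarity",
]

GAP = "-"


@dataclass
class MSA:
    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if not self.rows:
            raise ValueError("empty alignment")
        L = len(self.rows[0])
        for rid, row in zip(self.ids, self.rows):
            if len(row) != L:
                raise ValueError(f"ragged alignment: row {rid!r} has length {len(row)} != {L}")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def ungapped(self, rid: str) -> str:
        return self.rows[self.ids.index(rid)].replace(GAP, "")


def read_msa(path) -> MSA:
    """Read an aligned FASTA or Clustal file (format auto-detected)."""
    from Bio import AlignIO

    path = Path(path)
    head = path.read_text().lstrip()
    fmt = "clustal" if head.upper().startswith("CLUSTAL") else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return MSA([rec.id for rec in aln], [str(rec.seq) for rec in aln])


# ---------------------------------------------------------------------------
# Substitution matrices

def read_substitution_matrix(path) -> dict[tuple[str, str], float]:
    """Parse an NCBI-layout substitution matrix text file."""
    lines = [ln for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    cols = lines[0].split()
    mat: dict[tuple[str, str], float] = {}
    for ln in lines[1:]:
        parts = ln.split()
        row = parts[0]
        for c, v in zip(cols, parts[1:]):
            mat[(row, c)] = float(v)
    return mat


def load_blosum62() -> dict[tuple[str, str], float]:
    with resources.as_file(resources.files("idrpipe") / "data" / "blosum62.txt") as p:
        return read_substitution_matrix(p)


# ---------------------------------------------------------------------------
# Projection

def _column_spans(msa: MSA, reference_id: str,
                  ref_domains: Sequence[tuple[int, int, str]]):
    """Partition alignment columns into one span per reference domain.

    Domains are 1-based inclusive on the ungapped reference and must tile
    it. Insertion columns between two domain spans are absorbed by the
    following domain if it is disordered, else the preceding one if
    disordered, else the preceding domain; leading/trailing columns attach
    to the first/last domain.
    """
    if reference_id not in msa.ids:
        raise ValueError(f"reference {reference_id!r} absent from alignment")
    ref_row = msa.rows[msa.ids.index(reference_id)]
    ref_len = len(ref_row) - ref_row.count(GAP)

    doms = sorted(ref_domains, key=lambda d: d[0])
    cursor = 1
    for start, end, kind in doms:
        if kind not in ("folded", "idr"):
            raise ValueError(f"unknown domain kind {kind!r}")
        if start != cursor:
            raise ValueError(
                f"domains must tile the reference: expected start {cursor}, got {start}"
                + (" (overlap)" if start < cursor else " (gap)"))
        if end < start:
            raise ValueError(f"domain ({start}, {end}) has end < start")
        cursor = end + 1
    if cursor != ref_len + 1:
        raise ValueError(f"domains cover 1..{cursor - 1} but reference has {ref_len} residues")

    # ungapped reference position -> alignment column (0-based)
    pos2col = [c for c, ch in enumerate(ref_row) if ch != GAP]
    bounds = []
    for start, end, kind in doms:
        bounds.append([pos2col[start - 1], pos2col[end - 1], kind])
    # absorb inter-domain insertion columns
    for i in range(len(bounds) - 1):
        gap_lo, gap_hi = bounds[i][1] + 1, bounds[i + 1][0] - 1
        if gap_lo > gap_hi:
            continue
        if bounds[i + 1][2] == "idr":
            bounds[i + 1][0] = gap_lo
        else:
            bounds[i][1] = gap_hi
    bounds[0][0] = 0
    bounds[-1][1] = msa.n_cols - 1
    return [(lo, hi, kind) for lo, hi, kind in bounds]


def project_reference_idrs(msa: MSA, reference_id: str,
                           ref_domains: Sequence[tuple[int, int, str]]):
    """Project the reference segmentation onto every member.

    Returns {member_id: [(start, end, kind), ...]} in member-local 1-based
    ungapped coordinates; a member fully gapped across a span gets an
    empty (start > end) interval there. Segments concatenate to the full
    ungapped member sequence by construction.
    """
    spans = _column_spans(msa, reference_id, ref_domains)
    out: dict[str, list[tuple[int, int, str]]] = {}
    for rid, row in zip(msa.ids, msa.rows):
        segments = []
        pos = 0  # ungapped residues consumed
        for lo, hi, kind in spans:
            n_res = sum(1 for c in range(lo, hi + 1) if row[c] != GAP)
            segments.append((pos + 1, pos + n_res, kind))
            pos += n_res
        out[rid] = segments
    return out


# ---------------------------------------------------------------------------
# Homolog IDR sets

@dataclass
class HomologIDRSet:
    set_id: str
    reference_id: str
    members: list[tuple[str, str]] = field(default_factory=list)   # (id, idr seq)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(s) for _, s in self.members])

    def member_ids(self) -> list[str]:
        return [mid for mid, _ in self.members]


def extract_homolog_idr_sets(msa: MSA, reference_id: str,
                             ref_domains: Sequence[tuple[int, int, str]],
                             set_prefix: str = "idr") -> list[HomologIDRSet]:
    """One HomologIDRSet per reference IDR domain, with each member's
    projected IDR subsequence (empty members skipped)."""
    projection = project_reference_idrs(msa, reference_id, ref_domains)
    idr_indices = [i for i, (_, _, kind) in enumerate(projection[reference_id])
                   if kind == "idr"]
    sets = []
    for rank, di in enumerate(idr_indices):
        hs = HomologIDRSet(f"{set_prefix}_{rank}", reference_id)
        for rid in msa.ids:
            start, end, _ = projection[rid][di]
            if end >= start:
                ungapped = msa.ungapped(rid)
                hs.members.append((rid, ungapped[start - 1:end]))
        sets.append(hs)
    return sets


def filter_homolog_sets(sets: Sequence[HomologIDRSet], min_members: int = 11,
                        ref_min_len: int = 40, member_min_len: int = 15):
    """Apply the homolog-set filters.

    Drops whole sets whose reference IDR is shorter than ``ref_min_len``;
    drops individual members shorter than ``member_min_len``; keeps only
    sets that still have the reference plus more than ten members
    (``min_members`` total, strict reading of "more than ten"). Returns
    (kept sets, filter log)."""
    kept, log = [], []
    for hs in sets:
        ref = dict(hs.members).get(hs.reference_id)
        if ref is None:
            log.append((hs.set_id, "dropped", "reference absent"))
            continue
        if len(ref) < ref_min_len:
            log.append((hs.set_id, "dropped", f"reference IDR {len(ref)} < {ref_min_len}"))
            continue
        members = [(mid, s) for mid, s in hs.members
                   if len(s) >= member_min_len or mid == hs.reference_id]
        n_dropped = len(hs.members) - len(members)
        if len(members) < min_members:
            log.append((hs.set_id, "dropped",
                        f"{len(members)} members (< {min_members}) after dropping {n_dropped}"))
            continue
        out = HomologIDRSet(hs.set_id, hs.reference_id, members)
        kept.append(out)
        log.append((hs.set_id, "kept", f"{len(members)} members; {n_dropped} short members dropped"))
    return kept, log


@dataclass
class ConservationStats:
    sd_length: float          # residues
    sd_re: float              # A
    mean_re: float            # A
    null_sd_re: float         # A: Gaussian-null Re spread over member lengths
    n_members: int


def conservation_stats(hs: HomologIDRSet, estimator: Callable[[str], float]) -> ConservationStats:
    """Sample (n-1) standard deviations of member length and estimated Re,
    plus the Gaussian-chain null Re dispersion over the same lengths."""
    if len(hs.members) < 2:
        raise ValueError("need at least 2 members")
    lengths = hs.lengths.astype(float)
    res = np.array([estimator(s) for _, s in hs.members], dtype=float)
    null_res = np.array([afrc_reference(int(L))[1] for L in lengths])
    return ConservationStats(
        sd_length=float(np.std(lengths, ddof=1)),
        sd_re=float(np.std(res, ddof=1)),
        mean_re=float(res.mean()),
        null_sd_re=float(np.std(null_res, ddof=1)),
        n_members=len(hs.members))


# ---------------------------------------------------------------------------
# Similarity scores

def _pair_score(mat, a: str, b: str) -> float:
    if a == GAP or b == GAP:
        return 0.0
    return mat.get((a, b), mat.get((b, a), 0.0))


def msa_similarity(msa: MSA, matrix: dict | None = None):
    """Normalized SumOfPairs and StarScore of an alignment.

    SumOfPairs: per column, the substitution score summed over all
    unordered row pairs. StarScore: per column, the score of the most
    common residue (consensus; ties alphabetical; gaps excluded) against
    every row. Gap-residue and gap-gap pairs contribute 0 but columns
    still count toward the length normalization; totals are divided by the
    number of rows and by the alignment length.
    """
    if msa.n_rows < 2:
        raise ValueError("similarity scores need at least 2 rows")
    mat = matrix or load_blosum62()
    sop_total = 0.0
    star_total = 0.0
    for c in range(msa.n_cols):
        col = [row[c] for row in msa.rows]
        for i in range(len(col)):
            for j in range(i + 1, len(col)):
                sop_total += _pair_score(mat, col[i], col[j])
        residues = [ch for ch in col if ch != GAP]
        if residues:
            counts = Counter(residues)
            top = max(counts.values())
            consensus = min(ch for ch, n in counts.items() if n == top)
            for ch in col:
                star_total += _pair_score(mat, consensus, ch)
    norm = msa.n_rows * msa.n_cols
    return sop_total / norm, star_total / norm
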