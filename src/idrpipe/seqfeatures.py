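"""Scalar sequence features for disordered regions.

Charge-patterning and composition descriptors used throughout the package:
fraction of charged residues (FCR), net charge per residue (NCPR), the
charge-asymmetry parameter kappa, the sequence charge decoration (SCD) and
sequence hydropathy decoration (SHD) statistics, per-class composition
fractions and mean hydropathy.

Conventions
-----------
* Histidine is treated as uncharged (and not part of the Y/W/F aromatic
  class) for all charge statistics, consistent with a near-zero histidine
  charge at neutral pH in residue-level coarse-grained models. It is
  tracked separately under the ``histidine`` class fraction.
* Hydropathy defaults to the Kyte–Doolittle scale rescaled to [0, 1];
  any other per-residue scale may be supplied.
* Input is case-insensitive; a single trailing ``*`` stop is stripped with
  a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CANONICAL_AA",
    "KYTE_DOOLITTLE",
    "SequenceRecord",
    "FeatureVector",
    "parse_fasta",
    "write_fasta",
    "compute_fractions",
    "ncpr_fcr",
    "kappa",
    "scd",
    "shd",
    "compute_features",
    "feature_table",
    "hydropathy_scale",
]

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)

POSITIVE = frozenset("RK")
NEGATIVE = frozenset("DE")
AROMATIC = frozenset("FWY")
ALIPHATIC = frozenset("AILMV")
POLAR = frozenset("NQST")

#: Kyte–Doolittle hydropathy (raw scale, +4.5 most hydrophobic).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def hydropathy_scale(name: str = "kd_normalized") -> dict[str, float]:
    """Return a per-residue hydropathy mapping.

    ``kd_normalized`` (default) is Kyte–Doolittle linearly rescaled to
    [0, 1] so that isoleucine scores 1 and arginine scores 0. ``kd`` is
    the raw scale.
    """
    if name == "kd":
        return dict(KYTE_DOOLITTLE)
    if name == "kd_normalized":
        return {aa: (h + 4.5) / 9.0 for aa, h in KYTE_DOOLITTLE.items()}
    raise ValueError(f"unknown hydropathy scale {name!r}")


def _clean_sequence(raw: str, record_id: str) -> str:
    seq = raw.strip().upper()
    if seq.endswith("*"):
        warnings.warn(f"record {record_id!r}: stripping terminal stop '*'", stacklevel=3)
        seq = seq[:-1]
    if not seq:
        raise ValueError(f"record {record_id!r} has an empty sequence")
    for pos, ch in enumerate(seq, start=1):
        if ch not in _CANONICAL_SET:
            raise ValueError(
                f"record {record_id!r}: non-canonical residue {ch!r} at position {pos}"
            )
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    """An identifier plus a canonical amino-acid string."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", _clean_sequence(self.seq, self.id))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class FeatureVector:
    """All scalar features of one sequence; ``kappa`` is None when undefined."""

    fcr: float
    ncpr: float
    kappa: float | None
    scd: float
    shd: float
    mean_hydropathy: float
    class_fractions: Mapping[str, float] = field(default_factory=dict)


def _as_record(seq) -> SequenceRecord:
    if isinstance(seq, SequenceRecord):
        return seq
    return SequenceRecord("seq", str(seq))


# ---------------------------------------------------------------------------
# FASTA I/O

def parse_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into validated records, order preserved.

    Raises ``ValueError`` naming the record and 1-based position on any
    non-canonical character, and on empty records.
    """
    records: list[SequenceRecord] = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        records.append(SequenceRecord(header, "".join(chunks)))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].strip() else ""
                if not header:
                    raise ValueError(f"{path}: empty FASTA header")
                chunks = []
            else:
                if header is None:
                    raise ValueError(f"{path}: sequence data before first header")
                chunks.append(line)
    flush()
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[SequenceRecord], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Composition

def compute_fractions(seq, scale: Mapping[str, float] | None = None) -> dict[str, float]:
    """Per-class composition fractions plus mean hydropathy.

    Classes: aromatic (F/W/Y), aliphatic (A/I/L/M/V), polar (N/Q/S/T),
    proline, glycine, histidine, positive (R/K), negative (D/E).
    """
    rec = _as_record(seq)
    s = rec.seq
    L = len(s)
    scale = scale or hydropathy_scale()
    counts = {c: 0 for c in ("aromatic", "aliphatic", "polar", "proline",
                             "glycine", "histidine", "positive", "negative")}
    for ch in s:
        if ch in AROMATIC:
            counts["aromatic"] += 1
        elif ch in ALIPHATIC:
            counts["aliphatic"] += 1
        elif ch in POLAR:
            counts["polar"] += 1
        elif ch == "P":
            counts["proline"] += 1
        elif ch == "G":
            counts["glycine"] += 1
        elif ch == "H":
            counts["histidine"] += 1
        if ch in POSITIVE:
            counts["positive"] += 1
        elif ch in NEGATIVE:
            counts["negative"] += 1
    out = {k: v / L for k, v in counts.items()}
    out["mean_hydropathy"] = sum(scale[ch] for ch in s) / L
    return out


def ncpr_fcr(seq) -> tuple[float, float]:
    """Net charge per residue and fraction of charged residues."""
    rec = _as_record(seq)
    n_pos = sum(1 for ch in rec.seq if ch in POSITIVE)
    n_neg = sum(1 for ch in rec.seq if ch in NEGATIVE)
    L = len(rec.seq)
    return (n_pos - n_neg) / L, (n_pos + n_neg) / L


def _charges(s: str) -> np.ndarray:
    q = np.zeros(len(s))
    for i, ch in enumerate(s):
        if ch in POSITIVE:
            q[i] = 1.0
        elif ch in NEGATIVE:
            q[i] = -1.0
    return q


# ---------------------------------------------------------------------------
# kappa

def _sigma_windows(q: np.ndarray, g: int) -> np.ndarray:
    """Charge asymmetry sigma = (f+ - f-)^2 / (f+ + f-) over sliding blobs."""
    pos = (q > 0).astype(float)
    neg = (q < 0).astype(float)
    kern = np.ones(g)
    np_w = np.convolve(pos, kern, mode="valid") / g
    nn_w = np.convolve(neg, kern, mode="valid") / g
    tot = np_w + nn_w
    sig = np.zeros_like(tot)
    mask = tot > 0
    sig[mask] = (np_w[mask] - nn_w[mask]) ** 2 / tot[mask]
    return sig


def _delta(q: np.ndarray, g: int) -> float:
    n_pos = float((q > 0).sum())
    n_neg = float((q < 0).sum())
    L = len(q)
    f_tot = (n_pos + n_neg) / L
    sigma_global = 0.0 if f_tot == 0 else ((n_pos - n_neg) / L) ** 2 / f_tot
    sig = _sigma_windows(q, g)
    return float(np.mean((sig - sigma_global) ** 2))


def _delta_avg(q: np.ndarray, blobs: tuple[int, ...] = (5, 6)) -> float:
    return float(np.mean([_delta(q, g) for g in blobs]))


def _block_pattern(n_neg: int, n_pos: int, length: int, a: int, mid: int) -> np.ndarray:
    """Charge pattern: a neutrals, negative block, mid neutrals, positive
    block, remaining neutrals."""
    q = np.zeros(length)
    q[a:a + n_neg] = -1.0
    q[a + n_neg + mid:a + n_neg + mid + n_pos] = 1.0
    return q


def _max_segregated_pattern(n_neg: int, n_pos: int, length: int,
                            blobs: tuple[int, ...] = (5, 6)) -> np.ndarray:
    """Charge pattern maximizing the blob-averaged delta over arrangements
    with contiguous charge blocks (all neutral-split placements), polished
    by a deterministic swap hill-climb for short sequences.

    A single fixed pattern (such as charges at the two ends) does not
    maximize delta for every composition — interior blocks are covered by
    more windows — so the whole family must be searched for the
    normalization kappa <= 1 to hold.
    """
    n_neu = length - n_neg - n_pos
    cap = 10  # pad sizes above ~2 blob sizes are interchangeable
    if n_neu <= 2 * cap:
        splits = [(a, m) for a in range(n_neu + 1) for m in range(n_neu - a + 1)]
    else:
        offs = list(range(cap + 1)) + [n_neu]
        splits = [(a, m) for a in offs for m in offs if a + m <= n_neu]
    best_q, best = None, -1.0
    for a, m in splits:
        q = _block_pattern(n_neg, n_pos, length, a, m)
        d = _delta_avg(q, blobs)
        if d > best:
            best_q, best = q, d
    if length <= 200:
        # first-improvement swap polish, deterministic scan order
        q = best_q.copy()
        for _ in range(50):
            improved = False
            for i in range(length):
                for j in range(i + 1, length):
                    if q[i] == q[j]:
                        continue
                    q[i], q[j] = q[j], q[i]
                    d = _delta_avg(q, blobs)
                    if d > best + 1e-15:
                        best, improved = d, True
                    else:
                        q[i], q[j] = q[j], q[i]
            if not improved:
                break
        best_q = q
    return best_q


_DMAX_CACHE: dict[tuple, float] = {}


def _delta_max(n_neg: int, n_pos: int, length: int,
               blobs: tuple[int, ...] = (5, 6)) -> float:
    key = (n_neg, n_pos, length, blobs)
    if key not in _DMAX_CACHE:
        q = _max_segregated_pattern(n_neg, n_pos, length, blobs)
        _DMAX_CACHE[key] = _delta_avg(q, blobs)
    return _DMAX_CACHE[key]


def segregated_arrangement(seq) -> str:
    """Composition-preserving arrangement maximizing the blob-averaged
    charge-asymmetry variance delta (kappa = 1 by construction)."""
    rec = _as_record(seq)
    neg = [c for c in rec.seq if c in NEGATIVE]
    neu = [c for c in rec.seq if c not in NEGATIVE and c not in POSITIVE]
    pos = [c for c in rec.seq if c in POSITIVE]
    pattern = _max_segregated_pattern(len(neg), len(pos), len(rec.seq))
    out = []
    for v in pattern:
        out.append(neg.pop() if v < 0 else (pos.pop() if v > 0 else neu.pop()))
    return "".join(out)


def kappa(seq, blobs: tuple[int, int] = (5, 6)) -> float | None:
    """Charge-patterning asymmetry kappa in [0, 1]; None when undefined.

    kappa = delta / delta_max, where delta averages the squared deviation
    of blob-level charge asymmetry from the whole-sequence value over
    sliding blobs of sizes 5 and 6, and delta_max is the same quantity for
    the maximally segregated arrangement of the identical composition.
    Undefined (None) for sequences with no charged residues, sequences
    shorter than the largest blob, and degenerate compositions where even
    the segregated reference has zero blob-level variance (for example all
    charges of one sign).
    """
    rec = _as_record(seq)
    q = _charges(rec.seq)
    if not np.any(q != 0):
        return None
    if len(rec.seq) < max(blobs):
        return None
    n_neg = int((q < 0).sum())
    n_pos = int((q > 0).sum())
    dmax = _delta_max(n_neg, n_pos, len(rec.seq), tuple(blobs))
    if dmax <= 0:
        return None
    return _delta_avg(q, tuple(blobs)) / dmax


# ---------------------------------------------------------------------------
# Patterning decorations

def scd(seq) -> float:
    """Sequence charge decoration: (1/L) sum_{i<j} q_i q_j sqrt(j-i)."""
    rec = _as_record(seq)
    L = len(rec.seq)
    if L < 2:
        raise ValueError("SCD requires a sequence of length >= 2")
    q = _charges(rec.seq)
    idx = np.nonzero(q)[0]
    if len(idx) < 2:
        return 0.0
    qi = q[idx]
    sep = np.abs(idx[:, None] - idx[None, :])
    prod = qi[:, None] * qi[None, :] * np.sqrt(sep)
    iu = np.triu_indices(len(idx), k=1)
    return float(prod[iu].sum() / L)


def shd(seq, scale: Mapping[str, float] | None = None) -> float:
    """Sequence hydropathy decoration: (1/L) sum_{i<j} (h_i + h_j) / (j-i)."""
    rec = _as_record(seq)
    L = len(rec.seq)
    if L < 2:
        raise ValueError("SHD requires a sequence of length >= 2")
    scale = scale or hydropathy_scale()
    h = np.array([scale[ch] for ch in rec.seq])
    i = np.arange(L)
    sep = (i[None, :] - i[:, None]).astype(float)
    pair = h[:, None] + h[None, :]
    iu = np.triu_indices(L, k=1)
    return float((pair[iu] / sep[iu]).sum() / L)


# ---------------------------------------------------------------------------
# Aggregate

def compute_features(seq, scale: Mapping[str, float] | None = None) -> FeatureVector:
    rec = _as_record(seq)
    fr = compute_fractions(rec, scale=scale)
    ncpr, fcr = ncpr_fcr(rec)
    mean_h = fr.pop("mean_hydropathy")
    return FeatureVector(
        fcr=fcr,
        ncpr=ncpr,
        kappa=kappa(rec),
        scd=scd(rec) if len(rec) >= 2 else 0.0,
        shd=shd(rec, scale=scale) if len(rec) >= 2 else 0.0,
        mean_hydropathy=mean_h,
        class_fractions=fr,
    )


def feature_table(records: Sequence[SequenceRecord], scale=None):
    """One row per record with every FeatureVector field (pandas DataFrame)."""
    import pandas as pd

    rows = []
    for rec in records:
        fv = compute_features(rec, scale=scale)
        row = {
            "id": rec.id,
            "length": len(rec),
            "fcr": fv.fcr,
            "ncpr": fv.ncpr,
            "kappa": np.nan if fv.kappa is None else fv.kappa,
            "scd": fv.scd,
            "shd": fv.shd,
            "mean_hydropathy": fv.mean_hydropathy,
        }
        row.update({f"frac_{k}": v for k, v in fv.class_fractions.items()})
        rows.append(row)
    return pd.DataFrame(rows)
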