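"""Synthetic disordered-sequence design.

Builds libraries of synthetic IDR-like sequences that titrate one sequence
feature (composition, NCPR, FCR, kappa, mean hydropathy) while holding the
others approximately fixed, plus sticker--spacer block constructs
(glycine--serine spacers with polytyrosine stickers).

All designs draw from a disorder-promoting alphabet. Remainder composition
is filled from a neutral background (G, S, N, Q, T by default) so that
background fill never perturbs charge-targeted designs. An optional
``disorder_filter`` hook (sequence -> bool) lets callers plug in an external
disorder predictor; designs failing the filter are resampled.

Every designer is deterministic given its seed: the same spec and seed
produce the identical sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from . import seqfeatures
from .seqfeatures import SequenceRecord, hydropathy_scale

__all__ = [
    "DesignSpec",
    "SequenceLibrary",
    "DesignError",
    "design_by_composition",
    "design_by_kappa",
    "design_titration_series",
    "build_sticker_spacer",
    "DISORDER_ALPHABET",
    "NEUTRAL_BACKGROUND",
]

#: Disorder-promoting residues available to the designers.
DISORDER_ALPHABET = "GSTNQPEDKRA"
#: Default fill alphabet: neutral, disorder-promoting.
NEUTRAL_BACKGROUND = "GSNQT"

MIN_LEN, MAX_LEN = 10, 750


class DesignError(ValueError):
    """A design target is infeasible or was not reached."""


@dataclass(frozen=True)
class DesignSpec:
    length: int
    feature: str
    target_value: object
    tolerance: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not (MIN_LEN <= self.length <= MAX_LEN):
            raise ValueError(f"length {self.length} outside [{MIN_LEN}, {MAX_LEN}]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class SequenceLibrary:
    records: list[SequenceRecord] = field(default_factory=list)
    provenance: list[dict] = field(default_factory=list)
    failures: list[dict] = field(default_factory=list)

    def __len__(self):
        return len(self.records)

    def provenance_frame(self):
        import pandas as pd

        return pd.DataFrame(self.provenance)


# ---------------------------------------------------------------------------

def _largest_remainder_counts(targets: Mapping[str, float], length: int) -> dict[str, int]:
    """Integer counts summing to ``length`` from fractional targets
    (largest-remainder apportionment)."""
    keys = sorted(targets)
    raw = {k: targets[k] * length for k in keys}
    base = {k: math.floor(raw[k]) for k in keys}
    short = length - sum(base.values())
    if short < 0:
        raise DesignError("fractions imply more residues than the length")
    # ties broken deterministically by remainder then residue letter
    order = sorted(keys, key=lambda k: (-(raw[k] - base[k]), k))
    for k in order[:short]:
        base[k] += 1
    return {k: v for k, v in base.items() if v > 0}


def design_by_composition(
    fractions: Mapping[str, float],
    length: int,
    seed: int = 0,
    background: str = NEUTRAL_BACKGROUND,
    record_id: str | None = None,
    disorder_filter: Callable[[str], bool] | None = None,
    max_resample: int = 50,
) -> SequenceRecord:
    """Design a sequence with prescribed residue fractions.

    Specified fractions are apportioned exactly (largest remainder); the
    remaining mass is split uniformly over the ``background`` alphabet.
    Positions are shuffled by a seeded generator.
    """
    if length < MIN_LEN or length > MAX_LEN:
        raise DesignError(f"length {length} outside [{MIN_LEN}, {MAX_LEN}]")
    fractions = {k.upper(): float(v) for k, v in fractions.items()}
    for k, v in fractions.items():
        if k not in seqfeatures._CANONICAL_SET:
            raise DesignError(f"non-canonical residue {k!r} in composition")
        if v < 0:
            raise DesignError(f"negative fraction for {k!r}")
    total = sum(fractions.values())
    if total > 1.0 + 1e-9:
        raise DesignError(f"fractions sum to {total:.3f} > 1")
    remainder = max(0.0, 1.0 - total)
    full = dict(fractions)
    bg = [c for c in background.upper() if c not in full] or list(background.upper())
    for c in bg:
        full[c] = full.get(c, 0.0) + remainder / len(bg)
    counts = _largest_remainder_counts(full, length)
    # exactness guarantee for explicitly specified residues whose target
    # count is an integer (e.g. {Y: 0.1} at length 100 -> exactly 10 Y)
    rng = np.random.default_rng(seed)
    for attempt in range(max_resample):
        letters = [c for c, n in sorted(counts.items()) for _ in range(n)]
        arr = np.array(letters)
        rng.shuffle(arr)
        seq = "".join(arr)
        if disorder_filter is None or disorder_filter(seq):
            return SequenceRecord(record_id or f"comp_{seed}", seq)
    raise DesignError("disorder filter rejected all resampled designs")


def _kappa_fast(seq_arr: np.ndarray) -> float | None:
    return seqfeatures.kappa("".join(seq_arr))


def design_by_kappa(
    composition: Mapping[str, float],
    target_kappa: float,
    tolerance: float = 0.02,
    length: int = 100,
    seed: int = 0,
    max_swaps: int = 100_000,
    record_id: str | None = None,
) -> SequenceRecord:
    """Design a sequence of fixed composition with kappa near a target.

    Starts from a shuffled composition design and runs a seeded greedy
    position-swap search (with occasional uphill acceptance) on |kappa -
    target|. ``target_kappa = 1`` returns the segregated arrangement in
    closed form.
    """
    if not (0.0 <= target_kappa <= 1.0):
        raise DesignError("target kappa must lie in [0, 1]")
    base = design_by_composition(composition, length, seed=seed, record_id=record_id)
    if seqfeatures.kappa(base.seq) is None:
        raise DesignError("composition has no (or degenerate) charge content; kappa undefined")
    rid = record_id or f"kappa_{target_kappa:g}_{seed}"
    if target_kappa == 1.0:
        return SequenceRecord(rid, seqfeatures.segregated_arrangement(base.seq))

    rng = np.random.default_rng(seed + 1)
    arr = np.array(list(base.seq))
    cur = seqfeatures.kappa("".join(arr))
    best, best_arr = abs(cur - target_kappa), arr.copy()
    err = best
    for it in range(max_swaps):
        if err <= tolerance:
            return SequenceRecord(rid, "".join(arr))
        i, j = rng.integers(0, length, size=2)
        if arr[i] == arr[j]:
            continue
        arr[i], arr[j] = arr[j], arr[i]
        k = seqfeatures.kappa("".join(arr))
        new_err = abs(k - target_kappa)
        # greedy with a small seeded uphill probability to escape plateaus
        if new_err <= err or rng.random() < 0.02:
            err = new_err
            if new_err < best:
                best, best_arr = new_err, arr.copy()
        else:
            arr[i], arr[j] = arr[j], arr[i]
    if best <= tolerance:
        return SequenceRecord(rid, "".join(best_arr))
    raise DesignError(
        f"kappa target {target_kappa} unreachable within {max_swaps} swaps; "
        f"best |kappa - target| = {best:.4f}"
    )


# ---------------------------------------------------------------------------
# Feature-specific composition builders used by the titration driver.

def _composition_for_ncpr(ncpr: float, fcr: float | None = None) -> dict[str, float]:
    if fcr is None:
        fcr = max(abs(ncpr), 0.4)
    if abs(ncpr) > fcr + 1e-9 or fcr > 1:
        raise DesignError(f"ncpr {ncpr} incompatible with fcr {fcr}")
    return {"K": (fcr + ncpr) / 2, "E": (fcr - ncpr) / 2}


def _composition_for_fcr(fcr: float) -> dict[str, float]:
    if not (0 <= fcr <= 1):
        raise DesignError(f"fcr {fcr} outside [0, 1]")
    return {"K": fcr / 2, "E": fcr / 2}


def _composition_for_hydropathy(target: float) -> dict[str, float]:
    """Two-component A/Q mixture hitting a mean (normalized Kyte--Doolittle)
    hydropathy target; achievable range is [h(Q), h(A)]."""
    scale = hydropathy_scale()
    lo, hi = scale["Q"], scale["A"]
    if not (lo - 1e-9 <= target <= hi + 1e-9):
        raise DesignError(f"hydropathy {target:.3f} outside achievable [{lo:.3f}, {hi:.3f}]")
    x = (target - lo) / (hi - lo)
    return {"A": x, "Q": 1 - x}


def design_titration_series(
    feature: str,
    values: Sequence,
    n_per_value: int = 100,
    length: int = 100,
    seed: int = 0,
    tolerance: float = 0.02,
    kappa_composition: Mapping[str, float] | None = None,
) -> SequenceLibrary:
    """Design ``len(values) x n_per_value`` sequences titrating one feature.

    Defaults (100 sequences per value, length 100) match the study design
    this library emulates. Each record gets a distinct deterministic seed;
    infeasible values are recorded as failures and the series continues.
    """
    if n_per_value < 1:
        raise DesignError("n_per_value must be >= 1")
    feature = feature.lower()
    lib = SequenceLibrary()
    seed_stream = np.random.default_rng(seed).integers(0, 2**31 - 1, size=len(values) * n_per_value)
    si = 0
    for vi, value in enumerate(values):
        for rep in range(n_per_value):
            rec_seed = int(seed_stream[si]); si += 1
            rid = f"{feature}_{vi}_{rep}"
            try:
                if feature in ("composition", "composition-fractions"):
                    rec = design_by_composition(value, length, seed=rec_seed, record_id=rid)
                    achieved = None
                elif feature == "ncpr":
                    rec = design_by_composition(_composition_for_ncpr(float(value)),
                                                length, seed=rec_seed, record_id=rid)
                    achieved = seqfeatures.ncpr_fcr(rec)[0]
                elif feature == "fcr":
                    rec = design_by_composition(_composition_for_fcr(float(value)),
                                                length, seed=rec_seed, record_id=rid)
                    achieved = seqfeatures.ncpr_fcr(rec)[1]
                elif feature == "hydropathy":
                    rec = design_by_composition(_composition_for_hydropathy(float(value)),
                                                length, seed=rec_seed, record_id=rid)
                    achieved = seqfeatures.compute_fractions(rec)["mean_hydropathy"]
                elif feature == "kappa":
                    comp = dict(kappa_composition or {"K": 0.25, "E": 0.25})
                    rec = design_by_kappa(comp, float(value), tolerance=tolerance,
                                          length=length, seed=rec_seed, record_id=rid)
                    achieved = seqfeatures.kappa(rec.seq)
                else:
                    raise DesignError(f"unknown titration feature {feature!r}")
            except DesignError as exc:
                lib.failures.append({"feature": feature, "value": value,
                                     "seed": rec_seed, "error": str(exc)})
                continue
            if achieved is not None and abs(achieved - float(value)) > max(tolerance, 1.0 / length):
                lib.failures.append({"feature": feature, "value": value, "seed": rec_seed,
                                     "error": f"achieved {achieved:.4f} outside tolerance"})
                continue
            lib.records.append(rec)
            lib.provenance.append({
                "id": rec.id, "feature": feature, "target": value,
                "achieved": achieved, "seed": rec_seed, "length": length,
            })
    return lib


def build_sticker_spacer(n_repeats: int = 8, spacer_len: int = 2, sticker_len: int = 1,
                         record_id: str | None = None) -> SequenceRecord:
    """Sticker--spacer construct: ``n_repeats`` blocks of (GS)*(spacer_len/2)
    followed by Y*sticker_len.

    Spacers are glycine--serine dipeptide repeats 2--120 residues long;
    stickers are 0--8 tyrosines.
    """
    if n_repeats < 1:
        raise DesignError("n_repeats must be >= 1")
    if spacer_len % 2 != 0:
        raise DesignError("spacer_len must be even (GS dipeptide repeats)")
    if not (2 <= spacer_len <= 120):
        raise DesignError("spacer_len must lie in [2, 120]")
    if not (0 <= sticker_len <= 8):
        raise DesignError("sticker_len must lie in [0, 8]")
    block = "GS" * (spacer_len // 2) + "Y" * sticker_len
    rid = record_id or f"ss_n{n_repeats}_sp{spacer_len}_st{sticker_len}"
    return SequenceRecord(rid, block * n_repeats)
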