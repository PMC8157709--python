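"""RNAi trigger design with homoeolog coverage and paralog discrimination.

In allotetraploid tobacco every target exists as an S-genome and a T-genome
copy (homoeologs) at roughly 95% nucleotide identity.  A single hairpin
trigger should silence both copies, so the designer slides a fixed-length
window (default 430 nt) along the S/T global alignment and prefers the most
conserved window.  Where a target belongs to a multi-member family (e.g. the
three NtBl or four NtCUC genes), the trigger must *not* silence the sibling
paralogs, so windows whose best gapless match against any paralog — on either
strand, since hairpin RNAi produces sense and antisense small RNAs — reaches
the paralog identity cap (default 70%) are rejected.

Objective: maximize the S/T window identity subject to the hard paralog cap;
ties break to the leftmost window.  Paralog window identity is a gapless
sliding comparison (matches / window length, maximized over all offsets and
both strands), consistent with the substitution-dominated divergence of
recently duplicated plant genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .seqcore import (
    IdentityProfile,
    SequenceError,
    Subgenome,
    Transcript,
    global_align,
    reverse_complement,
    windowed_identity,
)

__all__ = [
    "HomoeologPair",
    "DesignConfig",
    "TriggerCandidate",
    "NoValidTriggerError",
    "homoeolog_window_scan",
    "paralog_discrimination_scan",
    "paralog_max_identity_profile",
    "design_trigger",
    "summarize_triggers",
]

_N_CODE = ord("N")


class NoValidTriggerError(SequenceError):
    """No window satisfies both identity constraints.

    ``diagnostics`` lists, per candidate window start, which constraint was
    binding (``"st_identity"``, ``"paralog"`` or ``"both"``).
    """

    def __init__(self, family_id: str, diagnostics: list[tuple[int, str]]):
        self.family_id = family_id
        self.diagnostics = diagnostics
        n_par = sum(1 for _, why in diagnostics if why in ("paralog", "both"))
        n_st = sum(1 for _, why in diagnostics if why in ("st_identity", "both"))
        super().__init__(
            f"family {family_id!r}: no valid trigger window "
            f"({n_st} windows below the homoeolog identity floor, "
            f"{n_par} windows at or above the paralog identity cap)"
        )


@dataclass
class HomoeologPair:
    """An S-gene and its T-genome counterpart."""

    s_gene: Transcript
    t_gene: Transcript
    family_id: str

    def __post_init__(self) -> None:
        if self.s_gene.subgenome is not Subgenome.S:
            raise SequenceError(f"family {self.family_id!r}: s_gene must carry subgenome tag S")
        if self.t_gene.subgenome is not Subgenome.T:
            raise SequenceError(f"family {self.family_id!r}: t_gene must carry subgenome tag T")


@dataclass(frozen=True)
class DesignConfig:
    trigger_length_nt: int = 430
    min_st_identity_pct: float = 90.0
    max_paralog_identity_pct: float = 70.0
    step_nt: int = 1
    source_subgenome: Subgenome = Subgenome.S  # which copy the trigger is cut from
    scan_both_strands: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.max_paralog_identity_pct < self.min_st_identity_pct <= 100):
            raise ValueError(
                "require 0 < max_paralog_identity_pct < min_st_identity_pct <= 100"
            )
        if self.trigger_length_nt < 1 or self.step_nt < 1:
            raise ValueError("trigger_length_nt and step_nt must be >= 1")


@dataclass
class TriggerCandidate:
    """A designed trigger window on the source gene (0-based, half-open)."""

    family_id: str
    source_gene_id: str
    start: int
    end: int
    sequence: str
    st_identity_pct: float
    max_paralog_identity_pct: float  # 0.0 when no paralogs were supplied
    paralog_identities: dict[str, float] = field(default_factory=dict)

    @property
    def length_nt(self) -> int:
        return self.end - self.start


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _sliding_max_matches(target: np.ndarray, paralog: np.ndarray, window: int) -> np.ndarray:
    """Max gapless match count per window start on ``target`` over all paralog offsets.

    Lag decomposition: for offset o = s + d the match count of window start s
    is a length-``window`` sum along diagonal d, computed with one cumulative
    sum per diagonal.  Only offsets placing the full window inside the
    paralog are considered.
    """
    n, m = len(target), len(paralog)
    n_windows = n - window + 1
    best = np.zeros(n_windows, dtype=np.int64)
    if m < window or n_windows <= 0:
        return best
    for d in range(-(n - window), m - window + 1):
        i0 = max(0, -d)
        i1 = min(n, m - d)
        s_lo = i0
        s_hi = min(n_windows - 1, i1 - window)
        if s_hi < s_lo:
            continue
        seg_t = target[i0:i1]
        seg_p = paralog[i0 + d : i1 + d]
        eq = (seg_t == seg_p) & (seg_t != _N_CODE)
        cum = np.concatenate(([0], np.cumsum(eq)))
        # window sum for start s: cum[s - i0 + window] - cum[s - i0]
        lo = s_lo - i0
        hi = s_hi - i0
        sums = cum[lo + window : hi + window + 1] - cum[lo : hi + 1]
        np.maximum(best[s_lo : s_hi + 1], sums, out=best[s_lo : s_hi + 1])
    return best


def _max_matches_any_overlap(window: np.ndarray, paralog: np.ndarray) -> int:
    """Best gapless match count over all lags, allowing partial overlap.

    Used when the paralog is shorter than the window; the denominator stays
    the window length, so short paralogs can never reach 100%.
    """
    w, m = len(window), len(paralog)
    best = 0
    for d in range(-(w - 1), m):
        i0 = max(0, -d)
        i1 = min(w, m - d)
        if i1 <= i0:
            continue
        seg_w = window[i0:i1]
        seg_p = paralog[i0 + d : i1 + d]
        best = max(best, int(((seg_w == seg_p) & (seg_w != _N_CODE)).sum()))
    return best


def homoeolog_window_scan(pair: HomoeologPair, config: DesignConfig) -> IdentityProfile:
    """Windowed S/T identity profile along the source gene."""
    source, other = _oriented(pair, config)
    if source.length_nt < config.trigger_length_nt:
        raise SequenceError(
            f"family {pair.family_id!r}: gene {source.id!r} is shorter "
            f"({source.length_nt} nt) than the trigger length "
            f"({config.trigger_length_nt} nt); configure a shorter trigger"
        )
    aln = global_align(source.sequence, other.sequence)
    return windowed_identity(aln, config.trigger_length_nt, config.step_nt)


def _oriented(pair: HomoeologPair, config: DesignConfig) -> tuple[Transcript, Transcript]:
    if config.source_subgenome is Subgenome.T:
        return pair.t_gene, pair.s_gene
    return pair.s_gene, pair.t_gene


def paralog_discrimination_scan(
    window_sequence: str,
    paralogs: Iterable[Transcript],
    scan_both_strands: bool = True,
) -> dict[str, float]:
    """Best gapless identity of the window against each paralog (max over offsets).

    Both strands of the paralog are scanned by default.  Identity is
    matches / window length, in percent.  Empty paralog set gives an empty
    map (the discrimination constraint is then vacuously satisfied).
    """
    w = _encode(window_sequence.upper())
    out: dict[str, float] = {}
    for p in paralogs:
        variants = [p.sequence]
        if scan_both_strands:
            variants.append(reverse_complement(p.sequence))
        best = 0
        for seq in variants:
            arr = _encode(seq)
            if len(arr) >= len(w):
                best = max(best, int(_sliding_max_matches(w, arr, len(w)).max()))
            else:
                best = max(best, _max_matches_any_overlap(w, arr))
        out[p.id] = 100.0 * best / len(w)
    return out


def paralog_max_identity_profile(
    source_sequence: str,
    paralogs: Sequence[Transcript],
    window: int,
    scan_both_strands: bool = True,
) -> np.ndarray:
    """Per-window-start max gapless identity (pct) against any paralog, any strand."""
    target = _encode(source_sequence.upper())
    n_windows = len(target) - window + 1
    best = np.zeros(n_windows, dtype=np.int64)
    for p in paralogs:
        variants = [p.sequence]
        if scan_both_strands:
            variants.append(reverse_complement(p.sequence))
        for seq in variants:
            arr = _encode(seq)
            if len(arr) >= window:
                np.maximum(best, _sliding_max_matches(target, arr, window), out=best)
            else:
                # paralog shorter than the window: evaluate per window start (rare path)
                for s in range(n_windows):
                    best[s] = max(
                        best[s], _max_matches_any_overlap(target[s : s + window], arr)
                    )
    return 100.0 * best / window


def design_trigger(
    pair: HomoeologPair,
    paralogs: Sequence[Transcript] = (),
    config: DesignConfig = DesignConfig(),
) -> TriggerCandidate:
    """Choose the trigger window for one target family.

    Returns the window maximizing S/T identity among windows whose best
    paralog identity is strictly below the cap and whose S/T identity meets
    the floor; ties break to the leftmost window.  Raises
    :class:`NoValidTriggerError` (with per-window diagnostics) when no window
    qualifies.
    """
    profile = homoeolog_window_scan(pair, config)
    source, _ = _oriented(pair, config)
    starts = np.asarray(profile.starts, dtype=np.int64)
    st = np.asarray(profile.identities, dtype=float)
    if paralogs:
        full = paralog_max_identity_profile(
            source.sequence, paralogs, config.trigger_length_nt, config.scan_both_strands
        )
        pmax = full[starts]
    else:
        pmax = np.zeros_like(st)
    ok_st = st >= config.min_st_identity_pct
    ok_par = pmax < config.max_paralog_identity_pct
    valid = ok_st & ok_par
    if not valid.any():
        why = np.where(
            ~ok_st & ~ok_par, "both", np.where(~ok_st, "st_identity", "paralog")
        )
        raise NoValidTriggerError(
            pair.family_id, list(zip(starts.tolist(), why.tolist()))
        )
    idx = np.flatnonzero(valid)
    chosen = idx[np.argmax(st[idx])]  # argmax returns the first maximum -> leftmost
    s = int(starts[chosen])
    e = s + config.trigger_length_nt
    window_seq = source.sequence[s:e]
    paralog_ids = paralog_discrimination_scan(
        window_seq, paralogs, config.scan_both_strands
    )
    return TriggerCandidate(
        family_id=pair.family_id,
        source_gene_id=source.id,
        start=s,
        end=e,
        sequence=window_seq,
        st_identity_pct=float(st[chosen]),
        max_paralog_identity_pct=max(paralog_ids.values(), default=0.0),
        paralog_identities=paralog_ids,
    )


def summarize_triggers(candidates: Sequence[TriggerCandidate]) -> dict[str, float]:
    """n, mean trigger length (nt) and mean S/T identity (%) over a design run."""
    if not candidates:
        raise ValueError("no trigger candidates to summarize")
    lengths = [c.length_nt for c in candidates]
    idents = [c.st_identity_pct for c in candidates]
    return {
        "n": len(candidates),
        "mean_length_nt": float(np.mean(lengths)),
        "mean_st_identity_pct": float(np.mean(idents)),
    }
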