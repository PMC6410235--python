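"""Exon-to-genome alignment: k-mer seeding plus semi-global affine-gap DP.

Each reference exon is located in a target genomic sequence in two steps:

1. :func:`seed_candidates` finds maximal clusters of exact shared k-mers
   (default word size 10) between exon and target, merged within a
   diagonal band, and returns candidate windows sorted by seed support.
2. :func:`align_exon` aligns the exon to a candidate window with a
   three-state affine-gap recurrence (Gotoh), global in the exon and with
   free end-gaps in the window, so the exon may land anywhere inside it.

Assembly gaps (N) score 0 against any base — neither match nor mismatch —
so runs of N can neither fake nor hide a mutation.

The DP is vectorized row-wise with numpy; the horizontal gap state is
computed with a running-maximum scan, which is exact whenever
``gap_open <= gap_extend`` (opening a fresh gap from inside a gap never
beats extending).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .gene_models import GeneModel, Genome, extract_exon

__all__ = [
    "ScoringScheme",
    "ExonAlignment",
    "GeneMapping",
    "seed_candidates",
    "seed_clusters",
    "align_exon",
    "map_gene",
]

NEG_INF = np.iinfo(np.int32).min // 4

#: minimum clustered word hits for a sub-threshold placement to count as
#: remnant evidence (a decayed exon leaves tens of clustered hits; an
#: isolated chance repeat only a handful)
REMNANT_MIN_SEED_SUPPORT = 5


@dataclass(frozen=True)
class ScoringScheme:
    """Blastn-like alignment parameters.

    A gap of length g scores ``gap_open + gap_extend * (g - 1)``.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    word_size: int = 10

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch >= 0:
            raise ValueError("mismatch penalty must be negative")
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError("require gap_open <= gap_extend < 0")
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")


@dataclass
class ExonAlignment:
    """One exon aligned (or not) to a target interval.

    ``aligned_columns`` is a list of ``(ref_pos | None, target_pos | None)``
    pairs; ``None`` marks a gap on that side. Positions are 0-based: ref
    positions are exon-local, target positions are target-sequence
    coordinates.
    """

    exon_index: int
    target_interval: tuple[int, int] | None
    aligned_columns: list[tuple[int | None, int | None]]
    identity: float
    score: int
    status: str  # mapped | missing_in_gap | missing_no_gap | low_identity
    seed_support: int = 0  # clustered word hits behind this placement

    @property
    def mapped(self) -> bool:
        return self.status == "mapped"


@dataclass
class GeneMapping:
    """Per-species projection of all reference exons onto one target."""

    species_id: str
    gene_id: str
    target_id: str
    exon_alignments: list[ExonAlignment]
    colinear: bool = True

    def exon(self, index: int) -> ExonAlignment:
        return self.exon_alignments[index]

    @property
    def mapped_exons(self) -> list[ExonAlignment]:
        return [a for a in self.exon_alignments if a.mapped]


def _encode(seq: str) -> np.ndarray:
    # A,C,G,T -> 0..3, N/other -> 4
    table = np.full(256, 4, dtype=np.int8)
    for i, base in enumerate("ACGT"):
        table[ord(base)] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def seed_candidates(
    exon_seq: str, target: str, scheme: ScoringScheme | None = None
) -> list[tuple[int, int]]:
    """Candidate target intervals that may contain the exon.

    Exact shared k-mers are clustered by alignment diagonal (band width 50
    to tolerate moderate indels); each cluster's target footprint is
    expanded by one exon length on both sides. Candidates are sorted by
    number of supporting k-mer hits (descending), ties broken by leftmost
    target start. Overlapping expanded windows are merged.
    """
    return [(lo, hi) for _support, lo, hi in seed_clusters(exon_seq, target, scheme)]


def seed_clusters(
    exon_seq: str, target: str, scheme: ScoringScheme | None = None
) -> list[tuple[int, int, int]]:
    """Like :func:`seed_candidates` but keeps the k-mer hit count:
    ``(support, window_start, window_end)`` per merged cluster."""
    scheme = scheme or ScoringScheme()
    k = scheme.word_size
    if len(exon_seq) < k:
        raise ValueError("exon shorter than word size")
    index: dict[str, list[int]] = {}
    for j in range(len(target) - k + 1):
        word = target[j : j + k]
        if "N" in word:
            continue
        index.setdefault(word, []).append(j)
    hits: list[tuple[int, int]] = []  # (diagonal, target_pos)
    for q in range(len(exon_seq) - k + 1):
        word = exon_seq[q : q + k]
        for j in index.get(word, ()):
            hits.append((j - q, j))
    if not hits:
        return []
    hits.sort()
    band = 50
    clusters: list[list[tuple[int, int]]] = []
    for diag, j in hits:
        if clusters and diag - clusters[-1][-1][0] <= band:
            clusters[-1].append((diag, j))
        else:
            clusters.append([(diag, j)])
    flank = len(exon_seq)
    raw = []
    for cl in clusters:
        lo = min(j for _, j in cl)
        hi = max(j for _, j in cl) + k
        raw.append((len(cl), max(0, lo - flank), min(len(target), hi + flank)))
    raw.sort(key=lambda t: (-t[0], t[1]))
    # merge overlapping windows, keeping the stronger cluster's rank
    merged: list[tuple[int, int, int]] = []
    for support, lo, hi in raw:
        for i, (ms, mlo, mhi) in enumerate(merged):
            if lo < mhi and mlo < hi:
                merged[i] = (max(ms, support), min(mlo, lo), max(mhi, hi))
                break
        else:
            merged.append((support, lo, hi))
    merged.sort(key=lambda t: (-t[0], t[1]))
    return merged


def _dp_matrices(
    x: np.ndarray, y: np.ndarray, scheme: ScoringScheme
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fill H (best), F (gap-in-target, vertical), E (gap-in-ref, horizontal)."""
    n, m = len(x), len(y)
    go, ge = scheme.gap_open, scheme.gap_extend
    H = np.empty((n + 1, m + 1), dtype=np.int32)
    F = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)
    H[0, :] = 0  # free leading target sequence (semi-global)
    for i in range(1, n + 1):
        H[i, 0] = go + ge * (i - 1)
        F[i, 0] = H[i, 0]
    js = np.arange(1, m + 1)
    for i in range(1, n + 1):
        xi = x[i - 1]
        sub = np.where(
            (xi == 4) | (y == 4),
            0,
            np.where(y == xi, scheme.match, scheme.mismatch),
        ).astype(np.int32)
        F[i, 1:] = np.maximum(H[i - 1, 1:] + go, F[i - 1, 1:] + ge)
        diag = H[i - 1, :-1] + sub
        h0 = np.maximum(diag, F[i, 1:])
        # E via running max: E[j] = max_{k<j} (H0[k] + go + ge*(j-1-k)),
        # exact because go <= ge (never better to re-open inside a gap).
        base = np.concatenate(([H[i, 0]], h0[:-1]))  # H candidates at col j-1
        a = base + go - ge * (js - 1)
        E[i, 1:] = np.maximum.accumulate(a) + ge * (js - 1)
        H[i, 1:] = np.maximum(h0, E[i, 1:])
    return H, F, E


def _traceback(
    x: np.ndarray,
    y: np.ndarray,
    H: np.ndarray,
    F: np.ndarray,
    E: np.ndarray,
    scheme: ScoringScheme,
    end_j: int,
) -> list[tuple[int | None, int | None]]:
    """Deterministic traceback, precedence diagonal > up (F) > left (E)."""
    go, ge = scheme.gap_open, scheme.gap_extend
    cols: list[tuple[int | None, int | None]] = []
    i, j = len(x), end_j
    state = "H"
    while i > 0:
        if state == "H":
            if j > 0:
                xi, yj = x[i - 1], y[j - 1]
                sub = 0 if (xi == 4 or yj == 4) else (
                    scheme.match if xi == yj else scheme.mismatch
                )
                if H[i, j] == H[i - 1, j - 1] + sub:
                    cols.append((i - 1, j - 1))
                    i -= 1
                    j -= 1
                    continue
            if H[i, j] == F[i, j]:
                state = "F"
            elif j > 0 and H[i, j] == E[i, j]:
                state = "E"
            else:  # row 0 free region handled by loop exit; defensive
                raise AssertionError("traceback dead end")
        elif state == "F":
            cols.append((i - 1, None))
            if i > 1 and F[i, j] == F[i - 1, j] + ge:
                i -= 1
            else:
                i -= 1
                state = "H"
        else:  # E
            cols.append((None, j - 1))
            if j > 1 and E[i, j] == E[i, j - 1] + ge:
                j -= 1
            else:
                j -= 1
                state = "H"
    cols.reverse()
    return cols


def align_exon(
    exon_seq: str,
    window: str,
    scheme: ScoringScheme | None = None,
    exon_index: int = 0,
    window_offset: int = 0,
    min_identity: float = 0.60,
    min_score_frac: float = 0.25,
) -> ExonAlignment:
    """Optimal semi-global affine-gap alignment of an exon inside a window.

    The exon is aligned end-to-end; leading/trailing window sequence is
    free. Among equally scoring end columns the leftmost is chosen.
    ``window_offset`` shifts reported target positions into the coordinate
    system of the full target sequence.

    A placement is accepted (status ``mapped``) only if identity over
    aligned columns reaches ``min_identity`` *and* the score reaches
    ``min_score_frac`` of the perfect score (match reward x exon length):
    under semi-global alignment a short relic fragment can meander
    through flanking sequence and collect enough chance matches to pass
    an identity cut alone, but its score density stays low.
    """
    if not exon_seq or not window:
        raise ValueError("empty sequence")
    scheme = scheme or ScoringScheme()
    x = _encode(exon_seq)
    y = _encode(window)
    H, F, E = _dp_matrices(x, y, scheme)
    last = H[len(x), :]
    score = int(last.max())
    end_j = int(np.argmax(last))  # leftmost maximum
    cols = _traceback(x, y, H, F, E, scheme, end_j)
    matches = sum(
        1
        for r, t in cols
        if r is not None and t is not None and x[r] == y[t] and x[r] != 4
    )
    identity = matches / len(cols) if cols else 0.0
    tpos = [t for _, t in cols if t is not None]
    interval = (
        (window_offset + tpos[0], window_offset + tpos[-1] + 1) if tpos else None
    )
    shifted = [
        (r, None if t is None else window_offset + t) for r, t in cols
    ]
    good_score = score >= min_score_frac * scheme.match * len(exon_seq)
    status = "mapped" if (identity >= min_identity and good_score) else "low_identity"
    return ExonAlignment(
        exon_index=exon_index,
        target_interval=interval,
        aligned_columns=shifted,
        identity=identity,
        score=score,
        status=status,
    )


def _n_fraction(seq: str) -> float:
    return seq.count("N") / len(seq) if seq else 0.0


def _expected_interval(
    model: GeneModel,
    exon_index: int,
    placed: dict[int, tuple[int, int]],
    target_len: int,
) -> tuple[int, int]:
    """Project where an unmapped exon should sit, from flanking mapped exons.

    Uses reference exon/intron spacing relative to the nearest mapped
    anchors on each side; clipped to the target.
    """
    ref_starts = []
    pos = 0
    for i in range(model.n_exons):
        ref_starts.append(pos)
        pos += model.exon_lengths[i]
        if i < model.n_exons - 1:
            lo, hi = sorted(
                [model.exons[i][1], model.exons[i + 1][0]]
            ) if model.strand == "+" else sorted(
                [model.exons[i + 1][1], model.exons[i][0]]
            )
            pos += hi - lo
    left_anchor = max((i for i in placed if i < exon_index), default=None)
    right_anchor = min((i for i in placed if i > exon_index), default=None)
    length = model.exon_lengths[exon_index]
    if left_anchor is not None:
        offset = ref_starts[exon_index] - (
            ref_starts[left_anchor] + model.exon_lengths[left_anchor]
        )
        start = placed[left_anchor][1] + offset
    elif right_anchor is not None:
        offset = ref_starts[right_anchor] - (ref_starts[exon_index] + length)
        start = placed[right_anchor][0] - offset - length
    else:
        return (0, target_len)
    start = max(0, min(start, target_len))
    end = max(0, min(start + length, target_len))
    return (start, end)


def map_gene(
    model: GeneModel,
    ref_genome: Genome,
    target_genome: Genome,
    target_id: str,
    species_id: str = "",
    scheme: ScoringScheme | None = None,
    min_identity: float = 0.60,
    gap_n_fraction: float = 0.30,
    max_candidates: int = 5,
) -> GeneMapping:
    """Seed and align every reference exon against one target sequence.

    Each exon is mapped independently; the best-scoring candidate window
    wins. Exons without seeds, or whose best alignment falls below the
    identity threshold, get a missing/low-identity status; the
    missing_in_gap vs missing_no_gap decision inspects the N content of
    the target interval projected from flanking mapped exons. Overlapping
    exon placements are resolved in favour of the higher score.
    """
    scheme = scheme or ScoringScheme()
    target = target_genome.sequences[target_id]
    alignments: list[ExonAlignment] = []
    for idx in range(model.n_exons):
        exon_seq = extract_exon(model, ref_genome, idx)
        if len(exon_seq) < scheme.word_size:
            candidates: list[tuple[int, int, int]] = []
        else:
            candidates = seed_clusters(exon_seq, target, scheme)
        best: ExonAlignment | None = None
        for support, lo, hi in candidates[:max_candidates]:
            aln = align_exon(
                exon_seq,
                target[lo:hi],
                scheme,
                exon_index=idx,
                window_offset=lo,
                min_identity=min_identity,
            )
            aln.seed_support = support
            if best is None or aln.score > best.score:
                best = aln
        if best is None:
            best = ExonAlignment(
                exon_index=idx,
                target_interval=None,
                aligned_columns=[],
                identity=0.0,
                score=0,
                status="missing_no_gap",  # refined below
            )
        alignments.append(best)

    # resolve overlapping placements: keep higher score, demote the other
    mapped = [a for a in alignments if a.mapped]
    mapped.sort(key=lambda a: -a.score)
    kept: list[ExonAlignment] = []
    for aln in mapped:
        lo, hi = aln.target_interval  # type: ignore[misc]
        clash = any(
            lo < k.target_interval[1] and k.target_interval[0] < hi  # type: ignore[index]
            for k in kept
        )
        if clash:
            aln.status = "low_identity"
        else:
            kept.append(aln)

    # refine missing statuses using projected intervals; sub-threshold
    # placements on too little seed support are chance hits, not remnants,
    # and are refined the same way
    placed = {
        a.exon_index: a.target_interval for a in alignments if a.mapped
    }
    for aln in alignments:
        weak = (
            aln.status == "low_identity"
            and aln.seed_support < REMNANT_MIN_SEED_SUPPORT
        )
        if aln.status == "missing_no_gap" or weak:
            lo, hi = _expected_interval(model, aln.exon_index, placed, len(target))
            region = target[lo:hi]
            if region and _n_fraction(region) >= gap_n_fraction:
                aln.status = "missing_in_gap"
                aln.target_interval = (lo, hi)
            else:
                aln.status = "missing_no_gap"
                aln.target_interval = (lo, hi) if region else None

    order = [a.target_interval for a in alignments if a.mapped]
    colinear = all(
        prev[1] <= nxt[0] for prev, nxt in zip(order, order[1:])
    )
    return GeneMapping(
        species_id=species_id,
        gene_id=model.gene_id,
        target_id=target_id,
        exon_alignments=alignments,
        colinear=colinear,
    )


def mapping_summary_rows(mapping: GeneMapping) -> list[dict]:
    """Per-exon TSV-ready summary (1-based inclusive coordinates)."""
    rows = []
    for aln in mapping.exon_alignments:
        iv = aln.target_interval
        rows.append(
            {
                "species": mapping.species_id,
                "gene": mapping.gene_id,
                "exon": aln.exon_index + 1,
                "target": mapping.target_id,
                "start": iv[0] + 1 if iv else ".",
                "end": iv[1] if iv else ".",
                "identity": round(aln.identity, 4),
                "score": aln.score,
                "status": aln.status,
            }
        )
    return rows
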