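"""Transcribed-segment calling from strand-specific nascent coverage.

Replicates are pooled per state, segments are called per chromosome-strand
either by a two-state Poisson-emission HMM (EM-fit, Viterbi-decoded) or by
a deterministic smoothed-threshold rule, and per-state segment sets can be
merged into maximal cross-state regions.
"""

from __future__ import annotations

import numpy as np

from .core import CoverageTrack, InputError, TranscribedSegment


def pool_state_coverage(tracks: list[CoverageTrack]) -> CoverageTrack:
    """Base-wise sum of replicate tracks (identical chromosome space required)."""
    if not tracks:
        raise InputError("need at least one replicate track")
    pooled = tracks[0].copy()
    for t in tracks[1:]:
        pooled.add(t)
    return pooled


def _runs_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def _join_and_filter(
    runs: list[tuple[int, int]], min_len: int, max_gap: float
) -> list[tuple[int, int]]:
    if not runs:
        return []
    joined = [list(runs[0])]
    for s, e in runs[1:]:
        if s - joined[-1][1] <= max_gap:
            joined[-1][1] = e
        else:
            joined.append([s, e])
    return [(s, e) for s, e in joined if e - s >= min_len]


def _smooth(arr: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return arr
    kernel = np.ones(window) / window
    return np.convolve(arr, kernel, mode="same")


def _threshold_mask(arr: np.ndarray, threshold: float, smooth_window: int) -> np.ndarray:
    return _smooth(arr, smooth_window) >= threshold


def _hmm_mask(arr: np.ndarray, max_iter: int = 200, tol: float = 1e-6) -> np.ndarray:
    """Viterbi state mask from an unsupervised two-state Poisson HMM."""
    from hmmlearn.hmm import PoissonHMM

    counts = np.rint(arr).astype(np.int64)
    if counts.max() == 0:
        return np.zeros(len(arr), dtype=bool)
    positive = counts[counts > 0]
    lam_hi = max(float(positive.mean()), 0.05)
    lam_lo = max(float(counts.mean()) / 10.0, 1e-3)
    model = PoissonHMM(n_components=2, n_iter=max_iter, tol=tol, init_params="", random_state=0)
    model.startprob_ = np.array([0.5, 0.5])
    model.transmat_ = np.array([[0.999, 0.001], [0.001, 0.999]])
    model.lambdas_ = np.array([[lam_lo], [lam_hi]])
    X = counts.reshape(-1, 1)
    try:
        model.fit(X)
        states = model.predict(X)
    except ValueError:
        return counts > 0
    hi = int(np.argmax(model.lambdas_.ravel()))
    return states == hi


def call_transcribed_segments(
    pooled: CoverageTrack,
    state: str,
    method: str = "threshold",
    min_len: int = 200,
    max_gap: int = 100,
    threshold: float = 1.0,
    smooth_window: int = 50,
) -> list[TranscribedSegment]:
    """Call sorted, non-overlapping transcribed segments per chromosome-strand.

    ``threshold``: bases whose ``smooth_window``-nt running-mean coverage is
    >= ``threshold`` form runs; runs closer than ``max_gap`` are joined and
    runs shorter than ``min_len`` dropped.  ``hmm``: two-state Poisson HMM
    fit by EM then Viterbi-decoded, with the same joining/length rules.
    All-zero coverage yields an empty segment set.
    """
    if method not in ("threshold", "hmm"):
        raise InputError(f"unknown segmentation method {method!r}")
    segments = []
    for chrom, strand in pooled.keys():
        arr = pooled.get(chrom, strand)
        if (arr < 0).any():
            raise InputError("coverage must be non-negative")
        if method == "threshold":
            mask = _threshold_mask(arr, threshold, smooth_window)
        else:
            if not (arr > 0).any():
                continue
            mask = _hmm_mask(arr)
        for s, e in _join_and_filter(_runs_from_mask(mask), min_len, max_gap):
            mean_cov = float(arr[s:e].mean())
            if mean_cov <= 0:
                continue
            segments.append(
                TranscribedSegment(
                    chrom=chrom, start=s, end=e, strand=strand, state=state, mean_coverage=mean_cov
                )
            )
    segments.sort(key=lambda g: (g.chrom, g.strand, g.start))
    return segments


def merge_segments_across_states(
    segment_sets: list[list[TranscribedSegment]],
) -> list[TranscribedSegment]:
    """Strand-aware interval union across per-state segment sets.

    Merged segments carry state label ``"merged"`` and a length-weighted
    mean of the contributing segments' mean coverages.
    """
    by_key: dict[tuple[str, str], list[TranscribedSegment]] = {}
    for segs in segment_sets:
        for s in segs:
            by_key.setdefault((s.chrom, s.strand), []).append(s)
    merged = []
    for (chrom, strand), segs in by_key.items():
        segs.sort(key=lambda s: s.start)
        cur_start, cur_end = segs[0].start, segs[0].end
        members = [segs[0]]
        groups = []
        for s in segs[1:]:
            if s.start <= cur_end:
                cur_end = max(cur_end, s.end)
                members.append(s)
            else:
                groups.append((cur_start, cur_end, members))
                cur_start, cur_end, members = s.start, s.end, [s]
        groups.append((cur_start, cur_end, members))
        for start, end, members in groups:
            w = np.array([m.length for m in members], dtype=float)
            mc = np.array([m.mean_coverage for m in members])
            merged.append(
                TranscribedSegment(
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    state="merged",
                    mean_coverage=float((w * mc).sum() / w.sum()),
                )
            )
    merged.sort(key=lambda s: (s.chrom, s.strand, s.start))
    return merged
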