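"""Read accuracy metrics, homopolymer scoring, chunking and stitching.

Accuracy follows the standard raw-read convention: a minimum-edit
(Levenshtein, unit cost) global alignment between the called sequence and
the truth, with

    identity = matches / (matches + mismatches + insertions + deletions)

and each error ratio reported against the same total column count, so
identity plus the error ratios sums to one.  Alignment is computed with
edlib; homopolymer scoring walks the alignment path.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

__all__ = [
    "AlignmentMetrics",
    "HomopolymerReport",
    "ChunkPlan",
    "align_and_score",
    "homopolymer_eval",
    "chunk_signal",
    "stitch_sequences",
]


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentMetrics:
    matches: int
    mismatches: int
    insertions: int  # bases in the call absent from the truth
    deletions: int  # truth bases missing from the call
    distance: int

    @property
    def columns(self) -> int:
        return self.matches + self.mismatches + self.insertions + self.deletions

    @property
    def identity(self) -> float:
        return self.matches / self.columns

    def error_ratios(self) -> dict[str, float]:
        c = self.columns
        return {
            "mismatch": self.mismatches / c,
            "insertion": self.insertions / c,
            "deletion": self.deletions / c,
        }


def _cigar_ops(pred: str, truth: str) -> list[tuple[int, str]]:
    res = edlib.align(pred, truth, mode="NW", task="path")
    out = []
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            out.append((int(num), ch))
            num = ""
    return out


def align_and_score(pred: str, truth: str) -> AlignmentMetrics:
    """Global minimum-edit alignment column counts between call and truth."""
    if not pred or not truth:
        raise EvaluationError("cannot align empty sequences")
    counts = {"=": 0, "X": 0, "I": 0, "D": 0}
    for n, op in _cigar_ops(pred, truth):
        counts[op] += n
    return AlignmentMetrics(
        matches=counts["="],
        mismatches=counts["X"],
        insertions=counts["I"],
        deletions=counts["D"],
        distance=counts["X"] + counts["I"] + counts["D"],
    )


@dataclass(frozen=True)
class HomopolymerReport:
    correct: int
    total: int
    per_length: dict[int, tuple[int, int]]  # run length -> (correct, total)

    @property
    def accuracy(self) -> float:
        return self.correct / self.total if self.total else float("nan")


def _alignment_columns(pred: str, truth: str) -> list[tuple[str, str]]:
    """(pred_char_or_gap, truth_char_or_gap) per alignment column."""
    cols = []
    i = j = 0
    for n, op in _cigar_ops(pred, truth):
        for _ in range(n):
            if op in "=X":
                cols.append((pred[i], truth[j]))
                i += 1
                j += 1
            elif op == "I":  # extra base in pred
                cols.append((pred[i], "-"))
                i += 1
            else:  # deletion from truth
                cols.append(("-", truth[j]))
                j += 1
    return cols


def homopolymer_eval(pred: str, truth: str, min_len: int = 3) -> HomopolymerReport:
    """Score maximal identical-base runs of the truth against the call.

    A truth run of base b and length L >= min_len is counted correct iff the
    maximal run of b in the call overlapping the aligned region has exactly
    length L with no other base aligned inside the run (substitutions,
    deletions, and same-base insertions at the run boundary all make the
    called run length wrong).
    """
    cols = _alignment_columns(pred, truth)
    # map: truth position -> alignment column index; column -> pred position
    truth_cols = [ci for ci, (_, t) in enumerate(cols) if t != "-"]
    pred_pos = []
    seen = 0
    for p, _ in cols:
        pred_pos.append(seen if p != "-" else -1)
        if p != "-":
            seen += 1
    correct = total = 0
    per_length: dict[int, list[int]] = {}
    j = 0
    n = len(truth)
    while j < n:
        b = truth[j]
        run = 1
        while j + run < n and truth[j + run] == b:
            run += 1
        if run >= min_len:
            lo, hi = truth_cols[j], truth_cols[j + run - 1]
            aligned = [pred_pos[ci] for ci in range(lo, hi + 1) if pred_pos[ci] >= 0]
            ok = False
            if aligned:
                segment = pred[aligned[0] : aligned[-1] + 1]
                if segment == b * len(segment):
                    # maximal run of b in the call around the aligned segment
                    i0, i1 = aligned[0], aligned[-1]
                    while i0 > 0 and pred[i0 - 1] == b:
                        i0 -= 1
                    while i1 + 1 < len(pred) and pred[i1 + 1] == b:
                        i1 += 1
                    ok = (i1 - i0 + 1) == run
            total += 1
            correct += ok
            c, t = per_length.get(run, (0, 0))
            per_length[run] = (c + ok, t + 1)
        j += run
    return HomopolymerReport(
        correct=correct,
        total=total,
        per_length={k: tuple(v) for k, v in sorted(per_length.items())},
    )


# ---------------------------------------------------------------------------
# chunking and stitching


@dataclass(frozen=True)
class ChunkPlan:
    """Overlapping sample windows covering [0, N), 0-based half-open."""

    length: int
    overlap: int
    windows: tuple[tuple[int, int], ...]


def chunk_signal(n_samples: int, length: int = 4096, overlap: int = 296) -> ChunkPlan:
    """Split a read into fixed-length windows with the given overlap.

    Window starts advance by ``length - overlap``; the final window is
    truncated at N.  Every sample is covered.
    """
    if length <= overlap or overlap < 0:
        raise EvaluationError(f"need length > overlap >= 0, got {length}, {overlap}")
    if n_samples < 1:
        raise EvaluationError("empty signal")
    stride = length - overlap
    windows = []
    start = 0
    while True:
        end = min(start + length, n_samples)
        windows.append((start, end))
        if start + length >= n_samples:
            break
        start += stride
    return ChunkPlan(length=length, overlap=overlap, windows=tuple(windows))


def _local_align_cut(left_tail: str, right_head: str) -> tuple[int, int] | None:
    """Best local-alignment end cell between a suffix and a prefix.

    Plain Smith-Waterman (match +1, mismatch/gap -1).  Returns (i, j): the
    number of characters of ``left_tail`` to keep and the number of
    ``right_head`` characters to drop; None when nothing aligns.
    """
    nl, nr = len(left_tail), len(right_head)
    if nl == 0 or nr == 0:
        return None
    H = np.zeros((nl + 1, nr + 1))
    best, cell = 0.0, None
    for i in range(1, nl + 1):
        prev = H[i - 1]
        cur = H[i]
        for j in range(1, nr + 1):
            s = prev[j - 1] + (1.0 if left_tail[i - 1] == right_head[j - 1] else -1.0)
            v = max(0.0, s, prev[j] - 1.0, cur[j - 1] - 1.0)
            cur[j] = v
            if v > best:
                best, cell = v, (i, j)
    if cell is None or best < 2.0:  # require at least a 2-base anchor
        return None
    return cell


def stitch_sequences(chunk_outputs: list[str], window: int = 120) -> str:
    """Assemble per-chunk basecalls into one sequence.

    For each consecutive pair the suffix of the left output (up to
    ``window`` bases) is locally aligned against the prefix of the right
    output; both are cut at the alignment's best column, removing the bases
    the two chunks called twice from the overlapping samples.  When no
    anchor is found the outputs are concatenated directly.
    """
    if not chunk_outputs:
        raise EvaluationError("no chunk outputs to stitch")
    merged = chunk_outputs[0]
    for nxt in chunk_outputs[1:]:
        w = min(window, len(merged), len(nxt))
        cut = _local_align_cut(merged[len(merged) - w :], nxt[:w]) if w else None
        if cut is None:
            merged = merged + nxt
        else:
            i, j = cut
            merged = merged[: len(merged) - w + i] + nxt[j:]
    return merged
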