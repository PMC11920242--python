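"""Independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations

import itertools

import numpy as np

from styscreen.library_design import (
    EditorSpec,
    TranscriptModel,
    _matches_iupac,
    revcomp,
    translate_codon,
)


def brute_force_designable(
    transcript: TranscriptModel, editor: EditorSpec | None = None
) -> set[tuple[str, str, tuple[str, int]]]:
    """Enumerate (spacer, strand, residue) by exhaustive search.

    Walks every 20-mer + PAM on both strands, applies every non-empty
    subset of window A-edits to the CDS, re-translates the full protein
    and records every S/T/Y residue changed to a different non-stop AA.
    Independent of the designer's codon bookkeeping.
    """
    editor = editor or EditorSpec()
    seq = transcript.context
    n = len(seq)
    cs, cl = len(transcript.flank5), len(transcript.cds)
    found: set[tuple[str, str, tuple[str, int]]] = set()
    for strand in ("sense", "antisense"):
        ss = seq if strand == "sense" else revcomp(seq)
        L, P = editor.protospacer_len, len(editor.pam)
        for i in range(len(ss) - L - P + 1):
            if not _matches_iupac(ss[i + L : i + L + P], editor.pam):
                continue
            window = [
                w
                for w in range(editor.window_start, editor.window_end + 1)
                if ss[i + w - 1] == "A"
            ]
            coding_idx = [
                (i + w - 1) if strand == "sense" else (n - 1 - (i + w - 1))
                for w in window
            ]
            coding_idx = [c for c in coding_idx if 0 <= c - cs < cl]
            for r in range(1, len(coding_idx) + 1):
                for combo in itertools.combinations(coding_idx, r):
                    cds = list(transcript.cds)
                    for c in combo:
                        cds[c - cs] = "G" if strand == "sense" else "C"
                    edited = "".join(cds)
                    for k in range(0, cl, 3):
                        c0, c1 = transcript.cds[k : k + 3], edited[k : k + 3]
                        if c0 == c1:
                            continue
                        aa0, aa1 = translate_codon(c0), translate_codon(c1)
                        if aa0 in "STY" and aa1 not in ("*", aa0):
                            found.add((ss[i : i + L], strand, (aa0, k // 3 + 1)))
    return found


def brute_force_size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors computed row by row, the slow way."""
    counts = np.asarray(counts, dtype=float)
    n_rows, n_samples = counts.shape
    gm = np.array([np.exp(np.mean(np.log(counts[i]))) if (counts[i] > 0).all() else 0.0
                   for i in range(n_rows)])
    keep = gm > 0
    sf = np.empty(n_samples)
    for j in range(n_samples):
        sf[j] = np.median(counts[keep, j] / gm[keep])
    return sf


def auroc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney U statistic."""
    from scipy.stats import mannwhitneyu

    u = mannwhitneyu(scores_pos, scores_neg, alternative="two-sided").statistic
    return float(u / (len(scores_pos) * len(scores_neg)))
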