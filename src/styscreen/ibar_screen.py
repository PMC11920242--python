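"""Enrichment statistics for sgRNA^iBAR sorting screens.

Each sgRNA carries several internal barcodes (iBARs) that behave as
independent replicates of the same perturbation. The screen statistic
combines, per sgRNA, the per-iBAR log2 fold changes between a FACS-sorted
population and the unsorted reference into one one-sided P value,
penalizing guides whose iBARs disagree in sign with the tested direction:

1. counts are normalized by median-of-ratios size factors;
2. per-iBAR log2 fold changes are standardized by a mean–variance trend
   fit on negative-control guides, binned by reference abundance;
3. the per-iBAR z-scores are combined Stouffer-style,
   ``z = sum(z_i) / sqrt(n * penalty)``, where ``penalty`` is 1 for
   direction-concordant iBAR sets and ``max(1, var(z_i))`` otherwise;
4. one-sided P values are Benjamini-Hochberg adjusted within direction
   and reported as a signed screen score ``±(-log10 p_adj)``; guides with
   ``|score|`` above the threshold (default 1) are hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class ScreenError(ValueError):
    pass


@dataclass
class CountTable:
    """sgRNA×iBAR×sample read counts.

    ``counts`` is indexed by (spacer_id, ibar) with one column per sample;
    ``roles`` maps sample name -> reference | sorted_high | sorted_low.
    """

    counts: pd.DataFrame
    roles: dict[str, str] = field(default_factory=dict)
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.nlevels != 2:
            raise ScreenError("counts must be indexed by (spacer_id, ibar)")
        if (self.counts.values < 0).any():
            raise ScreenError("counts must be non-negative")
        if self.counts.index.duplicated().any():
            raise ScreenError("duplicate (spacer_id, ibar) rows")

    def write_tsv(self, path) -> None:
        self.counts.reset_index().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, roles: dict[str, str] | None = None) -> "CountTable":
        df = pd.read_csv(path, sep="\t")
        df = df.set_index(["spacer_id", "ibar"])
        return cls(counts=df, roles=roles or {})


def count_guides(
    reads,
    library,
    spacer_start: int = 0,
    spacer_len: int = 20,
    ibar_start: int | None = None,
    ibar_len: int = 6,
    sample: str = "sample",
):
    """Exact-match assignment of reads to (spacer, ibar) library rows.

    ``reads`` is a FASTQ path or an iterable of sequence strings. Returns
    a zero-filled single-sample ``CountTable`` over the full library plus
    the number of unassigned reads.
    """
    from Bio import SeqIO

    if ibar_start is None:
        ibar_start = spacer_start + spacer_len
    seen: dict[str, list[str]] = {}
    for g in library.guides:
        seen.setdefault(g.spacer, list(g.ibars))
    index = pd.MultiIndex.from_tuples(
        [(sp, b) for sp, ibars in seen.items() for b in ibars],
        names=["spacer_id", "ibar"],
    )
    counts = pd.Series(0, index=index, name=sample)
    valid = set(index)
    unassigned = 0
    if isinstance(reads, (str, bytes)) or hasattr(reads, "read"):
        seqs = (str(rec.seq) for rec in SeqIO.parse(reads, "fastq"))
    else:
        seqs = iter(reads)
    for seq in seqs:
        key = (
            seq[spacer_start : spacer_start + spacer_len],
            seq[ibar_start : ibar_start + ibar_len],
        )
        if key in valid:
            counts[key] += 1
        else:
            unassigned += 1
    return CountTable(counts=counts.to_frame()), unassigned


def normalize_counts(counts: CountTable, pseudocount: float = 0.0) -> CountTable:
    """Median-of-ratios normalization.

    Size factor per sample = median over rows of count / geometric mean of
    the row across samples, computed over rows whose geometric mean is
    positive; normalized count = count / size factor. A pseudocount may be
    added before taking ratios (off by default so that exact column
    proportionality gives exact size-factor ratios).
    """
    df = counts.counts.astype(float)
    if df.shape[1] < 2:
        raise ScreenError("normalization needs at least 2 samples")
    if (df.sum(axis=0) == 0).any():
        raise ScreenError("a sample has zero total counts")
    work = df + pseudocount
    with np.errstate(divide="ignore"):
        log_gm = np.log(work).mean(axis=1)
    ok = np.isfinite(log_gm)
    if not ok.any():
        raise ScreenError("no rows with positive geometric mean")
    ratios = work.loc[ok].div(np.exp(log_gm[ok]), axis=0)
    size_factors = ratios.median(axis=0)
    norm = df.div(size_factors, axis=1)
    return CountTable(counts=norm, roles=dict(counts.roles), size_factors=size_factors)


def per_ibar_lfc(
    norm: CountTable, treatment: str, reference: str, pseudocount: float = 1.0
) -> pd.Series:
    """log2((treatment + pc) / (reference + pc)) on normalized counts."""
    t = norm.counts[treatment].astype(float)
    r = norm.counts[reference].astype(float)
    return np.log2((t + pseudocount) / (r + pseudocount)).rename("lfc")


def _control_sd_trend(
    lfc: pd.Series, ref_abund: pd.Series, fit_mask: np.ndarray, n_bins: int = 10
) -> np.ndarray:
    """Per-row null SD of lfc, from control rows binned by reference abundance."""
    log_ab = np.log1p(ref_abund.values)
    fit_ab = log_ab[fit_mask]
    fit_lfc = lfc.values[fit_mask]
    n_bins = max(1, min(n_bins, fit_mask.sum() // 10))
    edges = np.quantile(fit_ab, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 2:
        sd = max(float(np.std(fit_lfc, ddof=1)), 1e-6)
        return np.full(len(lfc), sd)
    which = np.clip(np.searchsorted(edges, fit_ab, side="right") - 1, 0, len(edges) - 2)
    centers, sds = [], []
    for b in range(len(edges) - 1):
        vals = fit_lfc[which == b]
        if len(vals) >= 2:
            centers.append(fit_ab[which == b].mean())
            sds.append(max(float(np.std(vals, ddof=1)), 1e-6))
    if not centers:
        sd = max(float(np.std(fit_lfc, ddof=1)), 1e-6)
        return np.full(len(lfc), sd)
    order = np.argsort(centers)
    return np.interp(log_ab, np.asarray(centers)[order], np.asarray(sds)[order])


def score_sgrnas(
    lfcs: pd.Series,
    ref_abundance: pd.Series,
    controls: pd.Series | None = None,
    direction: str = "up",
    threshold: float = 1.0,
    min_controls: int = 20,
) -> pd.DataFrame:
    """Combine per-iBAR fold changes into per-sgRNA screen scores.

    ``lfcs`` and ``ref_abundance`` are indexed by (spacer_id, ibar);
    ``controls`` is a boolean mask per spacer_id marking negative-control
    guides used to fit the null mean–variance trend (all guides are used
    when fewer than ``min_controls`` controls are available).
    """
    if direction not in ("up", "down"):
        raise ScreenError("direction must be 'up' or 'down'")
    spacers = lfcs.index.get_level_values(0)
    if controls is not None and controls.sum() >= min_controls:
        fit_mask = spacers.isin(controls.index[controls])
    else:
        fit_mask = np.ones(len(lfcs), dtype=bool)
    sigma = _control_sd_trend(lfcs, ref_abundance, np.asarray(fit_mask))
    z = lfcs.values / sigma

    zdf = pd.DataFrame({"spacer_id": spacers, "z": z, "lfc": lfcs.values})
    sign = 1.0 if direction == "up" else -1.0

    rows = []
    for spacer_id, grp in zdf.groupby("spacer_id", sort=False):
        zs = grp["z"].values
        n = len(zs)
        concordant = bool(np.all(sign * zs >= 0))
        if concordant or n < 2:
            penalty = 1.0
        else:
            penalty = max(1.0, float(np.var(zs, ddof=1)))
        z_comb = zs.sum() / np.sqrt(n * penalty)
        rows.append(
            {
                "spacer_id": spacer_id,
                "n_ibars": n,
                "mean_lfc": float(grp["lfc"].mean()),
                "consistency_penalty": penalty,
                "z_combined": float(z_comb),
                "flagged_few_ibars": n < 3,
            }
        )
        for i, v in enumerate(grp["lfc"].values[:3], start=1):
            rows[-1][f"lfc_ibar{i}"] = float(v)
    res = pd.DataFrame(rows).set_index("spacer_id")

    if direction == "up":
        p_raw = stats.norm.sf(res["z_combined"].values)
    else:
        p_raw = stats.norm.cdf(res["z_combined"].values)
    p_raw = np.clip(p_raw, np.finfo(float).eps, 1.0)
    _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")
    res["p_raw"] = p_raw
    res["p_adj"] = np.clip(p_adj, np.finfo(float).eps, 1.0)
    res["direction"] = direction
    res["screen_score"] = [screen_score(p, direction) for p in res["p_adj"]]
    res["is_hit"] = res["screen_score"].abs() > threshold
    if controls is not None:
        res["is_control"] = res.index.isin(controls.index[controls])
    return res


def screen_score(p_adj: float, direction: str) -> float:
    """Signed score: -log10 of the BH-adjusted P, negative for 'down'."""
    if not 0 <= p_adj <= 1:
        raise ScreenError(f"p_adj out of range: {p_adj}")
    p = max(p_adj, np.finfo(float).tiny)
    s = -np.log10(p)
    return -s if direction == "down" else s


def call_hits(results: pd.DataFrame, threshold: float = 1.0) -> pd.Index:
    """Guides with |screen_score| strictly above the threshold."""
    return results.index[results["screen_score"].abs() > threshold]


def analyze_screen(
    counts: CountTable,
    treatment: str,
    reference: str,
    direction: str = "up",
    controls: pd.Series | None = None,
    threshold: float = 1.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """End-to-end: normalize, per-iBAR lfc, combine, BH, hit calls."""
    norm = normalize_counts(counts)
    lfc = per_ibar_lfc(norm, treatment, reference, pseudocount)
    ref_ab = norm.counts[reference]
    return score_sgrnas(lfc, ref_ab, controls=controls, direction=direction, threshold=threshold)
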