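"""Weighted expression-signature scoring and immune-marker correlation.

A mutation signature is built from a differential-expression table by
taking the top-``n`` up- and downregulated genes ranked by their Wald
statistic ``w`` and weighting each selected gene ``k_i = w_i / max|w|``
(max over the selected genes), so that upregulated genes carry positive
and downregulated genes negative weights with ``max|k| = 1``. A sample's
signature score is the weighted sum ``S = sum_i k_i * X_i`` of its
log2TPM expression over the signature genes. Scores are correlated with
immune-marker composites (MHC-I, PD-L1, cytotoxic-T-lymphocyte averages)
and compared between immunotherapy responders (PR/CR) and non-responders
(PD/SD).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MHC1_GENES = ["HLA-A", "HLA-B", "HLA-C", "B2M"]
PDL1_GENES = ["CD274"]
CTL_GENES = ["CD8A", "CD8B", "GZMA", "GZMB", "PRF1"]

RESPONDERS = {"PR", "CR"}
NON_RESPONDERS = {"PD", "SD"}


class SignatureError(ValueError):
    pass


@dataclass
class SignatureModel:
    weights: pd.Series  # gene -> k_i, max|k| == 1
    n_top: int

    @property
    def genes(self) -> list[str]:
        return list(self.weights.index)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"n_top": self.n_top, "weights": {g: float(k) for g, k in self.weights.items()}},
            indent=1,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "SignatureModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        return cls(weights=pd.Series(d["weights"], dtype=float), n_top=int(d["n_top"]))


def build_signature(
    de: pd.DataFrame,
    n_top: int = 250,
    rank_by: str = "stat",
    max_signed: bool = False,
) -> SignatureModel:
    """Select top up/down genes and derive normalized weights.

    ``de`` needs a gene identifier (index or a ``gene`` column) and the
    ranking column (DESeq2's ``stat`` by default; ``log2FC``/
    ``log2FoldChange`` accepted via ``rank_by``). Weights are
    ``k_i = w_i / max|w|`` over the selected genes; ``max_signed`` divides
    by the signed maximum instead.
    """
    df = de.copy()
    if "gene" in df.columns:
        df = df.set_index("gene")
    col = rank_by
    if col not in df.columns:
        aliases = {"stat": ["wald_stat", "w"], "log2FC": ["log2FoldChange", "lfc"]}
        for alt in aliases.get(rank_by, []):
            if alt in df.columns:
                col = alt
                break
        else:
            raise SignatureError(f"ranking column {rank_by!r} not in DE table")
    w = pd.to_numeric(df[col], errors="coerce")
    w = w[np.isfinite(w)]
    w = w[~w.index.duplicated()]
    if len(w) < 2 * n_top:
        warnings.warn(
            f"only {len(w)} genes with finite statistics; shrinking n_top "
            f"from {n_top} to {len(w) // 2}",
            stacklevel=2,
        )
        n_top = len(w) // 2
        if n_top == 0:
            raise SignatureError("DE table too small to build a signature")
    # deterministic: sort by (statistic, gene id)
    order = pd.DataFrame({"w": w.values, "_gene": w.index.astype(str)}).sort_values(
        ["w", "_gene"], ascending=[False, True]
    )
    order.index = w.index[order.index]
    up = order.head(n_top)
    down = order.tail(n_top).sort_values(["w", "_gene"], ascending=[True, True]).head(n_top)
    selected = pd.concat([up["w"], down["w"]])
    selected = selected[~selected.index.duplicated()]
    denom = selected.max() if max_signed else selected.abs().max()
    if denom == 0:
        raise SignatureError("all selected statistics are zero")
    weights = (selected / denom).sort_index()
    return SignatureModel(weights=weights, n_top=n_top)


def score_profile(
    model: SignatureModel, profile: pd.Series | pd.DataFrame
) -> pd.DataFrame:
    """Signature score per sample: S = sum_i k_i * X_i.

    ``profile`` is a gene-indexed Series (one sample) or genes × samples
    DataFrame of log2TPM. Missing signature genes contribute 0; samples
    with more than half the signature absent are flagged.
    """
    if isinstance(profile, pd.Series):
        profile = profile.to_frame(profile.name or "sample")
    present = model.weights.index.intersection(profile.index)
    n_missing = len(model.weights) - len(present)
    if n_missing:
        warnings.warn(f"{n_missing} signature genes absent from profile", stacklevel=2)
    sub = profile.loc[present]
    scores = sub.mul(model.weights.loc[present], axis=0).sum(axis=0)
    return pd.DataFrame(
        {
            "score": scores,
            "n_missing": n_missing,
            "low_coverage": n_missing > len(model.weights) / 2,
        }
    ).rename_axis("sample")


def marker_scores(profile: pd.DataFrame) -> pd.DataFrame:
    """Immune-marker composites per sample (mean log2TPM of each gene set)."""
    if isinstance(profile, pd.Series):
        profile = profile.to_frame(profile.name or "sample")
    upper = {str(g).upper(): g for g in profile.index}
    out = {}
    for name, genes in (("mhc1", MHC1_GENES), ("pdl1", PDL1_GENES), ("ctl", CTL_GENES)):
        present = [upper[g] for g in genes if g in upper]
        if not present:
            warnings.warn(f"no {name} genes present; marker undefined", stacklevel=2)
            out[name] = pd.Series(np.nan, index=profile.columns)
        else:
            out[name] = profile.loc[present].mean(axis=0)
    return pd.DataFrame(out).rename_axis("sample")


def correlate_and_compare(
    scores: pd.Series,
    markers: pd.DataFrame | pd.Series | None = None,
    labels: pd.Series | None = None,
) -> dict:
    """Pearson correlations with markers and responder-group comparison.

    Returns ``{"correlations": {marker: {"r", "p", "n"}},
    "response": {"t", "p", "mean_responder", "mean_non_responder", ...}}``.
    """
    report: dict = {}
    if markers is not None:
        if isinstance(markers, pd.Series):
            markers = markers.to_frame(markers.name or "marker")
        cors = {}
        for col in markers.columns:
            joined = pd.concat([scores, markers[col]], axis=1, join="inner").dropna()
            if len(joined) < 3:
                raise SignatureError(f"need >=3 paired samples for correlation ({col})")
            x, y = joined.iloc[:, 0].values, joined.iloc[:, 1].values
            if np.std(x) == 0 or np.std(y) == 0:
                cors[col] = {"r": np.nan, "p": np.nan, "n": len(joined), "degenerate": True}
                continue
            r, p = stats.pearsonr(x, y)
            cors[col] = {"r": float(r), "p": float(p), "n": len(joined)}
        report["correlations"] = cors
    if labels is not None:
        labels = labels.reindex(scores.index)
        resp = scores[labels.isin(RESPONDERS)].dropna()
        non = scores[labels.isin(NON_RESPONDERS)].dropna()
        if len(resp) < 2 or len(non) < 2:
            raise SignatureError("need >=2 samples per response group")
        t, p = stats.ttest_ind(resp, non, equal_var=True)
        report["response"] = {
            "t": float(t),
            "p": float(p),
            "n_responder": len(resp),
            "n_non_responder": len(non),
            "mean_responder": float(resp.mean()),
            "mean_non_responder": float(non.mean()),
        }
    return report
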