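"""Synthetic-data generators with machine-readable ground truth.

Every input the pipeline consumes can be generated here under a fixed
seed: toy proteomes for guide design, negative-binomial sgRNA^iBAR count
tables under a two-round 10%-gate sorting model with planted hits,
amplicon read pairs with planted editing haplotypes and uniform
sequencing error, and expression cohorts carrying a planted signature.
Generators return the ground truth alongside the data so recall,
precision and rate-recovery can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from styscreen.amplicon_edits import AmpliconSpec
from styscreen.ibar_screen import CountTable
from styscreen.library_design import (
    DesignError,
    GuideDesign,
    LibraryTable,
    TranscriptModel,
    design_guides,
    revcomp,
    translate_codon,
)
from styscreen.signature_scoring import (
    CTL_GENES,
    MHC1_GENES,
    PDL1_GENES,
    SignatureModel,
)

_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if translate_codon(a + b + c) != "*"
]


# ---------------------------------------------------------------------------
# toy proteomes


def make_toy_proteome(
    n_genes: int = 5,
    cds_len_range: tuple[int, int] = (300, 600),
    seed: int = 0,
    flank_len: int = 30,
    max_tries: int = 200,
) -> list[TranscriptModel]:
    """Random transcripts, each guaranteed to yield >=1 designable guide.

    CDS are built from non-stop codons (ATG start) with random flanks;
    candidates without a designable S/T/Y guide are rejected and redrawn.
    """
    lo, hi = cds_len_range
    if lo % 3 or hi % 3 or lo < 9:
        raise DesignError("cds_len_range bounds must be multiples of 3 and >= 9")
    rng = np.random.default_rng(seed)
    out = []
    for g in range(n_genes):
        for _ in range(max_tries):
            n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
            codons = ["ATG"] + [
                _NON_STOP_CODONS[i]
                for i in rng.integers(0, len(_NON_STOP_CODONS), size=n_codons - 1)
            ]
            t = TranscriptModel(
                gene_id=f"GENE{g + 1}",
                protein_id=f"PROT{g + 1}",
                cds="".join(codons),
                flank5="".join(rng.choice(list("ACGT"), size=flank_len)),
                flank3="".join(rng.choice(list("ACGT"), size=flank_len)),
            )
            if design_guides(t):
                out.append(t)
                break
        else:
            raise DesignError(f"could not generate a designable CDS for gene {g + 1}")
    return out


def write_proteome_fasta(transcripts: list[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.gene_id}|{t.protein_id}|{t.flank5}|{t.flank3}\n{t.cds}\n")


# ---------------------------------------------------------------------------
# sorted-screen count simulation


@dataclass
class ScreenSimConfig:
    """Conditions of the simulated sorting screen.

    Defaults mirror the screen design this simulator emulates: top/bottom
    10% sorting gates, two rounds of FACS enrichment, about 500 reads per
    iBAR, with negative-binomial count noise (dispersion 0.05) on a
    lognormal (sigma=1) abundance backbone.
    """

    n_guides: int = 1000
    n_controls: int = 100
    n_hits_up: int = 10
    n_hits_down: int = 10
    effect: float = 2.0  # selection log2 odds-enrichment per sorting round
    gate_fraction: float = 0.10
    rounds: int = 2
    depth: float = 500.0  # mean reads per iBAR
    nb_dispersion: float = 0.05
    lognormal_sigma: float = 1.0
    n_ibars: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.gate_fraction < 1:
            raise ValueError("gate_fraction must be in (0,1)")
        if self.depth <= 0 or self.rounds < 1:
            raise ValueError("depth must be > 0 and rounds >= 1")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB via gamma-Poisson: Var = mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def _capture_prob(gate_fraction: float, effect: np.ndarray, rounds: int) -> np.ndarray:
    """Gate-capture probability after `rounds` sorts.

    A guide with selection effect e has its odds of falling inside the
    gate multiplied by 2**e per round relative to a null guide.
    """
    base_odds = gate_fraction / (1.0 - gate_fraction)
    odds = base_odds * np.power(2.0, np.asarray(effect, dtype=float) * rounds)
    return odds / (1.0 + odds)


def simulate_screen(
    library: LibraryTable | None = None, cfg: ScreenSimConfig | None = None
) -> tuple[CountTable, pd.DataFrame]:
    """Simulate reference + sorted-high + sorted-low sgRNA^iBAR counts.

    When no library is given, synthetic guide/control identifiers are
    used. Up-hits are enriched in the high gate, down-hits in the low
    gate. Returns the count table and per-guide truth (effects, hit
    class).
    """
    cfg = cfg or ScreenSimConfig()
    rng = np.random.default_rng(cfg.seed)

    if library is not None:
        guide_ids = list(dict.fromkeys(g.spacer for g in library.guides if not g.is_control))
        control_ids = list(dict.fromkeys(g.spacer for g in library.guides if g.is_control))
        ibars_of = {g.spacer: list(g.ibars) for g in library.guides}
    else:
        guide_ids = [f"g{i:05d}" for i in range(cfg.n_guides)]
        control_ids = [f"ctrl{i:04d}" for i in range(cfg.n_controls)]
        ibars_of = {}

    n_g = len(guide_ids)
    if cfg.n_hits_up + cfg.n_hits_down > n_g:
        raise ValueError("more planted hits than guides")
    hit_idx = rng.choice(n_g, size=cfg.n_hits_up + cfg.n_hits_down, replace=False)
    effect_high = np.zeros(n_g + len(control_ids))
    effect_low = np.zeros(n_g + len(control_ids))
    effect_high[hit_idx[: cfg.n_hits_up]] = cfg.effect
    effect_low[hit_idx[cfg.n_hits_up :]] = cfg.effect

    all_ids = guide_ids + control_ids
    is_control = np.array([False] * n_g + [True] * len(control_ids))

    rows = []
    for i, gid in enumerate(all_ids):
        barcodes = ibars_of.get(gid) or [f"b{j + 1}" for j in range(cfg.n_ibars)]
        for b in barcodes:
            rows.append((gid, b, i))
    index = pd.MultiIndex.from_tuples(
        [(g, b) for g, b, _ in rows], names=["spacer_id", "ibar"]
    )
    guide_of_row = np.array([i for _, _, i in rows])

    abundance = rng.lognormal(mean=0.0, sigma=cfg.lognormal_sigma, size=len(rows))
    abundance /= abundance.mean()

    p_null = _capture_prob(cfg.gate_fraction, np.zeros(1), cfg.rounds)[0]
    samples = {}
    mean_ref = cfg.depth * abundance
    samples["reference"] = _nb_draw(rng, mean_ref, cfg.nb_dispersion)
    for name, eff in (("sorted_high", effect_high), ("sorted_low", effect_low)):
        p = _capture_prob(cfg.gate_fraction, eff[guide_of_row], cfg.rounds)
        w = abundance * p / p_null
        mean = cfg.depth * w / w.mean() * abundance.mean()
        samples[name] = _nb_draw(rng, mean, cfg.nb_dispersion)

    counts = pd.DataFrame(samples, index=index)
    table = CountTable(
        counts=counts,
        roles={
            "reference": "reference",
            "sorted_high": "sorted_high",
            "sorted_low": "sorted_low",
        },
    )
    truth = pd.DataFrame(
        {
            "spacer_id": all_ids,
            "effect_high": effect_high,
            "effect_low": effect_low,
            "is_control": is_control,
            "hit_class": np.where(
                effect_high > 0, "up", np.where(effect_low > 0, "down", "null")
            ),
        }
    ).set_index("spacer_id")
    return table, truth


# ---------------------------------------------------------------------------
# amplicon reads


@dataclass
class Haplotype:
    """A planted editing outcome: substitutions within the target region."""

    edits: list[tuple[int, str]]  # (0-based target position, new base)
    fraction: float
    label: str = ""


def simulate_amplicon_reads(
    spec: AmpliconSpec,
    haplotypes: list[Haplotype] | None = None,
    edit_rates: dict[int, float] | None = None,
    error_rate: float = 0.001,
    n_reads: int = 10000,
    read_len: int = 150,
    seed: int = 0,
) -> tuple[list[tuple[str, list[int]]], list[tuple[str, list[int]]], pd.DataFrame]:
    """Paired amplicon reads with planted edits and uniform errors.

    Either ``haplotypes`` (joint outcomes with fractions; remainder is
    wild type) or ``edit_rates`` (independent per-position A→G rates) may
    be given. Returns (r1, r2, truth) where r1/r2 are lists of
    (sequence, phred qualities) and truth tabulates the planted
    haplotype fractions.
    """
    rng = np.random.default_rng(seed)
    ref = spec.reference
    variants: list[tuple[str, float, str]] = []
    if haplotypes:
        total = sum(h.fraction for h in haplotypes)
        if total > 1 + 1e-9:
            raise ValueError(f"haplotype fractions sum to {total} > 1")
        for h in haplotypes:
            seq = list(ref)
            for pos, base in h.edits:
                seq[spec.target_start + pos] = base
            variants.append(("".join(seq), h.fraction, h.label or f"hap{len(variants)}"))
        variants.append((ref, max(0.0, 1.0 - total), "WT"))
    elif edit_rates:
        # independent per-position edits: expand to joint haplotypes
        positions = sorted(edit_rates)
        variants = [(ref, 1.0, "WT")]
        for pos in positions:
            rate = edit_rates[pos]
            if not 0 <= rate <= 1:
                raise ValueError(f"edit rate out of [0,1] at {pos}")
            new_variants = []
            for seq, frac, label in variants:
                edited = list(seq)
                edited[spec.target_start + pos] = "G"
                new_variants.append((seq, frac * (1 - rate), label))
                new_variants.append(
                    ("".join(edited), frac * rate, f"{label}+{pos}G".replace("WT+", ""))
                )
            variants = new_variants
    else:
        variants = [(ref, 1.0, "WT")]

    seqs = [v[0] for v in variants]
    fracs = np.array([v[1] for v in variants])
    fracs = fracs / fracs.sum()
    choice = rng.choice(len(variants), size=n_reads, p=fracs)

    bases = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    r1, r2 = [], []
    q = [38] * read_len
    for c in choice:
        seq = np.frombuffer(seqs[c].encode(), dtype=np.uint8).copy()
        errs = rng.random(len(seq)) < error_rate
        if errs.any():
            for i in np.flatnonzero(errs):
                alt = bases[bases != seq[i]]
                seq[i] = alt[rng.integers(0, 3)]
        s = seq.tobytes().decode()
        r1.append((s[:read_len], q))
        r2.append((revcomp(s[-read_len:]), q))
    truth = pd.DataFrame(
        [(label, frac) for _, frac, label in variants], columns=["label", "fraction"]
    )
    return r1, r2, truth


def write_fastq(reads: list[tuple[str, list[int]]], path, prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, (seq, quals) in enumerate(reads):
            qs = "".join(chr(q + 33) for q in quals[: len(seq)])
            if len(qs) < len(seq):
                qs = qs + qs[-1] * (len(seq) - len(qs))
            fh.write(f"@{prefix}{i}\n{seq}\n+\n{qs}\n")


def make_demo_amplicon(seed: int = 0) -> AmpliconSpec:
    """A synthetic in-frame amplicon whose target carries L-S-Y codons.

    Codon layout of the 30-bp target (coding strand, frame 0):
    ... CTG (L) TCG (S) TAC (Y) ... so a single A→G in the Y codon gives
    a Y→C call and T→C co-edits in the L/S codons give an L→P/S→P
    co-mutation — the outcome shapes amplicon calling must label.
    """
    rng = np.random.default_rng(seed)
    pad = lambda n: "".join(rng.choice(list("ACGT"), size=n))
    target_codons = ["ATG", "GAA", "CTG", "TCG", "TAC", "AAA", "GGC", "TTC", "GAT", "CTT"]
    target = "".join(target_codons)
    flank5, flank3 = pad(60), pad(60)
    reference = flank5 + target + flank3
    residues = [
        (510 + i, translate_codon(c), 3 * i) for i, c in enumerate(target_codons)
    ]
    return AmpliconSpec(
        reference=reference,
        target_start=len(flank5),
        target_end=len(flank5) + len(target),
        frame_offset=0,
        strand_of_cds="+",
        residues=residues,
    )


# ---------------------------------------------------------------------------
# expression cohorts


def simulate_expression_cohort(
    model: SignatureModel,
    n_samples: int = 50,
    activation=None,
    noise_sd: float = 1.0,
    n_background_genes: int = 500,
    baseline: float = 5.0,
    marker_coef: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort of log2TPM profiles with a planted signature.

    Signature genes: ``X_i = baseline + activation_s * k_i + noise``;
    background genes are pure noise around the baseline. With
    ``marker_coef`` > 0, the immune-marker genes co-vary with activation
    so marker correlations are testable. Returns (profiles genes×samples,
    truth per sample).
    """
    rng = np.random.default_rng(seed)
    if activation is None:
        activation = rng.normal(0.0, 1.0, size=n_samples)
    activation = np.broadcast_to(np.asarray(activation, dtype=float), (n_samples,)).copy()

    sig_genes = model.genes
    k = model.weights.values[:, None]
    X_sig = baseline + activation[None, :] * k + rng.normal(
        0, noise_sd, size=(len(sig_genes), n_samples)
    )
    bg_genes = [f"BG{i:05d}" for i in range(n_background_genes)]
    X_bg = baseline + rng.normal(0, noise_sd, size=(n_background_genes, n_samples))

    marker_genes = [g for g in MHC1_GENES + PDL1_GENES + CTL_GENES if g not in sig_genes]
    X_mark = baseline + marker_coef * activation[None, :] + rng.normal(
        0, noise_sd, size=(len(marker_genes), n_samples)
    )

    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    profiles = pd.DataFrame(
        np.vstack([X_sig, X_bg, X_mark]),
        index=list(sig_genes) + bg_genes + marker_genes,
        columns=samples,
    )
    truth = pd.DataFrame({"sample": samples, "activation": activation}).set_index("sample")
    return profiles, truth


def make_toy_de_table(
    n_genes: int = 2000, n_top: int = 250, effect_scale: float = 8.0, seed: int = 0
) -> pd.DataFrame:
    """A DESeq2-dialect differential-expression table with clear tails."""
    rng = np.random.default_rng(seed)
    genes = [f"DEG{i:05d}" for i in range(n_genes)]
    stat = rng.normal(0, 1, size=n_genes)
    stat[:n_top] += effect_scale
    stat[n_top : 2 * n_top] -= effect_scale
    lfc = stat / 4.0
    from scipy import stats as sps

    p = 2 * sps.norm.sf(np.abs(stat))
    return pd.DataFrame(
        {"gene": genes, "log2FoldChange": lfc, "stat": stat, "pvalue": p, "padj": np.minimum(p * 2, 1.0)}
    )
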