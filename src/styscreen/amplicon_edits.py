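"""Quantification of base-editing outcomes from amplicon sequencing.

The workflow mirrors targeted-amplicon validation of individual guides:
paired reads covering a ~200-bp amplicon are overlap-merged, the edited
window is pulled out by its 10-bp flanking sequences, per-position base
composition is tabulated over length-conserved reads, and observed
haplotypes of the target region are translated into amino-acid outcome
labels such as ``Y98C`` or ``L512P/S513P``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from styscreen.library_design import revcomp, translate_codon

BASES = "ACGT"


class AmpliconError(ValueError):
    pass


@dataclass
class AmpliconSpec:
    """Reference description of one amplicon and its in-frame target region.

    ``residues`` lists the complete codons inside the target as
    ``(protein_pos, ref_AA, codon_start)`` where ``codon_start`` is the
    0-based offset of the codon's first base within the target, in coding
    orientation (i.e. after reverse complementing when ``strand_of_cds``
    is '-').
    """

    reference: str
    target_start: int
    target_end: int
    frame_offset: int = 0
    strand_of_cds: str = "+"
    residues: list[tuple[int, str, int]] = field(default_factory=list)
    flank_len: int = 10

    def __post_init__(self) -> None:
        self.reference = self.reference.upper()
        if not (0 <= self.target_start < self.target_end <= len(self.reference)):
            raise AmpliconError("target interval out of amplicon bounds")
        if self.target_start < self.flank_len or self.target_end + self.flank_len > len(
            self.reference
        ):
            raise AmpliconError("amplicon too short for flanks around the target")
        if self.strand_of_cds not in "+-":
            raise AmpliconError("strand_of_cds must be '+' or '-'")

    @property
    def flank5(self) -> str:
        return self.reference[self.target_start - self.flank_len : self.target_start]

    @property
    def flank3(self) -> str:
        return self.reference[self.target_end : self.target_end + self.flank_len]

    @property
    def target(self) -> str:
        return self.reference[self.target_start : self.target_end]

    def coding_target(self, target: str | None = None) -> str:
        t = self.target if target is None else target
        return t if self.strand_of_cds == "+" else revcomp(t)

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "target_start": self.target_start,
            "target_end": self.target_end,
            "frame_offset": self.frame_offset,
            "strand_of_cds": self.strand_of_cds,
            "residues": [list(r) for r in self.residues],
            "flank_len": self.flank_len,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AmpliconSpec":
        d = dict(d)
        d["residues"] = [tuple(r) for r in d.get("residues", [])]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AmpliconSpec":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def write_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)


@dataclass
class AmpliconProfile:
    composition: pd.DataFrame  # position, ref, fA,fC,fG,fT, coverage
    allele_table: pd.DataFrame  # haplotype, count, fraction [, aa_outcome]
    n_reads_used: int
    n_reads_unlocated: int
    n_reads_indel: int = 0


# ---------------------------------------------------------------------------
# read handling


def _read_fastq(path):
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fastq"):
        yield str(rec.seq), rec.letter_annotations["phred_quality"]


def merge_pairs(
    r1, r2, min_overlap: int = 20, max_mismatch_frac: float = 0.1
) -> tuple[list[str], int]:
    """Overlap-merge mate pairs; returns (merged sequences, n_dropped).

    ``r1``/``r2`` are FASTQ paths or iterables of ``(seq, quals)``. The
    best overlap by match count is used; within-overlap disagreements are
    resolved toward the higher-quality base. Pairs with no acceptable
    overlap are dropped and counted.
    """
    reads1 = list(_read_fastq(r1) if isinstance(r1, (str, bytes)) else r1)
    reads2 = list(_read_fastq(r2) if isinstance(r2, (str, bytes)) else r2)
    if len(reads1) != len(reads2):
        raise AmpliconError("mate files have different numbers of reads")
    pairs = zip(reads1, reads2)

    merged, dropped = [], 0
    for (s1, q1), (s2, q2) in pairs:
        s2rc = revcomp(s2)
        q2rc = list(reversed(q2))
        a1 = np.frombuffer(s1.encode(), dtype=np.uint8)
        a2 = np.frombuffer(s2rc.encode(), dtype=np.uint8)
        best = None  # (n_matches, overlap_len)
        max_ov = min(len(s1), len(s2rc))
        # scan long overlaps first; once no shorter overlap can beat the
        # best match count (matches <= k), stop
        for k in range(max_ov, min_overlap - 1, -1):
            if best is not None and best[0] >= k:
                break
            matches = int((a1[len(a1) - k :] == a2[:k]).sum())
            if k - matches <= max_mismatch_frac * k:
                if best is None or matches > best[0]:
                    best = (matches, k)
        if best is None:
            dropped += 1
            continue
        _, k = best
        head = s1[:-k]
        overlap = []
        for i in range(k):
            b1, b2 = s1[len(s1) - k + i], s2rc[i]
            if b1 == b2:
                overlap.append(b1)
            else:
                overlap.append(b1 if q1[len(s1) - k + i] >= q2rc[i] else b2)
        merged.append(head + "".join(overlap) + s2rc[k:])
    return merged, dropped


def _find_with_mismatch(read: str, pattern: str, max_mm: int) -> list[int]:
    hits = []
    m = len(pattern)
    for i in range(len(read) - m + 1):
        mm = 0
        for a, b in zip(read[i : i + m], pattern):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            hits.append(i)
    return hits


def locate_target(
    read: str, spec: AmpliconSpec, max_flank_mismatch: int = 1, search_rc: bool = False
) -> str | None:
    """Extract the sequence between the amplicon's target flanks.

    Each 10-bp flank may carry up to ``max_flank_mismatch`` mismatches.
    Ambiguous (multiple) placements return None. With ``search_rc`` the
    reverse complement of the read is also searched.
    """
    f5, f3 = spec.flank5, spec.flank3
    starts5 = _find_with_mismatch(read, f5, max_flank_mismatch)
    placements = []
    for s5 in starts5:
        t_start = s5 + len(f5)
        for s3 in _find_with_mismatch(read[t_start:], f3, max_flank_mismatch):
            placements.append((t_start, t_start + s3))
    if len(placements) == 1:
        a, b = placements[0]
        return read[a:b]
    if placements:
        return None  # ambiguous
    if search_rc:
        return locate_target(revcomp(read), spec, max_flank_mismatch, search_rc=False)
    return None


# ---------------------------------------------------------------------------
# composition and outcome calling


def base_composition(
    reads, spec: AmpliconSpec, max_flank_mismatch: int = 1, search_rc: bool = False
) -> AmpliconProfile:
    """Per-position base fractions and haplotype table over located reads.

    Only extracted targets whose length equals the reference target are
    used for positional composition; length-discordant (indel) targets
    are counted separately. Order- and duplication-invariant up to exact
    proportions.
    """
    ref_target = spec.target
    L = len(ref_target)
    counts = np.zeros((L, 4), dtype=np.int64)
    haplotypes: Counter[str] = Counter()
    n_unlocated = n_indel = 0
    base_idx = {b: i for i, b in enumerate(BASES)}
    for read in reads:
        t = locate_target(read, spec, max_flank_mismatch, search_rc)
        if t is None:
            n_unlocated += 1
            continue
        if len(t) != L:
            n_indel += 1
            haplotypes[t] += 1
            continue
        haplotypes[t] += 1
        for i, b in enumerate(t):
            if b in base_idx:
                counts[i, base_idx[b]] += 1
    coverage = counts.sum(axis=1)
    if coverage.sum() == 0:
        raise AmpliconError("no located, length-conserved reads")
    with np.errstate(invalid="ignore"):
        frac = np.where(coverage[:, None] > 0, counts / np.maximum(coverage, 1)[:, None], 0.0)
    comp = pd.DataFrame(
        {
            "position": np.arange(L),
            "ref": list(ref_target),
            "fA": frac[:, 0],
            "fC": frac[:, 1],
            "fG": frac[:, 2],
            "fT": frac[:, 3],
            "coverage": coverage,
        }
    )
    total = sum(haplotypes.values())
    allele = pd.DataFrame(
        [(h, c, c / total) for h, c in haplotypes.most_common()],
        columns=["haplotype", "count", "fraction"],
    )
    n_used = int(total - n_indel)
    return AmpliconProfile(
        composition=comp,
        allele_table=allele,
        n_reads_used=n_used,
        n_reads_unlocated=n_unlocated,
        n_reads_indel=n_indel,
    )


def editing_efficiency(profile: AmpliconProfile, position: int) -> float:
    """A→G conversion fraction at a reference-A position of the target."""
    row = profile.composition.iloc[position]
    if row["ref"] != "A":
        raise AmpliconError(f"reference base at position {position} is {row['ref']}, not A")
    return float(row["fG"])


def _label_haplotype(hap: str, spec: AmpliconSpec) -> str:
    ref_coding = spec.coding_target()
    if len(hap) != len(spec.target):
        return "indel"
    hap_coding = spec.coding_target(hap)
    changes = []
    for protein_pos, ref_aa, codon_start in sorted(spec.residues, key=lambda r: r[0]):
        ref_codon = ref_coding[codon_start : codon_start + 3]
        hap_codon = hap_coding[codon_start : codon_start + 3]
        if len(hap_codon) < 3:
            continue
        if translate_codon(ref_codon) != ref_aa:
            raise AmpliconError(
                f"spec residue {ref_aa}{protein_pos} disagrees with reference codon {ref_codon}"
            )
        new_aa = translate_codon(hap_codon)
        if new_aa != ref_aa:
            changes.append(f"{ref_aa}{protein_pos}{'*' if new_aa == '*' else new_aa}")
    if changes:
        return "/".join(changes)
    return "WT" if hap_coding == ref_coding else "synonymous"


def call_aa_outcomes(profile: AmpliconProfile, spec: AmpliconSpec) -> pd.DataFrame:
    """Annotate each observed haplotype with its amino-acid outcome label."""
    if not spec.residues:
        raise AmpliconError("spec.residues must be populated for outcome calling")
    table = profile.allele_table.copy()
    table["aa_outcome"] = [_label_haplotype(h, spec) for h in table["haplotype"]]
    return table
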