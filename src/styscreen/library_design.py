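"""sgRNA library design for adenine-base-editor S/T/Y mutagenesis.

An adenine base editor (ABE) converts A·T to G·C within a fixed window of
the protospacer. A serine, threonine or tyrosine codon is targetable when
a protospacer with a matching PAM places at least one of the codon's
editable bases (A on the protospacer strand) inside the editing window and
some combination of window edits changes the residue to a different,
non-stop amino acid. Guides are designed on both the sense strand (direct
A→G in the coding sequence) and the antisense strand (T→C when projected
back onto the coding strand). Each guide carries several internal barcodes
(iBARs) that act as built-in replicates for the screen statistic, and the
library is supplemented with safe-harbor (AAVS1) negative controls.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

STY = frozenset("STY")

_CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TO_AA[_stop] = "*"

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class DesignError(ValueError):
    """Raised for invalid transcripts, codons or edit requests."""


def translate_codon(codon: str) -> str:
    codon = codon.upper()
    if codon not in _CODON_TO_AA:
        raise DesignError(f"not a DNA codon: {codon!r}")
    return _CODON_TO_AA[codon]


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _matches_iupac(seq: str, pattern: str) -> bool:
    return len(seq) == len(pattern) and all(
        b in _IUPAC[p] for b, p in zip(seq, pattern.upper())
    )


@dataclass(frozen=True)
class EditorSpec:
    """Base-editor activity model.

    ``window_start``/``window_end`` are 1-based protospacer positions
    counted from the PAM-distal (5') end; the default 4–8 window is the
    canonical ABEmax high-activity window. The chemistry is fixed: A→G on
    the protospacer strand.
    """

    window_start: int = 4
    window_end: int = 8
    protospacer_len: int = 20
    pam: str = "NGG"

    def __post_init__(self) -> None:
        if not (1 <= self.window_start <= self.window_end <= self.protospacer_len):
            raise DesignError("editing window must satisfy 1 <= start <= end <= protospacer_len")
        if not self.pam:
            raise DesignError("PAM pattern must be non-empty")


@dataclass
class TranscriptModel:
    """A coding sequence with optional genomic flanks for PAM search."""

    gene_id: str
    protein_id: str
    cds: str
    flank5: str = ""
    flank3: str = ""

    def __post_init__(self) -> None:
        self.cds = self.cds.upper()
        self.flank5 = self.flank5.upper()
        self.flank3 = self.flank3.upper()
        if len(self.cds) % 3 != 0:
            raise DesignError(f"{self.gene_id}: CDS length {len(self.cds)} is not a multiple of 3")
        for name, s in (("cds", self.cds), ("flank5", self.flank5), ("flank3", self.flank3)):
            if set(s) - set("ACGT"):
                raise DesignError(f"{self.gene_id}: non-ACGT characters in {name}")

    @property
    def context(self) -> str:
        return self.flank5 + self.cds + self.flank3

    def reverse_complemented(self) -> "TranscriptModel":
        """Mirror transcript: RC the CDS and swap/RC the flanks."""
        return TranscriptModel(
            gene_id=self.gene_id,
            protein_id=self.protein_id,
            cds=revcomp(self.cds),
            flank5=revcomp(self.flank3),
            flank3=revcomp(self.flank5),
        )


@dataclass
class GuideDesign:
    spacer: str
    pam: str
    strand: str  # "sense" | "antisense" relative to the coding strand
    gene_id: str
    residue: tuple[str, int] | None  # (one-letter AA, 1-based protein position)
    on_target_change: str = ""
    bystander_changes: list[str] = field(default_factory=list)
    window_adenines: list[int] = field(default_factory=list)  # protospacer positions
    ibars: list[str] = field(default_factory=list)
    is_control: bool = False
    # outcome of every non-empty subset of window edits at the target codon,
    # keyed by the edited codon positions
    subset_outcomes: dict[tuple[int, ...], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.is_control:
            aa, pos = self.residue
            if aa not in STY:
                raise DesignError(f"target residue {aa}{pos} is not S/T/Y")
        if len(set(self.ibars)) != len(self.ibars):
            raise DesignError("iBARs of a guide must be pairwise distinct")


@dataclass
class LibraryTable:
    guides: list[GuideDesign]
    sublibrary: str  # "sense" | "antisense" | "controls"

    def validate(self) -> None:
        """No duplicate physical (spacer, ibar) oligos.

        A spacer may appear in several annotation rows (one per targeted
        residue); those rows must carry identical iBAR sets, since they
        describe the same physical guide.
        """
        by_spacer: dict[str, tuple[str, ...]] = {}
        for g in self.guides:
            ib = tuple(g.ibars)
            if g.spacer in by_spacer:
                if by_spacer[g.spacer] != ib:
                    raise DesignError(
                        f"rows for spacer {g.spacer} carry conflicting iBAR sets"
                    )
            else:
                by_spacer[g.spacer] = ib

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.guides:
            row = {
                "sublibrary": self.sublibrary,
                "gene_id": g.gene_id,
                "residue": "" if g.residue is None else f"{g.residue[0]}{g.residue[1]}",
                "spacer": g.spacer,
                "pam": g.pam,
                "strand": g.strand,
                "on_target_change": g.on_target_change,
                "bystanders": ",".join(g.bystander_changes),
                "is_control": g.is_control,
            }
            for i, b in enumerate(g.ibars, start=1):
                row[f"ibar{i}"] = b
            rows.append(row)
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sublibrary: str | None = None) -> "LibraryTable":
        if sublibrary is None:
            sublibrary = str(df["sublibrary"].iloc[0]) if len(df) else "sense"
        ibar_cols = sorted(c for c in df.columns if c.startswith("ibar"))
        guides = []
        for _, r in df.iterrows():
            res = None
            if isinstance(r.get("residue"), str) and r["residue"]:
                res = (r["residue"][0], int(r["residue"][1:]))
            guides.append(
                GuideDesign(
                    spacer=r["spacer"],
                    pam=r["pam"],
                    strand=r["strand"],
                    gene_id=r["gene_id"],
                    residue=res,
                    on_target_change=r.get("on_target_change", "") or "",
                    bystander_changes=[b for b in str(r.get("bystanders", "") or "").split(",") if b],
                    ibars=[r[c] for c in ibar_cols if isinstance(r.get(c), str) and r[c]],
                    is_control=bool(r["is_control"]),
                )
            )
        return cls(guides=guides, sublibrary=sublibrary)

    @classmethod
    def read_tsv(cls, path, sublibrary: str | None = None) -> "LibraryTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"), sublibrary)


# ---------------------------------------------------------------------------
# residue enumeration and codon consequences


def enumerate_sty_residues(transcript: TranscriptModel) -> list[tuple[int, str, str, int]]:
    """All S/T/Y codons of a CDS as (protein_pos, AA, codon, cds_offset).

    Protein positions are 1-based; cds_offset is the 0-based offset of the
    codon's first base in the CDS.
    """
    out = []
    for i in range(0, len(transcript.cds), 3):
        codon = transcript.cds[i : i + 3]
        aa = translate_codon(codon)
        if aa in STY:
            out.append((i // 3 + 1, aa, codon, i))
    return out


def codon_edit_outcomes(
    codon: str, edited_codon_positions, strand: str
) -> tuple[str, str, str]:
    """Apply ABE edits to a codon (coding-strand view) and classify.

    Sense-strand guides edit A→G directly in the codon; antisense guides
    edit A→G on the opposite strand, which reads as T→C on the coding
    strand. Returns ``(new_codon, new_AA, category)`` with category one of
    ``missense`` (different, non-stop AA), ``synonymous``, ``stop_gain``
    or ``other``.
    """
    codon = codon.upper()
    positions = sorted(set(edited_codon_positions))
    if strand not in ("sense", "antisense"):
        raise DesignError(f"strand must be sense|antisense, got {strand!r}")
    src, dst = ("A", "G") if strand == "sense" else ("T", "C")
    bases = list(codon)
    for p in positions:
        if p not in (1, 2, 3):
            raise DesignError(f"codon position {p} out of range")
        if bases[p - 1] != src:
            raise DesignError(
                f"position {p} of {codon} holds {bases[p-1]}, not editable {src} ({strand})"
            )
        bases[p - 1] = dst
    new_codon = "".join(bases)
    old_aa, new_aa = translate_codon(codon), translate_codon(new_codon)
    if new_aa == old_aa:
        category = "synonymous"
    elif new_aa == "*":
        category = "stop_gain"
    elif old_aa == "*":
        category = "other"
    else:
        category = "missense"
    return new_codon, new_aa, category


# ---------------------------------------------------------------------------
# guide design


def _scan_protospacers(strand_seq: str, editor: EditorSpec):
    """Yield (start, spacer, pam) for every PAM-matched protospacer."""
    L, P = editor.protospacer_len, len(editor.pam)
    for i in range(len(strand_seq) - L - P + 1):
        pam = strand_seq[i + L : i + L + P]
        if _matches_iupac(pam, editor.pam):
            yield i, strand_seq[i : i + L], pam


def _codon_groups(window_coding_idx, cds_start, cds_len):
    """Group coding-strand indices of editable window bases by codon.

    Returns {codon_index: [codon positions 1..3]} for bases inside the CDS.
    """
    groups: dict[int, list[int]] = {}
    for c in window_coding_idx:
        off = c - cds_start
        if 0 <= off < cds_len:
            groups.setdefault(off // 3, []).append(off % 3 + 1)
    return groups


def design_guides(
    transcript: TranscriptModel, editor: EditorSpec | None = None
) -> list[GuideDesign]:
    """Enumerate every guide that can install an S/T/Y missense change.

    One ``GuideDesign`` is emitted per (protospacer, strand, S/T/Y residue)
    for which at least one combination of window edits at that codon is
    missense. ``on_target_change`` is the consequence of editing *all*
    editable window bases of the target codon (the dominant multi-edit
    product of a processive editor); edits at other codons under the
    window are reported as bystanders.
    """
    editor = editor or EditorSpec()
    seq = transcript.context
    cds_start, cds_len = len(transcript.flank5), len(transcript.cds)
    rc_seq = revcomp(seq)
    n = len(seq)
    guides: list[GuideDesign] = []

    for strand in ("sense", "antisense"):
        strand_seq = seq if strand == "sense" else rc_seq
        src_base = "A"  # on the protospacer strand, always
        for start, spacer, pam in _scan_protospacers(strand_seq, editor):
            window_positions = [
                w
                for w in range(editor.window_start, editor.window_end + 1)
                if strand_seq[start + w - 1] == src_base
            ]
            if not window_positions:
                continue
            # map protospacer window positions to coding-strand indices
            if strand == "sense":
                coding_idx = {w: start + w - 1 for w in window_positions}
            else:
                coding_idx = {w: n - 1 - (start + w - 1) for w in window_positions}
            groups = _codon_groups(coding_idx.values(), cds_start, cds_len)
            if not groups:
                continue

            # precompute the all-edited consequence of every touched codon
            consequences: dict[int, tuple[str, str, str]] = {}
            for codon_idx, cpos in groups.items():
                codon = transcript.cds[codon_idx * 3 : codon_idx * 3 + 3]
                consequences[codon_idx] = codon_edit_outcomes(codon, cpos, strand)

            for codon_idx, cpos in groups.items():
                codon = transcript.cds[codon_idx * 3 : codon_idx * 3 + 3]
                aa = translate_codon(codon)
                if aa not in STY:
                    continue
                subset_outcomes: dict[tuple[int, ...], str] = {}
                any_missense = False
                for r in range(1, len(cpos) + 1):
                    for combo in itertools.combinations(sorted(cpos), r):
                        _, new_aa, cat = codon_edit_outcomes(codon, combo, strand)
                        subset_outcomes[combo] = f"{aa}{codon_idx + 1}{new_aa}|{cat}"
                        if cat == "missense":
                            any_missense = True
                if not any_missense:
                    continue
                _, on_aa, on_cat = consequences[codon_idx]
                bystanders = []
                for other_idx, (_, b_aa, b_cat) in sorted(consequences.items()):
                    if other_idx == codon_idx:
                        continue
                    other_codon = transcript.cds[other_idx * 3 : other_idx * 3 + 3]
                    other_aa = translate_codon(other_codon)
                    if b_aa != other_aa:
                        bysuffix = "*" if b_aa == "*" else b_aa
                        bystanders.append(f"{other_aa}{other_idx + 1}{bysuffix}")
                guides.append(
                    GuideDesign(
                        spacer=spacer,
                        pam=pam,
                        strand=strand,
                        gene_id=transcript.gene_id,
                        residue=(aa, codon_idx + 1),
                        on_target_change=f"{aa}{codon_idx + 1}{on_aa}",
                        bystander_changes=bystanders,
                        window_adenines=sorted(window_positions),
                        subset_outcomes=subset_outcomes,
                    )
                )
    return guides


# ---------------------------------------------------------------------------
# iBAR assignment and controls

_IBAR_ALPHABET = "ACGT"


def _has_homopolymer(s: str, run: int = 4) -> bool:
    count, prev = 1, ""
    for c in s:
        count = count + 1 if c == prev else 1
        if count >= run:
            return True
        prev = c
    return False


def _ibar_pool(length: int) -> list[str]:
    return [
        "".join(t)
        for t in itertools.product(_IBAR_ALPHABET, repeat=length)
        if not _has_homopolymer("".join(t))
    ]


def _spacer_key(spacer: str) -> int:
    # stable across processes (unlike hash())
    return int.from_bytes(hashlib.sha256(spacer.encode()).digest()[:4], "big")


def assign_ibars(
    library: LibraryTable, n_ibars: int = 3, length: int = 6, seed: int = 0
) -> LibraryTable:
    """Give each guide ``n_ibars`` distinct barcodes.

    Barcodes avoid homopolymer runs of 4+. Uniqueness is enforced within a
    guide, not globally; the draw is keyed on (seed, spacer) so the same
    spacer receives the same barcodes in every sub-library.
    """
    if n_ibars < 1:
        raise DesignError("n_ibars must be >= 1")
    pool = _ibar_pool(length)
    if n_ibars > len(pool):
        raise DesignError(
            f"barcode space exhausted: need {n_ibars} of {len(pool)} valid {length}-mers"
        )
    guides = []
    for g in library.guides:
        rng = np.random.default_rng([seed, _spacer_key(g.spacer)])
        picks = rng.choice(len(pool), size=n_ibars, replace=False)
        guides.append(replace(g, ibars=[pool[i] for i in picks]))
    out = LibraryTable(guides=guides, sublibrary=library.sublibrary)
    out.validate()
    return out


def add_controls(
    library: LibraryTable, control_spacers: list[str], label: str = "AAVS1"
) -> LibraryTable:
    """Append safe-harbor negative-control guides to a sub-library.

    The same control spacers are meant to be added to both the sense and
    antisense sub-libraries; combined with spacer-keyed iBAR assignment the
    control rows come out identical in both.
    """
    existing = {g.spacer for g in library.guides}
    controls = []
    for sp in control_spacers:
        sp = sp.upper()
        if len(sp) != 20:
            raise DesignError(f"control spacer must be 20 nt, got {len(sp)}")
        if sp in existing:
            raise DesignError(f"control spacer collides with an existing guide: {sp}")
        existing.add(sp)
        controls.append(
            GuideDesign(
                spacer=sp,
                pam="NGG",
                strand="sense",
                gene_id=label,
                residue=None,
                is_control=True,
            )
        )
    return LibraryTable(guides=library.guides + controls, sublibrary=library.sublibrary)


# ---------------------------------------------------------------------------
# FASTA input


def read_cds_fasta(path) -> list[TranscriptModel]:
    """Read transcripts from FASTA with headers ``gene_id|protein_id``.

    Optional third and fourth pipe-separated header fields carry the 5'
    and 3' flanks.
    """
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        gene_id = parts[0]
        protein_id = parts[1] if len(parts) > 1 else parts[0]
        flank5 = parts[2] if len(parts) > 2 else ""
        flank3 = parts[3] if len(parts) > 3 else ""
        out.append(
            TranscriptModel(
                gene_id=gene_id,
                protein_id=protein_id,
                cds=str(rec.seq),
                flank5=flank5,
                flank3=flank3,
            )
        )
    return out
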