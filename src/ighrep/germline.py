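"""Germline IGH segment references.

A reference set holds V, D, J and C gene segments as ungapped nucleotide
sequences.  V and J segments additionally carry a *CDR3 anchor*: the
0-based offset of the first base of the conserved 2nd-CYS codon (TGT/TGC,
near the V 3' end) or of the conserved J-TRP codon (TGG).  The junction
(CDR-H3 with both anchor residues included) is defined as the read span
from the V anchor codon through the J anchor codon, inclusive, so anchors
are load-time validated rather than trusted downstream.

Two FASTA dialects are supported: ``plain`` (ungapped records, optionally
with an ``anchor=<int>`` token in the description) and ``imgt_gapped``
(IMGT unique-numbering gaps written as ``.``; the 2nd-CYS sits at gapped
codon 104 and the J-TRP is located by the canonical W-G-x-G motif).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SEG_CLASSES = ("V", "D", "J", "C")
CYS_CODONS = frozenset({"TGT", "TGC"})
TRP_CODON = "TGG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: Human IGH constant-region genes in genomic (locus) order; used to name
#: synthetic C segments so isotype-stratified analyses work out of the box.
CANONICAL_ISOTYPES = (
    "IGHM", "IGHD", "IGHG3", "IGHG1", "IGHA1",
    "IGHG2", "IGHG4", "IGHE", "IGHA2", "IGHGP",
)

# IMGT unique numbering: 2nd-CYS is codon 104 -> gapped nt offset 309 (0-based)
_IMGT_CYS_GAPPED_OFFSET = 3 * (104 - 1)

_VALID_SEQ_RE = re.compile(r"^[ACGT]+$")
_ANCHOR_TOKEN_RE = re.compile(r"\banchor=(\d+)\b")


class GermlineError(ValueError):
    """Raised for malformed or inconsistent germline references."""


def family_of(seg_id: str) -> str:
    """Gene family of a segment id: allele suffix (``*01``) stripped, then
    everything up to the first ``-`` (``IGHV3-30-3`` -> ``IGHV3``)."""
    base = seg_id.split("*", 1)[0]
    return base.split("-", 1)[0]


@dataclass(frozen=True)
class GermlineSegment:
    """One reference gene segment."""

    id: str
    seg_class: str
    sequence: str
    anchor: Optional[int] = None

    def __post_init__(self) -> None:
        if self.seg_class not in SEG_CLASSES:
            raise GermlineError(f"{self.id}: unknown segment class {self.seg_class!r}")
        if not self.sequence:
            raise GermlineError(f"{self.id}: empty sequence")
        if not _VALID_SEQ_RE.match(self.sequence):
            raise GermlineError(
                f"{self.id}: sequence contains characters outside ACGT"
            )
        if self.seg_class in ("D", "C"):
            if self.anchor is not None:
                raise GermlineError(f"{self.id}: {self.seg_class} segments carry no anchor")
            return
        if self.anchor is None:
            raise GermlineError(f"{self.id}: {self.seg_class} segment requires an anchor")
        if not 0 <= self.anchor <= len(self.sequence) - 3:
            raise GermlineError(f"{self.id}: anchor {self.anchor} outside sequence")
        codon = self.sequence[self.anchor : self.anchor + 3]
        if self.seg_class == "V" and codon not in CYS_CODONS:
            raise GermlineError(
                f"{self.id}: V anchor codon {codon} is not a 2nd-CYS (TGT/TGC)"
            )
        if self.seg_class == "J" and codon != TRP_CODON:
            raise GermlineError(f"{self.id}: J anchor codon {codon} is not TGG (J-TRP)")

    @property
    def family(self) -> str:
        return family_of(self.id)


def anchor_of(segment: GermlineSegment) -> Optional[int]:
    """Stored CDR3 anchor offset for V/J segments; ``None`` for D and C."""
    return segment.anchor


@dataclass
class GermlineSet:
    """A validated collection of germline segments keyed by id."""

    segments: dict[str, GermlineSegment] = field(default_factory=dict)

    def add(self, segment: GermlineSegment) -> None:
        if segment.id in self.segments:
            raise GermlineError(f"duplicate segment id {segment.id!r}")
        self.segments[segment.id] = segment

    def update(self, other: "GermlineSet") -> None:
        for seg in other.segments.values():
            self.add(seg)

    def by_class(self, seg_class: str) -> list[GermlineSegment]:
        return sorted(
            (s for s in self.segments.values() if s.seg_class == seg_class),
            key=lambda s: s.id,
        )

    def __getitem__(self, seg_id: str) -> GermlineSegment:
        return self.segments[seg_id]

    def __contains__(self, seg_id: str) -> bool:
        return seg_id in self.segments

    def __len__(self) -> int:
        return len(self.segments)

    def ids(self, seg_class: Optional[str] = None) -> list[str]:
        if seg_class is None:
            return sorted(self.segments)
        return [s.id for s in self.by_class(seg_class)]

    def validate_for_annotation(self) -> None:
        if not self.by_class("V") or not self.by_class("J"):
            raise GermlineError("reference must contain at least one V and one J segment")

    def write_fasta(self, path: str | Path) -> None:
        records = []
        for seg in sorted(self.segments.values(), key=lambda s: (s.seg_class, s.id)):
            desc = f"class={seg.seg_class}"
            if seg.anchor is not None:
                desc += f" anchor={seg.anchor}"
            records.append(SeqRecord(Seq(seg.sequence), id=seg.id, description=desc))
        SeqIO.write(records, str(path), "fasta")


def _infer_anchor_plain(seq: str, seg_class: str) -> Optional[int]:
    """Best-effort anchor inference for plain (ungapped) records that do not
    declare one: last in-frame 2nd-CYS for V, W-G-x-G scan for J."""
    if seg_class == "V":
        candidates = [
            p for p in range(0, len(seq) - 2, 3) if seq[p : p + 3] in CYS_CODONS
        ]
        return candidates[-1] if candidates else None
    if seg_class == "J":
        return _find_j_trp(seq)
    return None


def _find_j_trp(seq: str) -> Optional[int]:
    """Locate the conserved J-TRP via the canonical W-G-x-G FR4 motif."""
    for frame in range(3):
        aa = str(Seq(seq[frame:]).translate(to_stop=False))
        m = re.search(r"WG.G", aa)
        if m:
            return frame + 3 * m.start()
    # fall back to the first TGG in any frame
    pos = seq.find(TRP_CODON)
    return pos if pos >= 0 else None


def load_germline_fasta(
    path: str | Path,
    seg_class: str,
    dialect: str = "plain",
) -> GermlineSet:
    """Load one segment class from FASTA into a :class:`GermlineSet`.

    ``imgt_gapped`` records have IMGT numbering gaps (``.``) removed and
    anchors recomputed onto the ungapped sequence.  Records containing N
    are skipped with a warning; any other non-ACGT character is an error.
    """
    if dialect not in ("plain", "imgt_gapped"):
        raise GermlineError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise GermlineError(f"germline FASTA not found: {path}")
    out = GermlineSet()
    n_records = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        seg_id = rec.id.split("|")[1] if "|" in rec.id else rec.id
        raw = str(rec.seq).upper()
        if dialect == "imgt_gapped":
            gapped = raw
            raw = raw.replace(".", "")
        if "N" in raw:
            warnings.warn(f"skipping {seg_id}: sequence contains N", stacklevel=2)
            continue
        if not raw or not _VALID_SEQ_RE.match(raw):
            raise GermlineError(f"{seg_id}: sequence contains characters outside ACGT")
        anchor: Optional[int] = None
        if seg_class in ("V", "J"):
            m = _ANCHOR_TOKEN_RE.search(rec.description)
            if m:
                anchor = int(m.group(1))
                if dialect == "imgt_gapped":
                    anchor = sum(1 for c in gapped[:anchor] if c != ".")
            elif dialect == "imgt_gapped" and seg_class == "V":
                if len(gapped) < _IMGT_CYS_GAPPED_OFFSET + 3:
                    raise GermlineError(f"{seg_id}: gapped V shorter than codon 104")
                anchor = sum(1 for c in gapped[:_IMGT_CYS_GAPPED_OFFSET] if c != ".")
            else:
                anchor = _infer_anchor_plain(raw, seg_class)
            if anchor is None:
                raise GermlineError(f"{seg_id}: could not determine {seg_class} anchor")
        out.add(GermlineSegment(id=seg_id, seg_class=seg_class, sequence=raw, anchor=anchor))
    if n_records == 0:
        raise GermlineError(f"no records in {path}")
    return out


def _hamming_identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    matches = sum(1 for x, y in zip(a, b) if x == y)
    return matches / max(len(a), len(b))


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n random codons avoiding stop codons."""
    bases = "ACGT"
    out = []
    while len(out) < n:
        codon = "".join(rng.choice(list(bases), size=3))
        if codon not in STOP_CODONS:
            out.append(codon)
    return "".join(out)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.asarray(list("ACGT"))[rng.integers(0, 4, size=n)])


def build_synthetic_reference(
    n_v: int = 30,
    n_d: int = 15,
    n_j: int = 6,
    n_c: int = 10,
    v_length: int = 294,
    min_pairwise_divergence: float = 0.15,
    seed: int = 0,
    d_length: int = 18,
    j_length: int = 48,
    c_length: int = 60,
) -> GermlineSet:
    """Build a random but structurally valid IGH reference set.

    Every V ends with ...2nd-CYS codon + 6 nt (anchor at ``v_length - 9``,
    a multiple of 3 so the V reading frame starts at offset 0); every J
    carries TGG at offset 6 followed by a W-G-x-G FR4 motif.  V and J
    coding regions are stop-free in frame so productive rearrangements are
    common.  Within each class all pairwise identities are at most
    ``1 - min_pairwise_divergence``; generation is deterministic per seed.
    """
    if min(n_v, n_d, n_j, n_c) < 1:
        raise GermlineError("segment counts must be >= 1")
    if not 0 <= min_pairwise_divergence < 1:
        raise GermlineError("min_pairwise_divergence must be in [0, 1)")
    if v_length % 3 != 0 or v_length < 60:
        raise GermlineError("v_length must be a multiple of 3 and >= 60")
    rng = np.random.default_rng(seed)
    max_identity = 1.0 - min_pairwise_divergence
    out = GermlineSet()

    def _make_unique(n: int, builder, namer, seg_class: str, anchor: Optional[int]) -> None:
        accepted: list[str] = []
        for i in range(n):
            for _attempt in range(500):
                seq = builder(i)
                if all(_hamming_identity(seq, prev) <= max_identity for prev in accepted):
                    accepted.append(seq)
                    out.add(
                        GermlineSegment(
                            id=namer(i), seg_class=seg_class, sequence=seq, anchor=anchor
                        )
                    )
                    break
            else:
                raise GermlineError(
                    f"could not satisfy divergence {min_pairwise_divergence} for "
                    f"{seg_class} segment {i + 1}; lower min_pairwise_divergence"
                )

    v_anchor = v_length - 9

    def _build_v(_i: int) -> str:
        cys = "TGT" if rng.random() < 0.5 else "TGC"
        return _random_codons(rng, v_anchor // 3) + cys + _random_codons(rng, 2)

    _make_unique(n_v, _build_v, lambda i: f"IGHV{i % 7 + 1}-{i + 1}", "V", v_anchor)

    def _build_j(_i: int) -> str:
        # 6 nt 5' of the anchor feed the junction; anchor frame reads W-G-x-G
        head = _random_seq(rng, 6)
        motif = "GG" + _random_seq(rng, 1) + _random_codons(rng, 1) + "GG" + _random_seq(rng, 1)
        tail_codons = (j_length - 18) // 3
        return head + TRP_CODON + motif + _random_codons(rng, tail_codons)

    _make_unique(n_j, _build_j, lambda i: f"IGHJ{i + 1}", "J", 6)
    _make_unique(
        n_d, lambda _i: _random_seq(rng, d_length),
        lambda i: f"IGHD{i % 7 + 1}-{i + 1}", "D", None,
    )

    def _c_name(i: int) -> str:
        if i < len(CANONICAL_ISOTYPES):
            return CANONICAL_ISOTYPES[i]
        return f"IGHC{i + 1}"

    _make_unique(n_c, lambda _i: _random_seq(rng, c_length), _c_name, "C", None)
    return out


def isotype_class(c_call: Optional[str]) -> Optional[str]:
    """Collapse a constant-gene call to its isotype class
    (IGHG1-4 -> IGHG, IGHA1-2 -> IGHA); other names pass through."""
    if c_call is None or c_call != c_call:  # None or NaN
        return None
    m = re.match(r"^(IGH[GA])\d$", c_call)
    return m.group(1) if m else c_call
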