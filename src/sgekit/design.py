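"""Amplicon/library designs, coordinate mapping and variant consequences.

An :class:`AmpliconDesign` describes one sequenced amplicon: its reference
sequence, which parts of it are exonic, how amplicon positions map onto
HGVS ``c.`` coordinates, where Cas9 cuts, and which fixed synonymous edits
act as the HDR marker.  Variants are identified by :class:`VariantKey`
(substitution edits in ``c.`` space); the marker edits are design metadata
and never part of a variant's identity, because reads are only counted as
library members conditional on the marker being present.

Coordinate conventions
----------------------
Amplicon positions are 0-based half-open throughout the package.  At the
interface, positions are HGVS-style: ``c.`` coordinates are 1-based and
intronic positions carry a signed offset from the nearest exon boundary
(``c.7007+7``, ``c.6938-12``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

_DNA = set("ACGT")
_STOPS = {"TAA", "TAG", "TGA"}


class CoordinateError(ValueError):
    """Position outside the amplicon or not mappable to c. space."""


class DesignError(ValueError):
    """Design invariant violated or variant inconsistent with the design."""


@dataclass(frozen=True, order=True)
class CdnaPosition:
    """HGVS-style c. coordinate: coding base plus signed intronic offset.

    ``offset == 0`` means exonic; ``offset`` is positive downstream of an
    exon end and negative upstream of an exon start.
    """

    base: int
    offset: int = 0

    def __str__(self) -> str:
        if self.offset == 0:
            return str(self.base)
        return f"{self.base}{self.offset:+d}"

    @property
    def is_exonic(self) -> bool:
        return self.offset == 0

    @classmethod
    def parse(cls, text: str | int | CdnaPosition) -> "CdnaPosition":
        if isinstance(text, CdnaPosition):
            return text
        if isinstance(text, int):
            return cls(text)
        m = re.fullmatch(r"(?:c\.)?(-?\d+)(?:([+-]\d+))?", str(text).strip())
        if not m:
            raise CoordinateError(f"cannot parse c. position {text!r}")
        return cls(int(m.group(1)), int(m.group(2) or 0))


@dataclass(frozen=True)
class Consequence:
    """Predicted effect of a variant under the declared reading frame."""

    kind: str  # synonymous | missense | nonsense | intronic | splice_region
    aa_ref: str = ""
    aa_alt: str = ""
    aa_number: int = 0

    @property
    def hgvs_p(self) -> str:
        if self.kind in ("intronic", "splice_region") or not self.aa_ref:
            return ""
        ref3 = seq3(self.aa_ref)
        if self.kind == "synonymous":
            return f"p.{ref3}{self.aa_number}="
        if self.kind == "nonsense":
            return f"p.{ref3}{self.aa_number}*"
        return f"p.{ref3}{self.aa_number}{seq3(self.aa_alt)}"


@dataclass(frozen=True)
class VariantKey:
    """Canonical identity of a library variant: sorted substitution edits.

    ``edits`` are ``(CdnaPosition, ref, alt)`` single-base substitutions.
    The empty-edit key (``hgvs_c == "c."``) is reserved for the
    marker-only allele, i.e. the wild-type codon drawn from the degenerate
    library: it carries the HDR marker but no other change.
    """

    amplicon_id: str
    edits: tuple[tuple[CdnaPosition, str, str], ...]
    hgvs_c: str
    hgvs_p: str = ""

    def __str__(self) -> str:
        return self.hgvs_c

    @property
    def is_marker_only(self) -> bool:
        return not self.edits


WT_CODON_HGVS = "c.="


def _exon_cumlen(exons: Sequence[tuple[int, int]]) -> list[int]:
    out, total = [], 0
    for s, e in exons:
        out.append(total)
        total += e - s
    return out


@dataclass
class AmpliconDesign:
    """Reference amplicon with exon structure, cut site and HDR marker.

    Parameters
    ----------
    reference_seq : str
        Uppercase ACGT reference amplicon.
    exon_intervals : list of (start, end)
        0-based half-open exonic intervals in amplicon coordinates, sorted
        and non-overlapping.
    cdna_offset : int
        Signed shift such that the *k*-th exonic base of the amplicon
        (1-based) has HGVS coordinate ``c.(k + cdna_offset)``.  Choosing it
        congruent with the true CDS position fixes the reading frame.
    cut_sites : list of int
        Blunt-cut positions (the cut falls between ``pos - 1`` and ``pos``).
    marker_edits : list of (position, ref, alt)
        The fixed synonymous PAM-blocking edits, amplicon coordinates.
    target_region : (start, end)
        Amplicon span holding the saturated codon(s)/region.
    """

    amplicon_id: str
    reference_seq: str
    exon_intervals: list[tuple[int, int]]
    cdna_offset: int
    cut_sites: list[int]
    marker_edits: list[tuple[int, str, str]]
    target_region: tuple[int, int]
    cds_frame_offset: int | None = None

    def __post_init__(self) -> None:
        self.reference_seq = self.reference_seq.upper()
        if set(self.reference_seq) - _DNA:
            raise DesignError("reference contains non-ACGT characters")
        n = len(self.reference_seq)
        self.exon_intervals = sorted(tuple(iv) for iv in self.exon_intervals)
        prev_end = -1
        for s, e in self.exon_intervals:
            if not (0 <= s < e <= n):
                raise DesignError(f"exon interval {(s, e)} outside amplicon")
            if s < prev_end:
                raise DesignError("exon intervals overlap")
            prev_end = e
        for c in self.cut_sites:
            if not 0 <= c <= n:
                raise DesignError(f"cut site {c} outside amplicon")
        for p, ref, _ in self.marker_edits:
            if not 0 <= p < n:
                raise DesignError(f"marker position {p} outside amplicon")
            if self.reference_seq[p] != ref:
                raise DesignError(f"marker ref mismatch at {p}")
        s, e = self.target_region
        if not 0 <= s < e <= n:
            raise DesignError("target region outside amplicon")
        derived_phase = self.cdna_offset % 3
        if self.cds_frame_offset is None:
            self.cds_frame_offset = derived_phase
        elif self.cds_frame_offset % 3 != derived_phase:
            raise DesignError(
                "cds_frame_offset inconsistent with cdna_offset phase"
            )
        self._cum = _exon_cumlen(self.exon_intervals)
        self._check_marker_synonymous()

    # -- coordinate mapping -------------------------------------------------

    def map_position(self, amplicon_pos: int) -> CdnaPosition:
        """Map an amplicon position to its HGVS ``c.`` coordinate."""
        n = len(self.reference_seq)
        if not 0 <= amplicon_pos < n:
            raise CoordinateError(f"position {amplicon_pos} outside amplicon")
        for (s, e), cum in zip(self.exon_intervals, self._cum):
            if s <= amplicon_pos < e:
                return CdnaPosition(cum + (amplicon_pos - s) + 1 + self.cdna_offset)
        # intronic/flanking: anchor at the nearest exon boundary; at equal
        # distance the upstream exon end (+ offset) wins, per HGVS practice.
        best: tuple[int, CdnaPosition] | None = None
        for (s, e), cum in zip(self.exon_intervals, self._cum):
            if amplicon_pos < s:
                d = s - amplicon_pos
                cand = CdnaPosition(cum + 1 + self.cdna_offset, -d)
            else:  # amplicon_pos >= e
                d = amplicon_pos - (e - 1)
                cand = CdnaPosition(cum + (e - s) + self.cdna_offset, d)
            if best is None or d < best[0]:
                best = (d, cand)
        if best is None:
            raise CoordinateError("design has no exon intervals")
        return best[1]

    def to_amplicon(self, pos: str | int | CdnaPosition) -> int:
        """Inverse of :meth:`map_position`."""
        cp = CdnaPosition.parse(pos)
        coding = cp.base - self.cdna_offset
        for (s, e), cum in zip(self.exon_intervals, self._cum):
            if cum < coding <= cum + (e - s):
                amp = s + (coding - cum - 1) + cp.offset
                if not 0 <= amp < len(self.reference_seq):
                    raise CoordinateError(f"{cp} falls outside the amplicon")
                return amp
        raise CoordinateError(f"c. position {cp} not covered by the design")

    # -- codon helpers ------------------------------------------------------

    def codon_positions(self, aa_number: int) -> list[int]:
        """Amplicon positions of codon ``aa_number`` (c. ``3a-2 .. 3a``)."""
        return [self.to_amplicon(CdnaPosition(3 * aa_number - 2 + k)) for k in range(3)]

    def wt_codon(self, aa_number: int) -> str:
        return "".join(self.reference_seq[p] for p in self.codon_positions(aa_number))

    def apply_edits(
        self,
        edits: Iterable[tuple[CdnaPosition, str, str]] = (),
        with_marker: bool = False,
    ) -> str:
        """Reference sequence with variant (and optionally marker) edits."""
        seq = list(self.reference_seq)
        if with_marker:
            for p, ref, alt in self.marker_edits:
                seq[p] = alt
        for cp, ref, alt in edits:
            p = self.to_amplicon(cp)
            if self.reference_seq[p] != ref:
                raise DesignError(f"edit ref mismatch at {cp}: design has "
                                  f"{self.reference_seq[p]}, edit says {ref}")
            seq[p] = alt
        return "".join(seq)

    def _check_marker_synonymous(self) -> None:
        if not self.marker_edits:
            return
        marked = self.apply_edits(with_marker=True)
        codons = set()
        for p, _, _ in self.marker_edits:
            cp = self.map_position(p)
            if not cp.is_exonic:
                continue
            codons.add((cp.base - 1) // 3 + 1)
        for aa in codons:
            positions = self.codon_positions(aa)
            ref_codon = "".join(self.reference_seq[q] for q in positions)
            alt_codon = "".join(marked[q] for q in positions)
            if str(Seq(ref_codon).translate()) != str(Seq(alt_codon).translate()):
                raise DesignError(
                    f"marker edit is not synonymous in codon {aa} "
                    f"({ref_codon}->{alt_codon})"
                )


# -- module-level operation wrappers ----------------------------------------


def map_position(design: AmpliconDesign, amplicon_pos: int) -> CdnaPosition:
    """HGVS ``c.`` coordinate of an amplicon position (see the class docs)."""
    return design.map_position(amplicon_pos)


def _hgvs_c(design: AmpliconDesign,
            edits: Sequence[tuple[CdnaPosition, str, str]]) -> str:
    """HGVS c. description; contiguous-codon edits collapse to a range."""
    if not edits:
        return WT_CODON_HGVS
    if len(edits) == 1:
        cp, ref, alt = edits[0]
        return f"c.{cp}{ref}>{alt}"
    if all(cp.is_exonic for cp, _, _ in edits):
        lo, hi = edits[0][0].base, edits[-1][0].base
        by_base = {cp.base: (ref, alt) for cp, ref, alt in edits}
        refs, alts = [], []
        for b in range(lo, hi + 1):
            if b in by_base:
                refs.append(by_base[b][0])
                alts.append(by_base[b][1])
            else:
                base = design.reference_seq[design.to_amplicon(CdnaPosition(b))]
                refs.append(base)
                alts.append(base)
        return f"c.{lo}_{hi}{''.join(refs)}>{''.join(alts)}"
    return "c." + ";".join(f"{cp}{ref}>{alt}" for cp, ref, alt in edits)


def make_variant_key(
    design: AmpliconDesign,
    edits: Iterable[tuple[CdnaPosition | str | int, str, str]],
) -> VariantKey:
    """Build a canonical :class:`VariantKey`, verifying each edit's ref base."""
    canon = []
    for cp, ref, alt in edits:
        cp = CdnaPosition.parse(cp)
        p = design.to_amplicon(cp)
        if design.reference_seq[p] != ref:
            raise DesignError(
                f"ref mismatch at {cp}: reference has {design.reference_seq[p]}"
            )
        if ref == alt:
            continue
        canon.append((cp, ref, alt))
    canon.sort(key=lambda t: (t[0].base, t[0].offset))
    key = VariantKey(design.amplicon_id, tuple(canon), _hgvs_c(design, canon))
    cons = annotate_consequence(design, key)
    return VariantKey(design.amplicon_id, tuple(canon), key.hgvs_c, cons.hgvs_p)


def variant_key_from_amplicon_edits(
    design: AmpliconDesign, edits: Iterable[tuple[int, str, str]]
) -> VariantKey:
    """As :func:`make_variant_key` but with amplicon-coordinate edits."""
    return make_variant_key(
        design, [(design.map_position(p), ref, alt) for p, ref, alt in edits]
    )


def annotate_consequence(design: AmpliconDesign, key: VariantKey) -> Consequence:
    """Classify a variant with the standard nuclear codon table.

    Multi-base replacements within a codon are translated as a unit.  Edits
    at the first/last two intronic bases are labelled ``splice_region``;
    deeper intronic edits are ``intronic``.
    """
    if key.is_marker_only:
        return Consequence("synonymous")
    intronic = [e for e in key.edits if not e[0].is_exonic]
    if intronic:
        if any(abs(cp.offset) <= 2 for cp, _, _ in intronic):
            return Consequence("splice_region")
        if len(intronic) == len(key.edits):
            return Consequence("intronic")
        return Consequence("splice_region")
    for cp, ref, alt in key.edits:
        p = design.to_amplicon(cp)
        if design.reference_seq[p] != ref:
            raise DesignError(f"variant/design inconsistency at {cp}")
    codons = sorted({(cp.base - 1) // 3 + 1 for cp, _, _ in key.edits})
    alt_seq = design.apply_edits(key.edits)
    try:
        aa_refs = [str(Seq(design.wt_codon(a)).translate()) for a in codons]
        aa_alts = [
            str(Seq("".join(alt_seq[p] for p in design.codon_positions(a))).translate())
            for a in codons
        ]
    except CoordinateError:
        # codon truncated by the amplicon boundary: the neighboring exon is
        # not part of a single-amplicon design, so the substitution cannot
        # be confirmed synonymous or nonsense; annotate conservatively.
        return Consequence("missense")
    for a, r, q in zip(codons, aa_refs, aa_alts):
        if q == "*":
            return Consequence("nonsense", r, "*", a)
    for a, r, q in zip(codons, aa_refs, aa_alts):
        if r != q:
            return Consequence("missense", r, q, a)
    return Consequence("synonymous", aa_refs[0], aa_refs[0], codons[0])


def enumerate_codon_library(design: AmpliconDesign, aa_number: int) -> list[VariantKey]:
    """All 63 non-wild-type codon replacements at one saturated residue.

    The degenerate NNN repair template yields 4**3 codons; the wild-type
    codon is represented downstream by the marker-only key, so it is not
    returned here.
    """
    positions = design.codon_positions(aa_number)
    s, e = design.target_region
    if not all(s <= p < e for p in positions):
        raise DesignError(f"codon {aa_number} not fully inside the target region")
    if any(positions[k + 1] != positions[k] + 1 for k in range(2)):
        raise DesignError(f"codon {aa_number} spans an exon boundary; unsupported")
    wt = design.wt_codon(aa_number)
    keys = []
    for b1 in "ACGT":
        for b2 in "ACGT":
            for b3 in "ACGT":
                alt = b1 + b2 + b3
                if alt == wt:
                    continue
                edits = [
                    (CdnaPosition(3 * aa_number - 2 + k), wt[k], alt[k])
                    for k in range(3)
                    if wt[k] != alt[k]
                ]
                keys.append(make_variant_key(design, edits))
    return keys


def enumerate_snv_library(
    design: AmpliconDesign,
    start: str | int | CdnaPosition,
    end: str | int | CdnaPosition,
) -> list[VariantKey]:
    """All single-nucleotide variants across a (c.-coordinate) region.

    ``start`` and ``end`` are inclusive and may be intronic
    (``"6938-12"``, ``"7007+7"``).  Three SNVs per reference base.
    """
    a0 = design.to_amplicon(start)
    a1 = design.to_amplicon(end)
    if a1 < a0:
        raise ValueError("inverted interval")
    keys = []
    for p in range(a0, a1 + 1):
        ref = design.reference_seq[p]
        cp = design.map_position(p)
        for alt in "ACGT":
            if alt != ref:
                keys.append(make_variant_key(design, [(cp, ref, alt)]))
    return keys
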